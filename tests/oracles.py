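"""Brute-force reference implementations used as independent oracles.

Every function here recomputes a package operation by the most literal
possible method (explicit loops, exhaustive enumeration) and must stay
independent of the implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np


def brute_rdf(trajectory, host_token: str, guest_token: str,
              bin_width: float, r_max: float) -> np.ndarray:
    """g(r) by explicit per-frame pair counting and shell normalization."""
    top = trajectory.topology
    hi = top.index_of(host_token)
    gi = top.index_of(guest_token)
    n_bins = int(round(r_max / bin_width))
    counts = np.zeros(n_bins)
    for f in range(trajectory.n_frames):
        d = math.dist(trajectory.coords[f][hi], trajectory.coords[f][gi])
        k = int(d / bin_width)
        if k < n_bins:
            counts[k] += 1
    box = top.box_edge
    g = np.zeros(n_bins)
    for k in range(n_bins):
        r_lo, r_hi = k * bin_width, (k + 1) * bin_width
        shell = 4.0 / 3.0 * math.pi * (r_hi ** 3 - r_lo ** 3)
        g[k] = counts[k] / trajectory.n_frames / shell / (1.0 / box ** 3)
    return g


def brute_detect(coords: np.ndarray, topology, target_indices,
                 d_max: float = 3.5, alpha_min: float = 100.0) -> set:
    """All passing (donor, hydrogen, acceptor) token triples by triple loop."""

    def ang(a, h, d):
        u = coords[a] - coords[h]
        w = coords[d] - coords[h]
        c = np.dot(u, w) / (np.linalg.norm(u) * np.linalg.norm(w))
        return math.degrees(math.acos(max(-1.0, min(1.0, c))))

    og = topology.index_of("HOR.O_g")
    hg = topology.index_of("HOR.H_g")
    found = set()
    for t in target_indices:
        if math.dist(coords[t], coords[og]) < d_max and ang(t, hg, og) > alpha_min:
            found.add(("HOR.O_g", "HOR.H_g", topology.token_of(t)))
    for dheavy, hyd in topology.donors:
        if dheavy == og or dheavy not in set(target_indices):
            continue
        if topology.atoms[dheavy].element == "C":
            continue
        if math.dist(coords[og], coords[dheavy]) < d_max \
                and ang(og, hyd, dheavy) > alpha_min:
            found.add((topology.token_of(dheavy), topology.token_of(hyd),
                       "HOR.O_g"))
    return found


def brute_surface(x, y, bin_width: float) -> dict:
    """Cell -> percent mapping by double loop with floor binning at origin 0."""
    cells: dict[tuple[int, int], int] = {}
    for xi, yi in zip(x, y):
        key = (math.floor(xi / bin_width), math.floor(yi / bin_width))
        cells[key] = cells.get(key, 0) + 1
    n = len(x)
    return {k: 100.0 * v / n for k, v in cells.items()}


def brute_occupancy(positions: np.ndarray, origin: np.ndarray,
                    spacing: float, shape) -> np.ndarray:
    """Voxel counts by per-point floor assignment."""
    counts = np.zeros(shape, dtype=int)
    for p in positions:
        i, j, k = ((p - origin) / spacing).astype(int)
        counts[i, j, k] += 1
    return counts


def brute_bias(centers, height: float, width: float, points) -> np.ndarray:
    """Naive double-loop Gaussian-hill summation."""
    out = np.zeros(len(points))
    for i, (sx, sy) in enumerate(points):
        acc = 0.0
        for cx, cy in centers:
            acc += height * math.exp(-((sx - cx) ** 2 + (sy - cy) ** 2)
                                     / (2.0 * width ** 2))
        out[i] = acc
    return out


def brute_minimax_barrier(f: np.ndarray, start, goal) -> float:
    """Exhaustive minimax path level between two cells (8-connectivity).

    Finds the smallest threshold t such that start and goal are connected
    through cells with value <= t, by scanning thresholds in sorted order
    with BFS connectivity checks.
    """
    values = np.unique(f)
    n1, n2 = f.shape
    for t in values:
        mask = f <= t
        if not (mask[start] and mask[goal]):
            continue
        seen = {start}
        stack = [start]
        while stack:
            i, j = stack.pop()
            if (i, j) == goal:
                return float(t)
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    ii, jj = i + di, j + dj
                    if 0 <= ii < n1 and 0 <= jj < n2 and mask[ii, jj] \
                            and (ii, jj) not in seen:
                        seen.add((ii, jj))
                        stack.append((ii, jj))
    raise AssertionError("unreachable: full grid always connects")
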