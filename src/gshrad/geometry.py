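"""Geometric kernels: superposition, RMSD, gyration radius, HT metrics.

Distances are Euclidean in Angstrom with no periodic wrapping; the only
place the simulation box matters (the radial distribution function) handles
minimum-image separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .topology import MASSES, Topology

__all__ = [
    "SuperpositionResult",
    "HTMetrics",
    "GeometryError",
    "kabsch_superpose",
    "rmsd_series",
    "radius_of_gyration",
    "ht_metrics",
    "angle",
    "dihedral",
]


class GeometryError(ValueError):
    pass


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid superposition of a mobile onto a reference subset.

    ``rotation`` (3x3, proper: det = +1) and ``translation`` map mobile
    coordinates onto the reference frame via ``x @ rotation.T + translation``;
    ``rmsd`` is the minimum least-squares RMSD over the subset.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass(frozen=True)
class HTMetrics:
    """Head-tail compactness metrics (both in Angstrom, both >= 0)."""

    ht: float
    cys_ht: float


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     atom_subset: Sequence[int] | None = None) -> SuperpositionResult:
    """Least-squares rigid superposition (Kabsch, via SVD).

    ``atom_subset`` selects the rows used for the fit (default: all).  The
    returned RMSD is the global minimum over proper rigid transforms.
    Raises :class:`GeometryError` for fewer than 3 fit atoms or degenerate
    (collinear) geometry.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if atom_subset is not None:
        sub = list(atom_subset)
        p, q = mobile[sub], reference[sub]
    else:
        p, q = mobile, reference
    if p.shape != q.shape or p.ndim != 2 or p.shape[1] != 3:
        raise GeometryError("coordinate subsets must both be (n, 3)")
    if len(p) < 3:
        raise GeometryError("superposition needs at least 3 atoms")
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    p0, q0 = p - pc, q - qc
    h = p0.T @ q0
    u, s, vt = np.linalg.svd(h)
    # rank < 2 means all fit atoms are collinear: rotation about the line
    # is unconstrained
    if np.sum(s > 1e-10 * max(s[0], 1e-300)) < 2:
        raise GeometryError("degenerate (collinear) fit geometry")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    moved = p0 @ rot.T
    rmsd = math.sqrt(np.mean(np.sum((moved - q0) ** 2, axis=1)))
    translation = qc - pc @ rot.T
    return SuperpositionResult(rotation=rot, translation=translation, rmsd=rmsd)


def rmsd_series(trajectory, reference_coords: np.ndarray,
                subset: Sequence[int]) -> np.ndarray:
    """Per-frame minimum RMSD (A) of ``subset`` atoms vs a reference frame."""
    subset = list(subset)
    if not subset:
        raise GeometryError("empty atom subset")
    ref = np.asarray(reference_coords, dtype=float)
    out = np.empty(trajectory.n_frames)
    for i, coords in enumerate(trajectory.coords):
        out[i] = kabsch_superpose(coords, ref, subset).rmsd
    return out


def radius_of_gyration(coords: np.ndarray, subset: Sequence[int],
                       masses: np.ndarray | None = None,
                       mass_weighted: bool = True,
                       topology: Topology | None = None) -> float:
    """Radius of gyration sqrt(sum w|r - rbar|^2 / sum w) over ``subset``.

    Mass weighting (the default, matching common trajectory-analysis tools)
    needs either explicit ``masses`` for the subset or a ``topology`` to
    look elements up from.
    """
    subset = list(subset)
    if not subset:
        raise GeometryError("empty atom subset")
    r = np.asarray(coords, dtype=float)[subset]
    if mass_weighted:
        if masses is None:
            if topology is None:
                raise GeometryError("mass weighting needs masses or a topology")
            masses = np.array([MASSES[topology.atoms[i].element] for i in subset])
        w = np.asarray(masses, dtype=float)
    else:
        w = np.ones(len(subset))
    center = (w[:, None] * r).sum(axis=0) / w.sum()
    return math.sqrt(float((w * np.sum((r - center) ** 2, axis=1)).sum() / w.sum()))


def rgyr_series(trajectory, subset: Sequence[int],
                mass_weighted: bool = True) -> np.ndarray:
    """Per-frame radius of gyration over ``subset``."""
    top = trajectory.topology
    masses = np.array([MASSES[top.atoms[i].element] for i in subset]) \
        if mass_weighted else None
    return np.array([
        radius_of_gyration(c, subset, masses=masses, mass_weighted=mass_weighted)
        for c in trajectory.coords
    ])


def ht_metrics(coords: np.ndarray, topology: Topology,
               cys_ht_carboxylate_only: bool = False) -> HTMetrics:
    """Head-tail (HT) and thiol head-tail (CYS-HT) distances for one frame.

    HT is the minimum over the six declared GLY-terminus / GGL-terminus atom
    pairs; CYS-HT is the minimum distance from CYS.SG to the five head/tail
    atoms (or to the four carboxylate oxygens only, under the narrower
    reading selected by ``cys_ht_carboxylate_only``).
    """
    coords = np.asarray(coords, dtype=float)
    try:
        pairs = topology.pair_selections["ht_head_tail"]
        sg = topology.index_of("CYS.SG")
        targets = list(topology.selections["cys_ht_targets"])
    except KeyError as exc:  # missing atom or selection
        raise GeometryError(f"topology lacks head-tail atoms: {exc}") from exc
    if cys_ht_carboxylate_only:
        targets = [t for t in targets if topology.atoms[t].atom_name in ("OT1", "OT2")]
    ht = min(float(np.linalg.norm(coords[i] - coords[j])) for i, j in pairs)
    cys_ht = min(float(np.linalg.norm(coords[sg] - coords[t])) for t in targets)
    return HTMetrics(ht=ht, cys_ht=cys_ht)


def ht_series(trajectory, **kwargs) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame (HT, CYS-HT) arrays."""
    vals = [ht_metrics(c, trajectory.topology, **kwargs) for c in trajectory.coords]
    return (np.array([v.ht for v in vals]), np.array([v.cys_ht for v in vals]))


def angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c at vertex b, in degrees within [0, 180]."""
    u = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    w = np.asarray(c, dtype=float) - np.asarray(b, dtype=float)
    nu, nw = np.linalg.norm(u), np.linalg.norm(w)
    if nu == 0.0 or nw == 0.0:
        raise GeometryError("zero-length angle arm")
    cosv = float(np.dot(u, w) / (nu * nw))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosv))))


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral p0-p1-p2-p3 in degrees (IUPAC convention)."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return math.degrees(math.atan2(y, x))


def metric_table(trajectory, values: np.ndarray, name: str = "value"):
    """Per-frame metric as a DataFrame with columns frame, time_ps, value."""
    import pandas as pd

    df = pd.DataFrame({
        "frame": np.arange(trajectory.n_frames),
        "time_ps": trajectory.times,
        "value": values,
    })
    df.attrs["metric"] = name
    return df
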