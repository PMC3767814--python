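"""2D population surfaces, difference surfaces and 3D guest occupancy.

Percentage-distribution surfaces bin two per-frame series (RMSD vs Rgyr,
or HT vs CYS-HT) into half-open cells ``[origin + k*w, origin + (k+1)*w)``
with origins fixed at 0.0 A, so standard cell bounds such as
[1.75, 2.00) x [3.75, 4.00) fall on bin edges with the default 0.25 A
width.  Each cell holds 100 x (frames in cell) / (total frames).

The occupancy grid superposes every selected frame onto a reference frame
by the host heavy atoms and accumulates the transformed guest position
into voxels, yielding the volumetric map of where the radical resides
around the host.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import kabsch_superpose
from .topology import select

__all__ = [
    "Surface2D",
    "DifferenceSurface",
    "OccupancyGrid",
    "population_surface",
    "difference_surface",
    "modal_cell",
    "representative_structure",
    "occupancy_grid",
]

DEFAULT_BIN_WIDTH = 0.25


@dataclass
class Surface2D:
    """Percentage distribution of frames over a 2D histogram.

    ``percent[ix, iy]`` covers the half-open cell starting at
    ``(x_origin + ix * bin_width_x, y_origin + iy * bin_width_y)``;
    cells sum to 100.
    """

    x_name: str
    y_name: str
    bin_width_x: float
    bin_width_y: float
    x_origin: float
    y_origin: float
    percent: np.ndarray
    n_frames: int = 0

    def to_frame(self) -> pd.DataFrame:
        nx, ny = self.percent.shape
        xs = self.x_origin + self.bin_width_x * np.arange(nx)
        ys = self.y_origin + self.bin_width_y * np.arange(ny)
        return pd.DataFrame(self.percent, index=pd.Index(xs, name=self.x_name),
                            columns=pd.Index(ys, name=self.y_name))


@dataclass
class DifferenceSurface:
    """Cellwise difference a - b of two aligned surfaces (signed percent)."""

    x_name: str
    y_name: str
    bin_width_x: float
    bin_width_y: float
    x_origin: float
    y_origin: float
    delta: np.ndarray
    max_abs: float


@dataclass
class OccupancyGrid:
    """3D voxel counts of guest positions after host superposition."""

    origin: np.ndarray
    spacing: float
    counts: np.ndarray
    frame_total: int

    @property
    def values(self) -> np.ndarray:
        return self.counts


def population_surface(x_series, y_series, bin_width: float = DEFAULT_BIN_WIDTH,
                       bin_width_y: float | None = None,
                       x_name: str = "x", y_name: str = "y",
                       origin: float = 0.0) -> Surface2D:
    """Bin two equal-length per-frame series into a percentage surface."""
    x = np.asarray(x_series, dtype=float)
    y = np.asarray(y_series, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("series must be equal-length 1D arrays")
    if x.size == 0:
        raise ValueError("empty series")
    wx = float(bin_width)
    wy = float(bin_width if bin_width_y is None else bin_width_y)
    if wx <= 0 or wy <= 0:
        raise ValueError("bin widths must be positive")
    ix = np.floor((x - origin) / wx).astype(int)
    iy = np.floor((y - origin) / wy).astype(int)
    x0, y0 = ix.min(), iy.min()
    counts = np.zeros((ix.max() - x0 + 1, iy.max() - y0 + 1))
    np.add.at(counts, (ix - x0, iy - y0), 1.0)
    return Surface2D(
        x_name=x_name, y_name=y_name, bin_width_x=wx, bin_width_y=wy,
        x_origin=origin + x0 * wx, y_origin=origin + y0 * wy,
        percent=100.0 * counts / x.size, n_frames=int(x.size),
    )


def _offset(origin_a: float, origin_b: float, width: float) -> int:
    k = (origin_a - origin_b) / width
    if abs(k - round(k)) > 1e-6:
        raise ValueError("surface origins are not on a common bin lattice")
    return int(round(k))


def difference_surface(a: Surface2D, b: Surface2D) -> DifferenceSurface:
    """Cellwise a - b over the union of occupied ranges, plus max |delta|."""
    if not math.isclose(a.bin_width_x, b.bin_width_x) or \
            not math.isclose(a.bin_width_y, b.bin_width_y):
        raise ValueError("incompatible bin widths")
    wx, wy = a.bin_width_x, a.bin_width_y
    ax0 = _offset(a.x_origin, b.x_origin, wx)  # a's origin in b-lattice units
    ay0 = _offset(a.y_origin, b.y_origin, wy)
    # union lattice, in units of b's origin
    x_lo = min(ax0, 0)
    y_lo = min(ay0, 0)
    x_hi = max(ax0 + a.percent.shape[0], b.percent.shape[0])
    y_hi = max(ay0 + a.percent.shape[1], b.percent.shape[1])
    delta = np.zeros((x_hi - x_lo, y_hi - y_lo))
    delta[ax0 - x_lo:ax0 - x_lo + a.percent.shape[0],
          ay0 - y_lo:ay0 - y_lo + a.percent.shape[1]] += a.percent
    delta[-x_lo:-x_lo + b.percent.shape[0],
          -y_lo:-y_lo + b.percent.shape[1]] -= b.percent
    return DifferenceSurface(
        x_name=a.x_name, y_name=a.y_name, bin_width_x=wx, bin_width_y=wy,
        x_origin=b.x_origin + x_lo * wx, y_origin=b.y_origin + y_lo * wy,
        delta=delta, max_abs=float(np.abs(delta).max()),
    )


@dataclass(frozen=True)
class ModalCell:
    """The most populated surface cell with its bounds and percentage."""

    x_lo: float
    x_hi: float
    y_lo: float
    y_hi: float
    percent: float
    ix: int
    iy: int

    def contains(self, x: float, y: float) -> bool:
        return self.x_lo <= x < self.x_hi and self.y_lo <= y < self.y_hi


def modal_cell(surface: Surface2D) -> ModalCell:
    """Cell with maximum percentage; ties resolve to the lowest (x, y) origin."""
    p = surface.percent
    best = np.max(p)
    # argmax over C-ordered array already picks lowest ix, then iy, on ties
    ix, iy = np.unravel_index(int(np.argmax(p)), p.shape)
    return ModalCell(
        x_lo=surface.x_origin + ix * surface.bin_width_x,
        x_hi=surface.x_origin + (ix + 1) * surface.bin_width_x,
        y_lo=surface.y_origin + iy * surface.bin_width_y,
        y_hi=surface.y_origin + (iy + 1) * surface.bin_width_y,
        percent=float(best), ix=int(ix), iy=int(iy),
    )


def representative_structure(trajectory, x_series, y_series,
                             cell: ModalCell) -> int:
    """Frame in ``cell`` closest (Euclidean, A) to the in-cell series means.

    Ties resolve to the earliest frame.  This is the standard selection of
    a representative conformer from the most populated region.
    """
    x = np.asarray(x_series, dtype=float)
    y = np.asarray(y_series, dtype=float)
    mask = (x >= cell.x_lo) & (x < cell.x_hi) & (y >= cell.y_lo) & (y < cell.y_hi)
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        raise ValueError("no frames fall in the requested cell")
    mx, my = x[idx].mean(), y[idx].mean()
    dist2 = (x[idx] - mx) ** 2 + (y[idx] - my) ** 2
    return int(idx[np.argmin(dist2)])  # argmin returns first minimum: earliest


def occupancy_grid(trajectory, frame_subset, align_subset="host_heavy",
                   guest_atom: str = "HOR.O_g", spacing: float = 0.5,
                   reference_frame: int = 0, margin: float = 2.0) -> OccupancyGrid:
    """Voxelized guest occurrence around the superposed host.

    Every frame in ``frame_subset`` is superposed onto ``reference_frame``
    by ``align_subset`` (default: host heavy atoms); the transformed guest
    position increments one voxel.  The grid is auto-sized to cover all
    guest positions plus ``margin`` on each side, so the total count equals
    the number of selected frames.
    """
    frame_subset = list(frame_subset)
    if not frame_subset:
        raise ValueError("empty frame subset")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    top = trajectory.topology
    align = select(top, align_subset) if isinstance(align_subset, str) else list(align_subset)
    gsel = select(top, guest_atom)
    if len(gsel) != 1:
        raise ValueError(f"{guest_atom!r} must resolve to a single atom")
    gi = gsel[0]
    ref = trajectory.coords[reference_frame]
    pos = np.empty((len(frame_subset), 3))
    for k, f in enumerate(frame_subset):
        sup = kabsch_superpose(trajectory.coords[f], ref, align)
        pos[k] = sup.transform(trajectory.coords[f][gi])
    origin = pos.min(axis=0) - margin
    idx = np.floor((pos - origin) / spacing).astype(int)
    shape = idx.max(axis=0) + 1 + int(np.ceil(margin / spacing))
    counts = np.zeros(tuple(shape), dtype=int)
    np.add.at(counts, (idx[:, 0], idx[:, 1], idx[:, 2]), 1)
    return OccupancyGrid(origin=origin, spacing=float(spacing), counts=counts,
                         frame_total=len(frame_subset))
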