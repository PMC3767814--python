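"""Standard metadynamics on two distance collective variables, desk scale.

The engine reconstructs a free-energy surface over the two guest-host
distances d(OT1-OH) and d(SG-OH) by depositing repulsive Gaussian hills
along an overdamped Langevin walker on an analytic 2D model potential.
Hills use the fixed height 0.03 kcal/mol and width 0.05 A with
half-harmonic walls at 6 A on each variable; the deposition pace and the
walker mobility are configurable.

The molecular system is never re-simulated: the bundled
:func:`double_well_channel` potential has the qualitative shape of the
recognition surface (a channel with a shallow outer minimum near
(3.6, 4.3) A, the global minimum near (2.65, 3.65) A and a sub-kcal/mol
barrier between them), and every quantitative check runs against the
direct Boltzmann reference of that analytic potential.

Because each hill is tiny, tens of thousands of hills are needed to fill
the surface; the sampler therefore keeps the bias and its gradient on a
fine internal grid, updated locally per hill, while
:func:`reconstruct_fes` always evaluates exact Gaussian sums.  The free
energy estimate can average the bias over the tail of the run, which
damps the oscillation of non-tempered metadynamics around -F.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KB_KCAL",
    "CollectiveVariables",
    "HillSchedule",
    "Hills",
    "FESGrid",
    "Minimum",
    "Barrier",
    "MinimaResult",
    "MetadResult",
    "deposit_bias",
    "run_metadynamics",
    "reconstruct_fes",
    "boltzmann_reference",
    "locate_minima",
    "ModelPotential2D",
    "double_well_channel",
    "harmonic_well",
    "flat_potential",
    "run_double_well_benchmark",
]

#: Boltzmann constant in kcal/mol/K
KB_KCAL = 0.0019872


@dataclass(frozen=True)
class CollectiveVariables:
    """One point in CV space: the two guest-host distances (A, both > 0)."""

    cv1: float  # d(OT1 - OH)
    cv2: float  # d(SG - OH)

    def __post_init__(self):
        if self.cv1 <= 0 or self.cv2 <= 0:
            raise ValueError("collective variables are distances (> 0)")


@dataclass(frozen=True)
class HillSchedule:
    """Gaussian hill parameters and wall placement.

    Defaults are the production settings of the reference protocol:
    0.03 kcal/mol hills of width 0.05 A, walls at 6 A.  ``deposit_stride``
    is in sampler steps; the wall is half-harmonic with
    ``wall_force_constant`` beyond ``wall_position`` on each CV.
    """

    height: float = 0.03
    width: float = 0.05
    deposit_stride: int = 500
    wall_position: float = 6.0
    wall_force_constant: float = 100.0

    def __post_init__(self):
        if self.height < 0 or self.width <= 0 or self.wall_position <= 0:
            raise ValueError("invalid hill schedule")


@dataclass
class Hills:
    """Deposited hills: centers (n, 2) plus shared height and width."""

    height: float
    width: float
    centers: list = field(default_factory=list)
    steps: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.centers)

    def center_array(self) -> np.ndarray:
        return np.asarray(self.centers, dtype=float).reshape(-1, 2)

    def bias(self, s1, s2, weights: np.ndarray | None = None) -> np.ndarray:
        """Exact bias potential V(s) = sum_h w_h * h * exp(-|s-c|^2/2w^2).

        ``s1``/``s2`` broadcast; evaluation is a direct (chunked) sum over
        all hills, independent of the sampler's internal grid.
        """
        s1 = np.asarray(s1, dtype=float)
        s2 = np.asarray(s2, dtype=float)
        out = np.zeros(np.broadcast(s1, s2).shape)
        if len(self) == 0:
            return out
        c = self.center_array()
        w = np.ones(len(c)) if weights is None else np.asarray(weights, dtype=float)
        inv2w2 = 1.0 / (2.0 * self.width ** 2)
        flat1 = np.broadcast_to(s1, out.shape).ravel()
        flat2 = np.broadcast_to(s2, out.shape).ravel()
        acc = np.zeros(flat1.size)
        for k in range(0, len(c), 4096):
            cc = c[k:k + 4096]
            ww = w[k:k + 4096]
            d2 = (flat1[:, None] - cc[None, :, 0]) ** 2 \
                + (flat2[:, None] - cc[None, :, 1]) ** 2
            acc += (np.exp(-d2 * inv2w2) * ww[None, :]).sum(axis=1)
        return (self.height * acc).reshape(out.shape)

    def to_frame(self):
        import pandas as pd

        c = self.center_array()
        return pd.DataFrame({
            "step": self.steps, "cv1": c[:, 0], "cv2": c[:, 1],
            "height": self.height, "width": self.width,
        })


def deposit_bias(hills: Hills, cv: CollectiveVariables,
                 schedule: HillSchedule, step: int = 0) -> Hills:
    """Append one hill centered at ``cv``; returns the updated hill list."""
    if cv.cv1 > schedule.wall_position or cv.cv2 > schedule.wall_position:
        raise ValueError("hill center outside the wall region")
    hills.centers.append((cv.cv1, cv.cv2))
    hills.steps.append(step)
    return hills


@dataclass
class FESGrid:
    """Free-energy estimate over a CV grid, min-shifted to zero."""

    cv1_axis: np.ndarray
    cv2_axis: np.ndarray
    free_energy: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.free_energy,
                            index=pd.Index(self.cv1_axis, name="cv1"),
                            columns=pd.Index(self.cv2_axis, name="cv2"))


# ---------------------------------------------------------------------------
# model potentials

class ModelPotential2D:
    """Analytic 2D potential: Gaussian basins plus a repulsive core.

    ``value(x, y)`` is vectorized and in kcal/mol.  The short-range core
    (half-harmonic below ``core_position`` on each axis) stands in for the
    excluded volume that keeps two atoms from interpenetrating.
    """

    def __init__(self, depths, centers, sigmas,
                 core_position: float = 1.8, core_k: float = 10.0):
        self.depths = tuple(float(d) for d in depths)
        self.centers = tuple((float(a), float(b)) for a, b in centers)
        self.sigmas = tuple(float(s) for s in sigmas)
        self.core_position = core_position
        self.core_k = core_k

    def value(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        v = np.zeros(np.broadcast(x, y).shape)
        for d, (cx, cy), s in zip(self.depths, self.centers, self.sigmas):
            v = v - d * np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2 * s ** 2))
        lo = self.core_position
        v = v + self.core_k * np.clip(lo - x, 0.0, None) ** 2
        v = v + self.core_k * np.clip(lo - y, 0.0, None) ** 2
        return v

    def __call__(self, x, y):
        return self.value(x, y)

    def minima(self) -> list[tuple[float, float]]:
        """Numerically refined minima, deepest first."""
        from scipy.optimize import minimize

        found = []
        for c in self.centers:
            res = minimize(lambda p: float(self.value(p[0], p[1])), x0=c,
                           method="Nelder-Mead",
                           options={"xatol": 1e-8, "fatol": 1e-12})
            found.append((res.x[0], res.x[1], res.fun))
        found.sort(key=lambda t: t[2])
        return [(x, y) for x, y, _ in found]


def double_well_channel() -> ModelPotential2D:
    """Two-basin channel: outer minimum near (3.6, 4.3) A, global minimum
    near (2.65, 3.65) A, connected by a sub-kcal/mol saddle."""
    return ModelPotential2D(
        depths=(1.2, 1.8),
        centers=((3.6, 4.3), (2.65, 3.65)),
        sigmas=(0.32, 0.30),
    )


def harmonic_well(center=(3.5, 3.5), k: float = 2.0) -> ModelPotential2D:
    """Quadratic single well (for unbiased-sampler checks)."""

    pot = ModelPotential2D(depths=(), centers=(), sigmas=(), core_k=0.0)
    cx, cy = center

    def value(x, y, _k=k):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return 0.5 * _k * ((x - cx) ** 2 + (y - cy) ** 2)

    pot.value = value  # type: ignore[method-assign]
    return pot


def flat_potential() -> ModelPotential2D:
    """Zero potential inside the walls."""
    return ModelPotential2D(depths=(), centers=(), sigmas=(), core_k=0.0)


# ---------------------------------------------------------------------------
# sampler

@dataclass
class MetadResult:
    """Hills plus a subsampled walker trace in CV space."""

    hills: Hills
    cv_trace: np.ndarray
    trace_stride: int
    schedule: HillSchedule
    temperature: float


def run_metadynamics(potential, schedule: HillSchedule, steps: int,
                     temperature: float = 310.0, seed: int = 0,
                     x0: tuple[float, float] | None = None,
                     domain: tuple[float, float] = (1.6, 6.4),
                     mobility: float = 5.0e-4,
                     trace_stride: int = 100) -> MetadResult:
    """Overdamped Langevin walk with periodic hill deposition.

    Update rule per step (``D dt = mobility``, kT from ``temperature``):

        s <- s + (D dt / kT) * F(s) + sqrt(2 D dt) * xi

    with F the force of the model potential plus walls plus current bias,
    reflected at the ``domain`` edges.  A hill is deposited every
    ``deposit_stride`` steps while the walker is inside the wall region.
    Fully reproducible per seed.  Forces are bilinearly interpolated from
    an internal grid (2 pm spacing) carrying the analytic potential and
    the incrementally-updated bias.
    """
    if steps <= 0:
        raise ValueError("steps must be positive")
    lo, hi = domain
    kt = KB_KCAL * temperature
    h_grid = 0.02
    axis = np.arange(lo, hi + h_grid / 2, h_grid)
    n = axis.size
    xg, yg = np.meshgrid(axis, axis, indexing="ij")

    v = np.asarray(potential.value(xg, yg), dtype=float)
    wp, wk = schedule.wall_position, schedule.wall_force_constant
    v = v + wk * np.clip(xg - wp, 0.0, None) ** 2
    v = v + wk * np.clip(yg - wp, 0.0, None) ** 2
    fx_g, fy_g = np.gradient(-v, h_grid, h_grid)

    hills = Hills(height=schedule.height, width=schedule.width)
    rng = np.random.default_rng(seed)
    sig = math.sqrt(2.0 * mobility)
    noise = rng.normal(scale=sig, size=(steps, 2))
    mob_kt = mobility / kt

    if x0 is None:
        x, y = 0.5 * (lo + wp), 0.5 * (lo + wp)
    else:
        x, y = float(x0[0]), float(x0[1])

    inv_h = 1.0 / h_grid
    w2 = schedule.width ** 2
    patch_r = max(2, int(math.ceil(4.0 * schedule.width / h_grid)))
    n_trace = steps // trace_stride
    trace = np.empty((n_trace, 2))
    t_i = 0
    span = hi - lo
    stride = schedule.deposit_stride

    for step in range(steps):
        # bilinear force interpolation
        u = (x - lo) * inv_h
        w = (y - lo) * inv_h
        i0 = int(u)
        j0 = int(w)
        if i0 >= n - 1:
            i0 = n - 2
        if j0 >= n - 1:
            j0 = n - 2
        du = u - i0
        dw = w - j0
        a00 = (1 - du) * (1 - dw)
        a10 = du * (1 - dw)
        a01 = (1 - du) * dw
        a11 = du * dw
        fx = (a00 * fx_g[i0, j0] + a10 * fx_g[i0 + 1, j0]
              + a01 * fx_g[i0, j0 + 1] + a11 * fx_g[i0 + 1, j0 + 1])
        fy = (a00 * fy_g[i0, j0] + a10 * fy_g[i0 + 1, j0]
              + a01 * fy_g[i0, j0 + 1] + a11 * fy_g[i0 + 1, j0 + 1])

        x = x + mob_kt * fx + noise[step, 0]
        y = y + mob_kt * fy + noise[step, 1]
        if not (math.isfinite(x) and math.isfinite(y)):
            raise RuntimeError(f"divergent sampler coordinate at step {step}")
        # reflect at the domain edges
        if x < lo:
            x = lo + (lo - x)
        elif x > hi:
            x = hi - (x - hi)
        if y < lo:
            y = lo + (lo - y)
        elif y > hi:
            y = hi - (y - hi)
        if x < lo or x > hi:
            x = lo + (x - lo) % span
        if y < lo or y > hi:
            y = lo + (y - lo) % span

        if trace_stride and (step + 1) % trace_stride == 0 and t_i < n_trace:
            trace[t_i] = (x, y)
            t_i += 1

        if schedule.height > 0.0 and (step + 1) % stride == 0 \
                and lo <= x <= wp and lo <= y <= wp:
            deposit_bias(hills, CollectiveVariables(x, y), schedule, step=step + 1)
            # local bias update on the force grids
            ic = int(round((x - lo) * inv_h))
            jc = int(round((y - lo) * inv_h))
            i_lo, i_hi = max(0, ic - patch_r), min(n, ic + patch_r + 1)
            j_lo, j_hi = max(0, jc - patch_r), min(n, jc + patch_r + 1)
            gx = axis[i_lo:i_hi][:, None] - x
            gy = axis[j_lo:j_hi][None, :] - y
            g = schedule.height * np.exp(-(gx ** 2 + gy ** 2) / (2.0 * w2))
            fx_g[i_lo:i_hi, j_lo:j_hi] += g * gx / w2
            fy_g[i_lo:i_hi, j_lo:j_hi] += g * gy / w2

    return MetadResult(hills=hills, cv_trace=trace[:t_i],
                       trace_stride=trace_stride, schedule=schedule,
                       temperature=temperature)


# ---------------------------------------------------------------------------
# reconstruction and minima

def reconstruct_fes(hills: Hills, axes,
                    time_average_fraction: float | None = None) -> FESGrid:
    """Free-energy estimate F(s) = -V_bias(s), min-shifted to zero.

    With ``time_average_fraction`` f, the estimate averages the bias over
    the checkpoints after each of the last f*N hills, which is equivalent
    to weighting hill j by min(N - j + 1, K)/K (K the number of averaged
    checkpoints).  This removes most of the oscillation of non-tempered
    metadynamics around the true -F.
    """
    if len(hills) == 0:
        raise ValueError("no hills to reconstruct from")
    ax1, ax2 = (np.asarray(a, dtype=float) for a in axes)
    weights = None
    if time_average_fraction is not None:
        n_h = len(hills)
        k = max(1, int(round(time_average_fraction * n_h)))
        n0 = n_h - k + 1  # checkpoints after hills n0..n_h
        j = np.arange(1, n_h + 1)
        weights = np.minimum(n_h - j + 1, k) / k
    bias = hills.bias(ax1[:, None], ax2[None, :], weights=weights)
    f = -bias
    f -= f.min()
    return FESGrid(cv1_axis=ax1, cv2_axis=ax2, free_energy=f)


def boltzmann_reference(potential, axes, temperature: float = 310.0) -> FESGrid:
    """Direct Boltzmann-integration reference on the same grid.

    Computes the normalized stationary density p ~ exp(-V/kT) of the
    overdamped sampler and returns F = -kT ln p, min-shifted; for a 2D
    model potential this reproduces the potential itself up to a constant.
    """
    ax1, ax2 = (np.asarray(a, dtype=float) for a in axes)
    kt = KB_KCAL * temperature
    v = np.asarray(potential.value(ax1[:, None], ax2[None, :]), dtype=float)
    logp = -v / kt
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    f = -kt * np.log(p)
    f -= f.min()
    return FESGrid(cv1_axis=ax1, cv2_axis=ax2, free_energy=f)


@dataclass(frozen=True)
class Minimum:
    cv1: float
    cv2: float
    value: float
    i: int
    j: int


@dataclass(frozen=True)
class Barrier:
    """Minimax-path barrier from ``minimum`` up to where it merges with a
    deeper basin: barrier = saddle value - the shallower minimum."""

    minimum: int
    merges_with: int
    saddle_value: float
    height: float


@dataclass
class MinimaResult:
    minima: list
    barriers: list


def locate_minima(fes: FESGrid, min_prominence: float = 0.0) -> MinimaResult:
    """Grid-local minima (8-neighborhood) with minimax-path barriers.

    Cells are flooded in order of increasing free energy (a watershed /
    union-find pass); the saddle between two basins is the level at which
    they first connect, and a basin's prominence is that level minus its
    minimum.  Basins with prominence below ``min_prominence`` are absorbed
    into their deeper neighbor.  Minima are returned deepest first.
    """
    f = fes.free_energy
    n1, n2 = f.shape
    order = np.argsort(f, axis=None, kind="stable")
    parent = -np.ones(f.size, dtype=int)
    comp_min = {}

    def find(a):
        root = a
        while parent[root] != root:
            root = parent[root]
        while parent[a] != root:
            parent[a], a = root, parent[a]
        return root

    merges = []  # (root kept, root absorbed, saddle value)
    seeds = []
    flat = f.ravel()
    for cell in order:
        i, j = divmod(int(cell), n2)
        neigh_roots = set()
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if di == 0 and dj == 0:
                    continue
                ii, jj = i + di, j + dj
                if 0 <= ii < n1 and 0 <= jj < n2:
                    nb = ii * n2 + jj
                    if parent[nb] >= 0:
                        neigh_roots.add(find(nb))
        if not neigh_roots:
            parent[cell] = cell
            comp_min[cell] = float(flat[cell])
            seeds.append(int(cell))
            continue
        roots = sorted(neigh_roots, key=lambda r: comp_min[r])
        deepest = roots[0]
        parent[cell] = deepest
        for r in roots[1:]:
            merges.append((deepest, r, float(flat[cell])))
            parent[r] = deepest

    saddle = {}  # absorbed seed root -> (kept root, saddle value)
    for kept, absorbed, val in merges:
        saddle[absorbed] = (kept, val)

    minima = []
    barriers = []
    kept_index = {}
    for s in seeds:
        prom = math.inf if s not in saddle else saddle[s][1] - comp_min[s]
        if prom < min_prominence:
            continue
        i, j = divmod(s, n2)
        kept_index[s] = len(minima)
        minima.append(Minimum(cv1=float(fes.cv1_axis[i]),
                              cv2=float(fes.cv2_axis[j]),
                              value=comp_min[s], i=i, j=j))
    ordering = sorted(range(len(minima)), key=lambda k: minima[k].value)
    rank = {old: new for new, old in enumerate(ordering)}
    minima = [minima[k] for k in ordering]
    for s, idx in kept_index.items():
        if s in saddle:
            kept, val = saddle[s]
            target = kept_index.get(kept)
            if target is not None:
                barriers.append(Barrier(
                    minimum=rank[idx], merges_with=rank[target],
                    saddle_value=val, height=val - comp_min[s]))
    return MinimaResult(minima=minima, barriers=barriers)


def run_double_well_benchmark(seed: int = 1, steps: int = 2_000_000,
                              deposit_stride: int = 25,
                              temperature: float = 310.0,
                              grid_spacing: float = 0.1,
                              time_average_fraction: float = 0.5,
                              region_cutoff: float = 1.5) -> dict:
    """Full benchmark: metadynamics on the double-well channel vs the
    Boltzmann reference.

    Returns the FES, reference, the mean absolute deviation over the
    sampled region (reference free energy within ``region_cutoff`` of its
    minimum), the located minima and the analytic minima.
    """
    pot = double_well_channel()
    schedule = HillSchedule(deposit_stride=deposit_stride)
    result = run_metadynamics(pot, schedule, steps=steps,
                              temperature=temperature, seed=seed)
    axis = np.arange(1.8, 6.0 + grid_spacing / 2, grid_spacing)
    fes = reconstruct_fes(result.hills, (axis, axis), time_average_fraction)
    ref = boltzmann_reference(pot, (axis, axis), temperature)
    region = ref.free_energy <= region_cutoff
    mad = float(np.abs(fes.free_energy - ref.free_energy)[region].mean())
    located = locate_minima(fes, min_prominence=0.15)
    return {
        "fes": fes,
        "reference": ref,
        "mad": mad,
        "region": region,
        "minima": located,
        "analytic_minima": pot.minima(),
        "n_hills": len(result.hills),
        "result": result,
    }
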