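"""Trajectory and volumetric-map I/O.

Supported formats: multi-model PDB (via biotite), extended XYZ (comment
line carries ``time=<ps>``) and the OpenDX scalar-field dialect understood
by common molecular viewers.  Coordinates are Angstrom throughout; no unit
conversion happens at I/O boundaries.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .topology import Topology, TopologyError, build_gsh_oh_topology

__all__ = [
    "Frame",
    "Trajectory",
    "TrajectoryParseError",
    "read_trajectory",
    "write_trajectory",
    "write_dx",
    "read_dx",
]

DEFAULT_STRIDE_PS = 9.8


class TrajectoryParseError(ValueError):
    """Malformed trajectory file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


@dataclass(frozen=True)
class Frame:
    """One trajectory frame: index, time (ps) and per-atom coordinates (A)."""

    index: int
    time: float
    coords: np.ndarray


@dataclass
class Trajectory:
    """Ordered frames over a fixed topology.

    ``coords`` has shape (n_frames, n_atoms, 3); ``times`` is ps, strictly
    increasing with spacing ``stride`` for uniformly sampled data.
    """

    topology: Topology
    coords: np.ndarray
    times: np.ndarray | None = None
    stride: float = DEFAULT_STRIDE_PS

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise TrajectoryParseError("coords must have shape (frames, atoms, 3)")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise TopologyError(
                f"{self.coords.shape[1]} coordinates per frame for a "
                f"{self.topology.n_atoms}-atom topology")
        if not np.all(np.isfinite(self.coords)):
            raise TrajectoryParseError("non-finite coordinates")
        if self.stride <= 0:
            raise ValueError("stride must be positive")
        if self.times is None:
            self.times = np.arange(self.n_frames) * self.stride
        else:
            self.times = np.asarray(self.times, dtype=float)
            if len(self.times) != self.n_frames:
                raise TrajectoryParseError("one time per frame required")
            if self.n_frames > 1 and not np.all(np.diff(self.times) > 0):
                raise TrajectoryParseError("frame times must strictly increase")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def frame(self, i: int) -> Frame:
        return Frame(index=i, time=float(self.times[i]), coords=self.coords[i])

    def __iter__(self) -> Iterator[Frame]:
        return (self.frame(i) for i in range(self.n_frames))

    def __len__(self) -> int:
        return self.n_frames


# ---------------------------------------------------------------------------
# multi-model PDB via biotite

def _to_atom_array_stack(trajectory: Trajectory):
    import biotite.structure as struc

    top = trajectory.topology
    n = top.n_atoms
    arr = struc.AtomArrayStack(trajectory.n_frames, n)
    res_ids = []
    rid = 0
    last = None
    for a in top.atoms:
        if a.residue_label != last:
            rid += 1
            last = a.residue_label
        res_ids.append(rid)
    arr.chain_id = np.array(["A"] * n)
    arr.res_id = np.array(res_ids)
    arr.res_name = np.array([a.residue_label for a in top.atoms])
    arr.atom_name = np.array([a.atom_name for a in top.atoms])
    arr.element = np.array([a.element for a in top.atoms])
    arr.hetero = np.array([True] * n)
    arr.coord = np.asarray(trajectory.coords, dtype=np.float32)
    return arr


def _write_pdb(trajectory: Trajectory, path: Path) -> None:
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile()
    pdb.set_structure(_to_atom_array_stack(trajectory))
    pdb.write(str(path))
    # prepend the topology table (residue, atom, element, charge) as REMARKs
    top = trajectory.topology
    header = ["REMARK 240 GSHRAD TOPOLOGY residue atom element charge"]
    for a in top.atoms:
        header.append(f"REMARK 240 {a.residue_label:>4s} {a.atom_name:>4s} "
                      f"{a.element:>2s} {a.partial_charge:+.3f}")
    body = path.read_text()
    path.write_text("\n".join(header) + "\n" + body)


def _read_pdb(path: Path, topology: Topology, stride: float) -> Trajectory:
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None)
    coords = np.asarray(stack.coord, dtype=float)
    if coords.ndim == 2:  # single model
        coords = coords[None]
    if coords.shape[0] == 0:
        raise TrajectoryParseError("no models in PDB file")
    names = [f"{r}.{a}" for r, a in zip(stack.res_name, stack.atom_name)]
    expected = [a.token for a in topology.atoms]
    if names != expected:
        raise TopologyError("PDB atom records do not match the topology")
    return Trajectory(topology=topology, coords=coords, stride=stride)


# ---------------------------------------------------------------------------
# extended XYZ

def _write_xyz(trajectory: Trajectory, path: Path) -> None:
    top = trajectory.topology
    with open(path, "w") as fh:
        for fr in trajectory:
            fh.write(f"{top.n_atoms}\n")
            fh.write(f"time={fr.time:.4f}\n")
            for a, (x, y, z) in zip(top.atoms, fr.coords):
                fh.write(f"{a.element:<2s} {x:12.6f} {y:12.6f} {z:12.6f}"
                         f"  # {a.token}\n")


_TIME_RE = re.compile(r"time=([-+0-9.eE]+)")


def _read_xyz(path: Path, topology: Topology, stride: float) -> Trajectory:
    frames, times = [], []
    with open(path) as fh:
        lines = fh.readlines()
    i, lineno = 0, 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            natoms = int(lines[i].split()[0])
        except ValueError as exc:
            raise TrajectoryParseError(f"expected atom count, got {lines[i]!r}",
                                       line=i + 1) from exc
        if natoms != topology.n_atoms:
            raise TopologyError(
                f"frame with {natoms} atoms for a {topology.n_atoms}-atom topology")
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        m = _TIME_RE.search(comment)
        times.append(float(m.group(1)) if m else len(frames) * stride)
        block = lines[i + 2:i + 2 + natoms]
        if len(block) < natoms:
            raise TrajectoryParseError("truncated frame", line=len(lines))
        coords = np.empty((natoms, 3))
        for k, ln in enumerate(block):
            parts = ln.split()
            if len(parts) < 4:
                raise TrajectoryParseError(f"malformed atom line {ln!r}",
                                           line=i + 3 + k)
            try:
                coords[k] = [float(parts[1]), float(parts[2]), float(parts[3])]
            except ValueError as exc:
                raise TrajectoryParseError(f"malformed coordinates {ln!r}",
                                           line=i + 3 + k) from exc
        frames.append(coords)
        i += 2 + natoms
    if not frames:
        raise TrajectoryParseError("empty trajectory file")
    return Trajectory(topology=topology, coords=np.array(frames),
                      times=np.array(times), stride=stride)


# ---------------------------------------------------------------------------
# public API

def read_trajectory(path, format: str | None = None,
                    topology: Topology | None = None,
                    stride: float = DEFAULT_STRIDE_PS) -> Trajectory:
    """Read a trajectory from multi-model PDB or extended XYZ.

    ``format`` is ``"pdb"`` / ``"xyz"`` (inferred from the suffix when
    omitted).  ``topology`` defaults to the canonical GSH + radical system;
    the file's atoms must match it in order and naming.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise TrajectoryParseError(f"empty trajectory file {path}")
    if format is None:
        format = "pdb" if path.suffix.lower() in (".pdb", ".ent") else "xyz"
    if topology is None:
        topology = build_gsh_oh_topology()
    if format == "pdb":
        return _read_pdb(path, topology, stride)
    if format == "xyz":
        return _read_xyz(path, topology, stride)
    raise ValueError(f"unknown trajectory format {format!r}")


def write_trajectory(trajectory: Trajectory, path, format: str | None = None) -> None:
    """Write a trajectory as multi-model PDB or extended XYZ."""
    path = Path(path)
    if format is None:
        format = "pdb" if path.suffix.lower() in (".pdb", ".ent") else "xyz"
    if format == "pdb":
        _write_pdb(trajectory, path)
    elif format == "xyz":
        _write_xyz(trajectory, path)
    else:
        raise ValueError(f"unknown trajectory format {format!r}")


def write_dx(grid, path) -> None:
    """Write an occupancy grid as an OpenDX scalar field.

    ``grid`` needs ``origin`` (3,), ``spacing`` (scalar A) and 3D ``counts``
    (or ``values``).  Data follow the DX convention (z varies fastest),
    which matches the row-major layout of ``counts[ix, iy, iz]``.
    """
    data = np.asarray(getattr(grid, "counts", getattr(grid, "values", None)),
                      dtype=float)
    if data is None or data.ndim != 3 or data.size == 0:
        raise ValueError("grid must carry a non-empty 3D data array")
    nx, ny, nz = data.shape
    ox, oy, oz = np.asarray(grid.origin, dtype=float)
    h = float(grid.spacing)
    with open(path, "w") as fh:
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write(f"origin {ox:.6f} {oy:.6f} {oz:.6f}\n")
        fh.write(f"delta {h:.6f} 0.000000 0.000000\n")
        fh.write(f"delta 0.000000 {h:.6f} 0.000000\n")
        fh.write(f"delta 0.000000 0.000000 {h:.6f}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(f"object 3 class array type double rank 0 items {data.size} "
                 "data follows\n")
        flat = data.ravel()
        for k in range(0, data.size, 3):
            fh.write(" ".join(f"{v:.6g}" for v in flat[k:k + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "density" class field\n')
        fh.write('component "positions" value 1\n')
        fh.write('component "connections" value 2\n')
        fh.write('component "data" value 3\n')


def read_dx(path):
    """Minimal OpenDX reader (origin, spacing, values) for round-trip checks."""
    origin = None
    deltas = []
    shape = None
    values: list[float] = []
    n_items = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            s = line.strip()
            if s.startswith("object 1"):
                shape = tuple(int(x) for x in s.split()[-3:])
            elif s.startswith("origin"):
                origin = np.array([float(x) for x in s.split()[1:4]])
            elif s.startswith("delta"):
                deltas.append([float(x) for x in s.split()[1:4]])
            elif s.startswith("object 3"):
                n_items = int(s.split("items")[1].split()[0])
            elif n_items is not None and len(values) < n_items and s \
                    and not s.startswith(("attribute", "object", "component")):
                values.extend(float(x) for x in s.split())
    if shape is None or origin is None or n_items is None:
        raise TrajectoryParseError("not an OpenDX scalar field")
    if len(values) != n_items or int(np.prod(shape)) != n_items:
        raise TrajectoryParseError(
            f"DX data length {len(values)} does not match header {shape}")
    spacing = deltas[0][0] if deltas else 1.0
    return origin, spacing, np.array(values).reshape(shape)
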