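"""Extended reference conformer of GSH built from internal coordinates.

The reference (all backbone torsions trans) serves two roles: it is the
"initial, extended structure" against which heavy-atom RMSD series are
measured, and it is the fixed internal-coordinate template the synthetic
generator perturbs.  Geometry uses standard bond lengths and angles
(C-C 1.53 A, C=O 1.23 A, carboxylate C-O 1.25 A, C-S 1.82 A, amide C-N
1.335 A, tetrahedral/trigonal angles); coordinates are built with the
natural-extension reference frame (NERF) construction.

``ROTATABLE_TORSIONS`` declares the ten single bonds whose rotation moves
heavy atoms (backbone phi/psi-like bonds, the gamma-chain of GGL, the two
carboxylate orientations, the CYS side chain and the thiol S-H).  Amide
bonds are kept planar-trans and are not rotatable.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np

__all__ = [
    "reference_coordinates",
    "ROTATABLE_TORSIONS",
    "torsion_downstream_sets",
    "apply_torsion_deltas",
]

# (atom, bonded-ref a, angle-ref b, torsion-ref c, bond A, angle deg, dihedral deg)
# Atom indices refer to the canonical topology order (see topology._ATOM_TABLE).
_ZMATRIX = [
    (6, 4, 0, None, 1.53, 111.0, None),        # CB  on CA-N plane
    (9, 6, 4, 0, 1.53, 111.0, 180.0),          # CG  anti
    (12, 9, 6, 4, 1.52, 112.0, 180.0),         # CD  anti
    (17, 12, 9, 6, 1.335, 115.0, 180.0),       # CYS.N (amide)
    (13, 12, 9, 6, 1.23, 121.0, 0.0),          # GGL.O opposite CYS.N
    (19, 17, 12, 9, 1.455, 121.0, 180.0),      # CYS.CA (omega trans)
    (18, 17, 12, 9, 1.01, 119.0, 0.0),         # CYS.HN
    (26, 19, 17, 12, 1.53, 110.0, -120.0),     # CYS.C   (phi ~ -120)
    (21, 19, 17, 12, 1.53, 110.0, 120.0),      # CYS.CB
    (20, 19, 17, 12, 1.10, 108.0, 0.0),        # CYS.HA
    (24, 21, 19, 17, 1.82, 114.0, 180.0),      # SG (chi1 anti)
    (22, 21, 19, 17, 1.10, 109.0, 60.0),
    (23, 21, 19, 17, 1.10, 109.0, -60.0),
    (25, 24, 21, 19, 1.34, 96.0, 180.0),       # thiol H
    (28, 26, 19, 17, 1.335, 115.0, 120.0),     # GLY.N  (psi ~ 120)
    (27, 26, 19, 17, 1.23, 121.0, -60.0),      # CYS.O opposite GLY.N
    (29, 28, 26, 19, 1.01, 119.0, 0.0),        # GLY.HN
    (30, 28, 26, 19, 1.455, 121.0, 180.0),     # GLY.CA (omega trans)
    (33, 30, 28, 26, 1.53, 110.0, -120.0),     # GLY.C
    (31, 30, 28, 26, 1.10, 109.0, 120.0),
    (32, 30, 28, 26, 1.10, 109.0, 0.0),
    (34, 33, 30, 28, 1.25, 117.0, 0.0),        # GLY.OT1
    (35, 33, 30, 28, 1.25, 117.0, 180.0),      # GLY.OT2
    (14, 4, 6, 9, 1.53, 110.0, 60.0),          # GGL.C (alpha-carboxylate)
    (5, 4, 6, 9, 1.10, 108.0, -60.0),          # GGL.HA
    (15, 14, 4, 6, 1.25, 117.0, 0.0),          # GGL.OT1
    (16, 14, 4, 6, 1.25, 117.0, 180.0),        # GGL.OT2
    (1, 0, 4, 6, 1.01, 109.5, 180.0),          # amine H x3 staggered
    (2, 0, 4, 6, 1.01, 109.5, 60.0),
    (3, 0, 4, 6, 1.01, 109.5, -60.0),
    (7, 6, 4, 0, 1.10, 109.0, 60.0),           # GGL HB
    (8, 6, 4, 0, 1.10, 109.0, -60.0),
    (10, 9, 6, 4, 1.10, 109.0, 60.0),          # GGL HG
    (11, 9, 6, 4, 1.10, 109.0, -60.0),
]

#: guest O-H equilibrium bond length (A)
GUEST_BOND_B0 = 0.9791

#: rotatable bonds (a, b): rotation turns the b-side of the molecule about
#: the a->b axis.  Order is root-to-leaf so sequential application is valid.
ROTATABLE_TORSIONS: tuple[tuple[int, int], ...] = (
    (4, 6),    # CA-CB   (GGL chain vs alpha head)
    (4, 14),   # CA-C    (GGL carboxylate orientation)
    (6, 9),    # CB-CG
    (9, 12),   # CG-CD
    (17, 19),  # N-CA    (CYS phi)
    (19, 21),  # CA-CB   (CYS chi1)
    (21, 24),  # CB-SG   (thiol H orientation)
    (19, 26),  # CA-C    (CYS psi)
    (28, 30),  # N-CA    (GLY phi)
    (30, 33),  # CA-C    (GLY psi / carboxylate orientation)
)


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """NERF placement: new atom X with |X-a|=bond, angle(X,a,b)=angle and
    dihedral(X,a,b,c)=dihedral (IUPAC sign convention)."""
    theta = math.radians(angle_deg)
    phi = math.radians(dihedral_deg)
    d = np.array([
        -bond * math.cos(theta),
        bond * math.sin(theta) * math.cos(phi),
        bond * math.sin(theta) * math.sin(phi),
    ])
    ab = a - b
    ab /= np.linalg.norm(ab)
    cb = b - c
    n = np.cross(cb, ab)
    n /= np.linalg.norm(n)
    m = np.column_stack([ab, np.cross(n, ab), n])
    return a + m @ d


@lru_cache(maxsize=1)
def _reference() -> tuple:
    coords = np.zeros((38, 3))
    # seed atoms: GGL.N at origin, CA on x, CB placement special-cased
    coords[0] = (0.0, 0.0, 0.0)
    coords[4] = (1.49, 0.0, 0.0)
    th = math.radians(111.0)
    coords[6] = coords[4] + 1.53 * np.array([-math.cos(th), math.sin(th), 0.0])
    for (i, a, b, c, r, ang, dih) in _ZMATRIX:
        if i == 6:
            continue
        if c is None:
            raise AssertionError("only atom 6 may omit the torsion reference")
        coords[i] = _place(coords[a], coords[b], coords[c], r, ang, dih)
    # guest parked 6 A beyond the GLY carboxylate, O-H at equilibrium length
    u = coords[34] - coords[33]
    u /= np.linalg.norm(u)
    coords[36] = coords[34] + 6.0 * u
    coords[37] = coords[36] + GUEST_BOND_B0 * u
    coords.setflags(write=False)
    return (coords,)


def reference_coordinates() -> np.ndarray:
    """Coordinates (38, 3) in Angstrom of the extended reference conformer.

    Deterministic; the returned array is read-only (copy before editing).
    """
    return _reference()[0]


@lru_cache(maxsize=1)
def torsion_downstream_sets() -> tuple[tuple[int, ...], ...]:
    """For each rotatable bond (a, b): indices moved by rotating about a->b.

    The moved set is the connected component containing ``b`` once the bond
    is deleted, excluding ``b`` itself (which lies on the axis).
    """
    from .topology import build_gsh_oh_topology

    top = build_gsh_oh_topology()
    nb = top.neighbor_map()
    out = []
    for a, b in ROTATABLE_TORSIONS:
        seen = {a, b}
        stack = [n for n in nb[b] if n != a]
        comp = set()
        while stack:
            x = stack.pop()
            if x in seen:
                continue
            seen.add(x)
            comp.add(x)
            stack.extend(nb[x] - seen)
        out.append(tuple(sorted(comp)))
    return tuple(out)


def _rotation_about_axis(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    x, y, z = axis
    c, s = math.cos(angle_rad), math.sin(angle_rad)
    C = 1.0 - c
    return np.array([
        [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
        [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
        [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
    ])


def apply_torsion_deltas(coords: np.ndarray, deltas_deg: np.ndarray) -> np.ndarray:
    """Rotate each rotatable torsion by its delta (degrees) from ``coords``.

    Rotations are applied root-to-leaf about the current bond axes, so the
    result is the conformer whose torsion angles differ from ``coords`` by
    exactly ``deltas_deg``.  Atoms not downstream of any rotated bond
    (including the guest) are left in place.
    """
    out = np.array(coords, dtype=float, copy=True)
    down = torsion_downstream_sets()
    for (a, b), moved, delta in zip(ROTATABLE_TORSIONS, down, deltas_deg):
        if delta == 0.0 or not moved:
            continue
        rot = _rotation_about_axis(out[b] - out[a], math.radians(delta))
        idx = list(moved)
        out[idx] = (out[idx] - out[b]) @ rot.T + out[b]
    return out
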