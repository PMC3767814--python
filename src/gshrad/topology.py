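"""Molecular data model for the glutathione-anion / hydroxyl-radical system.

Glutathione (GSH, the tripeptide gamma-L-glutamyl-L-cysteinyl-glycine) is
modelled in the protonation state dominant at physiological pH: the
gamma-glutamyl residue is zwitterionic (protonated -NH3+, deprotonated
alpha-carboxylate) and the glycyl carboxylate is deprotonated, giving a net
host charge of -1 e.  The guest is a single hydroxyl radical (residue label
``HOR``) whose two atoms carry point charges of -0.444 e (oxygen) and
+0.444 e (hydrogen).

Residues are named ``GGL`` (gamma-glutamyl), ``CYS`` (cysteinyl), ``GLY``
(glycyl) and ``HOR`` (the radical), and atoms follow the conventional
peptide scheme (``CA``/``CB``/... for carbons, ``OT1``/``OT2`` for terminal
carboxylate oxygens, ``SG`` for the thiol sulfur).  Hydrogens are explicit
because the hydrogen-bond criterion needs the A-H-D angle; their names
(``HN1``, ``HB2``, ...) are a package convention.

The topology also carries the named atom selections every downstream
analysis uses, most importantly ``attack_points`` (the ten heavy atoms
screened in the interaction census) and the six head-tail atom pairs that
define the HT distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "AtomSpec",
    "Topology",
    "SelectionError",
    "TopologyError",
    "build_gsh_oh_topology",
    "select",
    "MASSES",
]

#: standard atomic masses (u) for the elements occurring in the system
MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06}

#: default cubic box edge in Angstrom
DEFAULT_BOX_EDGE = 37.0

GUEST_O_CHARGE = -0.444
GUEST_H_CHARGE = +0.444


class SelectionError(KeyError):
    """An atom token or selection name did not resolve."""


class TopologyError(ValueError):
    """Structural inconsistency in a topology."""


@dataclass(frozen=True)
class AtomSpec:
    """One atom: residue label, name, element and bookkeeping point charge.

    ``partial_charge`` is in elementary-charge units.  Host charges are
    bookkeeping values that reproduce the formal charges (-0.5 e per
    carboxylate oxygen, +1 e spread over the protonated amine); only the
    guest charges and the residue sums are physically constrained.
    """

    residue_label: str
    atom_name: str
    element: str
    partial_charge: float

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"

    @property
    def token(self) -> str:
        return f"{self.residue_label}.{self.atom_name}"


# ---------------------------------------------------------------------------
# canonical atom table
#
# index  residue atom  element charge
_ATOM_TABLE = [
    # GGL (gamma-glutamyl, zwitterionic)
    ("GGL", "N", "N", 0.10),      # 0  protonated amine nitrogen
    ("GGL", "HN1", "H", 0.30),    # 1
    ("GGL", "HN2", "H", 0.30),    # 2
    ("GGL", "HN3", "H", 0.30),    # 3
    ("GGL", "CA", "C", 0.0),      # 4
    ("GGL", "HA", "H", 0.0),      # 5
    ("GGL", "CB", "C", 0.0),      # 6
    ("GGL", "HB1", "H", 0.0),     # 7
    ("GGL", "HB2", "H", 0.0),     # 8
    ("GGL", "CG", "C", 0.0),      # 9
    ("GGL", "HG1", "H", 0.0),     # 10
    ("GGL", "HG2", "H", 0.0),     # 11
    ("GGL", "CD", "C", 0.0),      # 12 gamma-amide carbonyl carbon
    ("GGL", "O", "O", 0.0),       # 13 gamma-amide carbonyl oxygen
    ("GGL", "C", "C", 0.0),       # 14 alpha-carboxylate carbon
    ("GGL", "OT1", "O", -0.50),   # 15
    ("GGL", "OT2", "O", -0.50),   # 16
    # CYS
    ("CYS", "N", "N", 0.0),       # 17
    ("CYS", "HN", "H", 0.0),      # 18
    ("CYS", "CA", "C", 0.0),      # 19
    ("CYS", "HA", "H", 0.0),      # 20
    ("CYS", "CB", "C", 0.0),      # 21
    ("CYS", "HB1", "H", 0.0),     # 22
    ("CYS", "HB2", "H", 0.0),     # 23
    ("CYS", "SG", "S", 0.0),      # 24 thiol sulfur
    ("CYS", "HG", "H", 0.0),      # 25 thiol hydrogen
    ("CYS", "C", "C", 0.0),       # 26
    ("CYS", "O", "O", 0.0),       # 27
    # GLY
    ("GLY", "N", "N", 0.0),       # 28
    ("GLY", "HN", "H", 0.0),      # 29
    ("GLY", "CA", "C", 0.0),      # 30
    ("GLY", "HA1", "H", 0.0),     # 31
    ("GLY", "HA2", "H", 0.0),     # 32
    ("GLY", "C", "C", 0.0),       # 33 terminal carboxylate carbon
    ("GLY", "OT1", "O", -0.50),   # 34
    ("GLY", "OT2", "O", -0.50),   # 35
    # HOR (hydroxyl radical guest)
    ("HOR", "O_g", "O", GUEST_O_CHARGE),  # 36
    ("HOR", "H_g", "H", GUEST_H_CHARGE),  # 37
]

#: covalent bonds as index pairs (host peptide + guest O-H)
_BONDS = [
    (0, 1), (0, 2), (0, 3), (0, 4),
    (4, 5), (4, 6), (4, 14),
    (6, 7), (6, 8), (6, 9),
    (9, 10), (9, 11), (9, 12),
    (12, 13), (12, 17),
    (14, 15), (14, 16),
    (17, 18), (17, 19),
    (19, 20), (19, 21), (19, 26),
    (21, 22), (21, 23), (21, 24),
    (24, 25),
    (26, 27), (26, 28),
    (28, 29), (28, 30),
    (30, 31), (30, 32), (30, 33),
    (33, 34), (33, 35),
    (36, 37),
]

#: hydrogen-bond donor pairs (heavy atom, attached hydrogen)
_DONORS = [
    (0, 1), (0, 2), (0, 3),    # GGL amine N-H x3
    (17, 18),                  # CYS amide N-H
    (24, 25),                  # CYS thiol S-H
    (28, 29),                  # GLY amide N-H
    (36, 37),                  # guest O-H
]


@dataclass(frozen=True)
class Topology:
    """Atoms, bonds, donors and named selections of the simulated system.

    ``selections`` maps a name to a tuple of atom indices (in topology
    order); ``pair_selections`` maps a name to a tuple of (i, j) atom-index
    pairs (used by the head-tail distance definition).
    """

    atoms: tuple[AtomSpec, ...]
    bonds: tuple[tuple[int, int], ...]
    donors: tuple[tuple[int, int], ...]
    selections: dict[str, tuple[int, ...]] = field(default_factory=dict)
    pair_selections: dict[str, tuple[tuple[int, int], ...]] = field(default_factory=dict)
    box_edge: float = DEFAULT_BOX_EDGE

    # -- basic queries ------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def index_of(self, token: str) -> int:
        """Resolve a ``RES.NAME`` token to its atom index."""
        try:
            res, name = token.split(".")
        except ValueError as exc:
            raise SelectionError(f"malformed atom token {token!r}") from exc
        for i, a in enumerate(self.atoms):
            if a.residue_label == res and a.atom_name == name:
                return i
        raise SelectionError(f"unknown atom token {token!r}")

    def token_of(self, index: int) -> str:
        return self.atoms[index].token

    @property
    def has_guest(self) -> bool:
        return any(a.residue_label == "HOR" for a in self.atoms)

    def neighbor_map(self) -> dict[int, set[int]]:
        nb: dict[int, set[int]] = {i: set() for i in range(self.n_atoms)}
        for i, j in self.bonds:
            nb[i].add(j)
            nb[j].add(i)
        return nb

    # -- serialization ------------------------------------------------------
    def to_table(self, path: str | Path) -> None:
        """Write the atom table (residue, atom, element, charge) as TSV."""
        df = pd.DataFrame(
            [(a.residue_label, a.atom_name, a.element, a.partial_charge) for a in self.atoms],
            columns=["residue", "atom", "element", "charge"],
        )
        df.to_csv(path, sep="\t", index=False)

    def host_only(self) -> "Topology":
        """Topology restricted to the host (guest residue removed)."""
        keep = [i for i, a in enumerate(self.atoms) if a.residue_label != "HOR"]
        keepset = set(keep)
        remap = {old: new for new, old in enumerate(keep)}

        def _remap_sel(idx: Iterable[int]) -> tuple[int, ...]:
            return tuple(remap[i] for i in idx if i in keepset)

        return Topology(
            atoms=tuple(self.atoms[i] for i in keep),
            bonds=tuple((remap[i], remap[j]) for i, j in self.bonds
                        if i in keepset and j in keepset),
            donors=tuple((remap[i], remap[j]) for i, j in self.donors
                         if i in keepset and j in keepset),
            selections={k: _remap_sel(v) for k, v in self.selections.items()
                        if k not in ("guest",)},
            pair_selections={k: tuple((remap[i], remap[j]) for i, j in v
                                      if i in keepset and j in keepset)
                             for k, v in self.pair_selections.items()},
            box_edge=self.box_edge,
        )


def from_table(path: str | Path) -> Topology:
    """Rebuild the canonical topology from a plain-text atom table.

    The table must list exactly the canonical atom set (same residues and
    atom names, same order); bonds, donors and selections are structural
    metadata reattached from the canonical template.  Charges are taken
    from the table.
    """
    df = pd.read_csv(path, sep="\t")
    canon = build_gsh_oh_topology()
    if len(df) != canon.n_atoms:
        raise TopologyError(
            f"atom table has {len(df)} rows, expected {canon.n_atoms}")
    atoms = []
    for i, row in df.iterrows():
        ref = canon.atoms[i]
        if row["residue"] != ref.residue_label or row["atom"] != ref.atom_name:
            raise TopologyError(
                f"row {i}: {row['residue']}.{row['atom']} does not match "
                f"canonical atom {ref.token}")
        atoms.append(replace(ref, element=row["element"],
                             partial_charge=float(row["charge"])))
    return replace(canon, atoms=tuple(atoms))


def _indices(tokens: Sequence[str], lookup: dict[str, int]) -> tuple[int, ...]:
    return tuple(lookup[t] for t in tokens)


def build_gsh_oh_topology(box_edge: float = DEFAULT_BOX_EDGE) -> Topology:
    """Build the canonical GSH-anion + hydroxyl-radical topology.

    Deterministic: repeated calls return identical objects.  The built-in
    selections are

    ``host`` / ``guest`` / ``host_heavy``
        partition of the atom list and the 20 host heavy atoms;
    ``attack_points``
        the ten heavy atoms screened for guest contacts
        (GGL: CA, N, OT1, OT2; CYS: SG, CA, CB; GLY: CA, OT1, OT2);
    ``carboxylate_oxygens``
        the four terminal carboxylate oxygens;
    ``cys_ht_targets``
        the five head/tail atoms the CYS-HT distance is measured against;

    and the pair selection ``ht_head_tail`` holds the six
    {GLY.OT1, GLY.OT2} x {GGL.OT1, GGL.OT2, GGL.N} pairs whose minimum
    defines the head-tail distance HT.
    """
    atoms = tuple(AtomSpec(r, n, e, q) for r, n, e, q in _ATOM_TABLE)
    lookup = {a.token: i for i, a in enumerate(atoms)}

    host = tuple(i for i, a in enumerate(atoms) if a.residue_label != "HOR")
    guest = tuple(i for i, a in enumerate(atoms) if a.residue_label == "HOR")
    host_heavy = tuple(i for i in host if atoms[i].is_heavy)

    attack = _indices(
        ["GGL.CA", "GGL.N", "GGL.OT1", "GGL.OT2",
         "CYS.SG", "CYS.CA", "CYS.CB",
         "GLY.CA", "GLY.OT1", "GLY.OT2"], lookup)
    carbox = _indices(["GGL.OT1", "GGL.OT2", "GLY.OT1", "GLY.OT2"], lookup)
    cys_ht = _indices(["GLY.OT1", "GLY.OT2", "GGL.OT1", "GGL.OT2", "GGL.N"], lookup)

    heads = _indices(["GLY.OT1", "GLY.OT2"], lookup)
    tails = _indices(["GGL.OT1", "GGL.OT2", "GGL.N"], lookup)
    ht_pairs = tuple((h, t) for h in heads for t in tails)

    return Topology(
        atoms=atoms,
        bonds=tuple(_BONDS),
        donors=tuple(_DONORS),
        selections={
            "host": host,
            "guest": guest,
            "host_heavy": host_heavy,
            "heavy": tuple(i for i, a in enumerate(atoms) if a.is_heavy),
            "attack_points": attack,
            "carboxylate_oxygens": carbox,
            "cys_ht_targets": cys_ht,
        },
        pair_selections={"ht_head_tail": ht_pairs},
        box_edge=box_edge,
    )


def select(topology: Topology, expression):
    """Resolve a selection expression to atom indices (topology order).

    ``expression`` may be a named selection (``"attack_points"``), a named
    pair selection (returns index pairs), a single ``RES.ATOM`` token, or an
    iterable of tokens.  Unknown names raise :class:`SelectionError` naming
    the offending token.  Idempotent in the sense that re-selecting the
    returned tokens yields the same indices.
    """
    if isinstance(expression, str):
        if expression in topology.selections:
            return list(topology.selections[expression])
        if expression in topology.pair_selections:
            return [tuple(p) for p in topology.pair_selections[expression]]
        if "." in expression:
            return [topology.index_of(expression)]
        raise SelectionError(f"unknown selection {expression!r}")
    return [topology.index_of(tok) for tok in expression]
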