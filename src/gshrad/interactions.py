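"""Geometric interaction detection, pattern census and motif classification.

A contact is a donor-hydrogen-acceptor triple satisfying the geometric
hydrogen-bond criteria d(A...D) < 3.5 A and alpha(A...H-D) > 100 deg, the
angle taken at the hydrogen.  Both directions are screened: the guest O-H
donating to a host target heavy atom, and host donor groups (protonated
amine, thiol, backbone amides) donating to the guest oxygen.  Host carbons
in the target set act as acceptors of the guest O-H only; they have no
acidic hydrogen in this analysis (a host-C-H-donates variant exists behind
``allow_carbon_donors`` and is off by default).

The per-frame pattern collapses multiple geometric events to the set of
interacting host heavy atoms from the ``attack_points`` selection, counts
contact tiers (>=1, >=2, =3) over a trajectory and classifies each frame's
anchoring motif:

zwitterionic
    the protonated GGL amine plus at least one carboxylate oxygen anchor
    the radical (-NH3+ ... OH ... -CO2-);
anionic
    a carboxylate oxygen anchors it together with one of the thiol /
    alpha- / beta-carbon sites (-CO2- ... OH ... -X-H);
other / none
    any other non-empty contact set, or no contact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .geometry import angle
from .topology import Topology, select

__all__ = [
    "D_MAX",
    "ALPHA_MIN",
    "InteractionEvent",
    "FramePattern",
    "PatternCensus",
    "detect_interactions",
    "intramolecular_hbond_census",
    "classify_frame",
    "frame_patterns",
    "pattern_census",
    "triple_interaction_frames",
]

#: geometric hydrogen-bond criteria
D_MAX = 3.5
ALPHA_MIN = 100.0

CARBOXYLATE_OXYGENS = frozenset({"GGL.OT1", "GGL.OT2", "GLY.OT1", "GLY.OT2"})
GLY_CARBOXYLATE = frozenset({"GLY.OT1", "GLY.OT2"})
GGL_CARBOXYLATE = frozenset({"GGL.OT1", "GGL.OT2"})
AMINE = "GGL.N"
THIOL = "CYS.SG"
#: anionic-group partner sites (-X-H side of the motif)
ANIONIC_PARTNERS = frozenset({"GGL.CA", "GLY.CA", "CYS.CA", "CYS.CB", "CYS.SG"})
#: heteroatom contacts counted as "hydrogen-bonded atoms" besides carboxylates
HBOND_HETEROATOMS = frozenset({AMINE, THIOL})


@dataclass(frozen=True)
class InteractionEvent:
    """One detected donor-H-acceptor contact in one frame."""

    frame: int
    donor: str
    hydrogen: str
    acceptor: str
    d_AD: float
    alpha_AHD: float
    direction: str  # "guest_donates" | "host_donates"


@dataclass(frozen=True)
class FramePattern:
    """Contact set (attack-point tokens) and motif label of one frame."""

    frame: int
    contact_set: frozenset[str]
    motif: str  # "zwitterionic" | "anionic" | "other" | "none"

    @property
    def n_contacts(self) -> int:
        return len(self.contact_set)


@dataclass
class PatternCensus:
    """Interaction-pattern statistics over a trajectory.

    Contact tiers are frame counts; fractions use the denominators of the
    standard presentation: ``frac_carboxylate`` / ``frac_thiol`` are over
    the frames with at least one contact (``n_ge1``), the GLY/GGL subgroup
    split and ``frac_dual`` are over the frames with at least two contacts
    (``n_ge2``).  ``frac_carboxylate_events`` is the event-level
    alternative denominator (carboxylate contacts over all counted
    contacts).  A frame touching both termini is assigned to the subgroup
    of its nearest carboxylate contact.
    """

    n_frames_total: int
    n_ge1: int
    n_ge2: int
    n_eq3: int
    frac_carboxylate: float
    frac_thiol: float
    frac_carboxylate_gly: float
    frac_carboxylate_ggl: float
    frac_dual: float
    frac_carboxylate_events: float
    motif_counts: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "n_frames_total": self.n_frames_total,
            "n_ge1": self.n_ge1,
            "n_ge2": self.n_ge2,
            "n_eq3": self.n_eq3,
            "frac_carboxylate": self.frac_carboxylate,
            "frac_thiol": self.frac_thiol,
            "frac_carboxylate_gly": self.frac_carboxylate_gly,
            "frac_carboxylate_ggl": self.frac_carboxylate_ggl,
            "frac_dual": self.frac_dual,
            "frac_carboxylate_events": self.frac_carboxylate_events,
            "motif_counts": dict(self.motif_counts),
        }


def _host_target_indices(topology: Topology, host_targets) -> list[int]:
    if isinstance(host_targets, str):
        return select(topology, host_targets)
    return [i if isinstance(i, (int, np.integer)) else topology.index_of(i)
            for i in host_targets]


def detect_interactions(coords: np.ndarray, topology: Topology,
                        host_targets="attack_points", frame: int = 0,
                        d_max: float = D_MAX, alpha_min: float = ALPHA_MIN,
                        allow_carbon_donors: bool = False) -> list[InteractionEvent]:
    """All guest-host contacts of one frame passing both criteria.

    Enumerates the guest O-H donating to every target heavy atom and every
    host donor pair whose heavy atom lies in the target set donating to the
    guest oxygen; returns exactly the events with d(A...D) < ``d_max`` and
    alpha(A...H-D) > ``alpha_min``.
    """
    coords = np.asarray(coords, dtype=float)
    if not topology.has_guest:
        return []
    og = topology.index_of("HOR.O_g")
    hg = topology.index_of("HOR.H_g")
    targets = _host_target_indices(topology, host_targets)
    events: list[InteractionEvent] = []

    # guest donates: O_g-H_g ... A(host)
    for t in targets:
        d = float(np.linalg.norm(coords[t] - coords[og]))
        if d >= d_max:
            continue
        a = angle(coords[t], coords[hg], coords[og])
        if a > alpha_min:
            events.append(InteractionEvent(
                frame=frame, donor="HOR.O_g", hydrogen="HOR.H_g",
                acceptor=topology.token_of(t), d_AD=d, alpha_AHD=a,
                direction="guest_donates"))

    # host donates: X-H ... O_g for donor pairs with X in the target set
    tset = set(targets)
    for dheavy, hyd in topology.donors:
        if dheavy == og or dheavy not in tset:
            continue
        if not allow_carbon_donors and topology.atoms[dheavy].element == "C":
            continue
        d = float(np.linalg.norm(coords[og] - coords[dheavy]))
        if d >= d_max:
            continue
        a = angle(coords[og], coords[hyd], coords[dheavy])
        if a > alpha_min:
            events.append(InteractionEvent(
                frame=frame, donor=topology.token_of(dheavy),
                hydrogen=topology.token_of(hyd),
                acceptor="HOR.O_g", d_AD=d, alpha_AHD=a,
                direction="host_donates"))
    return events


def _intra_pairs(topology: Topology) -> list[tuple[int, int, int]]:
    """(donor heavy, hydrogen, acceptor) triples for the intra-host scan.

    Acceptors are host N/O/S heavy atoms excluding the donor itself and
    its 1-2 / 1-3 covalent neighborhood.
    """
    nb = topology.neighbor_map()
    host = set(topology.selections["host"])
    acceptors = [i for i in host
                 if topology.atoms[i].element in ("N", "O", "S")]
    triples = []
    for dheavy, hyd in topology.donors:
        if dheavy not in host:
            continue
        excluded = {dheavy} | nb[dheavy]
        for n1 in nb[dheavy]:
            excluded |= nb[n1]
        for acc in acceptors:
            if acc not in excluded:
                triples.append((dheavy, hyd, acc))
    return triples


def intramolecular_hbond_census(trajectory, topology: Topology | None = None,
                                d_max: float = D_MAX,
                                alpha_min: float = ALPHA_MIN) -> float:
    """Fraction of frames with at least one intra-host hydrogen bond."""
    top = topology or trajectory.topology
    triples = _intra_pairs(top)
    if not triples:
        return 0.0
    dh = np.array([t[0] for t in triples])
    hh = np.array([t[1] for t in triples])
    ah = np.array([t[2] for t in triples])
    c = trajectory.coords
    dvec = c[:, ah, :] - c[:, dh, :]
    dist = np.linalg.norm(dvec, axis=2)
    u = c[:, ah, :] - c[:, hh, :]
    w = c[:, dh, :] - c[:, hh, :]
    cosa = (u * w).sum(axis=2) / (
        np.linalg.norm(u, axis=2) * np.linalg.norm(w, axis=2))
    alph = np.degrees(np.arccos(np.clip(cosa, -1.0, 1.0)))
    hit = ((dist < d_max) & (alph > alpha_min)).any(axis=1)
    return float(hit.mean())


def classify_frame(events: Sequence[InteractionEvent],
                   attack_tokens: Iterable[str] | None = None,
                   frame: int | None = None) -> FramePattern:
    """Collapse one frame's events into its contact set and motif label.

    ``attack_tokens`` restricts the contact set to the census atoms
    (default: the canonical attack-point tokens); events involving other
    host atoms, e.g. backbone amide donors, are bookkept out exactly as in
    the geometric analysis convention.
    """
    frames = {e.frame for e in events}
    if len(frames) > 1:
        raise ValueError(f"events from mixed frames {sorted(frames)}")
    if frame is None:
        frame = next(iter(frames)) if frames else 0
    if attack_tokens is None:
        attack_tokens = {
            "GGL.CA", "GGL.N", "GGL.OT1", "GGL.OT2",
            "CYS.SG", "CYS.CA", "CYS.CB",
            "GLY.CA", "GLY.OT1", "GLY.OT2"}
    attack_tokens = set(attack_tokens)
    contact = set()
    for e in events:
        host_atom = e.acceptor if e.direction == "guest_donates" else e.donor
        if host_atom in attack_tokens:
            contact.add(host_atom)

    if not contact:
        motif = "none"
    elif AMINE in contact and contact & CARBOXYLATE_OXYGENS:
        motif = "zwitterionic"
    elif contact & CARBOXYLATE_OXYGENS and contact & ANIONIC_PARTNERS:
        motif = "anionic"
    else:
        motif = "other"
    return FramePattern(frame=frame, contact_set=frozenset(contact), motif=motif)


def frame_patterns(trajectory, topology: Topology | None = None,
                   host_targets="attack_points") -> list[FramePattern]:
    """Per-frame contact patterns for a whole trajectory."""
    top = topology or trajectory.topology
    tokens = [top.token_of(i) for i in _host_target_indices(top, host_targets)]
    out = []
    for i in range(trajectory.n_frames):
        ev = detect_interactions(trajectory.coords[i], top, host_targets, frame=i)
        out.append(classify_frame(ev, attack_tokens=tokens, frame=i))
    return out


def _nearest_terminus(coords: np.ndarray, topology: Topology,
                      contact: frozenset[str]) -> str:
    og = topology.index_of("HOR.O_g")
    best, label = np.inf, "GLY"
    for tok in contact & CARBOXYLATE_OXYGENS:
        d = float(np.linalg.norm(coords[topology.index_of(tok)] - coords[og]))
        if d < best:
            best, label = d, tok.split(".")[0]
    return label


def pattern_census(trajectory, topology: Topology | None = None,
                   host_targets="attack_points",
                   patterns: Sequence[FramePattern] | None = None) -> PatternCensus:
    """Interaction-pattern census of a trajectory.

    Counts the contact tiers and the fractions described on
    :class:`PatternCensus`.  Precomputed ``patterns`` may be passed to
    avoid re-detection.
    """
    top = topology or trajectory.topology
    if patterns is None:
        patterns = frame_patterns(trajectory, top, host_targets)

    n_total = len(patterns)
    ge1 = [p for p in patterns if p.n_contacts >= 1]
    ge2 = [p for p in patterns if p.n_contacts >= 2]
    eq3 = [p for p in patterns if p.n_contacts == 3]

    n_ge1, n_ge2 = len(ge1), len(ge2)
    carbox = [p for p in ge1 if p.contact_set & CARBOXYLATE_OXYGENS]
    thiol = [p for p in ge1 if THIOL in p.contact_set]

    n_gly = n_ggl = n_dual = 0
    for p in ge2:
        cset = p.contact_set
        has_gly = bool(cset & GLY_CARBOXYLATE)
        has_ggl = bool(cset & GGL_CARBOXYLATE)
        if has_gly and has_ggl:
            side = _nearest_terminus(trajectory.coords[p.frame], top, cset)
            has_gly, has_ggl = side == "GLY", side == "GGL"
        n_gly += has_gly
        n_ggl += has_ggl
        if (cset & CARBOXYLATE_OXYGENS) and (cset & HBOND_HETEROATOMS):
            n_dual += 1

    n_events = sum(p.n_contacts for p in ge1)
    n_carbox_events = sum(len(p.contact_set & CARBOXYLATE_OXYGENS) for p in ge1)

    motifs: dict[str, int] = {}
    for p in patterns:
        motifs[p.motif] = motifs.get(p.motif, 0) + 1

    def _frac(num, den):
        return num / den if den else 0.0

    return PatternCensus(
        n_frames_total=n_total, n_ge1=n_ge1, n_ge2=n_ge2, n_eq3=len(eq3),
        frac_carboxylate=_frac(len(carbox), n_ge1),
        frac_thiol=_frac(len(thiol), n_ge1),
        frac_carboxylate_gly=_frac(n_gly, n_ge2),
        frac_carboxylate_ggl=_frac(n_ggl, n_ge2),
        frac_dual=_frac(n_dual, n_ge2),
        frac_carboxylate_events=_frac(n_carbox_events, n_events),
        motif_counts=motifs,
    )


def triple_interaction_frames(trajectory, topology: Topology | None = None,
                              host_targets="attack_points",
                              patterns: Sequence[FramePattern] | None = None
                              ) -> list[int]:
    """Frames with exactly three guest-host contacts, in frame order."""
    if patterns is None:
        patterns = frame_patterns(trajectory, topology, host_targets)
    return [p.frame for p in patterns if p.n_contacts == 3]
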