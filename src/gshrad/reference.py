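"""Tabulated reference values for the GSH / hydroxyl-radical system.

``REFERENCE_GMAX`` holds the published maxima of the radial distribution
functions between the radical oxygen and each of the twenty host heavy
atoms (distance of the maximum in A, g(r)max, and the normalized column
g(r)max / min g(r)max as printed, to two decimals).  These are inputs for
the normalization and attack-point-ranking examples, not outputs of this
package.

Note the printed Norm column was computed from unrounded maxima: for three
rows (GGL.CD, CYS.C, GLY.OT1) the ratio of the *printed* g(r)max to the
printed minimum (1.31) rounds one ulp away from the printed Norm value.

``CENSUS_COUNTS`` records the published interaction-census frame counts:
2305 frames with at least one guest contact, 838 with at least two, and 12
with three (the maximum observed).
"""

from __future__ import annotations

#: token -> (r_at_max [A], g(r)max, printed Norm)
REFERENCE_GMAX: dict[str, tuple[float, float, float]] = {
    "GGL.CA": (4.65, 2.06, 1.57),
    "GGL.CB": (5.35, 1.49, 1.14),
    "GGL.C": (3.25, 2.91, 2.22),
    "GGL.CD": (3.75, 1.40, 1.06),
    "GGL.O": (7.55, 1.31, 1.00),
    "GGL.CG": (3.65, 1.32, 1.01),
    "GGL.N": (5.35, 1.53, 1.17),
    "GGL.OT1": (2.65, 5.25, 4.01),
    "GGL.OT2": (2.65, 6.00, 4.58),
    "CYS.CA": (4.25, 1.49, 1.14),
    "CYS.CB": (3.85, 1.76, 1.34),
    "CYS.C": (3.95, 1.62, 1.23),
    "CYS.N": (5.65, 1.39, 1.06),
    "CYS.O": (7.15, 1.47, 1.12),
    "CYS.SG": (3.45, 2.24, 1.71),
    "GLY.CA": (3.75, 2.33, 1.78),
    "GLY.C": (3.15, 4.54, 3.47),
    "GLY.N": (5.15, 1.70, 1.30),
    "GLY.OT1": (2.65, 8.63, 6.58),
    "GLY.OT2": (2.65, 8.71, 6.65),
}

#: rows whose printed Norm equals round(printed g(r)max / 1.31, 2); the
#: remaining three differ by exactly 0.01 (rounding of unrounded maxima)
SELF_CONSISTENT_ROWS = tuple(
    tok for tok, (_, g, norm) in REFERENCE_GMAX.items()
    if round(g / 1.31, 2) == norm
)

#: published census frame counts over 25 000 trajectory frames
CENSUS_COUNTS = {"n_frames_total": 25000, "n_ge1": 2305, "n_ge2": 838, "n_eq3": 12}
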