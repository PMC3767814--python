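# Methods

`gshrad` analyses how the glutathione anion (GSH, the tripeptide
γ-Glu–Cys–Gly; "host") recognizes a hydroxyl radical (OH•; "guest") in
molecular-dynamics trajectories. This note describes the models and
procedures the package implements, the parameters that matter, what the
synthetic-trajectory generator does and does not emulate, and the
numerical choices behind the defaults.

## Molecular model

GSH is modelled in its dominant physiological protonation state: the
γ-glutamyl residue (`GGL`) is zwitterionic (protonated –NH3+, deprotonated
α-carboxylate) and the glycyl carboxylate (`GLY`) is deprotonated, for a
net host charge of −1 e. Hydrogens are explicit because the interaction
criterion needs the acceptor–H–donor angle; their names are a package
convention. The guest (`HOR`) carries point charges of −0.444 e (O) and
+0.444 e (H) and a harmonic O–H bond with b₀ = 0.9791 Å and
K_b = 444.8474 kcal/mol/Å². Host partial charges are bookkeeping values
that reproduce the formal charges (−0.5 e per carboxylate oxygen, +1 e
over the protonated amine); they enter no energy term.

The extended reference conformer is built from an internal-coordinate
(Z-matrix) template with standard bond lengths and angles via the
natural-extension-reference-frame construction, with all backbone-chain
torsions anti. It is both the RMSD reference ("deviation from the
initial, extended structure") and the base the generator perturbs. Ten
rotatable single bonds are declared (the GGL γ-chain, both ψ/φ-like
backbone bonds of CYS and GLY, the two carboxylate orientations, the CYS
side chain and the thiol S–H); amide bonds stay planar-trans.

## Analyses

**Flexibility.** Heavy-atom RMSD uses optimal (Kabsch) superposition per
frame; the radius of gyration is mass-weighted over host heavy atoms by
default (a flag switches to unweighted, since conventions differ).
Head–tail compactness uses HT = min over the six
{GLY.OT1/OT2} × {GGL.OT1/OT2/N} distances and CYS-HT = min distance from
CYS.SG to those five atoms (a narrower carboxylate-only reading is a
flag). Percentage-distribution surfaces bin two series into half-open
0.25 Å cells anchored at 0.0 Å, so conventional cell bounds (1.75, 2.00,
3.75, 4.00 Å) fall on bin edges. The representative structure of the
modal cell minimizes the unnormalized Euclidean distance (both axes in Å)
to the in-cell means, earliest frame on ties.

**Radial distribution functions.** For a single guest, g(r) is the
shell-averaged pair count divided by the ideal-gas expectation at density
1/V (V = box volume, cubic box of edge 37 Å), averaged over frames. Bins
are 0.10 Å wide with centers at 0.05 + k·0.10 Å, so tabulated maxima
positions (2.65, 3.45, 3.75 Å, …) sit on the lattice; the width is an
inference from those printed distances. Minimum-image wrapping applies
only when a periodic box is declared (synthetic data are non-periodic).
The normalized column is g(r)max divided by the smallest g(r)max in the
set, and sites with a normalized value ≥ 1.5 rank as probable attack
points. The bundled reference table adopts min = 1.31 (GGL.O) over all
twenty heavy atoms; because the published Norm column was computed from
unrounded maxima, three of its entries round one printed ulp (0.01) away
from ratios of the printed maxima — the package's checks treat those rows
at ±0.01.

**Interactions.** A contact is a donor–H–acceptor triple with
d(A···D) < 3.5 Å and α(A···H–D) > 100° (vertex at H — the only reading
for which 100° is a sensible hydrogen-bond cutoff). Both directions are
screened: guest O–H donating to each target heavy atom, and host donors
(amine, thiol, backbone amides) donating to the guest oxygen. Carbons in
the target set act only as acceptors of the guest O–H by default (they
have no acidic hydrogen here; a carbon-donor variant sits behind a flag).
A frame contributes at most one contact per host heavy atom, and the
census restricts contact sets to the ten attack-point atoms, so backbone
amide events are bookkept out, matching the geometric-analysis
convention. Tier counts (≥1, ≥2, =3 contacts) use frame denominators:
carboxylate and thiol fractions are over the ≥1 population, the GLY/GGL
terminus split and the dual (carboxylate + N/S heteroatom) fraction over
the ≥2 population; an event-level carboxylate fraction is also reported
because the population the published "~78%" refers to is ambiguous. A
frame touching both termini is assigned to the terminus of its nearest
carboxylate contact (each multi-contact frame counts once). Motifs:
*zwitterionic* if the contact set holds GGL.N plus a carboxylate oxygen,
*anionic* if a carboxylate oxygen plus one of {GGL.CA, GLY.CA, CYS.CA,
CYS.CB, CYS.SG}, else *other*/*none*. Intramolecular hydrogen bonds scan
host donors against host N/O/S acceptors, excluding 1-2 and 1-3
neighbours.

**Occupancy map.** Selected frames (by default those with ≥2 contacts)
are superposed on the first frame by host heavy atoms; the transformed
guest-oxygen position increments one voxel of a 0.5 Å grid auto-sized
with a 2 Å margin. Output is OpenDX.

## Metadynamics benchmark

The engine implements standard (non-tempered) metadynamics over two
distance collective variables with the production hill parameters:
height 0.03 kcal/mol, width 0.05 Å, half-harmonic walls at 6 Å
(k = 100 kcal/mol/Å², stiffness chosen since only the wall position is
prescribed). The molecular system is not re-simulated: the sampler is an
overdamped Langevin walker (update s ← s + (D·Δt/kT)F + √(2 D·Δt) ξ, with
D·Δt = 5×10⁻⁴ Å², i.e. ~Å-scale diffusion per 10³ steps) on an analytic
two-basin model of the recognition surface: Gaussian wells of depth
1.2 kcal/mol at (3.6, 4.3) Å and 1.8 kcal/mol at (2.65, 3.65) Å with
σ = 0.32/0.30 Å and a repulsive core below 1.8 Å, giving a 0.7 kcal/mol
saddle from the shallow basin — a channel with a sub-kcal/mol barrier, as
the recognition surface is described qualitatively. All quantitative
claims are against the direct Boltzmann reference of this analytic
potential (F = −kT ln p with p ∝ e^(−V/kT), which reproduces V up to a
constant), never against published free-energy values.

Because each hill is tiny, filling the surface takes tens of thousands of
hills. The schedule default deposits every 500 steps; the packaged
benchmark deposits every 25 steps for 2×10⁶ steps (~7×10⁴ hills) so it
converges at desk scale. The sampler keeps the bias and its gradient on
an internal 0.02 Å grid updated locally per hill (forces by bilinear
interpolation); `reconstruct_fes` always evaluates exact Gaussian sums.
The free-energy estimate averages the bias over the checkpoints of the
last half of deposition, which suppresses the oscillation of non-tempered
metadynamics around −F; the benchmark's agreement measure is the mean
absolute deviation over the region within 1.5 kcal/mol of the reference
minimum, after min-shifting both surfaces. Minima are grid-local
(8-neighbourhood) with minimax-path saddles from a union-find flood;
basins with prominence < 0.15 kcal/mol are absorbed when locating the
benchmark minima, which removes reconstruction-noise dimples.

## Synthetic-trajectory generator

The generator is a statistical emulator, not a force-field simulator: it
produces trajectories whose summary statistics match the conditions the
analyses target, with no energies or thermostat. Frames are 9.8 ps apart
(25 000 frames at study scale; the default `n_frames` is a desk-scale
1000).

*Host conformers.* A mean-reverting AR(1) walk in the ten rotatable
torsions around a moderately folded mean conformation (offsets
(−60, 10, 90, −80, 75, 20, 0, −85, 80, 10)° from the extended template),
stationary sd 40°, persistence 0.6; frames with non-bonded heavy-atom
pairs closer than 2 Å are redrawn. A pure random walk would drift to
uniform torsions, so mean reversion is what keeps the ensemble
stationary; successive frames 9.8 ps apart are treated as nearly
decorrelated. The mean offsets and sd were calibrated once so the
ensemble reproduces the reported flexibility bands — heavy-atom RMSD
mostly 1–3 Å against the extended reference (observed 1.7 ± 0.34 Å),
Rgyr mostly 3.0–4.5 Å (3.6 ± 0.2 Å), HT within 2–12 Å and CYS-HT within
2–8 Å — and left untouched thereafter.

*Guest placement.* With probability 2305/25000 ≈ 9.2% (the reported
fraction of frames with at least one contact) the frame is a contact
frame: a site class is drawn from the propensities carboxylate-GLY 0.48,
carboxylate-GGL 0.30, amine 0.05, thiol 0.04, Cys α/β carbons 0.08,
other α-carbons 0.05 (carboxylates total 0.78, matching the reported
share), a concrete atom uniformly within the class, and the guest oxygen
is placed at Normal(2.65, 0.15) Å along a direction that (a) avoids
clashes and (b) stays beyond the 3.5 Å criterion distance from every
attack-point atom outside the chosen functional group — the sibling
carboxylate oxygen is allowed, which is what produces multi-contact
frames. The guest hydrogen is oriented so the acceptor–H–donor angle is
uniform in (110°, 180°), guaranteeing detection; O–H bond lengths are
Boltzmann draws of the harmonic bond, sd = √(kB·T/K_b) (the ½k x²
convention) ≈ 0.037 Å at 310 K. Non-contact frames place the guest
uniformly in the box at ≥ 4.5 Å from the host. If a site is geometrically
incompatible with a conformer, the conformer (not the site) is redrawn,
so the configured propensities are exact; a bounded retry budget turns
truly impossible configurations into errors.

*What passing tests do and do not show.* Because every class of contact
site is inside the census's attack-point selection and cross-site
contamination is excluded by construction, the census recovering the
propensities (78% ± binomial noise carboxylate, 4% thiol) validates the
detector–census chain end to end, on data whose contact statistics are
known exactly. It does not validate force-field realism: the emulator
has no water, no kinetics between contact states (frames are
exchangeable draws), single-functional-group contacts only (so
three-contact frames and zwitterionic/anionic multi-group motifs occur
only in engineered or user-supplied data), and its folded conformers
retain the GGL amine–carboxylate salt bridge, so the intramolecular
hydrogen-bond fraction is far above the published < 0.05% (screening
that interaction requires explicit solvent, which is out of scope).
Absolute g(r) magnitudes are likewise larger than published values
because no water competes for the contact shell; positions and
normalized rankings are the meaningful outputs.

## Numerical choices and limitations

- Superposition uses SVD with a determinant correction (proper rotations
  only); collinear fit sets are rejected.
- Distance kernels never wrap coordinates; only the RDF applies
  minimum-image, and only when a box is declared.
- Surface difference requires commensurate bins and aligns on the union
  of occupied ranges; modal-cell ties resolve to the lowest (x, y)
  origin, representative-structure ties to the earliest frame.
- Degenerate inputs fail loudly: empty selections/series, non-finite
  coordinates, non-increasing frame times, zero-length angle arms, hills
  deposited outside the walls.
- The extended-XYZ dialect stores `time=<ps>` on the comment line; PDB
  I/O (via biotite) keeps coordinates at the format's 10⁻³ Å precision.
- Determinism: one `numpy` Generator per run seeds everything; paired
  systems derive child seeds from the master seed; reruns are
  byte-identical.
- Desk-scale defaults keep the full test suite and the acceptance script
  within minutes on one CPU: 25 000-frame trajectories for the
  study-scale checks, 2×10⁶-step metadynamics for the benchmark.
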