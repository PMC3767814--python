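# gshrad

Trajectory analysis of molecular radical recognition: how glutathione
(GSH, the tripeptide γ-Glu–Cys–Gly, modelled as its physiological anion)
catches and steers a hydroxyl radical (OH•). The package is aimed at
computational chemists analysing host–guest MD trajectories of this
system — or testing such analyses without access to the original
simulations, via its seeded synthetic-trajectory generator.

## What it computes

Given a multi-frame trajectory of the 38-atom GSH + OH• system (or a
generated one), `gshrad` produces the standard characterization of the
recognition process:

- **Flexibility surfaces** — heavy-atom RMSD vs the extended reference
  (Kabsch superposition per frame), radius of gyration R_gyr, the
  head–tail metrics HT = min d(GLY.OT1/OT2, GGL.OT1/OT2/N) and
  CYS-HT = min d(CYS.SG, head/tail atoms), and their 0.25 Å
  percentage-distribution surfaces with difference surfaces for paired
  (with/without guest) runs, modal cells and representative structures.
- **Radial distribution functions** — g(r) between the guest oxygen and
  every host heavy atom, with the normalized maxima
  Norm = g(r)max / min g(r)max and the ranking of probable radical
  attack points (Norm ≥ 1.5).
- **Interaction census** — geometric hydrogen-bond detection in both
  donation directions under d(A···D) < 3.5 Å and α(A···H–D) > 100°,
  per-frame contact patterns over the ten attack-point atoms, contact
  tiers (≥1, ≥2, =3), per-site fractions (carboxylate "catching" share,
  thiol share, GLY/GGL terminus split) and zwitterionic/anionic motif
  classification.
- **Occupancy map** — the OpenDX volumetric map of guest positions
  around the superposed host for multi-contact frames.
- **Metadynamics** — a standard (non-tempered) metadynamics engine over
  the two collective variables d(OT1–OH•) and d(SG–OH•) with
  0.03 kcal/mol × 0.05 Å Gaussian hills and walls at 6 Å, run with an
  overdamped Langevin sampler on analytic model potentials and checked
  against direct Boltzmann references (the molecular system is not
  re-simulated).

The generator emulates the study conditions statistically: host
conformers from a mean-reverting torsion walk on an internal-coordinate
template (RMSD ~1–3 Å, R_gyr ~3.0–4.5 Å), guest contacts in ~9.2% of
frames at 2.65 ± 0.15 Å with configurable per-site propensities
(carboxylates 0.78, thiol 0.04 by default), and guest O–H bond lengths
Boltzmann-distributed for the harmonic bond b₀ = 0.9791 Å,
K_b = 444.8474 kcal/mol/Å² at 310 K. See `docs/methods.md` for the full
model description and what the emulator deliberately does not reproduce.

## Worked example

Interaction census of a generated 8000-frame trajectory
(`examples/04_interaction_census.py`):

```text
frames analysed            : 8000
frames with >=1 contact    : 679 (8.5%)
frames with >=2 contacts   : 163
carboxylate contact share  : 75.7% (the 'catching' anchors)
thiol contact share        : 5.6% (the antioxidant site itself)
GLY vs GGL terminus split  : 47% / 34% of multi-contact frames
```

About 8.5% of frames carry at least one guest–host contact (the
configured rate is 9.2%; the difference is binomial noise at this run
length). Roughly three quarters of the contact frames anchor the radical
at a deprotonated carboxylate — the catching step — while direct thiol
contacts, the site of the actual antioxidant chemistry, are rare; the
glycine terminus dominates the multi-contact frames that reflect
steering. Each `examples/` script is a narrative single capability:
topology and trajectory I/O, flexibility surfaces, RDF ranking, the
census with the occupancy map, and the metadynamics benchmark, e.g.

```bash
python examples/05_metadynamics_benchmark.py
```

prints the number of hills deposited, the mean absolute deviation of the
reconstructed free-energy surface from the Boltzmann reference
(≈ 0.08 kcal/mol over the low-free-energy region) and the two located
minima vs their analytic positions.

A thin CLI wraps the same library calls:

```bash
gshrad generate --seed 1 --frames 1000 --out traj.pdb
gshrad analyze --seed 1 --frames 1000 --outdir out/
gshrad census --traj traj.pdb
gshrad metadyn-bench --seed 1
```

## Layout

```
src/gshrad/
  topology.py      atoms, charges, selections, host/guest partition
  template.py      extended reference conformer, rotatable torsions
  trajio.py        multi-model PDB / extended XYZ / OpenDX I/O
  geometry.py      Kabsch, RMSD, R_gyr, HT metrics, angles
  rdf.py           g(r), normalized maxima, attack-point ranking
  surfaces.py      2D percentage surfaces, differences, occupancy grid
  interactions.py  contact detection, census, motif classification
  metadyn.py       hills, Langevin sampler, FES reconstruction, minima
  synthgen.py      seeded synthetic-trajectory generator
  pipeline.py      end-to-end orchestration (summary.json and artifacts)
  cli.py           `gshrad` console entry point
```
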