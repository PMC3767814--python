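"""Radial distribution functions and radical attack-point ranking.

Computes g(r) between the guest oxygen and host heavy atoms on a
synthetic run, then demonstrates the normalization arithmetic on the
bundled literature reference maxima: each g(r)max is divided by the
smallest one, and sites with a normalized value above 1.5 are flagged as
probable attack points.
"""

from gshrad import GeneratorConfig, generate
from gshrad.rdf import (RDFResult, compute_rdf, normalize_gmax,
                        rank_attack_points, table1_frame)
from gshrad.reference import REFERENCE_GMAX
from gshrad.topology import build_gsh_oh_topology

traj = generate(GeneratorConfig(seed=9, n_frames=4000))
print("synthetic run, selected g(r) maxima (guest O vs host atom):")
for tok in ("GLY.OT2", "GGL.OT1", "CYS.SG", "GGL.O"):
    res = compute_rdf(traj, tok)
    print(f"  {tok:8s} r = {res.r_at_max:.2f} A   g(r)max = {res.g_max:6.2f}")
print("  (carboxylate oxygens are strongly enriched at contact range;")
print("   the 2.65 A shell reflects the configured contact distance)\n")

top = build_gsh_oh_topology()
results = [RDFResult.from_gmax(tok, g) for tok, (_, g, _) in REFERENCE_GMAX.items()]
normalize_gmax(results)
ranked = rank_attack_points(results, threshold=1.5, topology=top)
print("literature reference maxima, normalized (top rows):")
table = table1_frame(sorted(results, key=lambda r: -r.norm)[:5])
print(table[["Res.", "Atom", "g(r)max", "Norm."]].round(2).to_string(index=False))
print(f"\n{len(ranked)} sites exceed 1.5x the baseline probability; "
      f"ranked: {', '.join(ranked)}")
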