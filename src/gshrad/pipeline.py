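"""End-to-end orchestration of the full recognition-analysis workflow.

``run_full_analysis`` executes, in order: per-frame structural metrics,
population surfaces (plus the paired difference surface), representative
structures, the radial-distribution table with attack-point ranking, the
interaction census and motif classification, the guest occupancy map, and
optionally the metadynamics double-well benchmark — writing TSV/JSON/DX/PDB
artifacts into one output directory together with a machine-readable
``summary.json`` holding every headline statistic.

Reruns with the same configuration and seed produce byte-identical numeric
reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import geometry, interactions, metadyn, rdf, surfaces, synthgen, trajio
from .synthgen import GeneratorConfig
from .template import reference_coordinates
from .topology import build_gsh_oh_topology, select

__all__ = ["RunConfig", "PipelineError", "run_full_analysis"]

log = logging.getLogger("gshrad")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration of a full analysis run.

    Either ``input_path`` points at an existing trajectory (multi-model
    PDB or extended XYZ) or the synthetic ``generator`` config is used;
    with ``paired`` a matched host-only run is generated for the
    difference surface.
    """

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    input_path: str | None = None
    input_format: str | None = None
    paired: bool = True
    outdir: str = "gshrad_out"
    surface_bin_width: float = 0.25
    rdf_bin_width: float = 0.10
    rdf_r_max: float = 10.0
    attack_threshold: float = 1.5
    occupancy_spacing: float = 0.5
    run_metadyn_benchmark: bool = False
    metadyn_steps: int = 400_000
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        gen = raw.pop("generator", None)
        cfg = cls(**raw)
        if gen:
            cfg.generator = GeneratorConfig(**gen)
        return cfg


def _round_floats(obj, ndigits=6):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def _metrics(traj, label, outdir):
    top = traj.topology
    heavy = select(top, "host_heavy")
    # reference indexed like the trajectory's own topology (host-only
    # topologies drop the two guest atoms at the tail)
    ref_coords = reference_coordinates()[:top.n_atoms]
    rmsd = geometry.rmsd_series(traj, ref_coords, heavy)
    rgyr = geometry.rgyr_series(traj, heavy)
    ht, cys_ht = geometry.ht_series(traj)
    for name, vals in (("rmsd", rmsd), ("rgyr", rgyr),
                       ("ht", ht), ("cys_ht", cys_ht)):
        geometry.metric_table(traj, vals, name).to_csv(
            outdir / f"{label}_{name}.tsv", sep="\t", index=False,
            float_format="%.6f")
    return {"rmsd": rmsd, "rgyr": rgyr, "ht": ht, "cys_ht": cys_ht}


def run_full_analysis(config: RunConfig) -> dict:
    """Run the whole workflow; returns the summary dict (also written as
    ``summary.json`` in the output directory)."""
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": _round_floats(asdict(config))}

    stage = "inputs"
    try:
        if config.input_path:
            traj = trajio.read_trajectory(config.input_path,
                                          format=config.input_format)
            host_traj = None
        elif config.paired and config.generator.include_guest:
            host_traj, traj = synthgen.generate_paired_systems(config.generator)
        else:
            traj = synthgen.generate(config.generator)
            host_traj = None
        has_guest = traj.topology.has_guest
        log.info("inputs: %d frames (guest: %s)", traj.n_frames, has_guest)

        stage = "metrics"
        m = _metrics(traj, "system", outdir)
        summary["n_frames"] = traj.n_frames
        summary["rmsd_mean"] = float(np.mean(m["rmsd"]))
        summary["rgyr_mean"] = float(np.mean(m["rgyr"]))
        m_host = _metrics(host_traj, "host_only", outdir) if host_traj else None

        stage = "surfaces"
        w = config.surface_bin_width
        surf = surfaces.population_surface(m["rmsd"], m["rgyr"], w,
                                           x_name="rmsd", y_name="rgyr")
        surf.to_frame().to_csv(outdir / "surface_rmsd_rgyr.tsv", sep="\t",
                               float_format="%.6f")
        surf_ht = surfaces.population_surface(m["ht"], m["cys_ht"], w,
                                              x_name="ht", y_name="cys_ht")
        surf_ht.to_frame().to_csv(outdir / "surface_ht_cysht.tsv", sep="\t",
                                  float_format="%.6f")
        cell = surfaces.modal_cell(surf)
        summary["modal_cell"] = _round_floats({
            "rmsd_lo": cell.x_lo, "rmsd_hi": cell.x_hi,
            "rgyr_lo": cell.y_lo, "rgyr_hi": cell.y_hi,
            "percent": cell.percent})
        if m_host is not None:
            surf_h = surfaces.population_surface(m_host["rmsd"], m_host["rgyr"],
                                                 w, x_name="rmsd", y_name="rgyr")
            diff = surfaces.difference_surface(surf, surf_h)
            summary["difference_surface_max_abs"] = round(diff.max_abs, 6)
            diff_ht = surfaces.difference_surface(
                surf_ht, surfaces.population_surface(
                    m_host["ht"], m_host["cys_ht"], w,
                    x_name="ht", y_name="cys_ht"))
            summary["difference_surface_ht_max_abs"] = round(diff_ht.max_abs, 6)

        stage = "representative"
        rep = surfaces.representative_structure(traj, m["rmsd"], m["rgyr"], cell)
        summary["representative_frame"] = int(rep)
        rep_traj = trajio.Trajectory(topology=traj.topology,
                                     coords=traj.coords[rep:rep + 1],
                                     stride=traj.stride)
        trajio.write_trajectory(rep_traj, outdir / "representative.pdb")

        stage = "intramolecular"
        summary["intramolecular_hbond_fraction"] = round(
            interactions.intramolecular_hbond_census(traj), 6)

        if has_guest:
            stage = "rdf"
            top = traj.topology
            results = [rdf.compute_rdf(traj, top.token_of(i),
                                       bin_width=config.rdf_bin_width,
                                       r_max=config.rdf_r_max)
                       for i in select(top, "host_heavy")]
            enriched = [res for res in results if res.g_max > 0]
            if enriched:
                rdf.normalize_gmax(enriched)
                ranked = rdf.rank_attack_points(enriched,
                                                config.attack_threshold, top)
                summary["attack_points_ranked"] = ranked
            rdf.table1_frame(results).to_csv(outdir / "rdf_table.tsv",
                                             sep="\t", index=False,
                                             float_format="%.2f")

            stage = "census"
            patterns = interactions.frame_patterns(traj)
            import pandas as pd

            pd.DataFrame(
                [(p.frame, p.n_contacts, p.motif,
                  ",".join(sorted(p.contact_set))) for p in patterns],
                columns=["frame", "n_contacts", "motif", "contacts"],
            ).to_csv(outdir / "frame_patterns.tsv", sep="\t", index=False)
            census = interactions.pattern_census(traj, patterns=patterns)
            summary["census"] = _round_floats(census.as_dict())
            summary["triple_interaction_frames"] = \
                interactions.triple_interaction_frames(traj, patterns=patterns)
            with open(outdir / "census.json", "w") as fh:
                json.dump(_round_floats(census.as_dict()), fh, indent=2,
                          sort_keys=True)

            stage = "volumetric"
            ge2 = [p.frame for p in patterns if p.n_contacts >= 2]
            if ge2:
                grid = surfaces.occupancy_grid(
                    traj, ge2, spacing=config.occupancy_spacing)
                trajio.write_dx(grid, outdir / "occupancy.dx")
                summary["occupancy_frames"] = len(ge2)
        else:
            log.info("host-only input: guest-dependent stages skipped")
            summary["skipped"] = ["rdf", "census", "volumetric"]

        if config.run_metadyn_benchmark:
            stage = "metadynamics"
            bench = metadyn.run_double_well_benchmark(
                seed=config.generator.seed, steps=config.metadyn_steps)
            summary["metadyn"] = _round_floats({
                "mad": bench["mad"],
                "n_hills": bench["n_hills"],
                "minima": [(mn.cv1, mn.cv2) for mn in bench["minima"].minima[:2]],
                "analytic_minima": bench["analytic_minima"],
            })
            bench["fes"].to_frame().to_csv(outdir / "metadyn_fes.tsv",
                                           sep="\t", float_format="%.4f")
            bench["result"].hills.to_frame().to_csv(
                outdir / "metadyn_hills.tsv", sep="\t", index=False,
                float_format="%.4f")
    except PipelineError:
        raise
    except Exception as exc:
        log.error("stage %r failed: %s", stage, exc)
        raise PipelineError(stage, exc) from exc

    with open(outdir / "summary.json", "w") as fh:
        json.dump(_round_floats(summary), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
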