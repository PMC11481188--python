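"""End-to-end pipeline: simulate -> preprocess -> modules -> enrich ->
trajectories -> onset -> timeline.

``run_all`` chains every stage on a synthetic cohort with a single seed and
writes all intermediate tables as plain text, so two runs with the same
seed are byte-identical. It is the workhorse behind the ``run-all`` CLI
subcommand and the end-to-end tests.
"""

from __future__ import annotations

import json
import pathlib
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from . import enrich, netmod, onset, preprocess, synth, timeline, traj

__all__ = ["PipelineResult", "run_all"]


@dataclass
class PipelineResult:
    truth: synth.GroundTruth
    normalized: preprocess.NormalizedExpression
    modules: netmod.ModuleSet
    fits: pd.DataFrame
    enrichment: pd.DataFrame
    tipping_points: pd.DataFrame
    staining_fit: onset.SigmoidFit
    width_fit: traj.TrajectoryFit
    events: list
    timeline: pd.DataFrame


def _float_csv(df: pd.DataFrame, path, **kw) -> None:
    df.to_csv(path, float_format="%.10g", **kw)


def run_all(
    outdir,
    seed: int = 0,
    n_samples: int = 35,
    min_total: int = 30,
    power: float = 12.0,
    min_module_size: int = 30,
    deep_split: int = 2,
    merge_threshold: float = 0.25,
    alpha: float = 0.05,
    epsilon: float = 0.02,
    human_factor: float = 4.0,
    truth: synth.GroundTruth | None = None,
) -> PipelineResult:
    """Run the complete analysis on a synthetic cohort and write outputs."""
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- simulate ---------------------------------------------------------
    truth = truth if truth is not None else synth.default_ground_truth(seed, n_samples)
    synth.write_cohort(truth, outdir)
    expr = synth.generate_expression(truth)
    staining = synth.generate_staining(truth, n_animals=26)
    widths = synth.generate_widths(truth)
    ages = np.asarray(truth.sample_ages)
    pathways = {p.pathway_id: list(p.members) for p in truth.pathway_plan}

    # --- preprocess -------------------------------------------------------
    counts = preprocess.filter_low_counts(expr.counts, min_total=min_total)
    norm = preprocess.tmm_normalize(counts)
    scaled = preprocess.scale_per_transcript(norm.matrix)
    _float_csv(norm.scaling_factors.to_frame(), outdir / "tmm_factors.csv")

    # --- modules ----------------------------------------------------------
    modules = netmod.find_age_modules(
        scaled, ages, power=power, min_module_size=min_module_size,
        deep_split=deep_split, merge_threshold=merge_threshold, alpha=alpha,
    )
    modules.labels.to_frame().to_csv(outdir / "module_labels.csv")
    _float_csv(modules.eigengenes, outdir / "eigengenes.csv")
    _float_csv(modules.age_stats, outdir / "age_stats.csv")

    # --- trajectories (all module members; a symmetric quadratic trajectory
    # can carry no linear age correlation, so the linear screen must not
    # gate the tipping-point analysis) ------------------------------------
    in_module = modules.labels[modules.labels != netmod.UNASSIGNED].index
    fits = traj.fit_all_trajectories(scaled.loc[in_module], ages, alpha=alpha)
    _float_csv(fits, outdir / "trajectory_fits.tsv", sep="\t")

    # --- enrichment -------------------------------------------------------
    directions = enrich.assign_directions(
        modules.labels[modules.labels != netmod.UNASSIGNED], modules.age_stats, fits
    )
    universe = list(counts.index)
    enrichment = enrich.enrich_pathways(directions, pathways, universe, alpha=alpha)
    _float_csv(enrichment, outdir / "enrichment.tsv", sep="\t")

    # --- pathway tipping points -------------------------------------------
    tp_rows = []
    events: list[timeline.Event] = []
    for pw_id, members in pathways.items():
        tp = traj.pathway_tipping_point(fits, members, pw_id)
        if tp is None:
            continue
        tp_rows.append(
            {
                "pathway_id": pw_id,
                "mean_vertex": tp.mean_vertex,
                "sd_vertex": tp.sd_vertex,
                "n_members": tp.n_members,
            }
        )
        events.append(
            timeline.Event(label=pw_id, baboon_age=tp.mean_vertex,
                           source="pathway_tipping", sd=tp.sd_vertex)
        )
    tipping = pd.DataFrame(tp_rows).set_index("pathway_id") if tp_rows else pd.DataFrame()
    _float_csv(tipping, outdir / "tipping_points.tsv", sep="\t")

    # --- onset ------------------------------------------------------------
    sfit = onset.analyze_staining(staining, epsilon=epsilon)
    with open(outdir / "staining_fit.json", "w") as fh:
        json.dump(asdict(sfit), fh, indent=2, sort_keys=True)
    events.append(
        timeline.Event("GAG accumulation", (sfit.onset_age, sfit.end_age),
                       source="staining_window")
    )
    events.append(
        timeline.Event("GAG fast accumulation", (sfit.fast_start, sfit.fast_end),
                       source="staining_window")
    )

    # --- morphometry ------------------------------------------------------
    wfit = traj.fit_trajectory(widths["age"].to_numpy(), widths["width_um"].to_numpy())
    if wfit.chosen_model == "quadratic" and wfit.vertex_in_range:
        events.append(
            timeline.Event("Cardiomyocyte width increase", wfit.vertex_age,
                           source="morphometry")
        )

    # --- timeline ---------------------------------------------------------
    tl = timeline.timeline_table(events, factor=human_factor)
    _float_csv(tl, outdir / "timeline.tsv", sep="\t", index=False)
    with open(outdir / "timeline.json", "w") as fh:
        json.dump(tl.to_dict(orient="records"), fh, indent=2, sort_keys=True)

    return PipelineResult(
        truth=truth,
        normalized=norm,
        modules=modules,
        fits=fits,
        enrichment=enrichment,
        tipping_points=tipping,
        staining_fit=sfit,
        width_fit=wfit,
        events=events,
        timeline=tl,
    )
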