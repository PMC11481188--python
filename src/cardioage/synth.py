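"""Synthetic longitudinal cohorts with planted ground truth.

Emulates a cross-sectional-in-age primate cohort: ~35 animals spanning
7.5-22.1 years, a bulk RNA-seq count matrix in which groups of transcripts
(modules) share a latent trajectory of age that is flat, linear, or
quadratic with a known vertex, pathway gene sets with controlled up/down
composition, and per-animal histology read-outs (staining fractions on a
logistic curve, cardiomyocyte widths on a quadratic) -- so that every
downstream stage of the pipeline can be exercised against known truth.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence.spawn``, so each generator draws from an
independent, reproducible stream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd

TRAJECTORY_KINDS = ("flat", "linear", "quadratic")

__all__ = [
    "ModulePlan",
    "PathwayPlan",
    "StainingParams",
    "NoiseModel",
    "GroundTruth",
    "SyntheticExpression",
    "generate_ages",
    "generate_expression",
    "generate_staining",
    "generate_widths",
    "default_ground_truth",
    "write_cohort",
]


@dataclass(frozen=True)
class ModulePlan:
    """One planted co-expression module.

    ``correlation`` is the target within-module Pearson correlation of the
    latent (pre-count-noise) signals; 0 means members are independent noise
    transcripts (the unassigned background).
    """

    module_id: int
    n_transcripts: int
    kind: str  # flat | linear | quadratic
    slope: float = 0.0  # natural-log units per year (linear)
    vertex_age: float | None = None  # years (quadratic only)
    curvature: float = 0.0  # natural-log units per year^2 (quadratic)
    correlation: float = 0.85
    profile_sd: float = 0.6  # age-independent co-regulation shared by members

    def validate(self, age_min: float, age_max: float) -> None:
        if self.kind not in TRAJECTORY_KINDS:
            raise ValueError(f"unknown trajectory kind {self.kind!r}")
        if self.n_transcripts <= 0:
            raise ValueError("module plan with zero transcripts")
        if self.kind == "quadratic":
            if self.vertex_age is None:
                raise ValueError("quadratic module requires a vertex_age")
            if not (age_min <= self.vertex_age <= age_max):
                raise ValueError("planted vertex_age must lie inside the age range")
        elif self.vertex_age is not None:
            raise ValueError("vertex_age is only defined for quadratic modules")
        if not (0.0 <= self.correlation <= 1.0):
            raise ValueError("within-module correlation must be in [0, 1]")


@dataclass(frozen=True)
class PathwayPlan:
    """A planted gene set: member transcript IDs with their true direction."""

    pathway_id: str
    members: tuple[str, ...]
    directions: tuple[int, ...]  # +1 / -1 per member

    def __post_init__(self):
        if len(self.members) != len(self.directions):
            raise ValueError("one direction per pathway member required")
        if any(d not in (-1, 1) for d in self.directions):
            raise ValueError("directions must be +1 or -1")


@dataclass(frozen=True)
class StainingParams:
    """4-parameter logistic for the staining fraction vs age.

    fraction(a) = baseline + amplitude / (1 + exp(-rate * (a - midpoint_age)))
    """

    baseline: float = 0.02
    amplitude: float = 0.10
    midpoint_age: float = 16.3
    rate: float = 0.4  # per year


@dataclass(frozen=True)
class NoiseModel:
    nb_dispersion: float = 0.08  # NB variance = mu + dispersion * mu^2
    staining_sd: float = 0.005  # Gaussian sd on staining fractions
    library_size_sigma: float = 0.15  # log-normal sigma of per-sample depth


@dataclass(frozen=True)
class GroundTruth:
    sample_ages: tuple[float, ...]
    module_plan: tuple[ModulePlan, ...]
    pathway_plan: tuple[PathwayPlan, ...] = ()
    staining_params: StainingParams = StainingParams()
    noise: NoiseModel = NoiseModel()
    seed: int = 0

    @property
    def age_min(self) -> float:
        return min(self.sample_ages)

    @property
    def age_max(self) -> float:
        return max(self.sample_ages)

    def validate(self) -> None:
        if len(self.sample_ages) < 3:
            raise ValueError("need at least 3 samples")
        for plan in self.module_plan:
            plan.validate(self.age_min, self.age_max)


@dataclass
class SyntheticExpression:
    """Raw counts plus the noise-free latent signal and per-transcript truth."""

    counts: pd.DataFrame  # transcripts x samples, integer
    latent: pd.DataFrame  # transcripts x samples, natural-log scale
    truth_table: pd.DataFrame  # transcript_id, module_id, kind, vertex_age, loading
    library_factors: pd.Series  # per-sample depth multiplier


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_ages(n: int, age_min: float, age_max: float, seed: int) -> np.ndarray:
    """Draw ``n`` ages uniformly on [age_min, age_max], sorted ascending."""
    if n <= 0:
        raise ValueError("n must be positive")
    if n < 3:
        raise ValueError("need at least 3 samples")
    if not age_min < age_max:
        raise ValueError("age_min must be below age_max")
    rng = np.random.default_rng(seed)
    return np.sort(rng.uniform(age_min, age_max, size=n))


def _latent_profile(plan: ModulePlan, ages: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Shared module trajectory over samples, mean-centred (natural log scale).

    On top of the deterministic age trajectory every module carries its own
    age-independent random profile (sd ``profile_sd``): co-regulated genes
    share variation beyond the age trend, and without it modules whose
    trajectories are correlated curves of age would be inseparable in any
    correlation network. Flat modules consist of this random profile alone.
    """
    if plan.correlation == 0.0:
        return np.zeros_like(ages)
    if plan.profile_sd > 0:
        raw = rng.normal(0.0, 1.0, size=ages.size)
        # age-independent means exactly that: project out the quadratic age
        # design so co-regulation cannot masquerade as an age trajectory
        design = np.column_stack([np.ones_like(ages), ages, ages**2])
        beta, *_ = np.linalg.lstsq(design, raw, rcond=None)
        resid = raw - design @ beta
        coreg = resid * (plan.profile_sd / resid.std())
    else:
        coreg = 0.0
    if plan.kind == "flat":
        prof = np.zeros_like(ages)
    elif plan.kind == "linear":
        prof = plan.slope * (ages - ages.mean())
    else:  # quadratic
        prof = plan.curvature * (ages - plan.vertex_age) ** 2
    prof = prof + coreg
    return prof - prof.mean()


def generate_expression(truth: GroundTruth) -> SyntheticExpression:
    """Simulate a raw count matrix from the planted module structure.

    Each member transcript's latent log-signal is ``baseline + loading * shared
    + tau * eps`` with loading ~ U[0.6, 1.0] and ``tau`` set so that pairs of
    members correlate at the plan's declared level; counts are negative
    binomial around ``exp(latent)`` scaled by a log-normal per-sample library
    factor. ``nb_dispersion = 0`` falls back to Poisson noise.
    """
    truth.validate()
    ages = np.asarray(truth.sample_ages, dtype=float)
    n_samples = ages.size
    rng_lib = _streams(truth.seed, 2)[0]
    module_rngs = _streams(truth.seed + 1, max(len(truth.module_plan), 1))

    sample_ids = [f"S{i + 1:02d}" for i in range(n_samples)]
    lib = np.exp(rng_lib.normal(0.0, truth.noise.library_size_sigma, size=n_samples))
    lib /= lib.mean()

    rows, latent_rows, records = [], [], []
    for plan, rng in zip(truth.module_plan, module_rngs):
        shared = _latent_profile(plan, ages, rng)
        var_shared = shared.var()
        loadings = rng.uniform(0.6, 1.0, size=plan.n_transcripts)
        baselines = rng.uniform(np.log(100.0), np.log(1500.0), size=plan.n_transcripts)
        rho = plan.correlation
        if rho > 0.0 and var_shared > 0.0:
            # members correlate at ~rho when tau^2 = l^2 var(shared)(1-rho)/rho
            tau = np.sqrt((0.8**2) * var_shared * (1.0 - rho) / rho)
        else:
            tau = 0.4 if rho == 0.0 else 0.0
            if rho == 0.0:
                loadings = np.zeros_like(loadings)
        for t in range(plan.n_transcripts):
            eps = rng.normal(0.0, 1.0, size=n_samples) if tau > 0 else 0.0
            latent = baselines[t] + loadings[t] * shared + tau * eps
            rows.append(latent)
            latent_rows.append(latent)
            records.append(
                {
                    "transcript_id": f"M{plan.module_id}_T{t + 1:03d}",
                    "module_id": plan.module_id,
                    "kind": plan.kind,
                    "vertex_age": plan.vertex_age if plan.kind == "quadratic" else np.nan,
                    "loading": loadings[t],
                }
            )

    latent = np.asarray(latent_rows)
    mu = np.exp(latent) * lib[None, :]
    rng_counts = _streams(truth.seed + 2, 1)[0]
    disp = truth.noise.nb_dispersion
    if disp > 0.0:
        r = 1.0 / disp
        p = r / (r + mu)
        counts = rng_counts.negative_binomial(r, p)
    else:
        counts = rng_counts.poisson(mu)

    tt = pd.DataFrame(records)
    idx = pd.Index(tt["transcript_id"], name="transcript_id")
    return SyntheticExpression(
        counts=pd.DataFrame(counts, index=idx, columns=sample_ids),
        latent=pd.DataFrame(latent, index=idx, columns=sample_ids),
        truth_table=tt.set_index("transcript_id"),
        library_factors=pd.Series(lib, index=sample_ids, name="library_factor"),
    )


def staining_curve(ages: np.ndarray, params: StainingParams) -> np.ndarray:
    a = np.asarray(ages, dtype=float)
    return params.baseline + params.amplitude / (
        1.0 + np.exp(-params.rate * (a - params.midpoint_age))
    )


def generate_staining(
    truth: GroundTruth, n_animals: int, images_per_animal: int = 6
) -> pd.DataFrame:
    """Per-image staining fractions on a noisy logistic curve of age.

    Returns a long table (animal, age, image_id, fraction); each animal
    contributes ``images_per_animal`` replicate images.
    """
    p = truth.staining_params
    if p.amplitude <= 0 or p.rate <= 0:
        raise ValueError("staining amplitude and rate must be positive")
    if not (0.0 <= p.baseline and p.baseline + p.amplitude <= 1.0):
        raise ValueError("expected staining fractions leave [0, 1]")
    rng_ages, rng_noise = _streams(truth.seed + 3, 2)
    ages = np.sort(rng_ages.uniform(truth.age_min, truth.age_max, size=n_animals))
    rows = []
    for i, age in enumerate(ages):
        expected = float(staining_curve(np.array([age]), p)[0])
        noise = rng_noise.normal(0.0, truth.noise.staining_sd, size=images_per_animal)
        fracs = np.clip(expected + noise, 0.0, 1.0)
        for j in range(images_per_animal):
            rows.append(
                {
                    "animal": f"A{i + 1:02d}",
                    "age": age,
                    "image_id": f"img{j + 1}",
                    "fraction": fracs[j],
                }
            )
    return pd.DataFrame(rows)


def generate_widths(
    truth: GroundTruth,
    vertex_age: float = 13.0,
    baseline: float = 14.0,
    curvature: float = 0.08,
    sd: float = 0.4,
) -> pd.DataFrame:
    """Per-animal cardiomyocyte widths (micrometres), quadratic in age.

    Width is flat until the vertex then grows; used to exercise the
    morphometry arm of the timeline.
    """
    rng = _streams(truth.seed + 4, 1)[0]
    ages = np.asarray(truth.sample_ages, dtype=float)
    mean = baseline + curvature * (ages - vertex_age) ** 2
    width = mean + rng.normal(0.0, sd, size=ages.size)
    return pd.DataFrame(
        {
            "animal": [f"A{i + 1:02d}" for i in range(ages.size)],
            "age": ages,
            "width_um": width,
        }
    )


def default_ground_truth(seed: int = 0, n_samples: int = 35) -> GroundTruth:
    """The reference synthetic cohort used throughout the test-bench.

    35 animals aged 7.5-22.1 years; three quadratic modules whose vertices
    plant the event ordering metabolism-down (12.9 y) < GAG metabolism
    (13.7 y) < hypertrophy signalling (14.6 y), one linearly increasing
    module, and an unassigned noise background; pathways that subsample the
    modules with the matching direction, plus one null pathway drawn from
    the background.
    """
    ages = tuple(generate_ages(n_samples, 7.5, 22.1, seed))
    modules = (
        ModulePlan(1, 40, "quadratic", vertex_age=12.9, curvature=-0.02),
        ModulePlan(2, 40, "quadratic", vertex_age=13.7, curvature=0.02),
        ModulePlan(3, 40, "quadratic", vertex_age=14.6, curvature=0.02),
        ModulePlan(4, 35, "linear", slope=0.07),
        ModulePlan(0, 80, "flat", correlation=0.0),
    )

    def members(mid: int, n: int) -> tuple[str, ...]:
        return tuple(f"M{mid}_T{t + 1:03d}" for t in range(n))

    # null pathway sampled proportionally from the whole universe so its
    # overlap with the age-correlated set is hypergeometric-random
    null_members = tuple(
        f"M{mid}_T{t + 26:03d}" for mid, k in ((1, 3), (2, 3), (3, 3), (4, 3)) for t in range(k)
    ) + tuple(f"M0_T{t + 21:03d}" for t in range(8))
    pathways = (
        PathwayPlan("OXPHOS_TCA", members(1, 25), (-1,) * 25),
        PathwayPlan("GAG_METABOLISM", members(2, 25), (1,) * 25),
        PathwayPlan("CARDIAC_HYPERTROPHY", members(3, 25), (1,) * 25),
        PathwayPlan("ECM_SIGNALING", members(4, 20), (1,) * 20),
        PathwayPlan("NULL_SET", null_members, (1, -1) * 10),
    )
    return GroundTruth(
        sample_ages=ages,
        module_plan=modules,
        pathway_plan=pathways,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# on-disk cohort


def write_gmt(pathways: Sequence[PathwayPlan], path) -> None:
    with open(path, "w") as fh:
        for pw in pathways:
            fh.write("\t".join([pw.pathway_id, "synthetic"] + list(pw.members)) + "\n")


def read_gmt(path) -> dict[str, list[str]]:
    """Parse a GMT gene-set file: name <tab> description <tab> genes..."""
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            out[parts[0]] = [g for g in parts[2:] if g]
    return out


def write_cohort(truth: GroundTruth, outdir, n_staining_animals: int = 26) -> dict:
    """Write the full synthetic cohort to ``outdir`` as plain-text files.

    counts.tsv (transcripts x samples), ages.csv, pathways.gmt, staining.csv,
    widths.csv, and truth.json recording the plan. Returns the file map.
    """
    import pathlib

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    expr = generate_expression(truth)
    staining = generate_staining(truth, n_staining_animals)
    widths = generate_widths(truth)

    paths = {
        "counts": outdir / "counts.tsv",
        "ages": outdir / "ages.csv",
        "gmt": outdir / "pathways.gmt",
        "staining": outdir / "staining.csv",
        "widths": outdir / "widths.csv",
        "truth": outdir / "truth.json",
        "truth_table": outdir / "truth_table.csv",
    }
    expr.counts.to_csv(paths["counts"], sep="\t")
    pd.DataFrame(
        {"sample_id": expr.counts.columns, "age_years": list(truth.sample_ages)}
    ).to_csv(paths["ages"], index=False)
    write_gmt(truth.pathway_plan, paths["gmt"])
    staining.to_csv(paths["staining"], index=False)
    widths.to_csv(paths["widths"], index=False)
    expr.truth_table.to_csv(paths["truth_table"])
    with open(paths["truth"], "w") as fh:
        json.dump(asdict(truth), fh, indent=2, sort_keys=True, default=float)
    return paths
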