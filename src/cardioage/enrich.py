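"""Directional pathway enrichment.

Overlap significance by the two-tailed Fisher's exact test against a stated
transcript universe, Benjamini-Hochberg control across pathways, a pathway
activation z-score summarising member directionality, and an exact binomial
test for category skew (e.g. "20 of 24 downregulated pathways are
metabolic").

Member directions x_i are +/-1, encoded downstream of module detection: the
sign of the module-age correlation, overridden for transcripts with a
quadratic trajectory by the slope sign just after the vertex (the sign of
the quadratic coefficient). The activation z-score is z = sum(x_i)/sqrt(N);
the denominator is configurable because the plain sum and the mean are
occasionally seen in the wild, but sqrt(N) is the standard choice that
makes z a unit-variance statistic under random directions.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import binomtest, fisher_exact
from statsmodels.stats.multitest import multipletests

__all__ = [
    "fisher_enrichment",
    "bh_adjust",
    "activation_zscore",
    "binomial_skew_test",
    "assign_directions",
    "enrich_pathways",
]


def fisher_enrichment(set_genes, pathway_genes, universe_genes):
    """Two-tailed Fisher's exact test of set x pathway membership.

    Returns ``(table, p)`` where table is the 2x2 array
    [[in-set & in-pathway, in-set & out], [out-of-set & in-pathway, out & out]].
    Genes outside the universe are ignored.
    """
    universe = set(universe_genes)
    if not universe:
        raise ValueError("empty universe")
    s = set(set_genes) & universe
    p = set(pathway_genes) & universe
    a = len(s & p)
    b = len(s - p)
    c = len(p - s)
    d = len(universe) - a - b - c
    table = np.array([[a, b], [c, d]])
    _, pval = fisher_exact(table, alternative="two-sided")
    return table, float(pval)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def activation_zscore(directions, denominator: str = "sqrt") -> float:
    """Directional consistency of a pathway: z = sum(x_i) / sqrt(N).

    ``denominator`` may be "sqrt" (default, unit-variance statistic), "n"
    (the mean direction), or "none" (the raw sum).
    """
    x = np.asarray(list(directions), dtype=float)
    if x.size == 0:
        raise ValueError("directions must be non-empty")
    if not np.all(np.isin(x, (-1.0, 1.0))):
        raise ValueError("directions must be +1 or -1")
    total = x.sum()
    if denominator == "sqrt":
        return float(total / np.sqrt(x.size))
    if denominator == "n":
        return float(total / x.size)
    if denominator == "none":
        return float(total)
    raise ValueError(f"unknown denominator {denominator!r}")


def binomial_skew_test(k: int, n: int, p0: float = 0.5) -> float:
    """Exact two-tailed binomial test of k successes in n trials.

    The two-tailed p is the total probability of outcomes no more likely
    than the observed one (the minimum-likelihood method).
    """
    if not 0 < p0 < 1:
        raise ValueError("p0 must lie in (0, 1)")
    if n < 1 or not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n and n >= 1")
    return float(binomtest(k, n, p0, alternative="two-sided").pvalue)


def assign_directions(
    labels: pd.Series,
    age_stats: pd.DataFrame,
    fits: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-transcript direction (+1/-1) and inherited module p-value.

    The direction is the sign of the transcript's module-age correlation;
    for transcripts whose chosen trajectory is quadratic it is overridden by
    the post-vertex slope sign, i.e. the sign of the quadratic coefficient.
    Transcripts with neither a signed module nor a quadratic fit are
    excluded with a warning. ``fits`` is the per-transcript table from
    :func:`cardioage.traj.fit_all_trajectories` (may be None).
    """
    rows, dropped = [], []
    for t, mod in labels.items():
        direction = None
        p = np.nan
        if mod in age_stats.index:
            r = age_stats.loc[mod, "pearson_r"]
            if np.isfinite(r) and r != 0:
                direction = 1 if r > 0 else -1
                p = float(age_stats.loc[mod, "p_value"])
        if fits is not None and t in fits.index:
            row = fits.loc[t]
            if row["chosen_model"] == "quadratic" and row["B2_quad"] != 0:
                direction = 1 if row["B2_quad"] > 0 else -1
        if direction is None:
            dropped.append(t)
            continue
        rows.append({"transcript_id": t, "direction": direction, "p_value": p})
    if dropped:
        warnings.warn(f"{len(dropped)} transcripts had no direction source; excluded",
                      stacklevel=2)
    if not rows:
        return pd.DataFrame(columns=["direction", "p_value"],
                            index=pd.Index([], name="transcript_id"))
    return pd.DataFrame(rows).set_index("transcript_id")


def enrich_pathways(
    directions: pd.DataFrame,
    pathways: dict[str, list[str]],
    universe: list[str],
    alpha: float = 0.05,
    z_denominator: str = "sqrt",
) -> pd.DataFrame:
    """Fisher + BH + activation z-score for every pathway.

    ``directions`` is the table from :func:`assign_directions` (its index is
    the age-correlated gene set); ``universe`` is typically every transcript
    that passed the count filter.
    """
    set_genes = list(directions.index)
    rows = []
    for pw_id, members in pathways.items():
        table, pval = fisher_enrichment(set_genes, members, universe)
        overlap = [g for g in members if g in directions.index]
        z = activation_zscore(directions.loc[overlap, "direction"], z_denominator) if overlap else 0.0
        rows.append(
            {
                "pathway_id": pw_id,
                "N": len(overlap),
                "n_pathway": len(set(members) & set(universe)),
                "n_set_in_pathway": int(table[0, 0]),
                "fisher_p": pval,
                "z": z,
            }
        )
    out = pd.DataFrame(rows).set_index("pathway_id")
    out["bh_adjusted_p"] = bh_adjust(out["fisher_p"].to_numpy())
    out["significant"] = out["bh_adjusted_p"] <= alpha
    return out
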