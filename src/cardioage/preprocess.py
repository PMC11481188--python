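"""Count filtering, TMM normalization, and per-transcript scaling.

TMM (trimmed mean of M-values) computes one scaling factor per sample by
comparing it against a reference sample: per-transcript log2 expression
ratios (M) are trimmed at the extremes jointly with average log abundances
(A), and the surviving M values are combined in a precision-weighted mean.
Factors are rescaled so their geometric mean is 1. Normalized expression is
reported as log2 counts-per-million after dividing by ``library size x
factor`` with a pseudocount.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "NormalizedExpression",
    "filter_low_counts",
    "tmm_factors",
    "tmm_normalize",
    "scale_per_transcript",
]


@dataclass
class NormalizedExpression:
    matrix: pd.DataFrame  # transcripts x samples, log2 CPM
    scaling_factors: pd.Series  # per-sample TMM factor, geometric mean 1
    kept_transcripts: pd.Index


def filter_low_counts(counts: pd.DataFrame, min_total: int = 30) -> pd.DataFrame:
    """Drop transcripts whose total count across all samples is below
    ``min_total`` (strictly less; a row summing exactly to the threshold is
    kept). Row order is preserved."""
    if counts.size == 0:
        raise ValueError("empty count matrix")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    return counts.loc[counts.sum(axis=1) >= min_total]


def _tmm_factor_one(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float = 0.30,
    abundance_trim: float = 0.05,
) -> float:
    """TMM factor of one sample against the reference.

    Doubly trimmed (30% of M, 5% of A) weighted mean of log2 ratios, with
    inverse asymptotic binomial variances as weights.
    """
    pos = (obs > 0) & (ref > 0)
    if not pos.any():
        raise ValueError("sample shares no positively expressed transcripts with the reference")
    obs, ref = obs[pos].astype(float), ref[pos].astype(float)
    m = np.log2((obs / lib_obs) / (ref / lib_ref))
    a = 0.5 * (np.log2(obs / lib_obs) + np.log2(ref / lib_ref))
    v = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)

    finite = np.isfinite(m) & np.isfinite(a)
    m, a, v = m[finite], a[finite], v[finite]
    n = m.size
    if n == 0:
        return 1.0

    rank_m, rank_a = rankdata(m), rankdata(a)
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * abundance_trim) + 1
    hi_a = n + 1 - lo_a
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    w = 1.0 / v[keep]
    f = np.sum(w * m[keep]) / np.sum(w)
    if not np.isfinite(f) or abs(f) < 1e-10:
        f = 0.0
    return float(2.0**f)


def tmm_factors(counts: pd.DataFrame) -> pd.Series:
    """Per-sample TMM scaling factors (geometric mean 1).

    The reference is the sample whose 75th-percentile count fraction is
    closest to the mean of those fractions across samples.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM requires at least 2 samples")
    x = counts.to_numpy(dtype=float)
    lib = x.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("every sample must have a positive total count")
    f75 = np.quantile(x / lib[None, :], 0.75, axis=0)
    ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.array(
        [
            _tmm_factor_one(x[:, j], x[:, ref_idx], lib[j], lib[ref_idx])
            for j in range(x.shape[1])
        ]
    )
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def tmm_normalize(counts: pd.DataFrame, pseudocount: float = 0.5) -> NormalizedExpression:
    """TMM-normalize a raw count matrix to log2 counts-per-million.

    normalized = log2((count + pseudocount) / (library_size * factor) * 1e6)
    """
    factors = tmm_factors(counts)
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    eff = lib * factors.to_numpy()
    norm = np.log2((counts.to_numpy(dtype=float) + pseudocount) / eff[None, :] * 1e6)
    return NormalizedExpression(
        matrix=pd.DataFrame(norm, index=counts.index, columns=counts.columns),
        scaling_factors=factors,
        kept_transcripts=counts.index,
    )


def scale_per_transcript(matrix: pd.DataFrame) -> pd.DataFrame:
    """Scale each transcript row to mean 0, population standard deviation 1.

    Constant rows map to all-zero. Idempotent up to floating-point error.
    """
    if matrix.shape[1] < 2:
        raise ValueError("scaling requires at least 2 samples")
    x = matrix.to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)  # population (ddof=0) convention
    safe = np.where(sd > 0, sd, 1.0)
    z = (x - mu) / safe
    z[(sd == 0).ravel(), :] = 0.0
    return pd.DataFrame(z, index=matrix.index, columns=matrix.columns)
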