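"""Linear-vs-quadratic trajectory fitting and tipping-point extraction.

Each transcript's expression y is regressed on age x under both nested
models

    linear:     y = B0 + B1 x
    quadratic:  y = B0 + B1 x + B2 x^2

and the quadratic is retained when the extra-sum-of-squares F test rejects
at alpha = 0.05:

    F = (SSE_lin - SSE_quad) / (SSE_quad / (n - 3)),  F ~ F(1, n - 3).

Whether age matters at all is judged by the t test of the top-order
coefficient of the chosen model (B1 = 0 under linear, B2 = 0 under
quadratic). For quadratic trajectories the vertex -B1/(2 B2) is the age at
which the trajectory changes direction (the "tipping point"); a pathway's
tipping point is the mean +/- standard deviation of its members' vertices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.stats import f as f_dist
from scipy.stats import t as t_dist
from sklearn.decomposition import PCA

__all__ = [
    "TrajectoryFit",
    "PathwayTippingPoint",
    "fit_trajectory",
    "fit_all_trajectories",
    "vertex",
    "pathway_tipping_point",
    "pathway_average_profile",
    "cluster_profiles",
    "pca_profiles",
]

_SSE_TOL = 1e-10  # relative threshold below which a fit is residual-free


@dataclass
class TrajectoryFit:
    linear_coef: tuple[float, float]  # (B0, B1)
    quad_coef: tuple[float, float, float]  # (B0, B1, B2)
    sse_linear: float
    sse_quadratic: float
    df_linear: int
    df_quadratic: int
    f_stat: float
    f_p: float
    chosen_model: str  # "linear" | "quadratic"
    age_effect_p: float
    vertex_age: float | None
    vertex_in_range: bool


def _ols(x_design: np.ndarray, y: np.ndarray):
    """Least squares with coefficient standard errors and residual SS."""
    coef, _, rank, _ = np.linalg.lstsq(x_design, y, rcond=None)
    resid = y - x_design @ coef
    sse = float(resid @ resid)
    df = y.size - x_design.shape[1]
    if df > 0 and rank == x_design.shape[1]:
        sigma2 = sse / df
        cov = sigma2 * np.linalg.inv(x_design.T @ x_design)
        se = np.sqrt(np.diag(cov))
    else:
        se = np.full(x_design.shape[1], np.nan)
    return coef, se, sse, df


def _coef_p(coef: float, se: float, df: int, sse: float, scale: float) -> float:
    if sse <= _SSE_TOL * scale:  # residual-free fit: t test degenerates
        return 0.0 if abs(coef) > 1e-8 else 1.0
    if not np.isfinite(se) or se == 0 or df <= 0:
        return np.nan
    return float(2.0 * t_dist.sf(abs(coef) / se, df))


def fit_trajectory(ages, values, alpha: float = 0.05,
                   vertex_range_margin: float = 1.0) -> TrajectoryFit:
    """Fit both models, select by the extra-sum-of-squares F test."""
    x = np.asarray(ages, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need at least 4 (age, value) pairs")
    if np.unique(x).size < 4:
        raise ValueError("need at least 4 distinct ages")

    ones = np.ones_like(x)
    lin_coef, lin_se, sse_l, df_l = _ols(np.column_stack([ones, x]), y)
    quad_coef, quad_se, sse_q, df_q = _ols(np.column_stack([ones, x, x * x]), y)
    sse_q = min(sse_q, sse_l)  # guard: nested model cannot fit worse
    scale = max(1.0, float(y @ y))

    if sse_q <= _SSE_TOL * scale:
        if sse_l <= _SSE_TOL * scale:
            f_stat, f_p = 0.0, 1.0  # both residual-free: prefer the simpler
        else:
            f_stat, f_p = np.inf, 0.0
    else:
        f_stat = (sse_l - sse_q) / (sse_q / df_q)
        f_p = float(f_dist.sf(f_stat, 1, df_q))

    chosen = "quadratic" if f_p <= alpha else "linear"
    if chosen == "quadratic":
        age_p = _coef_p(quad_coef[2], quad_se[2], df_q, sse_q, scale)
        b1, b2 = float(quad_coef[1]), float(quad_coef[2])
        v = -b1 / (2.0 * b2) if b2 != 0 else None
    else:
        age_p = _coef_p(lin_coef[1], lin_se[1], df_l, sse_l, scale)
        v = None
    in_range = bool(
        v is not None
        and (x.min() - vertex_range_margin) <= v <= (x.max() + vertex_range_margin)
    )
    return TrajectoryFit(
        linear_coef=(float(lin_coef[0]), float(lin_coef[1])),
        quad_coef=(float(quad_coef[0]), float(quad_coef[1]), float(quad_coef[2])),
        sse_linear=sse_l,
        sse_quadratic=sse_q,
        df_linear=df_l,
        df_quadratic=df_q,
        f_stat=float(f_stat),
        f_p=float(f_p),
        chosen_model=chosen,
        age_effect_p=float(age_p),
        vertex_age=v,
        vertex_in_range=in_range,
    )


def fit_all_trajectories(expr: pd.DataFrame, ages, alpha: float = 0.05,
                         vertex_range_margin: float = 1.0) -> pd.DataFrame:
    """Row-wise trajectory fits; returns one table row per transcript."""
    rows = []
    for t in expr.index:
        fit = fit_trajectory(ages, expr.loc[t].to_numpy(), alpha, vertex_range_margin)
        rows.append(
            {
                "transcript_id": t,
                "B0_lin": fit.linear_coef[0],
                "B1_lin": fit.linear_coef[1],
                "B0_quad": fit.quad_coef[0],
                "B1_quad": fit.quad_coef[1],
                "B2_quad": fit.quad_coef[2],
                "sse_linear": fit.sse_linear,
                "sse_quadratic": fit.sse_quadratic,
                "f_stat": fit.f_stat,
                "f_p": fit.f_p,
                "chosen_model": fit.chosen_model,
                "age_effect_p": fit.age_effect_p,
                "vertex_age": np.nan if fit.vertex_age is None else fit.vertex_age,
                "vertex_in_range": fit.vertex_in_range,
            }
        )
    return pd.DataFrame(rows).set_index("transcript_id")


def vertex(b1: float, b2: float) -> float:
    """Vertex age -B1/(2 B2) of a quadratic trajectory."""
    if b2 == 0:
        raise ValueError("no vertex: quadratic coefficient is zero")
    return -b1 / (2.0 * b2)


@dataclass
class PathwayTippingPoint:
    pathway_id: str
    vertices: np.ndarray
    mean_vertex: float
    sd_vertex: float
    n_members: int
    sd_defined: bool  # False when only one eligible member


def pathway_tipping_point(fits: pd.DataFrame, members, pathway_id: str = "") -> PathwayTippingPoint | None:
    """Mean +/- sample SD of member vertices.

    Only members whose chosen model is quadratic and whose vertex lies
    within the observed age range contribute. Returns None (with a warning)
    when no member is eligible.
    """
    present = [m for m in members if m in fits.index]
    sub = fits.loc[present]
    eligible = sub[(sub["chosen_model"] == "quadratic") & sub["vertex_in_range"]]
    v = eligible["vertex_age"].to_numpy(dtype=float)
    if v.size == 0:
        warnings.warn(f"pathway {pathway_id!r}: no eligible quadratic members", stacklevel=2)
        return None
    sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    return PathwayTippingPoint(
        pathway_id=pathway_id,
        vertices=v,
        mean_vertex=float(v.mean()),
        sd_vertex=sd,
        n_members=int(v.size),
        sd_defined=v.size > 1,
    )


def pathway_average_profile(expr_scaled: pd.DataFrame, members, ages):
    """Per-sample mean of member scaled expression, with its trajectory fit."""
    present = [m for m in members if m in expr_scaled.index]
    if not present:
        raise ValueError("no pathway members present in the matrix")
    profile = expr_scaled.loc[present].mean(axis=0)
    return profile, fit_trajectory(ages, profile.to_numpy())


def cluster_profiles(expr_scaled: pd.DataFrame):
    """Average-linkage hierarchical clustering of row profiles on Euclidean
    distance. Returns (leaf order as row positions, linkage matrix). Ties in
    merge distance are broken deterministically by scipy's lowest-index rule."""
    if expr_scaled.shape[0] < 2:
        raise ValueError("need at least 2 transcripts")
    z = linkage(expr_scaled.to_numpy(dtype=float), method="average", metric="euclidean")
    return leaves_list(z), z


def pca_profiles(expr_scaled: pd.DataFrame, n_components: int | None = None):
    """PCA of row profiles (transcripts as observations).

    Returns (scores, explained variance ratios); the ratios sum to <= 1.
    """
    x = expr_scaled.to_numpy(dtype=float)
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 transcripts and 2 samples")
    k = n_components or min(x.shape[0] - 1, x.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(x)
    return scores, pca.explained_variance_ratio_
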