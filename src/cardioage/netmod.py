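"""Weighted co-expression module detection and age screening.

A simplified WGCNA-style workflow: soft-thresholded (|r|^beta, unsigned)
adjacency, topological overlap transformation, average-linkage hierarchical
clustering of 1 - TOM with a static height cut mapped from the deep-split
level, eigengene extraction, merging of modules with similar eigengenes,
and Pearson correlation of module eigengenes with age. Transcripts not
assigned to any module keep label 0 (the conventional "grey" background).

The dynamic hybrid tree-cut of the reference package is deliberately
replaced by a static quantile cut; the intent is faithful module recovery
on data with planted structure, not bit-compatibility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr

__all__ = [
    "ModuleSet",
    "soft_adjacency",
    "topological_overlap",
    "detect_modules",
    "module_eigengene",
    "merge_close_modules",
    "correlate_modules_with_age",
    "find_age_modules",
]

UNASSIGNED = 0


@dataclass
class ModuleSet:
    labels: pd.Series  # transcript -> module id (0 = unassigned)
    eigengenes: pd.DataFrame  # samples x modules, unit variance
    age_stats: pd.DataFrame  # module, pearson_r, p_value, significant, n_transcripts


def soft_adjacency(expr: pd.DataFrame, power: float = 12.0) -> np.ndarray:
    """Unsigned soft-threshold adjacency |pearson_r|^power with unit diagonal.

    Constant transcript rows have undefined correlations; their adjacencies
    are set to 0 and a warning is emitted.
    """
    if expr.shape[1] < 4:
        raise ValueError("need at least 4 samples")
    x = expr.to_numpy(dtype=float)
    sd = x.std(axis=1)
    if (sd == 0).any():
        warnings.warn("constant transcript rows: adjacency set to 0", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x)
    corr = np.nan_to_num(corr, nan=0.0)
    adj = np.abs(corr) ** power
    np.fill_diagonal(adj, 1.0)
    return np.clip(adj, 0.0, 1.0)


def topological_overlap(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of an adjacency in [0, 1].

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) for
    i != j, with k the connectivity (row sum excluding the diagonal) and the
    shared-neighbour sum excluding u in {i, j}; diagonal 1.
    """
    a = np.asarray(adjacency, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    b = a.copy()
    np.fill_diagonal(b, 0.0)
    k = b.sum(axis=1)
    shared = b @ b  # includes no u==i/u==j terms because diag(b)=0
    denom = np.minimum.outer(k, k) + 1.0 - b
    tom = (shared + b) / denom
    np.fill_diagonal(tom, 1.0)
    return tom


def detect_modules(
    tom: np.ndarray,
    min_module_size: int = 30,
    deep_split: int = 2,
    index: pd.Index | None = None,
) -> pd.Series:
    """Cut the average-linkage tree of 1 - TOM into modules.

    The cut height is chosen adaptively: every merge height is a candidate
    cut, and the one producing the largest number of clusters of at least
    ``min_module_size`` members wins. Ties are broken toward the lowest
    (finest) qualifying cut when ``deep_split >= 2`` and toward the highest
    otherwise, mirroring the role of the deep-split level in dynamic tree
    cutting. A fixed-height cut is hopeless here because soft-thresholding
    at high powers compresses all dissimilarities into a narrow band whose
    location depends on the data. Clusters below ``min_module_size`` are
    assigned label 0. Surviving modules are relabelled 1..K by decreasing
    size so labels are deterministic.
    """
    n = tom.shape[0]
    idx = index if index is not None else pd.RangeIndex(n)
    if n < min_module_size:
        warnings.warn("fewer transcripts than min_module_size: all unassigned", stacklevel=2)
        return pd.Series(UNASSIGNED, index=idx, name="module_id")
    dist = 1.0 - tom
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    z = linkage(squareform(dist, checks=False), method="average")
    heights = np.unique(z[:, 2])
    best_raw, best_score, eps = None, (-1,), 1e-12
    candidates = heights if deep_split >= 2 else heights[::-1]
    for cut in candidates:
        raw_c = fcluster(z, t=cut + eps, criterion="distance")
        _, counts = np.unique(raw_c, return_counts=True)
        big = counts >= min_module_size
        # prefer more min-size clusters; among those, capture more members
        score = (int(big.sum()), int(counts[big].sum()))
        if score > best_score:
            best_raw, best_score = raw_c, score
    raw = best_raw

    labels = np.zeros(n, dtype=int)
    ids, counts = np.unique(raw, return_counts=True)
    next_id = 1
    for cl in ids[np.lexsort((ids, -counts))]:  # size desc, cluster id asc
        if counts[ids == cl][0] >= min_module_size:
            labels[raw == cl] = next_id
            next_id += 1
    return pd.Series(labels, index=idx, name="module_id")


def module_eigengene(expr_scaled: pd.DataFrame, member_mask: np.ndarray) -> np.ndarray:
    """First principal component of a module's scaled submatrix.

    Computed over samples (observations = samples, variables = member
    transcripts), sign-aligned so the eigengene correlates non-negatively
    with the module's mean expression profile, and scaled to unit
    (population) variance.
    """
    sub = expr_scaled.to_numpy(dtype=float)[member_mask, :]
    if sub.shape[0] < 2:
        raise ValueError("module needs at least 2 members")
    if not np.any(sub.std(axis=1) > 0):
        raise ValueError("singular module submatrix")
    # rows are already mean-centred; PCA of samples = SVD of sub.T
    u, s, _ = np.linalg.svd(sub.T, full_matrices=False)
    eig = u[:, 0]
    mean_profile = sub.mean(axis=0)
    if np.dot(eig, mean_profile) < 0:
        eig = -eig
    sd = eig.std()
    if sd == 0:
        raise ValueError("degenerate eigengene")
    return eig / sd


def compute_eigengenes(expr_scaled: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    mods = sorted(m for m in labels.unique() if m != UNASSIGNED)
    data = {
        m: module_eigengene(expr_scaled, (labels == m).to_numpy()) for m in mods
    }
    return pd.DataFrame(data, index=expr_scaled.columns)


def merge_close_modules(
    expr_scaled: pd.DataFrame, labels: pd.Series, merge_threshold: float = 0.25
) -> pd.Series:
    """Iteratively merge module pairs with eigengene dissimilarity
    (1 - pearson r) below ``merge_threshold``, recomputing eigengenes after
    each merge, until no pair qualifies. The closest pair merges first; the
    merged module keeps the smaller id."""
    labels = labels.copy()
    while True:
        mods = sorted(m for m in labels.unique() if m != UNASSIGNED)
        if len(mods) < 2:
            break
        eig = compute_eigengenes(expr_scaled, labels)
        best, best_d = None, np.inf
        for i, mi in enumerate(mods):
            for mj in mods[i + 1 :]:
                d = 1.0 - np.corrcoef(eig[mi], eig[mj])[0, 1]
                if d < best_d - 1e-12:
                    best, best_d = (mi, mj), d
        if best is None or best_d >= merge_threshold:
            break
        keep, drop = best
        labels[labels == drop] = keep
    # compact ids to 1..K by decreasing size for determinism
    mods = [m for m in labels.unique() if m != UNASSIGNED]
    sizes = {m: int((labels == m).sum()) for m in mods}
    order = sorted(mods, key=lambda m: (-sizes[m], m))
    remap = {m: i + 1 for i, m in enumerate(order)}
    remap[UNASSIGNED] = UNASSIGNED
    return labels.map(remap).rename("module_id")


def correlate_modules_with_age(
    eigengenes: pd.DataFrame,
    ages: np.ndarray,
    r_threshold: float = 0.30,
    alpha: float = 0.05,
    labels: pd.Series | None = None,
) -> pd.DataFrame:
    """Pearson correlation of each eigengene with age.

    A module is flagged significant when |r| >= r_threshold and the
    two-tailed t-based p-value is <= alpha. Zero-variance eigengenes are
    reported as r = NaN and non-significant.
    """
    ages = np.asarray(ages, dtype=float)
    if ages.size < 4:
        raise ValueError("need at least 4 samples")
    if not np.all(np.isfinite(ages)):
        raise ValueError("ages must be finite")
    rows = []
    for m in eigengenes.columns:
        e = eigengenes[m].to_numpy(dtype=float)
        if e.std() == 0 or ages.std() == 0:
            r, p, sig = np.nan, np.nan, False
        else:
            r, p = pearsonr(e, ages)
            sig = bool(abs(r) >= r_threshold and p <= alpha)
        n_members = int((labels == m).sum()) if labels is not None else np.nan
        rows.append(
            {"module_id": m, "pearson_r": r, "p_value": p, "significant": sig,
             "n_transcripts": n_members}
        )
    return pd.DataFrame(rows).set_index("module_id")


def find_age_modules(
    expr_scaled: pd.DataFrame,
    ages: np.ndarray,
    power: float = 12.0,
    min_module_size: int = 30,
    deep_split: int = 2,
    merge_threshold: float = 0.25,
    r_threshold: float = 0.30,
    alpha: float = 0.05,
) -> ModuleSet:
    """End-to-end module detection and age screening on scaled expression."""
    adj = soft_adjacency(expr_scaled, power=power)
    tom = topological_overlap(adj)
    labels = detect_modules(tom, min_module_size=min_module_size,
                            deep_split=deep_split, index=expr_scaled.index)
    if (labels != UNASSIGNED).any():
        labels = merge_close_modules(expr_scaled, labels, merge_threshold)
        eig = compute_eigengenes(expr_scaled, labels)
        stats = correlate_modules_with_age(eig, ages, r_threshold, alpha, labels)
    else:
        eig = pd.DataFrame(index=expr_scaled.columns)
        stats = pd.DataFrame(
            columns=["pearson_r", "p_value", "significant", "n_transcripts"]
        )
    return ModuleSet(labels=labels, eigengenes=eig, age_stats=stats)
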