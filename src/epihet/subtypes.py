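"""Epigenetic subtype discovery from hyper-variable peaks.

PCA on the row-centered HVP-by-tumor-sample matrix, a permutation test for
which components carry signal, one-way ANOVA of component scores against
clinical covariates, and PC1-based hierarchical clustering whose number of
clusters is chosen by consensus stability under 80% subsampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage


@dataclass
class PcaResult:
    scores: pd.DataFrame            # sample x PC
    loadings: np.ndarray            # peak x PC
    variance_explained: np.ndarray
    significant: np.ndarray | None = None
    perm_null_quantiles: np.ndarray | None = None


def pca_on_hvps(matrix: pd.DataFrame, tol: float = 1e-12) -> PcaResult:
    """PCA of the row-centered (per-peak) matrix; no unit-variance scaling.

    Signal magnitudes are already normalized and the peaks were selected
    *by* variance, so variance carries information.  Components are
    oriented so the largest-magnitude loading entry is positive.  Only
    components with nonzero singular value are returned.
    """
    if matrix.shape[1] < 3:
        raise ValueError("need >= 3 samples for PCA")
    if matrix.shape[0] < 2:
        raise ValueError("need >= 2 peaks for PCA")
    x = matrix.to_numpy(dtype=float)
    x = x - x.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    keep = s > tol * max(s[0], 1.0)
    u, s, vt = u[:, keep], s[keep], vt[keep]
    # sign convention: largest-|.| loading entry positive per component
    flip = np.sign(u[np.abs(u).argmax(axis=0), np.arange(u.shape[1])])
    flip[flip == 0] = 1.0
    u = u * flip
    vt = vt * flip[:, None]
    scores = (vt.T * s)  # sample scores
    var_exp = s**2 / np.sum(s**2)
    return PcaResult(
        scores=pd.DataFrame(
            scores,
            index=matrix.columns,
            columns=[f"PC{i + 1}" for i in range(len(s))],
        ),
        loadings=u,
        variance_explained=var_exp,
    )


def significant_pcs(
    matrix: pd.DataFrame,
    n_perm: int = 1000,
    level: float = 0.05,
    seed: int = 0,
    max_pcs: int | None = None,
) -> PcaResult:
    """Permutation test for which principal components carry structure.

    The null shuffles each peak's values across samples independently and
    recomputes the variance-explained spectrum; PC j is significant when
    its observed share exceeds the (1-level) null quantile, and the flags
    are truncated at the first non-significant component.
    """
    if n_perm < 100:
        warnings.warn(
            f"n_perm={n_perm} < 100 gives a coarse null", stacklevel=2
        )
    res = pca_on_hvps(matrix)
    obs = res.variance_explained
    k = len(obs) if max_pcs is None else min(max_pcs, len(obs))
    rng = np.random.default_rng(seed)
    x = matrix.to_numpy(dtype=float)
    null = np.zeros((n_perm, k))
    for b in range(n_perm):
        xp = rng.permuted(x, axis=1)
        xp = xp - xp.mean(axis=1, keepdims=True)
        s = np.linalg.svd(xp, compute_uv=False)
        ve = s**2 / np.sum(s**2)
        null[b] = ve[:k]
    q = np.quantile(null, 1.0 - level, axis=0)
    raw = obs[:k] > q
    flags = np.zeros(k, dtype=bool)
    for j in range(k):
        if not raw[j]:
            break
        flags[j] = True
    res.significant = flags
    res.perm_null_quantiles = q
    return res


def associate_pc_covariate(
    scores: pd.Series, covariate: pd.Series
) -> tuple[float, float, bool]:
    """One-way ANOVA of a PC score on a categorical covariate.

    Returns (F, p, degenerate) where ``degenerate`` marks zero
    within-group variance with separated means (p reported as 0).
    """
    cov = covariate.reindex(scores.index)
    if cov.isna().any():
        raise ValueError("covariate missing for some samples")
    groups = [scores[cov == lv].to_numpy(dtype=float) for lv in cov.unique()]
    if len(groups) < 2:
        raise ValueError("covariate must have >= 2 levels")
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    means = np.array([g.mean() for g in groups])
    if ssw == 0.0 and np.ptp(means) > 0:
        return float("inf"), 0.0, True
    with np.errstate(invalid="ignore"):
        f, p = stats.f_oneway(*groups)
    if not np.isfinite(f):  # all values identical everywhere
        return 0.0, 1.0, False
    return float(f), float(p), False


def _cut_1d(values: np.ndarray, k: int) -> np.ndarray:
    """Average-linkage Euclidean hierarchical clustering of 1-D scores."""
    z = linkage(values.reshape(-1, 1), method="average", metric="euclidean")
    return fcluster(z, t=k, criterion="maxclust")


@dataclass
class SubgroupAssignment:
    assignments: pd.DataFrame       # sample_id, group, pc1_score
    chosen_k: int
    stability: dict[int, float]     # k -> mean within-cluster consensus
    anchor: str                     # how GII was anchored
    single_cluster: bool = False


def cluster_pc1(
    pc1: pd.Series,
    k_candidates: tuple[int, ...] = (2, 3),
    n_resample: int = 500,
    subsample: float = 0.8,
    seed: int = 0,
    covariate: pd.Series | None = None,
    covariate_positive: str | None = None,
) -> SubgroupAssignment:
    """Cluster tumor samples on PC1 with a consensus-stability choice of k.

    The consensus matrix counts how often two samples co-cluster among the
    subsamples that contain both; stability for k is the mean consensus
    over within-cluster pairs of the full-data partition, and the k with
    the highest stability wins (ties -> smaller k).  GII is anchored to
    the cluster with the higher rate of ``covariate_positive`` when a
    covariate is given, else to the higher-mean-PC1 cluster.
    """
    if len(pc1) < 4:
        raise ValueError("need >= 4 samples to cluster")
    values = pc1.to_numpy(dtype=float)
    n = len(values)
    if np.allclose(values, values[0]):
        warnings.warn("all PC1 scores identical; returning one cluster",
                      stacklevel=2)
        df = pd.DataFrame(
            {"sample_id": pc1.index, "group": "GI", "pc1_score": values}
        )
        return SubgroupAssignment(df, 1, {}, anchor="degenerate",
                                  single_cluster=True)

    rng = np.random.default_rng(seed)
    m = max(2, int(round(subsample * n)))
    stability: dict[int, float] = {}
    full_labels: dict[int, np.ndarray] = {}
    for k in k_candidates:
        full_labels[k] = _cut_1d(values, k)
    hits = {k: np.zeros((n, n)) for k in k_candidates}
    both = np.zeros((n, n))
    draws = [rng.choice(n, size=m, replace=False) for _ in range(n_resample)]
    for idx in draws:
        sub = values[idx]
        pair = np.ix_(idx, idx)
        both[pair] += 1.0
        for k in k_candidates:
            lab = _cut_1d(sub, k)
            co = (lab[:, None] == lab[None, :]).astype(float)
            hits[k][pair] += co
    for k in k_candidates:
        with np.errstate(invalid="ignore"):
            consensus = np.where(both > 0, hits[k] / np.maximum(both, 1), 0.0)
        lab = full_labels[k]
        within = (lab[:, None] == lab[None, :]) & ~np.eye(n, dtype=bool)
        observed = within & (both > 0)
        stability[k] = (
            float(consensus[observed].mean()) if observed.any() else 1.0
        )
    chosen = max(sorted(k_candidates), key=lambda k: (stability[k], -k))
    labels = full_labels[chosen]

    # anchor group labels
    clusters = np.unique(labels)
    if covariate is not None and covariate_positive is not None:
        cov = covariate.reindex(pc1.index)
        rate = {
            c: float((cov[labels == c] == covariate_positive).mean())
            for c in clusters
        }
        anchor = f"covariate:{covariate.name}={covariate_positive}"
        ordered = sorted(clusters, key=lambda c: (rate[c], values[labels == c].mean()))
    else:
        anchor = "pc1_mean"
        ordered = sorted(clusters, key=lambda c: values[labels == c].mean())
    # highest rate / highest mean cluster becomes GII; with k > 2 the
    # intermediate clusters get GII.2 style suffixes in rank order
    name_map: dict[int, str] = {}
    for rank, c in enumerate(ordered):
        if rank == len(ordered) - 1:
            name_map[c] = "GII"
        elif rank == 0:
            name_map[c] = "GI"
        else:
            name_map[c] = f"G{rank + 1}"
    df = pd.DataFrame(
        {
            "sample_id": pc1.index,
            "group": [name_map[c] for c in labels],
            "pc1_score": values,
        }
    )
    return SubgroupAssignment(df, int(chosen), stability, anchor=anchor)
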