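"""Distal enhancer-to-gene assignment against an empirical correlation null.

Candidate pairs are all (enhancer, gene) combinations with the enhancer
midpoint within ±500 kb of the TSS (closed boundary).  A null distribution
of non-specific correlations is built from random pairs that are *not*
candidates (different chromosome or farther than the window); the observed
Pearson correlation of every candidate is converted to a one-sided normal
p-value under N(mu, sigma) of that null and BH-corrected; FDR < 0.05
declares a link.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_adjust
from .intervals import midpoints

LINK_WINDOW = 500_000


@dataclass
class NullModel:
    mu: float
    sigma: float
    n_pairs: int
    seed: int


def candidate_pairs(
    enhancers: pd.DataFrame, tss: pd.DataFrame, window: int = LINK_WINDOW
) -> pd.DataFrame:
    """All same-chromosome (enhancer, gene) pairs with |midpoint - TSS| <=
    window; each pair appears once."""
    mids = midpoints(enhancers)
    rows = []
    for chrom, sub in tss.groupby("chrom"):
        mask = (enhancers["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        e_idx = np.flatnonzero(mask)
        e_mid = mids[mask]
        pos = sub["tss"].to_numpy(dtype=np.int64)
        genes = sub["gene_id"].to_numpy()
        order = np.argsort(pos, kind="mergesort")
        pos, genes = pos[order], genes[order]
        lo = np.searchsorted(pos, e_mid - window, side="left")
        hi = np.searchsorted(pos, e_mid + window, side="right")
        for ei, m, l, h in zip(e_idx, e_mid, lo, hi):
            for j in range(l, h):
                rows.append(
                    (enhancers["peak_id"].iloc[ei], genes[j],
                     int(abs(int(m) - int(pos[j]))))
                )
    return pd.DataFrame(rows, columns=["peak_id", "gene_id", "distance"])


def _standardize(rows: np.ndarray) -> np.ndarray:
    """Rows scaled to zero mean, unit SD (ddof=1); zero-variance rows NaN."""
    mu = rows.mean(axis=1, keepdims=True)
    sd = rows.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return (rows - mu) / sd


def fit_null(
    signal: pd.DataFrame,
    expression: pd.DataFrame,
    enhancers: pd.DataFrame,
    tss: pd.DataFrame,
    window: int = LINK_WINDOW,
    n_pairs: int = 100_000,
    seed: int = 0,
) -> NullModel:
    """Mean/SD of Pearson correlations over random non-proximal pairs.

    Pairs are sampled uniformly with replacement from (enhancer, gene)
    combinations on different chromosomes or farther apart than the
    window.  A degenerate null (sigma = 0) raises.
    """
    common = [c for c in signal.columns if c in expression.columns]
    if len(common) < 4:
        raise ValueError("need >= 4 shared samples to correlate")
    enh = enhancers.reset_index(drop=True)
    cand = candidate_pairs(enh, tss, window=window)
    banned = set(zip(cand["peak_id"], cand["gene_id"]))
    e_ids = enh["peak_id"].to_numpy()
    g_ids = tss["gene_id"].to_numpy()
    g_ids = g_ids[np.isin(g_ids, expression.index)]
    if len(e_ids) == 0 or len(g_ids) == 0:
        raise ValueError("no enhancers or no genes with expression")
    if len(e_ids) * len(g_ids) <= len(banned):
        raise ValueError("no eligible non-proximal pairs for the null")

    rng = np.random.default_rng(seed)
    zs = _standardize(signal.loc[e_ids, common].to_numpy(dtype=float))
    ze = _standardize(expression.loc[g_ids, common].to_numpy(dtype=float))
    n = len(common)
    got: list[np.ndarray] = []
    total = 0
    while total < n_pairs:
        take = min(4 * (n_pairs - total) + 1000, 4_000_000)
        ei = rng.integers(0, len(e_ids), size=take)
        gi = rng.integers(0, len(g_ids), size=take)
        ok = np.fromiter(
            ((e_ids[a], g_ids[b]) not in banned for a, b in zip(ei, gi)),
            count=take, dtype=bool,
        )
        ei, gi = ei[ok][: n_pairs - total], gi[ok][: n_pairs - total]
        r = np.nansum(zs[ei] * ze[gi], axis=1) / (n - 1)
        got.append(r)
        total += len(r)
    corr = np.concatenate(got)
    corr = corr[np.isfinite(corr)]
    if len(corr) == 0:
        raise ValueError("no finite null correlations")
    mu = float(np.mean(corr))
    sigma = float(np.std(corr, ddof=1))
    if sigma <= 1e-12:
        raise ValueError("degenerate null: sigma = 0")
    return NullModel(mu=mu, sigma=sigma, n_pairs=int(len(corr)), seed=seed)


def link(
    pairs: pd.DataFrame,
    signal: pd.DataFrame,
    expression: pd.DataFrame,
    null: NullModel,
    alpha: float = 0.05,
    two_sided: bool = False,
) -> pd.DataFrame:
    """Score candidate pairs against the null and call links at FDR < alpha.

    One-sided on positive correlation by default (H3K27ac marks
    activation); ``two_sided=True`` tests |pcc - mu| instead.
    """
    if null.sigma <= 0:
        raise ValueError("null sigma must be positive")
    common = [c for c in signal.columns if c in expression.columns]
    n = len(common)
    zs = _standardize(signal.loc[pairs["peak_id"], common].to_numpy(dtype=float))
    ze = _standardize(
        expression.loc[pairs["gene_id"], common].to_numpy(dtype=float)
    )
    pcc = np.nansum(zs * ze, axis=1) / (n - 1)
    zstat = (pcc - null.mu) / null.sigma
    if two_sided:
        p = 2.0 * stats.norm.sf(np.abs(zstat))
    else:
        p = stats.norm.sf(zstat)
    p_adj = bh_adjust(p)
    out = pairs.copy()
    out["pcc"] = pcc
    out["p"] = p
    out["p_adj"] = p_adj
    out["is_link"] = p_adj < alpha
    return out


def null_p(pcc: float, null: NullModel) -> float:
    """Upper-tail normal probability of one correlation under the null."""
    return float(stats.norm.sf((pcc - null.mu) / null.sigma))
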