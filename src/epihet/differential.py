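"""Two-group differential tests for peak signal and gene expression.

Peaks: Welch's t-test per peak on normalized log2 signal, with MA-plot
coordinates (M = mean difference, A = mean average) and the usual
differential-site rule |M| >= 1 and BH-adjusted p <= 0.05.

Genes: the same machinery on log expression with optional adjustment for
one categorical covariate by within-stratum centering.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

LABEL_A = "A_specific"
LABEL_B = "B_specific"
LABEL_NS = "unchanged"


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _welch_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Welch p-values with explicit degenerate-variance handling:
    zero variance in both groups gives p = 1 for equal means, p = 0 for
    separated means."""
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    m = a.mean(axis=1) - b.mean(axis=1)
    degenerate = ~np.isfinite(p)
    p[degenerate & (m == 0.0)] = 1.0
    p[degenerate & (m != 0.0)] = 0.0
    return p


def differential_sites(
    matrix: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    m_cutoff: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-peak M/A/p/p_adj and A_specific / B_specific / unchanged labels.

    M = mean(A) - mean(B) on the log2 scale, so the |M| >= 1 default is the
    2-fold change rule; p from Welch's t; BH over all tested peaks.
    """
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)[:5]}")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need >= 2 samples per group")
    a = matrix[list(group_a)].to_numpy(dtype=float)
    b = matrix[list(group_b)].to_numpy(dtype=float)
    m = a.mean(axis=1) - b.mean(axis=1)
    avg = (a.mean(axis=1) + b.mean(axis=1)) / 2.0
    p = _welch_t(a, b)
    p_adj = bh_adjust(p)
    label = np.full(len(m), LABEL_NS, dtype=object)
    label[(m >= m_cutoff) & (p_adj <= alpha)] = LABEL_A
    label[(m <= -m_cutoff) & (p_adj <= alpha)] = LABEL_B
    return pd.DataFrame(
        {
            "peak_id": matrix.index.to_numpy(),
            "M": m,
            "A": avg,
            "p": p,
            "p_adj": p_adj,
            "label": label,
        }
    )


def differential_expression(
    expression: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    covariate: pd.Series | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Covariate-adjusted two-group DEG test on log expression.

    The optional covariate (indexed by sample ID) is removed by centering
    each gene within each covariate level before the Welch test; a level
    containing samples from only one group is a confound and raises.
    Returns gene_id, log2FC, p, p_adj, is_deg and the up-group label.
    """
    cols = list(group_a) + list(group_b)
    if set(group_a) & set(group_b):
        raise ValueError("groups overlap")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need >= 2 samples per group")
    x = expression[cols].to_numpy(dtype=float)
    in_a = np.array([c in set(group_a) for c in cols])
    if covariate is not None:
        cov = covariate.reindex(cols)
        if cov.isna().any():
            raise ValueError("covariate missing for some samples")
        for level, idx in cov.groupby(cov).groups.items():
            members = np.array([c in set(idx) for c in cols])
            n_a = int((members & in_a).sum())
            n_b = int((members & ~in_a).sum())
            if n_a == 0 or n_b == 0:
                raise ValueError(
                    f"covariate level {level!r} is confounded with group "
                    f"(nA={n_a}, nB={n_b})"
                )
            x[:, members] = x[:, members] - x[:, members].mean(
                axis=1, keepdims=True
            )
    a = x[:, in_a]
    b = x[:, ~in_a]
    lfc = a.mean(axis=1) - b.mean(axis=1)
    p = _welch_t(a, b)
    p_adj = bh_adjust(p)
    is_deg = p_adj < alpha
    label = np.where(lfc > 0, LABEL_A, np.where(lfc < 0, LABEL_B, LABEL_NS))
    label = np.where(is_deg, label, LABEL_NS)
    return pd.DataFrame(
        {
            "gene_id": expression.index.to_numpy(),
            "log2FC": lfc,
            "p": p,
            "p_adj": p_adj,
            "is_deg": is_deg,
            "label": label,
        }
    )
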