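"""ssGSEA scoring and GI-like / GII-like / intergroup assignment.

Each sample in an external expression cohort is scored with single-sample
GSEA against the GI-specific and GII-specific gene sets; the 1/3 and 2/3
quantiles of each score across the cohort split samples into GI-like
(high GI score, low GII score), GII-like (the converse) and the
intermediate intergroup.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

GI_LIKE = "GI_like"
GII_LIKE = "GII_like"
INTERGROUP = "intergroup"


def ssgsea(
    expression: pd.Series | np.ndarray,
    genes: list[str] | pd.Index,
    gene_set: set[str] | list[str],
    weight: float = 0.25,
) -> float:
    """Single-sample gene-set enrichment score of one expression profile.

    Genes are ranked by expression (highest gets rank N); walking down the
    ranked list, the score accumulates the difference between the weighted
    in-set ECDF (weights |rank|^weight) and the uniform out-set ECDF.  A
    rank-preserving transform of the expression leaves the score
    unchanged.  A gene set covering every expressed gene is degenerate and
    scores 0 (with a warning).
    """
    values = np.asarray(expression, dtype=float)
    genes = np.asarray(list(genes))
    if len(values) != len(genes):
        raise ValueError("expression and gene list length mismatch")
    in_set = np.isin(genes, list(gene_set))
    if not in_set.any():
        missing = sorted(set(gene_set))[:5]
        raise ValueError(
            f"gene set has no overlap with expressed genes (e.g. {missing})"
        )
    n = len(values)
    n_out = n - int(in_set.sum())
    if n_out == 0:
        warnings.warn("gene set covers all genes; score defined as 0",
                      stacklevel=2)
        return 0.0
    # descending expression; ties broken by input order (stable)
    order = np.argsort(-values, kind="mergesort")
    ranks = np.empty(n)
    ranks[order] = np.arange(n, 0, -1)  # top gene gets rank N
    w = np.abs(ranks[order]) ** weight
    inset_ordered = in_set[order]
    w_in = np.where(inset_ordered, w, 0.0)
    p_in = np.cumsum(w_in) / w_in.sum()
    p_out = np.cumsum(~inset_ordered) / n_out
    return float(np.sum(p_in - p_out))


def ssgsea_matrix(
    expression: pd.DataFrame,
    gene_set: set[str] | list[str],
    weight: float = 0.25,
    normalize: bool = False,
) -> pd.Series:
    """ssGSEA score of one gene set for every sample column.

    ``normalize=True`` rescales scores by the cohort-wide score range
    (GSVA-style); the default leaves raw scores, which is what the
    tertile assignment consumes.
    """
    scores = pd.Series(
        {
            c: ssgsea(expression[c].to_numpy(), expression.index, gene_set,
                      weight=weight)
            for c in expression.columns
        }
    )
    if normalize:
        span = scores.max() - scores.min()
        if span > 0:
            scores = scores / span
    return scores


def assign_groups(
    gi_score: pd.Series, gii_score: pd.Series
) -> pd.DataFrame:
    """Tertile-rule labels from the two subgroup scores.

    GI_like requires gi above its 2/3 quantile *and* gii below its 1/3
    quantile (strict inequalities; boundary samples fall to intergroup);
    GII_like is the mirror image; everything else is intergroup.
    Quantiles use linear interpolation between order statistics.
    """
    if not gi_score.index.equals(gii_score.index):
        gii_score = gii_score.reindex(gi_score.index)
    if len(gi_score) < 3:
        raise ValueError("need >= 3 samples for tertile assignment")
    labels = pd.Series(INTERGROUP, index=gi_score.index, dtype=object)
    if gi_score.nunique() < 3 or gii_score.nunique() < 3:
        warnings.warn("fewer than 3 distinct score values; all samples "
                      "assigned to the intergroup", stacklevel=2)
    else:
        gi_lo, gi_hi = np.quantile(gi_score, [1 / 3, 2 / 3])
        gii_lo, gii_hi = np.quantile(gii_score, [1 / 3, 2 / 3])
        labels[(gi_score > gi_hi) & (gii_score < gii_lo)] = GI_LIKE
        labels[(gii_score > gii_hi) & (gi_score < gi_lo)] = GII_LIKE
    return pd.DataFrame(
        {
            "sample_id": gi_score.index,
            "gi_score": gi_score.to_numpy(),
            "gii_score": gii_score.to_numpy(),
            "label": labels.to_numpy(),
        }
    )
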