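"""Hyper-variable peak (HVP) detection via a mean-variance trend.

Across-sample variance of normalized log2 signal grows with mean signal;
to find peaks that are *excessively* variable we fit a smooth trend of
variance on mean (running median in equal-count mean bins, linearly
interpolated, rescaled to be median-unbiased under a Gaussian null) and
score each peak with

    T = (n - 1) * var_obs / var_fit  ~  chi-square(n - 1)

under the null that the peak's variance follows the trend.  Peaks with the
upper-tail p <= alpha (default 0.01) and var_obs above the trend are HVPs.
Sex-chromosome peaks are never flagged for downstream use.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import is_sex_chromosome


def mean_variance_trend(
    means: np.ndarray, variances: np.ndarray, n_bins: int = 50
) -> np.ndarray:
    """Trend-predicted variance at each peak's mean.

    Running median of the variance in up to ``n_bins`` equal-count mean
    bins, linearly interpolated between bin centers and clamped at the
    edges.  The running median of sample variances underestimates their
    expectation, so the curve is divided by the median of
    chi2(df)/df evaluated with a nominal df; callers pass the final
    df-specific correction via :func:`hyper_variable_peaks`.
    """
    order = np.argsort(means, kind="mergesort")
    n = len(means)
    n_bins = max(1, min(n_bins, n // 20)) if n >= 40 else 1
    splits = np.array_split(order, n_bins)
    bin_x = np.array([np.median(means[s]) for s in splits])
    bin_y = np.array([np.median(variances[s]) for s in splits])
    # bin centers must be increasing for interp; enforce strict order
    keep = np.concatenate([[True], np.diff(bin_x) > 0])
    return np.interp(means, bin_x[keep], bin_y[keep])


def hyper_variable_peaks(
    matrix: pd.DataFrame,
    peaks: pd.DataFrame | None = None,
    alpha: float = 0.01,
    n_bins: int = 50,
    sex_chromosomes: tuple[str, ...] = ("chrx", "chry", "x", "y"),
) -> pd.DataFrame:
    """Score every peak for hyper-variability across the given samples.

    Parameters
    ----------
    matrix:
        Normalized peak-by-sample log2 signal restricted to one tissue
        (e.g. all tumor samples); needs >= 8 samples.
    peaks:
        Optional interval frame (chrom/start/end/peak_id) used for the
        sex-chromosome filter; without it no peak is excluded.

    Returns a frame with peak_id, mean, var_obs, var_fit, p, is_hvp.
    """
    n = matrix.shape[1]
    if n < 8:
        raise ValueError(f"need >= 8 samples for the variance test, got {n}")
    values = matrix.to_numpy(dtype=float)
    means = values.mean(axis=1)
    var_obs = values.var(axis=1, ddof=1)
    df = n - 1

    if np.allclose(var_obs, 0.0):
        var_fit = np.zeros_like(var_obs)
        p = np.ones_like(var_obs)
    else:
        trend = mean_variance_trend(means, var_obs, n_bins=n_bins)
        # median-unbias: sample variances around the trend are ~ sigma^2 *
        # chi2(df)/df whose median is below 1; rescale so E[T] matches chi2
        correction = stats.chi2.median(df) / df
        var_fit = trend / correction
        with np.errstate(divide="ignore", invalid="ignore"):
            t_stat = df * var_obs / var_fit
        p = np.where(
            var_fit > 0, stats.chi2.sf(t_stat, df), 1.0
        )

    if peaks is not None:
        chrom = (
            peaks.set_index("peak_id")["chrom"]
            .reindex(matrix.index)
            .fillna("")
        )
        excluded = is_sex_chromosome(chrom, names=sex_chromosomes)
    else:
        excluded = np.zeros(len(matrix), dtype=bool)
    is_hvp = (p <= alpha) & (var_obs > var_fit) & ~excluded
    return pd.DataFrame(
        {
            "peak_id": matrix.index.to_numpy(),
            "mean": means,
            "var_obs": var_obs,
            "var_fit": var_fit,
            "p": p,
            "is_hvp": is_hvp,
        }
    )
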