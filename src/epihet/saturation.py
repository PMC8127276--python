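"""Peak saturation analysis: novel peaks gained as samples accumulate.

For each random ordering of samples, a peak of the next sample counts as
novel when it overlaps no peak of any earlier sample (after removing
blacklist-overlapping peaks).  The cumulative curve is the running sum of
novel counts, so it is monotone non-decreasing by construction.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .intervals import overlaps_any, validate_intervals

_Chrom = dict[str, tuple[np.ndarray, np.ndarray]]


def _merge_arrays(starts: np.ndarray, ends: np.ndarray):
    """Union of intervals as sorted disjoint (starts, ends) arrays."""
    order = np.argsort(starts, kind="mergesort")
    s, e = starts[order], ends[order]
    cummax = np.maximum.accumulate(e)
    brk = np.empty(len(s), dtype=bool)
    brk[0] = True
    brk[1:] = s[1:] > cummax[:-1]
    idx = np.flatnonzero(brk)
    return s[idx], np.maximum.reduceat(cummax, idx)


def _by_chrom(df: pd.DataFrame) -> _Chrom:
    out: _Chrom = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        out[str(chrom)] = (
            sub["start"].to_numpy(dtype=np.int64),
            sub["end"].to_numpy(dtype=np.int64),
        )
    return out


def _novel(sample: _Chrom, union: _Chrom) -> int:
    count = 0
    for chrom, (qs, qe) in sample.items():
        if chrom not in union:
            count += len(qs)
            continue
        us, ue = union[chrom]
        j = np.searchsorted(ue, qs, side="right")
        hit = (j < len(us)) & (us[np.minimum(j, len(us) - 1)] < qe)
        count += int((~hit).sum())
    return count


def _absorb(union: _Chrom, sample: _Chrom) -> None:
    for chrom, (s, e) in sample.items():
        if chrom in union:
            us, ue = union[chrom]
            union[chrom] = _merge_arrays(
                np.concatenate([us, s]), np.concatenate([ue, e])
            )
        else:
            union[chrom] = _merge_arrays(s, e)


def saturation_curve(
    peaksets: Mapping[str, pd.DataFrame],
    n_perm: int = 100,
    blacklist: pd.DataFrame | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean cumulative distinct-peak and per-step novel-peak counts.

    Returns one row per step (1..n_samples) with the across-permutation
    mean and standard deviation of the cumulative count and the gain.
    """
    if len(peaksets) < 2:
        raise ValueError("need >= 2 samples")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    names = sorted(peaksets)
    cleaned: dict[str, _Chrom] = {}
    for name in names:
        df = validate_intervals(peaksets[name]).reset_index(drop=True)
        if blacklist is not None and len(blacklist):
            df = df.loc[~overlaps_any(df, blacklist)].reset_index(drop=True)
        cleaned[name] = _by_chrom(df)

    n = len(names)
    gains = np.zeros((n_perm, n), dtype=float)
    for perm in range(n_perm):
        order = rng.permutation(n)
        union: _Chrom = {}
        for step, si in enumerate(order):
            sample = cleaned[names[si]]
            gains[perm, step] = (
                sum(len(s) for s, _ in sample.values())
                if not union
                else _novel(sample, union)
            )
            _absorb(union, sample)
    cumulative = gains.cumsum(axis=1)
    return pd.DataFrame(
        {
            "step": np.arange(1, n + 1),
            "cumulative_mean": cumulative.mean(axis=0),
            "cumulative_sd": cumulative.std(axis=0, ddof=0),
            "gain_mean": gains.mean(axis=0),
            "gain_sd": gains.std(axis=0, ddof=0),
        }
    )
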