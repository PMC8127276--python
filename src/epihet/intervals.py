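"""Genomic interval algebra on 0-based half-open coordinates.

Peaks and stitched regions are plain :class:`pandas.DataFrame` objects with
at least ``chrom``, ``start`` and ``end`` columns (optionally ``peak_id`` and
``score``).  All operations treat intervals as [start, end) on the forward
strand; book-ended intervals ([10,20) followed by [20,30)) are considered
connected, matching the merge-into-a-consensus-list convention with no gap
parameter.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

INTERVAL_COLUMNS = ["chrom", "start", "end"]


class IntervalError(ValueError):
    """Raised for malformed genomic intervals."""


def validate_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Check interval invariants (start < end, nonempty chrom)."""
    for col in INTERVAL_COLUMNS:
        if col not in df.columns:
            raise IntervalError(f"missing interval column {col!r}")
    if len(df) == 0:
        return df
    starts = np.asarray(df["start"], dtype=np.int64)
    ends = np.asarray(df["end"], dtype=np.int64)
    if (starts >= ends).any():
        bad = df.loc[starts >= ends].iloc[0]
        raise IntervalError(
            f"interval with start >= end: {bad['chrom']}:{bad['start']}-{bad['end']}"
        )
    if df["chrom"].astype(str).str.len().eq(0).any():
        raise IntervalError("interval with empty chromosome name")
    return df


def sort_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Sort by (chrom, start, end) — genome order for string chromosomes."""
    return df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(
        drop=True
    )


def merge_intervals(
    frames: pd.DataFrame | Iterable[pd.DataFrame], gap: int = 0
) -> pd.DataFrame:
    """Merge intervals into the connected components of their union.

    Two intervals connect when the start of the later one is within ``gap``
    bases of the end of the earlier one (``gap=0`` merges overlapping and
    book-ended intervals; ``gap=12500`` is enhancer stitching).

    Returns a sorted, disjoint frame with columns chrom/start/end plus
    ``n_members`` and, when input rows carry ``peak_id``, a tuple-valued
    ``members`` column of the constituent peak ids.
    """
    if isinstance(frames, pd.DataFrame):
        df = frames
    else:
        frames = list(frames)
        if not frames:
            return pd.DataFrame(columns=INTERVAL_COLUMNS + ["n_members"])
        df = pd.concat(frames, ignore_index=True)
    validate_intervals(df)
    if len(df) == 0:
        return pd.DataFrame(columns=INTERVAL_COLUMNS + ["n_members"])
    df = sort_intervals(df)
    chroms = df["chrom"].to_numpy()
    starts = df["start"].to_numpy(dtype=np.int64)
    ends = df["end"].to_numpy(dtype=np.int64)

    # a new component begins where the chromosome changes or the start
    # exceeds the running maximum end of the current component by > gap
    cummax = np.maximum.accumulate(ends)
    new_chrom = np.empty(len(df), dtype=bool)
    new_chrom[0] = True
    new_chrom[1:] = chroms[1:] != chroms[:-1]
    chrom_block = np.cumsum(new_chrom)
    # reset the running max at chromosome boundaries
    cummax_per_chrom = np.empty_like(cummax)
    for _, idx in pd.Series(np.arange(len(df))).groupby(chrom_block):
        sl = idx.to_numpy()
        cummax_per_chrom[sl] = np.maximum.accumulate(ends[sl])
    breaks = new_chrom.copy()
    breaks[1:] |= starts[1:] - cummax_per_chrom[:-1] > gap
    group = np.cumsum(breaks) - 1

    res = pd.DataFrame(
        {
            "chrom": chroms,
            "start": starts,
            "end": cummax_per_chrom,
            "group": group,
        }
    )
    agg = res.groupby("group", sort=True).agg(
        chrom=("chrom", "first"), start=("start", "min"), end=("end", "max"),
        n_members=("start", "size"),
    ).reset_index(drop=True)
    if "peak_id" in df.columns:
        agg["members"] = [
            tuple(v)
            for v in df["peak_id"].groupby(group, sort=True).agg(list)
        ]
    return agg


def select_top_peaks(peaks: pd.DataFrame, k: int, score_col: str = "score") -> pd.DataFrame:
    """Keep the ``k`` most significant peaks of one sample.

    Ties on the score are broken in favor of the peak earlier in genome
    order.  Fewer than ``k`` peaks → all retained.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    validate_intervals(peaks)
    if score_col not in peaks.columns:
        raise IntervalError(f"missing score column {score_col!r}")
    ordered = peaks.sort_values(
        [score_col, "chrom", "start"],
        ascending=[False, True, True],
        kind="mergesort",
    )
    return sort_intervals(ordered.head(k))


def overlaps_any(
    query: pd.DataFrame, subject: pd.DataFrame
) -> np.ndarray:
    """Boolean mask: does each query interval overlap any subject interval?

    Both frames may be unsorted; overlap is strict (shared base), so
    book-ended intervals do not overlap.
    """
    validate_intervals(query)
    validate_intervals(subject)
    mask = np.zeros(len(query), dtype=bool)
    if len(query) == 0 or len(subject) == 0:
        return mask
    for chrom, sub in subject.groupby("chrom", sort=False):
        sel = query["chrom"].to_numpy() == chrom
        if not sel.any():
            continue
        # merge subject intervals so a sorted two-pointer suffices
        merged = merge_intervals(sub[INTERVAL_COLUMNS])
        s = merged["start"].to_numpy(dtype=np.int64)
        e = merged["end"].to_numpy(dtype=np.int64)
        qs = query.loc[sel, "start"].to_numpy(dtype=np.int64)
        qe = query.loc[sel, "end"].to_numpy(dtype=np.int64)
        # interval j is the first merged region ending after the query start
        j = np.searchsorted(e, qs, side="right")
        hit = (j < len(s)) & (s[np.minimum(j, len(s) - 1)] < qe)
        mask[np.flatnonzero(sel)] = hit
    return mask


def midpoints(df: pd.DataFrame) -> np.ndarray:
    """Integer midpoints of intervals (floor of the average)."""
    return (
        df["start"].to_numpy(dtype=np.int64) + df["end"].to_numpy(dtype=np.int64)
    ) // 2


def tss_windows(tss: pd.DataFrame, half_width: int) -> pd.DataFrame:
    """± ``half_width`` windows around TSS positions as an interval frame."""
    pos = tss["tss"].to_numpy(dtype=np.int64)
    return pd.DataFrame(
        {
            "chrom": tss["chrom"].to_numpy(),
            "start": np.maximum(pos - half_width, 0),
            "end": pos + half_width + 1,
        }
    )


def is_sex_chromosome(chroms: Sequence[str] | pd.Series,
                      names: tuple[str, ...] = ("chrx", "chry", "x", "y")) -> np.ndarray:
    """Case-insensitive chrX/chrY membership mask."""
    arr = pd.Series(chroms).astype(str).str.lower()
    return arr.isin(names).to_numpy()
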