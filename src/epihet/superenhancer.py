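"""ROSE-style super-enhancer calling and downstream SE statistics.

Distal H3K27ac peaks are stitched into enhancer regions (12.5-kb gap,
whole peaks overlapping a ±2.5-kb TSS window excluded first).  Per sample,
regions are ranked by total signal and the hockey-stick tangent rule flags
the disproportionately strong regions as super-enhancers; the SE score of
a region in a sample is the mean signal of its member peaks.  Differential
SEs come from a one-sided Fisher exact test of member differential-peak
enrichment against all other distal peaks, BH-corrected across SEs; SEs
are annotated to genes by correlating the SE score with promoter H3K27ac
signal and with gene expression inside a ±500-kb window.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .differential import LABEL_A, LABEL_B, bh_adjust
from .intervals import merge_intervals, overlaps_any, tss_windows

STITCH_GAP = 12_500
TSS_EXCLUSION = 2_500
LINK_WINDOW = 500_000


def stitch(
    peaks: pd.DataFrame,
    tss: pd.DataFrame,
    gap: int = STITCH_GAP,
    tss_excl: int = TSS_EXCLUSION,
) -> pd.DataFrame:
    """Stitch distal peaks into enhancer regions.

    Whole peaks overlapping any [tss - tss_excl, tss + tss_excl] window are
    removed first (constituent-level exclusion, not trimming); remaining
    same-chromosome peaks whose end-to-start gap is <= ``gap`` merge.
    Returns sorted disjoint regions with ``members`` peak-id tuples.
    """
    if tss_excl > 0 and len(tss):
        windows = tss_windows(tss, tss_excl)
        distal = peaks.loc[~overlaps_any(peaks, windows)]
    else:
        distal = peaks
    regions = merge_intervals(distal, gap=gap)
    if len(regions):
        regions = regions.assign(
            region_id=[f"se_region_{i + 1:04d}" for i in range(len(regions))]
        )
    return regions


def region_scores(
    regions: pd.DataFrame, signal: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample total and mean (SE score) member signal of each region."""
    totals = np.zeros((len(regions), signal.shape[1]))
    means = np.zeros_like(totals)
    for i, members in enumerate(regions["members"]):
        block = signal.loc[list(members)].to_numpy(dtype=float)
        totals[i] = block.sum(axis=0)
        means[i] = block.mean(axis=0)
    idx = regions["region_id"].to_numpy()
    return (
        pd.DataFrame(totals, index=idx, columns=signal.columns),
        pd.DataFrame(means, index=idx, columns=signal.columns),
    )


def call_ses(total_signal: pd.Series, slope_cutoff: float = 1.0) -> pd.Series:
    """Hockey-stick SE call for one sample.

    Regions are ranked by signal ascending and both axes are scaled to
    [0, 1]; scanning down from the top rank, regions stay super-enhancers
    while the discrete slope of the scaled curve exceeds ``slope_cutoff``
    (the de-facto tangent rule).  Constant signal yields no SEs.
    """
    if len(total_signal) < 10:
        raise ValueError("need >= 10 regions to call super-enhancers")
    x = total_signal.to_numpy(dtype=float)
    order = np.argsort(x, kind="mergesort")
    y = x[order]
    span = y[-1] - y[0]
    if span <= 0:
        warnings.warn("constant region signal; no super-enhancers called",
                      stacklevel=2)
        return pd.Series(False, index=total_signal.index)
    ys = (y - y[0]) / span
    xs = np.linspace(0.0, 1.0, len(y))
    slopes = np.diff(ys) / np.diff(xs)
    is_se_sorted = np.zeros(len(y), dtype=bool)
    for i in range(len(slopes) - 1, -1, -1):
        if slopes[i] > slope_cutoff:
            is_se_sorted[i + 1] = True
        else:
            break
    flags = np.zeros(len(y), dtype=bool)
    flags[order] = is_se_sorted
    return pd.Series(flags, index=total_signal.index)


def call_ses_matrix(
    total_signal: pd.DataFrame, slope_cutoff: float = 1.0
) -> pd.DataFrame:
    """Per-sample hockey-stick calls for every column."""
    return pd.DataFrame(
        {c: call_ses(total_signal[c], slope_cutoff) for c in total_signal.columns}
    )


def differential_ses(
    regions: pd.DataFrame,
    peak_labels: pd.Series,
    threshold: float = 0.05,
    label_a: str = LABEL_A,
    label_b: str = LABEL_B,
    status_a: str = "A_specific",
    status_b: str = "B_specific",
) -> pd.DataFrame:
    """Fisher-exact differential status per stitched region.

    For each region and direction the 2x2 table contrasts member peaks
    (differential vs not) with the background of all other distal peaks
    carrying labels; one-sided (enrichment) p, BH across regions per
    direction.  The direction with adjusted p <= threshold wins; if both
    pass, the smaller p; exact ties -> ``ns`` with a diagnostic column.
    """
    member_sets = [list(m) for m in regions["members"]]
    total_n = len(peak_labels)
    total_a = int((peak_labels == label_a).sum())
    total_b = int((peak_labels == label_b).sum())
    rows = []
    for members in member_sets:
        lab = peak_labels.loc[members]
        rows.append((len(members), int((lab == label_a).sum()),
                     int((lab == label_b).sum())))
    if any(total_n - n == 0 for n, _, _ in rows):
        raise ValueError(
            "empty background: a region contains every labeled distal peak"
        )

    def fisher_greater(k: int, n: int, kb: int, nb: int) -> float:
        table = [[k, n - k], [kb, nb - kb]]
        return float(stats.fisher_exact(table, alternative="greater")[1])

    # background per region: all labeled distal peaks outside that region
    p_a = np.array([
        fisher_greater(ka, n, total_a - ka, total_n - n)
        for n, ka, _ in rows
    ])
    p_b = np.array([
        fisher_greater(kb, n, total_b - kb, total_n - n)
        for n, _, kb in rows
    ])
    p_adj_a = bh_adjust(p_a)
    p_adj_b = bh_adjust(p_b)
    status = []
    tie = []
    for pa, pb, qa, qb in zip(p_a, p_b, p_adj_a, p_adj_b):
        hit_a = qa <= threshold
        hit_b = qb <= threshold
        if hit_a and hit_b:
            if pa < pb:
                status.append(status_a)
            elif pb < pa:
                status.append(status_b)
            else:
                status.append("ns")
                tie.append(True)
                continue
        elif hit_a:
            status.append(status_a)
        elif hit_b:
            status.append(status_b)
        else:
            status.append("ns")
        tie.append(False)
    return pd.DataFrame(
        {
            "region_id": regions["region_id"].to_numpy(),
            "n_members": [r[0] for r in rows],
            "n_diff_a": [r[1] for r in rows],
            "n_diff_b": [r[2] for r in rows],
            "p_a": p_a,
            "p_b": p_b,
            "p_adj_a": p_adj_a,
            "p_adj_b": p_adj_b,
            "status": status,
            "tie": tie,
        }
    )


def annotate_se_genes(
    regions: pd.DataFrame,
    se_scores: pd.DataFrame,
    tss: pd.DataFrame,
    expression: pd.DataFrame | None = None,
    promoter_signal: pd.DataFrame | None = None,
    window: int = LINK_WINDOW,
    fdr_promoter: float = 0.01,
    fdr_expression: float = 0.05,
) -> pd.DataFrame:
    """Link each SE region to genes by signal/expression correlation.

    Candidate genes have their TSS within ``window`` of the region.  Two
    evidence channels: Pearson correlation of the SE score with (a) the
    gene's promoter H3K27ac signal (BH <= 0.01) and (b) its expression
    (BH <= 0.05), each BH family global per channel.  A region with no
    passing gene falls back to the most correlated in-window gene, then to
    the nearest TSS; a region with no gene on its chromosome is returned
    unlinked with ``evidence='none'``.
    """
    cand_rows = []  # (region pos, gene_id, distance)
    tss_by_chrom = {c: sub for c, sub in tss.groupby("chrom")}
    for i, reg in regions.reset_index(drop=True).iterrows():
        sub = tss_by_chrom.get(reg["chrom"])
        if sub is None:
            continue
        pos = sub["tss"].to_numpy(dtype=np.int64)
        # distance from the region's span to the TSS (0 inside)
        d = np.maximum(
            0, np.maximum(reg["start"] - pos, pos - (reg["end"] - 1))
        )
        for gene, dist in zip(sub["gene_id"].to_numpy()[d <= window],
                              d[d <= window]):
            cand_rows.append((i, gene, int(dist)))

    def correlate(channel: pd.DataFrame, pairs: list[tuple[int, str, int]]):
        common = [c for c in se_scores.columns if c in channel.columns]
        if len(common) < 3:
            return {}
        score_m = se_scores[common]
        out = {}
        for i, gene, dist in pairs:
            if gene not in channel.index:
                continue
            x = score_m.iloc[i].to_numpy(dtype=float)
            y = channel.loc[gene, common].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(y) == 0:
                continue
            r, p = stats.pearsonr(x, y)
            out[(i, gene)] = (float(r), float(p), dist)
        return out

    results: dict[tuple[int, str], dict] = {}
    for channel, fdr, name in (
        (promoter_signal, fdr_promoter, "promoter"),
        (expression, fdr_expression, "expression"),
    ):
        if channel is None:
            continue
        corr = correlate(channel, cand_rows)
        if not corr:
            continue
        keys = list(corr)
        p_adj = bh_adjust(np.array([corr[k][1] for k in keys]))
        for k, q in zip(keys, p_adj):
            r, p, dist = corr[k]
            entry = results.setdefault(
                k, {"pcc": r, "p": p, "distance": dist, "evidence": set(),
                    "p_adj": q}
            )
            entry["p_adj"] = min(entry["p_adj"], q)
            entry["pcc"] = max(entry["pcc"], r)
            if q <= fdr:
                entry["evidence"].add(name)

    out_rows = []
    regs = regions.reset_index(drop=True)
    for i in range(len(regs)):
        passing = [
            (k[1], v) for k, v in results.items()
            if k[0] == i and v["evidence"]
        ]
        if passing:
            for gene, v in sorted(passing):
                out_rows.append(
                    (regs.at[i, "region_id"], gene, v["distance"], v["pcc"],
                     "+".join(sorted(v["evidence"])))
                )
            continue
        # fallback: most correlated in-window gene, then nearest TSS
        here = [(k[1], v) for k, v in results.items() if k[0] == i]
        if here:
            # highest correlation wins; exact ties fall to the nearer gene
            gene, v = max(here, key=lambda kv: (kv[1]["pcc"], -kv[1]["distance"]))
            out_rows.append(
                (regs.at[i, "region_id"], gene, v["distance"], v["pcc"],
                 "fallback_correlation")
            )
            continue
        in_window = [(g, d) for j, g, d in cand_rows if j == i]
        sub = tss_by_chrom.get(regs.at[i, "chrom"])
        if in_window:
            gene, dist = min(in_window, key=lambda gd: gd[1])
            out_rows.append((regs.at[i, "region_id"], gene, dist, np.nan,
                             "fallback_nearest"))
        elif sub is not None and len(sub):
            pos = sub["tss"].to_numpy(dtype=np.int64)
            d = np.maximum(
                0, np.maximum(regs.at[i, "start"] - pos,
                              pos - (regs.at[i, "end"] - 1))
            )
            j = int(np.argmin(d))
            out_rows.append((regs.at[i, "region_id"],
                             sub["gene_id"].iloc[j], int(d[j]), np.nan,
                             "fallback_nearest"))
        else:
            out_rows.append((regs.at[i, "region_id"], None, np.nan, np.nan,
                             "none"))
    return pd.DataFrame(
        out_rows, columns=["region_id", "gene_id", "distance", "pcc", "evidence"]
    )
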