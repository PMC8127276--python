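"""Shared fixtures: synthetic cohorts generated once per session."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from epihet.simulate import Cohort, SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort() -> Cohort:
    """The standard desk-scale cohort (40 patients, 2,000 peaks, seed 1)."""
    return generate_cohort(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def tumor_samples(default_cohort) -> list[str]:
    s = default_cohort.samples
    return s.loc[s["tissue"] == "tumor", "sample_id"].tolist()


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """A fast cohort for tests that regenerate many replicates."""
    return SyntheticConfig(
        n_patients=12, n_peaks=400, n_genes=200, n_hvp=30, n_deg=40,
        n_true_links=10, n_se_clusters=4, n_regulators=17,
        n_bipartite_regulators=2, targets_per_regulator=3,
        chrom_length=30_000_000, seed=0,
    )


def make_intervals(rows: list[tuple[str, int, int]]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["chrom", "start", "end"]).assign(
        peak_id=lambda d: [f"p{i}" for i in range(len(d))]
    )


@pytest.fixture
def interval_factory():
    return make_intervals


def brute_force_gap_merge(
    df: pd.DataFrame, gap: int = 0
) -> list[tuple[str, int, int]]:
    """Position-mask oracle for interval union / gap merging.

    Marks every covered base of each chromosome in a boolean mask, reads
    off maximal runs, then joins consecutive runs separated by <= gap
    uncovered bases.  Independent of the sorted-sweep implementation.
    """
    out: list[tuple[str, int, int]] = []
    for chrom in sorted(df["chrom"].unique()):
        sub = df[df["chrom"] == chrom]
        hi = int(sub["end"].max())
        mask = np.zeros(hi + 1, dtype=bool)
        for s, e in zip(sub["start"], sub["end"]):
            mask[int(s): int(e)] = True
        runs: list[list[int]] = []
        pos = 0
        while pos <= hi:
            if mask[pos]:
                start = pos
                while pos <= hi and mask[pos]:
                    pos += 1
                runs.append([start, pos])
            else:
                pos += 1
        merged: list[list[int]] = []
        for run in runs:
            if merged and run[0] - merged[-1][1] <= gap:
                merged[-1][1] = run[1]
            else:
                merged.append(run)
        out.extend((chrom, s, e) for s, e in merged)
    return out
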