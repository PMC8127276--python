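"""Stitching, hockey-stick SE calling, Fisher differential SEs, SE-gene
annotation."""

from math import comb

import numpy as np
import pandas as pd
import pytest

from epihet.superenhancer import (
    annotate_se_genes,
    call_ses,
    differential_ses,
    region_scores,
    stitch,
)

from conftest import make_intervals


def _tss(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand"])


EMPTY_TSS = _tss([])


class TestStitch:
    def test_gap_below_threshold_merges(self):
        peaks = make_intervals([("chr1", 0, 500), ("chr1", 12_000, 12_500)])
        res = stitch(peaks, EMPTY_TSS)  # gap 11,500 <= 12,500
        assert len(res) == 1
        assert (res.iloc[0]["start"], res.iloc[0]["end"]) == (0, 12_500)

    def test_gap_above_threshold_splits(self):
        peaks = make_intervals([("chr1", 0, 500), ("chr1", 13_100, 13_600)])
        res = stitch(peaks, EMPTY_TSS)  # gap 12,600 > 12,500
        assert len(res) == 2

    def test_peak_inside_tss_window_removed(self):
        peaks = make_intervals(
            [("chr1", 9_000, 9_400), ("chr1", 50_000, 50_500)]
        )
        tss = _tss([("G1", "chr1", 10_000, "+")])
        res = stitch(peaks, tss)
        members = {p for m in res["members"] for p in m}
        assert members == {"p1"}

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        starts = np.sort(rng.integers(0, 300_000, size=40))
        peaks = make_intervals(
            [("chr1", int(s), int(s) + 400) for s in starts]
        )
        once = stitch(peaks, EMPTY_TSS)
        again = stitch(
            once.rename(columns={"region_id": "peak_id"})[
                ["chrom", "start", "end", "peak_id"]
            ],
            EMPTY_TSS,
        )
        assert list(zip(again["chrom"], again["start"], again["end"])) == list(
            zip(once["chrom"], once["start"], once["end"])
        )


class TestCallSes:
    def _series(self, values):
        return pd.Series(
            values, index=[f"r{i}" for i in range(len(values))], dtype=float
        )

    def test_single_outlier_is_the_only_se(self):
        flags = call_ses(self._series([1, 1, 1, 1, 100] + [1] * 6))
        assert flags.sum() == 1
        assert flags["r4"]

    def test_linear_signal_yields_at_most_one(self):
        flags = call_ses(self._series(np.linspace(1, 10, 20)))
        assert flags.sum() <= 1

    def test_constant_signal_warns_no_ses(self):
        with pytest.warns(UserWarning, match="constant"):
            flags = call_ses(self._series([5.0] * 12))
        assert not flags.any()

    def test_count_monotone_in_slope_cutoff(self):
        rng = np.random.default_rng(1)
        sig = self._series(np.exp(rng.normal(size=200)))
        counts = [call_ses(sig, slope_cutoff=c).sum() for c in (0.5, 1, 2, 4)]
        assert counts == sorted(counts, reverse=True)

    def test_planted_clusters_flagged(self, default_cohort, tumor_samples):
        c = default_cohort
        regions = stitch(c.peaks, c.tss)
        totals, _ = region_scores(regions, c.signal)
        from epihet.intervals import overlaps_any

        for sample in tumor_samples[:3]:
            flags = call_ses(totals[sample])
            called = regions.loc[flags.to_numpy()]
            assert overlaps_any(c.truth.se_regions, called).all()

    def test_minimum_regions_enforced(self):
        with pytest.raises(ValueError, match=">= 10"):
            call_ses(self._series([1, 2, 3]))


def hypergeom_tail(k: int, n: int, kb: int, nb: int) -> float:
    """Exact one-sided enrichment tail by explicit enumeration.

    P(X >= k) for X ~ Hypergeom(population n + nb, successes k + kb,
    draws n), computed with integer binomials.
    """
    pop, succ, draws = n + nb, k + kb, n
    denom = comb(pop, draws)
    total = 0
    for x in range(k, min(succ, draws) + 1):
        if draws - x > pop - succ:
            continue
        total += comb(succ, x) * comb(pop - succ, draws - x)
    return total / denom


class TestDifferentialSes:
    def _regions(self, member_lists):
        return pd.DataFrame(
            {
                "region_id": [f"se{i}" for i in range(len(member_lists))],
                "chrom": "chr1",
                "start": 0,
                "end": 1,
                "members": [tuple(m) for m in member_lists],
            }
        )

    def _labels(self, n_bg, n_bg_a, members_labels):
        labels = {}
        for i, lab in enumerate(members_labels):
            labels[f"m{i}"] = lab
        for i in range(n_bg):
            labels[f"bg{i}"] = "A_specific" if i < n_bg_a else "unchanged"
        return pd.Series(labels)

    def test_fisher_p_matches_hypergeometric_enumeration(self):
        members = [f"m{i}" for i in range(10)]
        labels = self._labels(1000, 100,
                              ["A_specific"] * 8 + ["unchanged"] * 2)
        res = differential_ses(self._regions([members]), labels)
        assert res["p_a"].iloc[0] == pytest.approx(
            hypergeom_tail(8, 10, 100, 1000), rel=1e-9
        )

    def test_background_rate_member_fraction_not_enriched(self):
        members = [f"m{i}" for i in range(10)]
        labels = self._labels(1000, 100,
                              ["A_specific"] * 1 + ["unchanged"] * 9)
        res = differential_ses(self._regions([members]), labels)
        assert res["p_a"].iloc[0] >= 0.5
        assert res["status"].iloc[0] == "ns"

    def test_no_differential_members_never_specific(self):
        members = [f"m{i}" for i in range(5)]
        labels = self._labels(500, 250, ["unchanged"] * 5)
        res = differential_ses(self._regions([members]), labels)
        assert res["status"].iloc[0] == "ns"

    def test_empty_background_rejected(self):
        members = ["m0", "m1"]
        labels = pd.Series({"m0": "A_specific", "m1": "unchanged"})
        with pytest.raises(ValueError, match="background"):
            differential_ses(self._regions([members]), labels)

    def test_enriched_se_gets_direction(self):
        strong = [f"m{i}" for i in range(10)]
        labels = self._labels(1000, 10, ["A_specific"] * 9 + ["unchanged"])
        res = differential_ses(self._regions([strong]), labels)
        assert res["status"].iloc[0] == "A_specific"


class TestAnnotateSeGenes:
    def _setup(self, n=12):
        rng = np.random.default_rng(0)
        regions = pd.DataFrame(
            {
                "region_id": ["se0"],
                "chrom": ["chr1"],
                "start": [100_000],
                "end": [110_000],
                "members": [("p0",)],
            }
        )
        samples = [f"s{i}" for i in range(n)]
        scores = pd.DataFrame(
            rng.normal(size=(1, n)), index=["se0"], columns=samples
        )
        return regions, scores, samples

    def test_identical_expression_vector_linked_with_r_one(self):
        regions, scores, samples = self._setup()
        tss = _tss([("G1", "chr1", 150_000, "+"), ("G2", "chr1", 400_000, "+")])
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(
            np.vstack([scores.iloc[0].to_numpy(),
                       rng.normal(size=len(samples))]),
            index=["G1", "G2"], columns=samples,
        )
        res = annotate_se_genes(regions, scores, tss, expression=expr)
        row = res[res["gene_id"] == "G1"].iloc[0]
        assert row["pcc"] == pytest.approx(1.0)
        assert "expression" in row["evidence"]

    def test_tied_correlation_falls_to_nearest_gene(self):
        regions, scores, samples = self._setup()
        # both genes carry the identical (uncorrelated) expression vector:
        # correlations tie exactly, so the 10-kb gene must win over 50-kb
        tss = _tss([("NEAR", "chr1", 120_000, "+"),
                    ("FAR", "chr1", 160_000, "+")])
        rng = np.random.default_rng(2)
        v = rng.normal(size=len(samples))
        expr = pd.DataFrame([v, v], index=["NEAR", "FAR"], columns=samples)
        res = annotate_se_genes(regions, scores, tss, expression=expr)
        assert len(res) == 1
        assert res.iloc[0]["gene_id"] == "NEAR"
        assert res.iloc[0]["evidence"].startswith("fallback")

    def test_no_gene_in_window_uses_nearest_on_chromosome(self):
        regions, scores, samples = self._setup()
        tss = _tss([("ONLY", "chr1", 5_000_000, "+")])
        expr = pd.DataFrame(
            np.random.default_rng(3).normal(size=(1, len(samples))),
            index=["ONLY"], columns=samples,
        )
        res = annotate_se_genes(regions, scores, tss, expression=expr)
        assert res.iloc[0]["gene_id"] == "ONLY"
        assert res.iloc[0]["evidence"] == "fallback_nearest"

    def test_no_gene_on_chromosome_unlinked(self):
        regions, scores, samples = self._setup()
        tss = _tss([("G", "chr9", 1_000, "+")])
        expr = pd.DataFrame(
            np.random.default_rng(4).normal(size=(1, len(samples))),
            index=["G"], columns=samples,
        )
        res = annotate_se_genes(regions, scores, tss, expression=expr)
        assert res.iloc[0]["gene_id"] is None
        assert res.iloc[0]["evidence"] == "none"

    def test_planted_se_gene_links_recovered(self, default_cohort,
                                             tumor_samples):
        """SE score of a planted cluster correlates with a nearby planted
        gene when the generator links one; here we check promoter-channel
        machinery runs on the cohort without error and links regions."""
        c = default_cohort
        regions = stitch(c.peaks, c.tss)
        _, scores = region_scores(regions, c.signal[tumor_samples])
        res = annotate_se_genes(regions.head(50), scores.head(50), c.tss,
                                expression=c.expression[tumor_samples])
        assert len(res) >= 50  # every region gets >= 1 row
        assert set(res["region_id"]) == set(regions.head(50)["region_id"])
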