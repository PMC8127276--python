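"""PCA on HVPs, PC significance, ANOVA association, PC1 clustering."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from epihet.subtypes import (
    associate_pc_covariate,
    cluster_pc1,
    pca_on_hvps,
    significant_pcs,
)


def _matrix(values, samples=None):
    values = np.asarray(values, dtype=float)
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return pd.DataFrame(values, columns=samples,
                        index=[f"p{i}" for i in range(values.shape[0])])


class TestPca:
    def test_rank_one_matrix_explains_everything(self):
        u = np.array([1.0, 2.0, -1.0, 0.5])
        v = np.array([3.0, -1.0, 2.0])
        res = pca_on_hvps(_matrix(np.outer(u, v)))
        np.testing.assert_allclose(res.variance_explained, [1.0])

    def test_duplicated_samples_get_identical_scores(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(30, 4))
        x[:, 3] = x[:, 0]
        res = pca_on_hvps(_matrix(x))
        np.testing.assert_allclose(
            res.scores.iloc[0], res.scores.iloc[3], atol=1e-10
        )

    def test_scores_match_covariance_eigendecomposition(self):
        """Independent oracle: eigen-solve the peak-centred covariance of
        samples and compare projections, up to the sign convention."""
        x = np.array(
            [[2.0, 0.0, 1.0], [1.0, 1.0, 4.0], [0.0, 3.0, 2.0], [5.0, 1.0, 0.0]]
        )
        res = pca_on_hvps(_matrix(x))
        xc = x - x.mean(axis=1, keepdims=True)
        evals, evecs = np.linalg.eigh(xc.T @ xc)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        keep = evals > 1e-10
        oracle = evecs[:, keep] * np.sqrt(evals[keep])
        got = res.scores.to_numpy()
        assert got.shape == oracle.shape
        for j in range(oracle.shape[1]):
            assert (
                np.allclose(got[:, j], oracle[:, j], atol=1e-8)
                or np.allclose(got[:, j], -oracle[:, j], atol=1e-8)
            )

    def test_invariant_to_peak_and_sample_reordering(self):
        rng = np.random.default_rng(1)
        x = _matrix(rng.normal(size=(40, 8)))
        base = pca_on_hvps(x)
        shuffled = x.sample(frac=1, random_state=2)          # permute peaks
        res = pca_on_hvps(shuffled)
        np.testing.assert_allclose(
            np.abs(res.scores.to_numpy()), np.abs(base.scores.to_numpy()),
            atol=1e-8,
        )
        cols = list(x.columns[::-1])
        res2 = pca_on_hvps(x[cols])
        np.testing.assert_allclose(
            np.abs(res2.scores.loc[x.columns].to_numpy()),
            np.abs(base.scores.to_numpy()),
            atol=1e-8,
        )

    def test_sign_convention_largest_loading_positive(self):
        rng = np.random.default_rng(3)
        res = pca_on_hvps(_matrix(rng.normal(size=(25, 6))))
        for j in range(res.loadings.shape[1]):
            col = res.loadings[:, j]
            assert col[np.abs(col).argmax()] > 0

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            pca_on_hvps(_matrix(np.zeros((10, 2))))


class TestSignificantPcs:
    def test_pure_noise_rarely_yields_significant_pcs(self):
        ok = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            res = significant_pcs(
                _matrix(rng.normal(size=(200, 30))), n_perm=100, seed=seed,
                max_pcs=5,
            )
            ok += int(res.significant.sum() == 0)
        assert ok >= 18  # >= 90% of seeds

    def test_single_planted_factor_yields_exactly_pc1(self):
        ok = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            f = rng.normal(size=30)
            x = rng.normal(size=(200, 30)) + np.outer(
                0.8 * rng.normal(size=200), f
            )
            res = significant_pcs(_matrix(x), n_perm=100, seed=seed, max_pcs=5)
            ok += int(res.significant.sum() == 1 and res.significant[0])
        assert ok >= 18

    def test_flags_deterministic_under_seed(self):
        rng = np.random.default_rng(5)
        x = _matrix(rng.normal(size=(100, 12)))
        a = significant_pcs(x, n_perm=100, seed=9)
        b = significant_pcs(x, n_perm=100, seed=9)
        assert (a.significant == b.significant).all()
        np.testing.assert_allclose(a.perm_null_quantiles,
                                   b.perm_null_quantiles)

    def test_low_n_perm_warns_but_runs(self):
        rng = np.random.default_rng(6)
        with pytest.warns(UserWarning, match="n_perm"):
            significant_pcs(_matrix(rng.normal(size=(50, 8))), n_perm=50)


class TestAnovaAssociation:
    def test_identical_groups_no_effect(self):
        scores = pd.Series([2.0, 4.0, 2.0, 4.0], index=list("abcd"))
        cov = pd.Series(["x", "x", "y", "y"], index=list("abcd"))
        f, p, degenerate = associate_pc_covariate(scores, cov)
        assert f == 0.0 and p == 1.0 and not degenerate

    def test_perfect_separation_degenerate_flag(self):
        scores = pd.Series([0.0, 0.0, 0.0, 1.0, 1.0, 1.0],
                           index=list("abcdef"))
        cov = pd.Series(["x"] * 3 + ["y"] * 3, index=list("abcdef"))
        f, p, degenerate = associate_pc_covariate(scores, cov)
        assert p == 0.0 and degenerate

    def test_closed_form_f_statistic(self):
        scores = pd.Series([1.0, 2.0, 3.0, 2.0, 3.0, 4.0],
                           index=list("abcdef"))
        cov = pd.Series(["x"] * 3 + ["y"] * 3, index=list("abcdef"))
        f, p, _ = associate_pc_covariate(scores, cov)
        assert f == pytest.approx(1.5)  # hand computation: SSB/1 / (SSW/4)

    def test_single_level_rejected(self):
        scores = pd.Series([1.0, 2.0], index=list("ab"))
        with pytest.raises(ValueError, match="levels"):
            associate_pc_covariate(scores, pd.Series(["x", "x"],
                                                     index=list("ab")))


class TestClusterPc1:
    def test_perfectly_separated_scores(self):
        pc1 = pd.Series([-5.0, -4.0, -4.5, 5.0, 4.0, 4.5],
                        index=[f"s{i}" for i in range(6)])
        res = cluster_pc1(pc1, n_resample=200, seed=0)
        assert res.chosen_k == 2
        assert res.stability[2] == pytest.approx(1.0)
        groups = res.assignments.set_index("sample_id")["group"]
        assert set(groups[:3]) == {"GI"} and set(groups[3:]) == {"GII"}

    def test_planted_cohort_recovered_exactly(self, default_cohort,
                                              tumor_samples):
        c = default_cohort
        pca = pca_on_hvps(c.signal.loc[c.truth.hvp, tumor_samples])
        res = cluster_pc1(pca.scores["PC1"], n_resample=200, seed=0)
        lab = res.assignments.set_index("sample_id").loc[tumor_samples,
                                                         "group"]
        truth = [c.truth.subgroup[s] for s in tumor_samples]
        assert adjusted_rand_score(truth, list(lab)) == 1.0

    def test_uniform_scores_show_no_strong_k_preference(self):
        diffs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            pc1 = pd.Series(rng.uniform(size=24),
                            index=[f"s{i}" for i in range(24)])
            res = cluster_pc1(pc1, n_resample=100, seed=seed)
            diffs.append(abs(res.stability[2] - res.stability[3]))
        assert np.mean(diffs) < 0.1

    def test_constant_scores_single_cluster_with_warning(self):
        pc1 = pd.Series([1.0] * 6, index=[f"s{i}" for i in range(6)])
        with pytest.warns(UserWarning, match="identical"):
            res = cluster_pc1(pc1)
        assert res.single_cluster
        assert res.assignments["group"].nunique() == 1

    def test_covariate_anchoring_controls_gii_label(self):
        pc1 = pd.Series([-5.0, -4.0, -4.5, 5.0, 4.0, 4.5],
                        index=[f"s{i}" for i in range(6)])
        cov = pd.Series(["positive"] * 3 + ["negative"] * 3, index=pc1.index,
                        name="node_status")
        res = cluster_pc1(pc1, n_resample=100, seed=0, covariate=cov,
                          covariate_positive="positive")
        groups = res.assignments.set_index("sample_id")["group"]
        # the covariate-positive (low-PC1) cluster is GII despite lower PC1
        assert set(groups[:3]) == {"GII"}

    def test_stability_in_unit_interval(self):
        rng = np.random.default_rng(11)
        pc1 = pd.Series(rng.normal(size=15),
                        index=[f"s{i}" for i in range(15)])
        res = cluster_pc1(pc1, n_resample=100, seed=1)
        assert all(0.0 <= v <= 1.0 for v in res.stability.values())


def test_moderate_noise_pipeline_recovery():
    """simulate -> hvp -> pca -> cluster at hvp_effect=1.0, noise_sd=0.5:
    median ARI across 20 seeds >= 0.8."""
    import dataclasses

    from epihet.hvp import hyper_variable_peaks
    from epihet.simulate import SyntheticConfig, generate_cohort

    cfg = SyntheticConfig(hvp_effect=1.0, noise_sd=0.5)
    aris = []
    for seed in range(20):
        c = generate_cohort(dataclasses.replace(cfg, seed=seed))
        tumor = [s for s in c.signal.columns if s.endswith("_T")]
        hv = hyper_variable_peaks(c.signal[tumor], peaks=c.peaks)
        ids = hv.loc[hv["is_hvp"], "peak_id"]
        if len(ids) < 2:
            aris.append(0.0)
            continue
        pca = pca_on_hvps(c.signal.loc[ids, tumor])
        res = cluster_pc1(pca.scores["PC1"], n_resample=100, seed=seed)
        lab = res.assignments.set_index("sample_id").loc[tumor, "group"]
        aris.append(
            adjusted_rand_score([c.truth.subgroup[s] for s in tumor],
                                list(lab))
        )
    assert np.median(aris) >= 0.8
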