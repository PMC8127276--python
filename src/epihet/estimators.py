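"""scikit-learn-compatible estimators over the functional core.

These wrappers follow the sklearn contract (``fit``/``transform`` or
``fit``/``predict``, ``get_params``/``set_params``, fitted attributes with
a trailing underscore) so the stages compose with sklearn pipelines and
model selection.  They operate on sample-by-feature arrays / DataFrames,
i.e. the transpose of the peak-by-sample matrices the functional API
uses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, ClusterMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .hvp import hyper_variable_peaks
from .normalize import normalize_ma
from .subtypes import cluster_pc1, pca_on_hvps
from .transfer import assign_groups, ssgsea_matrix


def _as_frame(X, feature_names=None) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    cols = (
        list(feature_names)
        if feature_names is not None
        else [f"f{i}" for i in range(X.shape[1])]
    )
    return pd.DataFrame(X, columns=cols)


class MANormalizer(TransformerMixin, BaseEstimator):
    """MA-trend normalization of log2 signal (samples x peaks).

    ``baseline`` is a sample index/ID or ``"median"``; the baseline
    profile is learned in ``fit`` and each transformed sample is aligned
    to it, so new samples can be normalized against the training cohort.
    """

    def __init__(self, baseline: str = "median"):
        self.baseline = baseline

    def fit(self, X, y=None):
        df = _as_frame(X)
        if df.shape[1] < 10:
            raise ValueError("need >= 10 peaks")
        if self.baseline == "median":
            self.baseline_profile_ = df.median(axis=0).to_numpy()
        else:
            self.baseline_profile_ = df.loc[self.baseline].to_numpy(dtype=float)
        self.n_features_in_ = df.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "baseline_profile_")
        df = _as_frame(X)
        mat = df.T  # peaks x samples for the functional core
        mat = mat.assign(__baseline__=self.baseline_profile_)
        out = normalize_ma(mat, baseline="__baseline__")
        return out.drop(columns="__baseline__").T.to_numpy()


class HyperVariablePeakSelector(TransformerMixin, BaseEstimator):
    """Select hyper-variable peaks (features) from samples x peaks data.

    ``transform`` keeps only the flagged peaks; ``results_`` holds the
    per-peak statistics; ``get_support()`` the boolean mask.
    """

    def __init__(self, alpha: float = 0.01, n_bins: int = 50,
                 peaks: pd.DataFrame | None = None):
        self.alpha = alpha
        self.n_bins = n_bins
        self.peaks = peaks

    def fit(self, X, y=None):
        df = _as_frame(X)
        res = hyper_variable_peaks(
            df.T, peaks=self.peaks, alpha=self.alpha, n_bins=self.n_bins
        )
        self.results_ = res
        self.support_ = res["is_hvp"].to_numpy()
        self.n_features_in_ = df.shape[1]
        return self

    def get_support(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_

    def transform(self, X):
        check_is_fitted(self, "support_")
        df = _as_frame(X)
        return df.to_numpy()[:, self.support_]


class EpigeneticSubtyper(ClusterMixin, BaseEstimator):
    """PC1-based two-state subtyping of tumor samples (samples x HVPs).

    ``fit`` runs row-centered PCA and consensus-stable hierarchical
    clustering of PC1; ``labels_`` holds GI/GII strings, ``pc1_`` the
    scores, ``stability_`` the per-k consensus stability.
    """

    def __init__(self, k_candidates: tuple[int, ...] = (2, 3),
                 n_resample: int = 500, random_state: int = 0):
        self.k_candidates = k_candidates
        self.n_resample = n_resample
        self.random_state = random_state

    def fit(self, X, y=None):
        df = _as_frame(X)
        pca = pca_on_hvps(df.T)
        assignment = cluster_pc1(
            pca.scores["PC1"],
            k_candidates=tuple(self.k_candidates),
            n_resample=self.n_resample,
            seed=self.random_state,
        )
        self.pca_ = pca
        self.pc1_ = pca.scores["PC1"].to_numpy()
        self.labels_ = assignment.assignments["group"].to_numpy()
        self.chosen_k_ = assignment.chosen_k
        self.stability_ = assignment.stability
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


class SsgseaTransferClassifier(ClassifierMixin, BaseEstimator):
    """Tertile-rule GI-like / GII-like / intergroup labels for a cohort.

    ``fit`` stores the subgroup gene sets (and, from optional training
    expression, nothing else — the tertile cut is cohort-relative);
    ``predict`` scores a samples x genes frame and returns labels.
    """

    def __init__(self, gi_genes: list[str] | None = None,
                 gii_genes: list[str] | None = None, weight: float = 0.25):
        self.gi_genes = gi_genes
        self.gii_genes = gii_genes
        self.weight = weight

    def fit(self, X=None, y=None):
        if not self.gi_genes or not self.gii_genes:
            raise ValueError("gi_genes and gii_genes must be provided")
        self.gi_set_ = set(self.gi_genes)
        self.gii_set_ = set(self.gii_genes)
        return self

    def decision_function(self, X) -> pd.DataFrame:
        check_is_fitted(self, "gi_set_")
        df = _as_frame(X).T  # genes x samples
        gi = ssgsea_matrix(df, self.gi_set_, weight=self.weight)
        gii = ssgsea_matrix(df, self.gii_set_, weight=self.weight)
        return assign_groups(gi, gii)

    def predict(self, X) -> np.ndarray:
        return self.decision_function(X)["label"].to_numpy()
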