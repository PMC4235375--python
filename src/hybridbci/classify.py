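"""Per-feature classifiers and META decision fusion.

Three of the four feature types (HbO, HbR, POW) are classified with a
shrinkage-regularized linear discriminant; the ERP waveform is classified
with a soft-margin linear SVM whose margin is mapped to probabilities by a
monotone (Platt-style) calibration fitted on the training data.  The META
classifier forms the weighted sum of the per-classifier class-probability
vectors, with weights derived from evaluation-data accuracies, and picks
the maximum-probability class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

FEATURE_TYPES = ("HbO", "HbR", "POW", "ERP")


class ShrinkageLda(ClassifierMixin, BaseEstimator):
    """Linear discriminant with covariance shrunk toward a scaled identity.

    The pooled covariance estimate is regularized as

        S_reg = (1 - gamma) * S + gamma * (tr(S) / d) * I

    with shrinkage factor ``gamma`` (default 0.5).  ``gamma = 0`` recovers
    classical pooled-covariance LDA; ``gamma = 1`` reduces the decision rule
    to nearest class mean (identity covariance).  Posterior probabilities
    come from the two Gaussian discriminants with empirical priors.
    """

    def __init__(self, shrinkage: float = 0.5):
        self.shrinkage = shrinkage

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, float))
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) != 2:
            raise ValueError(
                f"binary classifier requires exactly 2 classes, got {len(self.classes_)}"
            )
        n, d = X.shape
        counts = np.bincount(y_idx, minlength=2)
        self.priors_ = counts / n
        self.means_ = np.stack([X[y_idx == k].mean(axis=0) for k in range(2)])
        # pooled ML covariance, weighted by class frequency (matches the
        # classical shrinkage-LDA formulation and sklearn's lsqr solver)
        cov = np.zeros((d, d))
        for k in range(2):
            Xk = X[y_idx == k] - self.means_[k]
            cov += (Xk.T @ Xk) / n
        gamma = float(self.shrinkage)
        target = (np.trace(cov) / d) * np.eye(d)
        cov_reg = (1 - gamma) * cov + gamma * target
        w = np.linalg.solve(cov_reg, self.means_.T)  # (d, 2)
        b = -0.5 * np.einsum("kd,dk->k", self.means_, w) + np.log(self.priors_)
        self.coef_ = (w[:, 1] - w[:, 0])
        self.intercept_ = float(b[1] - b[0])
        return self

    def decision_function(self, X):
        X = np.atleast_2d(np.asarray(X, float))
        return X @ self.coef_ + self.intercept_

    def predict_proba(self, X):
        p1 = expit(self.decision_function(X))
        return np.column_stack([1 - p1, p1])

    def predict(self, X):
        return self.classes_[(self.decision_function(X) > 0).astype(int)]


class CalibratedLinearSvm(ClassifierMixin, BaseEstimator):
    """Soft-margin linear SVM (libsvm, C = 1) with monotone Platt calibration.

    The sigmoid is fitted to the training margins; its slope is clamped to
    be non-negative, so a larger margin never yields a smaller positive-class
    probability.  ``predict`` uses the raw SVM decision; ``predict_proba``
    the calibrated probabilities.
    """

    def __init__(self, C: float = 1.0):
        self.C = C

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, float))
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError(
                f"binary classifier requires exactly 2 classes, got {len(self.classes_)}"
            )
        self.svc_ = SVC(kernel="linear", C=self.C).fit(X, y)
        margins = self.svc_.decision_function(X)
        y01 = (y == self.classes_[1]).astype(int)
        if len(np.unique(y01)) == 2:
            lr = LogisticRegression(max_iter=1000).fit(margins[:, None], y01)
            a, b = float(lr.coef_[0, 0]), float(lr.intercept_[0])
        else:  # pragma: no cover - guarded by the two-class check above
            a, b = 0.0, 0.0
        self.calib_slope_ = max(a, 0.0)
        self.calib_intercept_ = b if a >= 0 else 0.0
        return self

    def decision_function(self, X):
        return self.svc_.decision_function(np.atleast_2d(np.asarray(X, float)))

    def predict_proba(self, X):
        p1 = expit(self.calib_slope_ * self.decision_function(X)
                   + self.calib_intercept_)
        return np.column_stack([1 - p1, p1])

    def predict(self, X):
        return self.svc_.predict(np.atleast_2d(np.asarray(X, float)))


def make_classifier(feature_type: str, shrinkage: float = 0.5, svm_C: float = 1.0):
    """The study's classifier for a given feature type (LDA except ERP->SVM)."""
    if feature_type == "ERP":
        return CalibratedLinearSvm(C=svm_C)
    return ShrinkageLda(shrinkage=shrinkage)


# ----------------------------------------------------------------- fusion


@dataclass(frozen=True)
class FusionWeights:
    """Normalized non-negative weights over (HbO, HbR, POW, ERP)."""

    values: tuple[float, ...]
    feature_types: tuple[str, ...] = FEATURE_TYPES

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if (v < 0).any() or abs(v.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be non-negative and sum to 1")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, float)


def estimate_fusion_weights(
    accuracies, baseline: float = 0.5, feature_types=FEATURE_TYPES
) -> FusionWeights:
    """Map evaluation accuracies to fusion weights.

    Accuracies above chance are linearly rescaled so baseline -> 0 and
    1.0 -> 1; sub-chance classifiers get weight 0; the vector is then
    normalized by its 1-norm.  If every accuracy is at or below baseline the
    fallback is uniform weighting.
    """
    acc = np.asarray(accuracies, float)
    if acc.min() < 0 or acc.max() > 1:
        raise ValueError("accuracies must lie in [0, 1]")
    raw = np.clip((acc - baseline) / (1.0 - baseline), 0.0, None)
    total = raw.sum()
    if total <= 0:
        raw = np.ones_like(raw)
        total = raw.sum()
    return FusionWeights(tuple(raw / total), tuple(feature_types))


def fuse_probabilities(probs: np.ndarray, weights: FusionWeights) -> np.ndarray:
    """Weighted sum p_meta = sum_m w_m * p_m over classifiers.

    `probs` has shape (n_trials, n_classifiers, 2); each per-classifier row
    must be a distribution, so the fused rows are too (convex combination).
    """
    probs = np.asarray(probs, float)
    if probs.ndim != 3 or probs.shape[1] != len(weights.values):
        raise ValueError("probability table does not match the weight vector")
    return np.einsum("nmk,m->nk", probs, weights.as_array())


def fuse_predict(probs: np.ndarray, weights: FusionWeights
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Fused prediction: argmax class index, ties resolved to the first class.

    Returns ``(class_index, p_meta)`` with class_index in {0, 1}.
    """
    p_meta = fuse_probabilities(probs, weights)
    pred = (p_meta[:, 1] > p_meta[:, 0]).astype(int)
    return pred, p_meta


class MetaFusionClassifier(BaseEstimator):
    """Decision-fusion model over per-feature-type classifiers.

    ``fit`` trains one classifier per feature block on already-standardized
    feature matrices; weights (from held-out evaluation accuracies) are
    supplied, not learned here.
    """

    def __init__(self, shrinkage: float = 0.5, svm_C: float = 1.0,
                 feature_types=FEATURE_TYPES):
        self.shrinkage = shrinkage
        self.svm_C = svm_C
        self.feature_types = feature_types

    def fit(self, Xs: dict[str, np.ndarray], y, weights: FusionWeights):
        missing = [ft for ft in self.feature_types if ft not in Xs]
        if missing:
            raise ValueError(f"missing feature blocks {missing}")
        if tuple(weights.feature_types) != tuple(self.feature_types):
            raise ValueError("weights cover a different classifier set")
        self.classifiers_ = {
            ft: make_classifier(ft, self.shrinkage, self.svm_C).fit(Xs[ft], y)
            for ft in self.feature_types
        }
        self.weights_ = weights
        self.classes_ = self.classifiers_[self.feature_types[0]].classes_
        return self

    def component_proba(self, Xs: dict[str, np.ndarray]) -> np.ndarray:
        return np.stack(
            [self.classifiers_[ft].predict_proba(Xs[ft]) for ft in self.feature_types],
            axis=1,
        )

    def predict_proba(self, Xs: dict[str, np.ndarray]) -> np.ndarray:
        return fuse_probabilities(self.component_proba(Xs), self.weights_)

    def predict(self, Xs: dict[str, np.ndarray]):
        pred, _ = fuse_predict(self.component_proba(Xs), self.weights_)
        return self.classes_[pred]
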