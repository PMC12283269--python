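"""Conventional and classical machine-learning comparators.

* Single-feature threshold classifiers on the per-wavelength linear-fit
  features (slope or median at a chosen wavelength, e.g. 700/1210/1370 nm).
  The cut point maximises Youden's J (sensitivity + specificity - 1) on the
  training data and the orientation (greater-is-tumor or the reverse) is
  learned from the data.
* Linear and quadratic discriminant analysis on the per-wavelength
  slope+median feature table (154 features) with shrinkage/regularised
  covariances; a raw-flattened 77x90 mode backs the feature screening.
* Validation-driven feature screening: every (wavelength, frequency-bin)
  scalar of the spectrum matrix is scored by the validation accuracy of a
  one-dimensional Gaussian LDA rule, and the top-k are retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)

from .preprocess import fit_features_matrix
from .synth import Cohort, wavelength_grid

__all__ = [
    "FeatureSelector",
    "ThresholdClassifier",
    "ScreenedFeatureSet",
    "select_feature",
    "feature_matrix",
    "fit_threshold",
    "lda_fit",
    "lda_predict",
    "qda_fit",
    "qda_predict",
    "lda_feature_screen",
]


@dataclass(frozen=True)
class FeatureSelector:
    """A single (wavelength, slope-or-median) scalar feature."""

    wavelength: float
    feature: str  # "slope" | "median"

    def validate(self) -> None:
        if self.feature not in ("slope", "median"):
            raise ValueError("feature must be 'slope' or 'median'")
        lam = wavelength_grid()
        if not np.any(np.isclose(lam, self.wavelength)):
            raise ValueError(f"wavelength {self.wavelength} nm is not on the grid")


def select_feature(cohort: Cohort, selector: FeatureSelector) -> np.ndarray:
    """The selected per-sample scalar feature."""
    selector.validate()
    slope, _, median = fit_features_matrix(cohort.spectra, cohort.frequencies_mhz)
    col = int(np.flatnonzero(np.isclose(cohort.wavelengths_nm, selector.wavelength))[0])
    return (slope if selector.feature == "slope" else median)[:, col]


def feature_matrix(cohort: Cohort) -> np.ndarray:
    """The 154-column slope+median feature table (one row per sample)."""
    slope, _, median = fit_features_matrix(cohort.spectra, cohort.frequencies_mhz)
    return np.concatenate([slope, median], axis=1)


def fit_threshold(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Youden-optimal cut point and orientation for a scalar feature.

    Returns ``(threshold, orientation)`` with orientation +1 meaning
    "predict tumor when x > threshold" and -1 the reverse. Ties in J are
    broken toward the smaller threshold with orientation +1 first.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y).astype(int)
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present to fit a threshold")
    values = np.unique(x)
    if values.size < 2:
        raise ValueError("feature is single-valued; no threshold separates it")
    cuts = np.concatenate(
        [[values[0] - 1.0], (values[:-1] + values[1:]) / 2.0, [values[-1] + 1.0]]
    )
    n_pos = (y == 1).sum()
    n_neg = (y == 0).sum()
    best = (-np.inf, None, None)
    for orientation in (1, -1):
        pred = (orientation * (x[None, :] - cuts[:, None]) > 0).astype(int)
        tp = ((pred == 1) & (y == 1)).sum(axis=1)
        tn = ((pred == 0) & (y == 0)).sum(axis=1)
        j = tp / n_pos + tn / n_neg - 1.0
        k = int(np.argmax(j))
        if j[k] > best[0]:
            best = (float(j[k]), float(cuts[k]), orientation)
    return best[1], best[2]


class ThresholdClassifier:
    """Scalar decision rule on one linear-fit feature."""

    def __init__(self, selector: FeatureSelector):
        selector.validate()
        self.selector = selector
        self.threshold: float | None = None
        self.orientation: int | None = None

    def fit(self, cohort: Cohort) -> "ThresholdClassifier":
        x = select_feature(cohort, self.selector)
        self.threshold, self.orientation = fit_threshold(x, cohort.labels)
        return self

    def decision_scores(self, cohort: Cohort) -> np.ndarray:
        if self.threshold is None:
            raise RuntimeError("classifier is not fitted")
        x = select_feature(cohort, self.selector)
        return self.orientation * (x - self.threshold)

    def predict(self, cohort: Cohort) -> np.ndarray:
        return (self.decision_scores(cohort) > 0).astype(int)


def lda_fit(features: np.ndarray, labels: np.ndarray) -> LinearDiscriminantAnalysis:
    """Pooled-covariance Gaussian discriminant with automatic shrinkage."""
    _check_two_per_class(labels)
    model = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
    return model.fit(np.asarray(features, dtype=float), np.asarray(labels).astype(int))


def lda_predict(model, features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(predicted labels, continuous discriminant scores usable for AUC)."""
    features = np.asarray(features, dtype=float)
    return model.predict(features), model.decision_function(features)


def qda_fit(
    features: np.ndarray, labels: np.ndarray, reg_param: float = 0.5,
    max_components: int = 20,
):
    """Per-class-covariance Gaussian discriminant, regularised for small n.

    A per-class covariance needs more samples than dimensions, which spectral
    feature tables never have at clinical cohort sizes; features are first
    projected onto at most ``max_components`` principal components.
    """
    _check_two_per_class(labels)
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels).astype(int)
    _, counts = np.unique(labels, return_counts=True)
    n_comp = int(min(max_components, counts.min() - 1, features.shape[1]))
    from sklearn.decomposition import PCA
    from sklearn.pipeline import Pipeline

    model = Pipeline(
        [
            ("pca", PCA(n_components=n_comp, random_state=0)),
            ("qda", QuadraticDiscriminantAnalysis(reg_param=reg_param)),
        ]
    )
    return model.fit(features, labels)


def qda_predict(model, features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    features = np.asarray(features, dtype=float)
    log_probs = model.predict_log_proba(features)
    return model.predict(features), log_probs[:, 1] - log_probs[:, 0]


def _check_two_per_class(labels: np.ndarray) -> None:
    labels = np.asarray(labels).astype(int)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("both classes must be present")
    if counts.min() < 2:
        raise ValueError("each class needs more than one sample")


@dataclass
class ScreenedFeatureSet:
    """Top-k (wavelength index, frequency-bin index) pairs with their utility."""

    pairs: np.ndarray  # (k, 2) integer indices into the 77x90 matrix
    utilities: np.ndarray  # (k,) validation accuracies

    def mask(self) -> np.ndarray:
        m = np.zeros((77, 90), dtype=bool)
        m[self.pairs[:, 0], self.pairs[:, 1]] = True
        return m


def _lda_1d_threshold(
    x: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form 1-d Gaussian LDA cut points, vectorised over features.

    ``x`` is (n_samples, n_features). Returns ``(threshold, sign)`` where the
    rule predicts 1 when sign * (x - threshold) > 0. Equal-variance 1-d LDA
    reduces to x* = (m0 + m1)/2 + s^2 ln(pi0/pi1) / (m1 - m0).
    """
    y = np.asarray(y).astype(int)
    x0, x1 = x[y == 0], x[y == 1]
    m0, m1 = x0.mean(axis=0), x1.mean(axis=0)
    n0, n1 = len(x0), len(x1)
    var = (
        ((x0 - m0) ** 2).sum(axis=0) + ((x1 - m1) ** 2).sum(axis=0)
    ) / max(n0 + n1 - 2, 1)
    var = np.maximum(var, 1e-12)
    delta = m1 - m0
    safe = np.where(np.abs(delta) < 1e-12, np.inf, delta)
    thr = (m0 + m1) / 2.0 + var * np.log(n0 / n1) / safe
    return thr, np.sign(delta)


def lda_feature_screen(
    train: Cohort, validation: Cohort, k: int = 20
) -> ScreenedFeatureSet:
    """Score every (wavelength, bin) scalar by single-feature LDA validation
    accuracy and keep the top-k."""
    n_features = 77 * 90
    if k > n_features:
        raise ValueError(f"k={k} exceeds the {n_features} available features")
    if validation.n == 0:
        raise ValueError("validation set is empty")
    xt = train.spectra.reshape(train.n, -1)
    xv = validation.spectra.reshape(validation.n, -1)
    thr, sign = _lda_1d_threshold(xt, train.labels)
    pred = (sign[None, :] * (xv - thr[None, :]) > 0).astype(int)
    acc = (pred == validation.labels[:, None]).mean(axis=0)
    acc = np.where(np.isfinite(thr), acc, 0.0)
    top = np.argsort(-acc, kind="stable")[:k]
    pairs = np.stack(np.unravel_index(top, (77, 90)), axis=1)
    return ScreenedFeatureSet(pairs=pairs, utilities=acc[top])
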