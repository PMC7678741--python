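"""Two-class linear soft-margin SVM with resubstitution scoring.

The model is the standard soft-margin linear SVM, min over (w, b) of
``1/2 ||w||^2 + C * sum_i max(0, 1 - y_i (w.x_i + b))``, fitted on
z-score-standardized features by a deterministic SMO dual solver
(tolerance 1e-6, no randomized initialization). Group C is the positive
class (+1), group A negative (-1).

Discriminability of a feature set is measured by *resubstitution*
accuracy — the fraction of training samples the fitted hyperplane
classifies correctly. With cohorts of a few dozen samples no honest
held-out validation is possible; resubstitution answers the narrower
question "does a separating hyperplane exist for these samples", and is
reported as such, never as generalization performance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import _smo
from .errors import ParameterError
from .containers import GROUPS

logger = logging.getLogger("lfqpanel")

MAX_ITER = 200_000
POSITIVE_GROUP = "C"


@dataclass
class SvmConfig:
    """Fit settings: regularization C, solver tolerance, standardization."""

    regularization_c: float = 1.0
    tol: float = 1e-6
    standardize: bool = True

    def validate(self) -> None:
        if self.regularization_c <= 0:
            raise ParameterError("regularization_c must be positive")
        if self.tol <= 0:
            raise ParameterError("tol must be positive")


@dataclass
class SvmModel:
    """A fitted linear SVM in standardized feature space."""

    weights: np.ndarray
    bias: float
    regularization_c: float
    feature_means: np.ndarray
    feature_sds: np.ndarray

    def decision_function(self, features: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(features, dtype=float))
        Z = (X - self.feature_means) / self.feature_sds
        return Z @ self.weights + self.bias

    def predict(self, features: np.ndarray) -> np.ndarray:
        d = self.decision_function(features)
        return np.where(d >= 0, POSITIVE_GROUP, "A")

    def to_dict(self) -> dict:
        return {
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "regularization_c": self.regularization_c,
            "feature_means": self.feature_means.tolist(),
            "feature_sds": self.feature_sds.tolist(),
        }


@dataclass
class ClassificationResult:
    """Per-sample resubstitution outcome of one model on one feature set."""

    accuracy_percent: float  # full precision
    predicted_labels: dict[str, str]
    misclassified_ids: dict[str, list[str]] = field(default_factory=dict)

    @property
    def accuracy_display(self) -> float:
        """Accuracy rounded to one decimal for reporting."""
        return round(self.accuracy_percent, 1)

    @property
    def n_samples(self) -> int:
        return len(self.predicted_labels)

    @property
    def n_misclassified(self) -> int:
        return sum(len(v) for v in self.misclassified_ids.values())

    def to_dict(self) -> dict:
        return {
            "accuracy_percent": self.accuracy_display,
            "n_samples": self.n_samples,
            "misclassified_ids": self.misclassified_ids,
        }


def signed_labels(labels) -> np.ndarray:
    """Map group labels C/A to +1/-1, validating both classes are present."""
    arr = np.asarray(labels)
    bad = set(arr.tolist()) - set(GROUPS)
    if bad:
        raise ParameterError(f"unknown class labels: {sorted(bad)}")
    y = np.where(arr == POSITIVE_GROUP, 1.0, -1.0)
    if len(np.unique(y)) < 2:
        raise ParameterError("both classes C and A must be present")
    return y


def standardize(features: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-feature z-scoring; zero-variance features get sd 1 (with warning)."""
    X = np.asarray(features, dtype=float)
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=0)
    zero = sds == 0
    if np.any(zero):
        logger.warning(
            "%d zero-variance feature(s); sd set to 1 (uninformative after centering)",
            int(zero.sum()),
        )
        sds = np.where(zero, 1.0, sds)
    return (X - means) / sds, means, sds


def fit_svm(
    features: np.ndarray,
    labels,
    regularization_c: float = 1.0,
    tol: float = 1e-6,
    standardize_features: bool = True,
) -> SvmModel:
    """Fit the soft-margin linear SVM.

    ``features`` is sample x feature (no missing values); ``labels`` maps
    each sample to "C" or "A". Deterministic for fixed input.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ParameterError("features must be a 2-D sample x feature array")
    if np.any(~np.isfinite(X)):
        raise ParameterError("features contain non-finite values")
    y = signed_labels(labels)
    if len(y) != X.shape[0]:
        raise ParameterError("labels length does not match feature rows")
    if regularization_c <= 0:
        raise ParameterError("regularization_c must be positive")

    if standardize_features:
        Z, means, sds = standardize(X)
    else:
        Z = X
        means = np.zeros(X.shape[1])
        sds = np.ones(X.shape[1])

    w, b, _alpha, n_iter, gap = _smo.fit_linear(
        np.ascontiguousarray(Z), y, float(regularization_c), float(tol), MAX_ITER
    )
    if gap > tol:
        logger.warning("SMO hit iteration cap (KKT gap %.2e > tol)", gap)
    return SvmModel(
        weights=np.asarray(w),
        bias=float(b),
        regularization_c=float(regularization_c),
        feature_means=means,
        feature_sds=sds,
    )


def resubstitution_accuracy(
    model: SvmModel,
    features: np.ndarray,
    labels,
    sample_ids: list[str] | None = None,
) -> ClassificationResult:
    """Score the model on the samples it was fitted to.

    Accuracy is kept at full precision internally (it is an exact ratio
    of integers, so ties between feature panels are exact); display
    rounding to one decimal happens only in reports.
    """
    X = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if X.shape[0] != len(labels):
        raise ParameterError("labels length does not match feature rows")
    if X.shape[1] != len(model.weights):
        raise ParameterError("feature count does not match model weights")
    if sample_ids is None:
        sample_ids = [str(i) for i in range(X.shape[0])]
    predicted = model.predict(X)
    correct = predicted == labels
    accuracy = 100.0 * correct.sum() / len(labels)
    misclassified: dict[str, list[str]] = {g: [] for g in GROUPS}
    for sid, ok, true_group in zip(sample_ids, correct, labels):
        if not ok:
            misclassified[str(true_group)].append(sid)
    return ClassificationResult(
        accuracy_percent=float(accuracy),
        predicted_labels=dict(zip(sample_ids, predicted)),
        misclassified_ids=misclassified,
    )


def fit_and_score(
    features: np.ndarray,
    labels,
    config: SvmConfig | None = None,
    sample_ids: list[str] | None = None,
) -> tuple[SvmModel, ClassificationResult]:
    """Convenience wrapper: fit, then resubstitute on the same samples."""
    config = config or SvmConfig()
    config.validate()
    model = fit_svm(
        features,
        labels,
        regularization_c=config.regularization_c,
        tol=config.tol,
        standardize_features=config.standardize,
    )
    return model, resubstitution_accuracy(model, features, labels, sample_ids)
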