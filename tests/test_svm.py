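"""Linear SVM core: solver correctness, invariances, reference agreement."""

import numpy as np
import pytest
from scipy.optimize import linprog

from lfqpanel import (
    ParameterError,
    fit_and_score,
    fit_svm,
    resubstitution_accuracy,
)


def _score(X, labels, C=1.0):
    model = fit_svm(np.asarray(X, float), np.asarray(labels), regularization_c=C)
    return model, resubstitution_accuracy(model, np.asarray(X, float), np.asarray(labels))


def test_symmetric_separable_1d():
    X = [[-2.0], [-1.0], [1.0], [2.0]]
    labels = ["A", "A", "C", "C"]
    model, result = _score(X, labels)
    assert result.accuracy_percent == 100.0
    # decision boundary (in raw coordinates) between -1 and 1
    boundary = -model.bias / model.weights[0] * model.feature_sds[0] + model.feature_means[0]
    assert -1.0 < boundary < 1.0


def _separating_line_exists(X, y_signed):
    """LP feasibility: does any (w, b) satisfy y_i (w.x_i + b) >= 1?"""
    X = np.asarray(X, float)
    n, d = X.shape
    # variables: w (d), b (1); constraints -y_i (w.x_i + b) <= -1
    A = -(y_signed[:, None] * np.hstack([X, np.ones((n, 1))]))
    b_ub = -np.ones(n)
    res = linprog(
        c=np.zeros(d + 1), A_ub=A, b_ub=b_ub,
        bounds=[(None, None)] * (d + 1), method="highs",
    )
    return res.success


def test_xor_layout_not_linearly_separable():
    """No line classifies the 4-point XOR layout perfectly; the SVM must
    score at most 75% on it (verified against an LP feasibility oracle)."""
    X = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
    labels = np.array(["C", "C", "A", "A"])
    y = np.where(labels == "C", 1.0, -1.0)
    assert not _separating_line_exists(X, y)
    _, result = _score(X, labels, C=100.0)
    assert result.accuracy_percent <= 75.0


def test_duplicating_samples_with_half_c_gives_same_hyperplane():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(10, 2))
    labels = np.array(["C"] * 5 + ["A"] * 5)
    m1 = fit_svm(X, labels, regularization_c=1.0)
    X2 = np.vstack([X, X])
    labels2 = np.concatenate([labels, labels])
    m2 = fit_svm(X2, labels2, regularization_c=0.5)
    assert np.allclose(m1.weights, m2.weights, atol=1e-6)
    assert m1.bias == pytest.approx(m2.bias, abs=1e-5)


def test_accuracy_invariant_under_sample_order_and_feature_scaling(rng):
    X = rng.normal(size=(20, 3))
    labels = np.array(["C"] * 11 + ["A"] * 9)
    _, base = _score(X, labels)
    perm = rng.permutation(20)
    _, permuted = _score(X[perm], labels[perm])
    assert permuted.accuracy_percent == base.accuracy_percent
    scaled = X * np.array([3.0, 0.01, 250.0]) + np.array([5.0, -2.0, 1e6])
    _, rescaled = _score(scaled, labels)
    assert rescaled.accuracy_percent == base.accuracy_percent


def test_label_swap_negates_decision_function(rng):
    X = rng.normal(size=(14, 2))
    labels = np.array(["C"] * 7 + ["A"] * 7)
    swapped = np.where(labels == "C", "A", "C")
    m1 = fit_svm(X, labels)
    m2 = fit_svm(X, swapped)
    assert np.allclose(m1.decision_function(X), -m2.decision_function(X), atol=1e-5)
    r1 = resubstitution_accuracy(m1, X, labels)
    r2 = resubstitution_accuracy(m2, X, swapped)
    assert r1.accuracy_percent == r2.accuracy_percent


def test_large_c_separable_reaches_100(rng):
    X = np.vstack([rng.normal(-3, 1, size=(15, 2)), rng.normal(3, 1, size=(15, 2))])
    labels = np.array(["A"] * 15 + ["C"] * 15)
    _, result = _score(X, labels, C=1e3)
    assert result.accuracy_percent == 100.0


def test_agreement_with_reference_svm_on_random_instances():
    """Predictions match sklearn's libsvm-based SVC on >= 95% of 50 random
    small instances (differences allowed only at decision-boundary ties)."""
    from sklearn.svm import SVC

    rng = np.random.default_rng(42)
    n_match = 0
    for _ in range(50):
        n = int(rng.integers(6, 20))
        d = int(rng.integers(1, 4))
        X = rng.normal(size=(n, d))
        labels = np.where(rng.uniform(size=n) < 0.5, "C", "A")
        labels[0], labels[1] = "C", "A"
        C = float(rng.choice([0.1, 1.0, 10.0]))
        model = fit_svm(X, labels, regularization_c=C)
        Z = (X - model.feature_means) / model.feature_sds
        ref = SVC(kernel="linear", C=C, tol=1e-8).fit(Z, (labels == "C").astype(int))
        pred_ref = np.where(ref.predict(Z) == 1, "C", "A")
        n_match += np.array_equal(model.predict(X), pred_ref)
    assert n_match >= 48  # >= 95% of 50


def test_accuracy_arithmetic_and_display_rounding():
    labels = np.array(["C"] * 32 + ["A"] * 28)
    X = np.where(labels == "C", 1.0, -1.0)[:, None] + 0.0
    model = fit_svm(X, labels, regularization_c=10.0)
    result = resubstitution_accuracy(model, X, labels)
    assert result.accuracy_percent == 100.0
    # flip 4 C and 3 A feature values across the boundary
    X2 = X.copy()
    X2[:4, 0] = -1.0
    X2[32:35, 0] = 1.0
    result2 = resubstitution_accuracy(model, X2, labels)
    assert result2.n_misclassified == 7
    assert result2.accuracy_percent == pytest.approx(100 * 53 / 60)
    assert result2.accuracy_display == 88.3
    assert sorted(map(len, result2.misclassified_ids.values())) == [3, 4]


def test_fully_wrong_two_sample_set_scores_zero():
    labels = np.array(["C", "A"])
    X = np.array([[1.0], [-1.0]])
    model = fit_svm(X, labels, regularization_c=10.0)
    flipped = X[::-1]
    result = resubstitution_accuracy(model, flipped, labels)
    assert result.accuracy_percent == 0.0


def test_zero_variance_feature_warned_not_fatal(caplog):
    import logging

    X = np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0], [4.0, 5.0]])
    labels = np.array(["A", "A", "C", "C"])
    with caplog.at_level(logging.WARNING, logger="lfqpanel"):
        _, result = fit_and_score(X, labels)
    assert result.accuracy_percent == 100.0
    assert any("zero-variance" in rec.message for rec in caplog.records)


def test_single_class_rejected():
    X = np.zeros((3, 1))
    with pytest.raises(ParameterError):
        fit_svm(X, np.array(["C", "C", "C"]))
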