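"""Confusion-matrix metrics, classifier delegation, and the Welch t-test."""

import numpy as np
import pytest

from dermtex import ClassifierSpec, confusion, fit_predict, metrics, welch_ttest
from dermtex.errors import InputError, ShapeError, TrainingError
from oracles import welch_p_oracle


# ---------------------------------------------------------------------------
# confusion matrix


def test_confusion_perfect_and_inverted():
    np.testing.assert_array_equal(
        confusion([0, 1, 0, 1], [0, 1, 0, 1]), [[2, 0], [0, 2]]
    )
    np.testing.assert_array_equal(
        confusion([0, 0, 1, 1], [1, 1, 0, 0]), [[0, 2], [2, 0]]
    )


def test_confusion_total_conservation(rng):
    y_true = rng.integers(0, 4, 1000)
    y_pred = rng.integers(0, 4, 1000)
    assert confusion(y_true, y_pred).sum() == 1000


def test_confusion_length_mismatch():
    with pytest.raises(ShapeError):
        confusion([0, 1], [0, 1, 1])


# ---------------------------------------------------------------------------
# metrics


def test_binary_metrics_worked_example():
    # TP=50, FP=10, FN=20, TN=40 (positive class = malignant = label 1)
    cm = np.array([[40, 10], [20, 50]])
    rep = metrics(cm)
    assert rep.precision == pytest.approx(50 / 60)
    assert rep.recall == pytest.approx(50 / 70)
    assert rep.f1 == pytest.approx(2 * (50 / 60) * (50 / 70) / (50 / 60 + 50 / 70))
    assert rep.f1 == pytest.approx(0.76923, abs=1e-5)
    assert rep.accuracy == pytest.approx(90 / 120)


def test_perfect_classifier_metrics_are_one():
    rep = metrics(np.array([[30, 0], [0, 20]]))
    assert (rep.accuracy, rep.precision, rep.recall, rep.f1) == (1.0, 1.0, 1.0, 1.0)


def test_f1_is_harmonic_mean_fixed_point():
    # symmetric errors give precision == recall == F1
    rep = metrics(np.array([[45, 5], [5, 45]]))
    assert rep.precision == rep.recall == pytest.approx(rep.f1)


def test_zero_division_cells_yield_zero():
    # class 1 never predicted: precision denominator is 0
    cm = np.array([[50, 0], [20, 0]])
    rep = metrics(cm)
    assert rep.precision == 0.0 and rep.recall == 0.0 and rep.f1 == 0.0
    assert rep.accuracy == pytest.approx(50 / 70)


def test_multiclass_weighted_vs_macro():
    cm = np.array([[8, 2, 0], [1, 4, 0], [0, 0, 5]])
    w = metrics(cm, averaging="weighted")
    m = metrics(cm, averaging="macro")
    total = cm.sum()
    assert w.accuracy == m.accuracy == pytest.approx(np.trace(cm) / total)
    # weighted recall is exactly the accuracy for one-vs-rest per-class recall
    assert w.recall == pytest.approx(np.trace(cm) / total)
    assert 0 <= m.f1 <= 1 and 0 <= w.f1 <= 1
    with pytest.raises(InputError):
        metrics(cm, averaging="median")


def test_empty_matrix_is_input_error():
    with pytest.raises(InputError):
        metrics(np.zeros((2, 2)))


# ---------------------------------------------------------------------------
# Welch t-test


def test_welch_self_test_is_zero_one():
    preds = [0, 1, 1, 0, 1, 0, 0, 1]
    res = welch_ttest(preds, preds)
    assert res.t == 0.0 and res.p == 1.0 and res.significant is False


def test_welch_antisymmetry():
    a, b = [1, 2, 3, 4, 5], [2, 2, 4, 4, 9]
    ab, ba = welch_ttest(a, b), welch_ttest(b, a)
    assert ab.t == pytest.approx(-ba.t)
    assert ab.p == pytest.approx(ba.p)


@pytest.mark.parametrize(
    "a,b",
    [
        ([1, 2, 3, 4, 5], [2, 4, 6, 8, 10]),
        ([0, 0, 1, 1, 1, 0], [1, 1, 1, 1, 0, 1, 1]),
        ([10.5, 11.2, 9.8, 10.1], [8.0, 8.4, 7.9, 8.8, 8.1]),
    ],
)
def test_welch_p_matches_quadrature_oracle(a, b):
    res = welch_ttest(a, b)
    assert res.p == pytest.approx(welch_p_oracle(res.t, res.df), abs=1e-9)


def test_welch_frozen_example():
    # expected values frozen from the quadrature oracle
    res = welch_ttest([1, 2, 3, 4, 5], [2, 4, 6, 8, 10])
    assert res.t == pytest.approx(-1.897366596101, abs=1e-9)
    assert res.df == pytest.approx(5.882352941176, abs=1e-9)
    assert res.p == pytest.approx(0.107531194931, abs=1e-9)
    assert res.significant is False


def test_welch_both_constant_defined_as_zero_one():
    res = welch_ttest([3, 3, 3], [3, 3, 3, 3])
    assert res.t == 0.0 and res.p == 1.0


def test_welch_short_vector_is_input_error():
    with pytest.raises(InputError):
        welch_ttest([1], [1, 2, 3])


# ---------------------------------------------------------------------------
# classifier delegation


@pytest.fixture(scope="module")
def gaussian_clouds():
    rng = np.random.default_rng(7)
    X = np.vstack([rng.normal(-5, 1, (100, 2)), rng.normal(5, 1, (100, 2))])
    y = np.array([0] * 100 + [1] * 100)
    return X[::2], y[::2], X[1::2], y[1::2]


@pytest.mark.parametrize("kind", ["SVM", "XGBOOST"])
def test_separable_clouds_are_classified_perfectly(gaussian_clouds, kind):
    X_tr, y_tr, X_te, y_te = gaussian_clouds
    pred = fit_predict(ClassifierSpec(kind=kind, seed=0), X_tr, y_tr, X_te)
    assert (pred == y_te).mean() >= 0.95


@pytest.mark.parametrize("kind", ["SVM", "XGBOOST"])
def test_fit_predict_is_deterministic(gaussian_clouds, kind):
    X_tr, y_tr, X_te, _ = gaussian_clouds
    spec = ClassifierSpec(kind=kind, seed=3)
    np.testing.assert_array_equal(
        fit_predict(spec, X_tr, y_tr, X_te), fit_predict(spec, X_tr, y_tr, X_te)
    )


def test_fit_predict_errors(gaussian_clouds):
    X_tr, y_tr, X_te, _ = gaussian_clouds
    with pytest.raises(ShapeError):
        fit_predict(ClassifierSpec(), X_tr, y_tr, X_te[:, :1])
    with pytest.raises(TrainingError):
        fit_predict(ClassifierSpec(), X_tr, np.zeros_like(y_tr), X_te)
    with pytest.raises(InputError):
        fit_predict(ClassifierSpec(kind="FOREST"), X_tr, y_tr, X_te)
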