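"""Classification and evaluation.

Classifiers are delegated to their library implementations with default
hyperparameters — sklearn's ``SVC`` and xgboost's ``XGBClassifier`` — since
the method under study is the feature representation, not the classifier.

Evaluation follows the standard confusion-matrix metrics. For a binary
task the positive class is "malignant" (label 1) and

    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    recall    = TP / (TP + FN)
    precision = TP / (TP + FP)
    F1        = 2 * precision * recall / (precision + recall)

Multi-class metrics are one-vs-rest per class, combined by weighted
(default) or macro averaging. Cells with a zero denominator (no predicted
or no actual positives) contribute 0 by convention rather than raising;
degenerate classifiers must not crash the evaluation.

Two prediction vectors are compared with a two-tailed Welch t-test
(unequal variances, Welch–Satterthwaite degrees of freedom) at α = 0.05,
with class indices cast to numerics. Identical predictions give t = 0,
p = 1 by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import InputError, ShapeError, TrainingError

__all__ = [
    "ClassifierSpec",
    "MetricsReport",
    "WelchResult",
    "make_classifier",
    "delegate_info",
    "fit_predict",
    "confusion",
    "metrics",
    "welch_ttest",
    "plot_confusion",
]

logger = logging.getLogger(__name__)

ALPHA = 0.05


@dataclass(frozen=True)
class ClassifierSpec:
    """Which delegate classifier to use. ``params`` is empty by default:
    the delegate's library defaults are used, recorded in the run report."""

    kind: str = "XGBOOST"  # "SVM" or "XGBOOST"
    params: dict = field(default_factory=dict)
    seed: int = 0


def make_classifier(spec: ClassifierSpec):
    kind = spec.kind.upper()
    if kind == "SVM":
        from sklearn.svm import SVC

        return SVC(random_state=spec.seed, **spec.params)
    if kind == "XGBOOST":
        from xgboost import XGBClassifier

        return XGBClassifier(random_state=spec.seed, **spec.params)
    raise InputError(f"unknown classifier kind: {spec.kind!r}")


def delegate_info(spec: ClassifierSpec) -> dict:
    """Delegate library version and the effective hyperparameters."""
    kind = spec.kind.upper()
    if kind == "SVM":
        import sklearn

        version = f"scikit-learn {sklearn.__version__}"
    else:
        import xgboost

        version = f"xgboost {xgboost.__version__}"
    clf = make_classifier(spec)
    params = {k: v for k, v in clf.get_params().items() if v is not None}
    return {"kind": kind, "version": version, "params": {k: str(v) for k, v in params.items()}}


def fit_predict(
    spec: ClassifierSpec,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
) -> np.ndarray:
    """Train the delegate on (X_train, y_train) and predict labels for X_test."""
    X_train = np.asarray(X_train, dtype=np.float64)
    X_test = np.asarray(X_test, dtype=np.float64)
    y_train = np.asarray(y_train)
    if np.unique(y_train).size < 2:
        raise TrainingError("training set contains a single class")
    if X_train.ndim != 2 or X_test.ndim != 2 or X_train.shape[1] != X_test.shape[1]:
        raise ShapeError(
            f"train/test dimension mismatch: {X_train.shape} vs {X_test.shape}"
        )
    clf = make_classifier(spec)
    logger.debug("fitting %s", delegate_info(spec)["version"])
    clf.fit(X_train, y_train)
    return np.asarray(clf.predict(X_test))


def confusion(y_true, y_pred, n_classes: int | None = None) -> np.ndarray:
    """C×C count matrix, rows = true class, columns = predicted class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ShapeError(
            f"length mismatch: {y_true.shape[0]} true vs {y_pred.shape[0]} predicted"
        )
    if n_classes is None:
        n_classes = int(max(y_true.max(), y_pred.max())) + 1
    from sklearn.metrics import confusion_matrix

    return confusion_matrix(y_true, y_pred, labels=np.arange(n_classes))


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        logger.warning("zero denominator in %s; reporting 0 by convention", what)
        return 0.0
    return num / den


@dataclass(frozen=True)
class MetricsReport:
    """Accuracy, precision, recall and F1, each a fraction in [0, 1]."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    averaging: str = "weighted"

    def as_percent(self) -> dict:
        return {
            "accuracy": 100.0 * self.accuracy,
            "precision": 100.0 * self.precision,
            "recall": 100.0 * self.recall,
            "f1": 100.0 * self.f1,
        }


def metrics(cm: np.ndarray, averaging: str = "weighted") -> MetricsReport:
    """Compute the metric report from a confusion matrix.

    Binary matrices treat label 1 (malignant) as the positive class.
    Multi-class matrices use one-vs-rest per-class metrics combined by
    ``averaging`` in {"weighted", "macro"}.
    """
    cm = np.asarray(cm, dtype=np.float64)
    total = cm.sum()
    if cm.size == 0 or total == 0:
        raise InputError("empty confusion matrix")
    if averaging not in ("weighted", "macro"):
        raise InputError(f"unknown averaging mode: {averaging!r}")
    acc = np.trace(cm) / total

    n = cm.shape[0]
    if n == 2:
        tp, fn = cm[1, 1], cm[1, 0]
        fp = cm[0, 1]
        pr = _safe_div(tp, tp + fp, "precision")
        rc = _safe_div(tp, tp + fn, "recall")
        f1 = _safe_div(2 * pr * rc, pr + rc, "F1")
        return MetricsReport(acc, pr, rc, f1, averaging)

    support = cm.sum(axis=1)
    prs, rcs, f1s = [], [], []
    for c in range(n):
        tp = cm[c, c]
        pr = _safe_div(tp, cm[:, c].sum(), f"precision[{c}]")
        rc = _safe_div(tp, support[c], f"recall[{c}]")
        prs.append(pr)
        rcs.append(rc)
        f1s.append(_safe_div(2 * pr * rc, pr + rc, f"F1[{c}]"))
    if averaging == "weighted":
        w = support / total
    else:
        w = np.full(n, 1.0 / n)
    return MetricsReport(
        acc,
        float(np.dot(w, prs)),
        float(np.dot(w, rcs)),
        float(np.dot(w, f1s)),
        averaging,
    )


@dataclass(frozen=True)
class WelchResult:
    t: float
    p: float
    df: float
    significant: bool  # p < 0.05

    def as_dict(self) -> dict:
        return {"t": self.t, "p": self.p, "df": self.df, "significant": self.significant}


def welch_ttest(a, b) -> WelchResult:
    """Two-tailed Welch t-test on two numeric vectors.

    Degenerate case: if both sample variances are zero (both vectors
    constant) and the means are equal, t is defined as 0 with p = 1.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise InputError("Welch t-test needs at least 2 observations per group")
    va = a.var(ddof=1) / a.size
    vb = b.var(ddof=1) / b.size
    diff = a.mean() - b.mean()
    if va + vb == 0:
        t = 0.0 if diff == 0 else np.inf * np.sign(diff)
        p = 1.0 if diff == 0 else 0.0
        df = float(a.size + b.size - 2)
    else:
        t = diff / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
        p = 2.0 * stats.t.sf(abs(t), df)
    return WelchResult(float(t), float(p), float(df), bool(p < ALPHA))


def plot_confusion(cm: np.ndarray, path, class_names=None) -> None:
    """Render a confusion matrix heat map to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cm = np.asarray(cm)
    n = cm.shape[0]
    names = class_names or [str(i) for i in range(n)]
    fig, ax = plt.subplots(figsize=(1.2 * n + 2, 1.2 * n + 1.5))
    im = ax.imshow(cm, cmap="Blues")
    for i in range(n):
        for j in range(n):
            ax.text(j, i, str(int(cm[i, j])), ha="center", va="center",
                    color="white" if cm[i, j] > cm.max() / 2 else "black")
    ax.set_xticks(range(n), names)
    ax.set_yticks(range(n), names)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
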