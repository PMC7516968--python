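"""Shallow classifiers and the imbalance-aware evaluation suite.

The melanoma class is the positive class throughout.  Besides the usual
accuracy / sensitivity / specificity / precision / F-score / MCC family,
the imbalance-aware metrics are provided:

* geometric mean ``G = sqrt(sensitivity * specificity)``,
* dominance ``sensitivity - specificity``,
* Index of Balanced Accuracy ``IBA = (1 - dominance) * G**2``,

which jointly reward models that are accurate on the minority class
without sacrificing the majority.  AUC is computed two ways -- the
rank-based (Mann-Whitney) area under the ROC curve of the continuous
scores, and balanced accuracy ``(sensitivity + specificity) / 2`` -- so
the two quantities are never conflated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields

import numpy as np
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from .balance import LabeledDataset

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "TrainedModel",
    "confusion",
    "metrics",
    "imbalance_metrics",
    "auc_score",
    "train_classifier",
    "predict",
    "evaluate",
]

CLASSIFIER_KINDS = ("logistic", "svm_linear", "svm_rbf", "rvm")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")
        if self.total < 1:
            raise ValueError("confusion table is empty")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f_score: float
    mcc: float
    g_mean: float = np.nan
    dominance: float = np.nan
    iba: float = np.nan
    auc_roc: float = np.nan
    balanced_accuracy: float = np.nan

    def as_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}


@dataclass
class TrainedModel:
    """Fitted shallow classifier with a score threshold for hard labels."""

    kind: str
    estimator: object
    threshold: float
    n_features: int


def confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    """2x2 tally with label 1 (melanoma) as the positive class."""
    y_true = np.asarray(y_true).ravel()
    y_pred = np.asarray(y_pred).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred lengths differ")
    for arr, name in ((y_true, "y_true"), (y_pred, "y_pred")):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} must be binary 0/1")
    return ConfusionCounts(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN", stacklevel=3)
        return float("nan")
    return num / den


def metrics(c: ConfusionCounts) -> MetricsReport:
    """Accuracy, sensitivity, specificity, precision, F-score and MCC."""
    tp, tn, fp, fn = c.tp, c.tn, c.fp, c.fn
    accuracy = (tp + tn) / c.total
    sensitivity = _ratio(tp, tp + fn, "sensitivity")
    specificity = _ratio(tn, tn + fp, "specificity")
    precision = _ratio(tp, tp + fp, "precision")
    f_score = _ratio(2 * tp, 2 * tp + fp + fn, "f_score")
    denom = np.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = _ratio(float(tp) * tn - float(fp) * fn, denom, "mcc")
    report = MetricsReport(
        accuracy=float(accuracy),
        sensitivity=float(sensitivity),
        specificity=float(specificity),
        precision=float(precision),
        f_score=float(f_score),
        mcc=float(mcc),
    )
    if np.isfinite(sensitivity) and np.isfinite(specificity):
        g, d, iba = imbalance_metrics(sensitivity, specificity)
        report.g_mean, report.dominance, report.iba = g, d, iba
        report.balanced_accuracy = (sensitivity + specificity) / 2.0
    return report


def imbalance_metrics(sensitivity: float, specificity: float) -> tuple[float, float, float]:
    """G-mean, dominance and the Index of Balanced Accuracy."""
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    g_mean = float(np.sqrt(sensitivity * specificity))
    dominance = float(sensitivity - specificity)
    iba = float((1.0 - dominance) * g_mean**2)
    return g_mean, dominance, iba


def auc_score(scores: np.ndarray, y_true: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) area under the ROC curve; ties count 1/2."""
    scores = np.asarray(scores, dtype=np.float64).ravel()
    y_true = np.asarray(y_true).ravel()
    if scores.shape != y_true.shape:
        raise ValueError("scores and labels lengths differ")
    n_pos = int((y_true == 1).sum())
    n_neg = int((y_true == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    rank_sum = ranks[y_true == 1].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def train_classifier(
    train: LabeledDataset, kind: str = "svm_rbf", hyper: dict | None = None
) -> TrainedModel:
    """Fit a shallow classifier; logistic and SVM kinds are always available.

    ``hyper`` may carry ``seed`` plus estimator keyword overrides.  The
    relevance vector machine (``rvm``) is an optional plugin with no
    bundled backend.
    """
    hyper = dict(hyper or {})
    seed = int(hyper.pop("seed", 0))
    classes, counts = np.unique(train.y, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError("need at least 2 instances of each class to train")
    if kind == "logistic":
        est = LogisticRegression(max_iter=1000, random_state=seed, **hyper)
        threshold = 0.5
    elif kind == "svm_linear":
        est = SVC(kernel="linear", C=hyper.pop("C", 1.0), random_state=seed, **hyper)
        threshold = 0.0
    elif kind == "svm_rbf":
        est = SVC(
            kernel="rbf",
            C=hyper.pop("C", 1.0),
            gamma=hyper.pop("gamma", "auto"),  # 1 / n_features
            random_state=seed,
            **hyper,
        )
        threshold = 0.0
    elif kind == "rvm":
        raise RuntimeError(
            "the relevance vector machine is an optional plugin; no sparse "
            "Bayesian backend is installed -- use 'logistic', 'svm_linear' "
            "or 'svm_rbf'"
        )
    else:
        raise ValueError(f"unknown classifier kind {kind!r}; known: {CLASSIFIER_KINDS}")
    est.fit(train.X, train.y)
    return TrainedModel(
        kind=kind, estimator=est, threshold=threshold, n_features=train.X.shape[1]
    )


def predict(model: TrainedModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hard labels and continuous class-1 scores for a feature matrix."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"expected {model.n_features} features, got shape {X.shape}"
        )
    est = model.estimator
    # probabilistic scores when available (threshold 0.5); SVM margins
    # otherwise (threshold 0)
    if hasattr(est, "predict_proba"):
        scores = np.asarray(est.predict_proba(X)[:, 1], dtype=np.float64)
    else:
        scores = np.asarray(est.decision_function(X), dtype=np.float64)
    labels = (scores >= model.threshold).astype(np.int64)
    return labels, scores


def evaluate(model: TrainedModel, X: np.ndarray, y_true: np.ndarray) -> MetricsReport:
    """Predict on a partition and assemble the full metric report."""
    labels, scores = predict(model, X)
    report = metrics(confusion(y_true, labels))
    report.auc_roc = auc_score(scores, y_true)
    return report
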