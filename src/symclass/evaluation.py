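"""Metrics and the cross-validation training harness.

Each balanced binary dataset is split 70:30 (stratified); the training part
goes through 5-fold cross validation where every fold's run of the GPSC engine
yields one symbolic expression, so a full run produces a five-expression set
with per-fold train/test metrics.  Metrics are accuracy, ROC AUC (on the
sigmoid scores), precision, recall and F1; summary panels report the mean and
population standard deviation over the five folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import engine
from . import expressions as ex

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "SESet",
    "MetricError",
    "confusion",
    "accuracy",
    "precision",
    "recall",
    "f1_score",
    "auc",
    "compute_metrics",
    "split_70_30",
    "five_fold_train",
    "evaluate_on",
]

METRIC_NAMES = ("acc", "auc", "precision", "recall", "f1")


class MetricError(ValueError):
    pass


@dataclass
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    acc: float
    auc: float
    precision: float
    recall: float
    f1: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def confusion(y_true, y_pred) -> ConfusionMatrix:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred lengths differ")
    return ConfusionMatrix(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); returning 0")
        return 0.0
    return num / den


def accuracy(cm: ConfusionMatrix) -> float:
    return _ratio(cm.tp + cm.tn, cm.total, "accuracy")


def precision(cm: ConfusionMatrix) -> float:
    return _ratio(cm.tp, cm.tp + cm.fp, "precision")


def recall(cm: ConfusionMatrix) -> float:
    return _ratio(cm.tp, cm.tp + cm.fn, "recall")


def f1_score(cm: ConfusionMatrix) -> float:
    p, r = precision(cm), recall(cm)
    if p + r == 0:
        warnings.warn("F1 undefined (precision + recall = 0); returning 0")
        return 0.0
    return 2 * p * r / (p + r)


def auc(y_true, scores) -> float:
    """Rank-based (trapezoidal) area under the ROC curve; ties averaged."""
    y_true = np.asarray(y_true, dtype=int)
    if np.unique(y_true).size < 2:
        raise MetricError("AUC needs both classes present")
    return float(roc_auc_score(y_true, np.asarray(scores, dtype=float)))


def compute_metrics(y_true, raw_scores) -> tuple[MetricsReport, ConfusionMatrix]:
    """Metrics of a raw-output classifier: labels at raw >= 0, AUC on the
    sigmoid of the raw scores."""
    raw_scores = np.asarray(raw_scores, dtype=float)
    y_pred = (raw_scores >= 0).astype(int)
    cm = confusion(y_true, y_pred)
    try:
        a = auc(y_true, engine.sigmoid(raw_scores))
    except MetricError:
        warnings.warn("single-class target; AUC reported as 0")
        a = 0.0
    return (
        MetricsReport(
            acc=accuracy(cm),
            auc=a,
            precision=precision(cm),
            recall=recall(cm),
            f1=f1_score(cm),
        ),
        cm,
    )


def split_70_30(X, y, rng: np.random.Generator):
    """Stratified 70:30 train/test split (falls back to unstratified with a
    warning when a class is too small to stratify)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(y) < 10:
        raise ValueError("need at least 10 samples for a 70:30 split")
    seed = int(rng.integers(2**31))
    _, counts = np.unique(y, return_counts=True)
    stratify = y
    if counts.min() < 2:
        warnings.warn("a class has fewer than 2 samples; splitting unstratified")
        stratify = None
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, train_size=0.7, random_state=seed, stratify=stratify
    )
    return X_tr, X_te, y_tr, y_te


@dataclass
class SESet:
    """The five symbolic expressions from one 5-fold-CV run, with metrics."""

    expressions: list
    train_reports: list[MetricsReport]
    test_reports: list[MetricsReport]
    class_label: int | None = None
    method: str | None = None
    lengths: list[int] = field(default_factory=list)
    #: optional summary of metrics on a held-out split, filled by the pipeline
    holdout: dict | None = None

    def __post_init__(self):
        if not self.lengths:
            self.lengths = [ex.length(t) for t in self.expressions]

    @property
    def average_length(self) -> float:
        return float(np.mean(self.lengths))

    def _summary(self, reports) -> dict[str, tuple[float, float]]:
        out = {}
        for name in METRIC_NAMES:
            vals = np.array([getattr(r, name) for r in reports])
            out[name] = (float(vals.mean()), float(vals.std()))  # population sigma
        return out

    def train_summary(self) -> dict[str, tuple[float, float]]:
        """Mean and population std of each metric over the five folds."""
        return self._summary(self.train_reports)

    def test_summary(self) -> dict[str, tuple[float, float]]:
        return self._summary(self.test_reports)

    def mean_train_metrics(self) -> dict[str, float]:
        return {k: v[0] for k, v in self.train_summary().items()}


def five_fold_train(
    X, y, cfg: engine.GPSCConfig, rng: np.random.Generator, n_folds: int = 5
) -> SESet:
    """Train the GPSC engine once per stratified fold.

    Per fold the engine evolves on the other folds' rows and the best tree is
    scored on both that training portion and the held-out fold.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    seed = int(rng.integers(2**31))
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    trees, train_reports, test_reports = [], [], []
    for train_idx, test_idx in skf.split(X, y):
        result = engine.evolve(cfg, X[train_idx], y[train_idx], rng)
        tree = result.best_tree
        trees.append(tree)
        train_reports.append(
            compute_metrics(y[train_idx], ex.evaluate(tree, X[train_idx]))[0]
        )
        test_reports.append(
            compute_metrics(y[test_idx], ex.evaluate(tree, X[test_idx]))[0]
        )
    return SESet(expressions=trees, train_reports=train_reports, test_reports=test_reports)


def evaluate_on(model, X, y):
    """Evaluate a trained model on a dataset.

    For an expression set, returns the per-expression reports plus a
    mean/population-std summary; for a majority-vote ensemble (anything with a
    ``predict`` method), returns its metrics report and confusion matrix.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if isinstance(model, SESet):
        reports = [
            compute_metrics(y, ex.evaluate(t, X))[0] for t in model.expressions
        ]
        summary = {}
        for name in METRIC_NAMES:
            vals = np.array([getattr(r, name) for r in reports])
            summary[name] = (float(vals.mean()), float(vals.std()))
        return reports, summary
    if hasattr(model, "predict"):
        y_pred = np.asarray(model.predict(X), dtype=int)
        cm = confusion(y, y_pred)
        # vote fraction is a graded score for the ROC area when available
        scores = (
            model.vote_fraction(X)
            if hasattr(model, "vote_fraction")
            else y_pred.astype(float)
        )
        try:
            a = auc(y, scores)
        except MetricError:
            a = 0.0
        report = MetricsReport(
            acc=accuracy(cm),
            auc=a,
            precision=precision(cm),
            recall=recall(cm),
            f1=f1_score(cm),
        )
        return report, cm
    raise TypeError(f"cannot evaluate model of type {type(model).__name__}")
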