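"""Majority-vote ensembles of symbolic expressions and decision-tree stacking.

The best five-expression set from each oversampling variant of a class is
pooled into one per-class ensemble (15 expressions when all three samplers
balanced the class, 5 when only one did).  A sample is labeled positive when
at least half the expressions — ceil(count / 2) — vote positive.  The stacker
appends each class's vote vector to the principal-component features and fits
a default CART decision tree (Gini, best splits, unlimited depth) per class.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.tree import DecisionTreeClassifier

from . import engine
from . import expressions as ex
from .evaluation import MetricsReport, compute_metrics, confusion, split_70_30
from .evaluation import accuracy, auc, f1_score, precision, recall, MetricError
from .evaluation import SESet

__all__ = [
    "EnsembleModel",
    "StackedModel",
    "majority_vote",
    "build_ensembles",
    "stack_with_tree",
    "resolve_multiclass",
]


@dataclass
class EnsembleModel:
    """Per-class pooled expressions with a majority-vote threshold."""

    class_label: int
    expressions: list
    vote_threshold: int = 0
    #: which oversampling methods contributed expressions, for provenance
    methods: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.expressions:
            raise ValueError("ensemble needs at least one expression")
        if self.vote_threshold == 0:
            self.vote_threshold = math.ceil(len(self.expressions) / 2)
        if not (1 <= self.vote_threshold <= len(self.expressions)):
            raise ValueError(
                f"vote_threshold {self.vote_threshold} outside "
                f"[1, {len(self.expressions)}]"
            )

    def vote_counts(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        votes = np.zeros(X.shape[0], dtype=int)
        for tree in self.expressions:
            votes += engine.classify(tree, X)
        return votes

    def vote_fraction(self, X) -> np.ndarray:
        return self.vote_counts(X) / len(self.expressions)

    def predict(self, X) -> np.ndarray:
        return majority_vote(self, X)


def majority_vote(model: EnsembleModel, X) -> np.ndarray:
    """Label 1 iff at least ``vote_threshold`` expressions predict 1."""
    return (model.vote_counts(X) >= model.vote_threshold).astype(int)


def build_ensembles(
    best_sets: Mapping[tuple[int, str], SESet],
) -> dict[int, EnsembleModel]:
    """Pool each class's best expression sets across oversampling methods.

    ``best_sets`` maps ``(class_label, method)`` to the winning five-expression
    set for that pair.  The same set object may not be supplied twice.
    """
    seen: list[int] = []
    per_class: dict[int, list[tuple[str, SESet]]] = {}
    for (class_label, method), se_set in best_sets.items():
        if id(se_set) in seen:
            raise ValueError(
                f"duplicate expression set supplied for class {class_label} "
                f"({method})"
            )
        seen.append(id(se_set))
        per_class.setdefault(int(class_label), []).append((method, se_set))

    ensembles: dict[int, EnsembleModel] = {}
    for class_label, entries in sorted(per_class.items()):
        expressions, methods = [], []
        for method, se_set in sorted(entries, key=lambda e: e[0]):
            expressions.extend(se_set.expressions)
            methods.append(method)
        if not expressions:
            warnings.warn(f"class {class_label} has no expression sets; excluded")
            continue
        ensembles[class_label] = EnsembleModel(
            class_label=class_label, expressions=expressions, methods=methods
        )
    return ensembles


@dataclass
class StackedModel:
    """Per-class decision trees fitted on PC features plus the vote vector."""

    ensembles: dict[int, EnsembleModel]
    trees: dict[int, DecisionTreeClassifier]
    criterion: str = "gini"
    splitter: str = "best"
    max_depth: int | None = None
    min_samples_split: int = 2

    def predict_class(self, class_label: int, X_pc) -> np.ndarray:
        X_pc = np.asarray(X_pc, dtype=float)
        votes = majority_vote(self.ensembles[class_label], X_pc)
        stacked = np.column_stack([X_pc, votes])
        return self.trees[class_label].predict(stacked)


def _tree_report(tree, X_stacked, y_bin) -> MetricsReport:
    y_pred = tree.predict(X_stacked)
    cm = confusion(y_bin, y_pred)
    try:
        a = auc(y_bin, tree.predict_proba(X_stacked)[:, 1])
    except (MetricError, IndexError):
        a = 0.0
    return MetricsReport(
        acc=accuracy(cm),
        auc=a,
        precision=precision(cm),
        recall=recall(cm),
        f1=f1_score(cm),
    )


def stack_with_tree(
    ensembles: dict[int, EnsembleModel],
    X_pc,
    y_int,
    rng: np.random.Generator,
    holdout_only: bool = False,
) -> tuple[StackedModel, dict[int, MetricsReport]]:
    """Fit one decision tree per class on (PC features + vote vector).

    Per class the stacked dataset is split 70:30 and the tree is trained on
    the 70% part.  By default metrics are reported on the **entire** dataset
    (training rows included), matching the published protocol; pass
    ``holdout_only=True`` for an honest evaluation on the 30% part only —
    the default leaks training rows into the reported numbers.
    """
    X_pc = np.asarray(X_pc, dtype=float)
    y_int = np.asarray(y_int, dtype=int)
    trees: dict[int, DecisionTreeClassifier] = {}
    reports: dict[int, MetricsReport] = {}
    for class_label, model in sorted(ensembles.items()):
        y_bin = (y_int == class_label).astype(int)
        if np.unique(y_bin).size < 2:
            warnings.warn(f"class {class_label} target is degenerate; skipped")
            continue
        votes = majority_vote(model, X_pc)
        stacked = np.column_stack([X_pc, votes])
        idx = np.arange(len(y_bin))
        tr_idx, te_idx, _, _ = split_70_30(idx.reshape(-1, 1), y_bin, rng)
        tr_idx = tr_idx.ravel().astype(int)
        te_idx = te_idx.ravel().astype(int)
        tree = DecisionTreeClassifier(
            criterion="gini",
            splitter="best",
            max_depth=None,
            min_samples_split=2,
            random_state=int(rng.integers(2**31)),
        )
        tree.fit(stacked[tr_idx], y_bin[tr_idx])
        trees[class_label] = tree
        if holdout_only:
            reports[class_label] = _tree_report(tree, stacked[te_idx], y_bin[te_idx])
        else:
            reports[class_label] = _tree_report(tree, stacked, y_bin)
    return StackedModel(ensembles=ensembles, trees=trees), reports


def resolve_multiclass(
    predictions: Mapping[int, Sequence[int]],
) -> tuple[np.ndarray, list[tuple[int, list[int]]]]:
    """Combine per-class binary predictions into integer labels.

    A sample claimed by exactly one class gets that label; samples claimed by
    zero or several classes are unresolved (label -1) and reported with all
    claiming classes.
    """
    classes = sorted(predictions)
    mat = np.column_stack([np.asarray(predictions[c], dtype=int) for c in classes])
    labels = np.full(mat.shape[0], -1, dtype=int)
    conflicts: list[tuple[int, list[int]]] = []
    for i in range(mat.shape[0]):
        claimed = [classes[j] for j in np.where(mat[i] == 1)[0]]
        if len(claimed) == 1:
            labels[i] = claimed[0]
        else:
            conflicts.append((i, claimed))
    return labels, conflicts
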