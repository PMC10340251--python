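"""Minority-class oversampling: SMOTE, Borderline-SMOTE and SVM-SMOTE.

All three samplers create synthetic minority points on (or, for the SVM
variant, just beyond) segments joining a minority seed to one of its nearest
minority neighbors, and repeat until the class counts are equal.  They differ
in which minority points may act as seeds:

* SMOTE — every minority point;
* Borderline-SMOTE — only the DANGER set: minority points whose neighborhood
  in the full dataset is majority-dominated but not entirely majority;
* SVM-SMOTE — minority support vectors of a linear soft-margin SVM (points
  whose whole neighborhood is majority are discarded as noise).

When a sampler's seed set is empty the dataset cannot be balanced by that
method; the input is returned unchanged and the report is flagged, and such
(class, method) pairs are excluded from downstream training.

Inputs are assumed to be already scaled/projected; distances are plain
Euclidean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC

from .preprocessing import BinaryTask

__all__ = [
    "OversampleReport",
    "BalancedDataset",
    "ResamplingError",
    "smote",
    "borderline_smote",
    "svm_smote",
    "balance_all",
]


class ResamplingError(ValueError):
    pass


@dataclass
class OversampleReport:
    method: str  # "smote" | "borderline" | "svmsmote"
    before: dict[int, int]  # class label -> count
    after: dict[int, int]
    balanced: bool


@dataclass
class BalancedDataset:
    class_label: int
    method: str
    X: np.ndarray
    y: np.ndarray
    report: OversampleReport
    #: boolean mask over rows: True for original samples, False for synthetic
    original_mask: np.ndarray


def _split_classes(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    labels, counts = np.unique(y, return_counts=True)
    if labels.size != 2:
        raise ResamplingError(f"expected a binary target, found labels {labels}")
    # minority by count; tie resolves to label 1 (the positive class)
    if counts[0] == counts[1]:
        minority = 1
    else:
        minority = int(labels[np.argmin(counts)])
    majority = int(labels[0] if labels[1] == minority else labels[1])
    return X, y, minority, majority


def _counts(y) -> dict[int, int]:
    labels, counts = np.unique(np.asarray(y, dtype=int), return_counts=True)
    return {int(l): int(c) for l, c in zip(labels, counts)}


def _minority_neighbors(X_min, k: int):
    k_eff = min(k, len(X_min) - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(X_min)
    idx = nn.kneighbors(X_min, return_distance=False)[:, 1:]  # drop self
    return idx, k_eff


def _interpolate(X_min, seeds: np.ndarray, nn_idx: np.ndarray, n_new: int, rng):
    """Draw n_new points x + lam * (x_nn - x) with lam ~ U(0, 1)."""
    picks = rng.integers(len(seeds), size=n_new)
    out = np.empty((n_new, X_min.shape[1]))
    for row, s in enumerate(picks):
        seed = int(seeds[s])
        base = X_min[seed]
        nbr = X_min[nn_idx[seed][rng.integers(nn_idx.shape[1])]]
        lam = rng.random()
        out[row] = base + lam * (nbr - base)
    return out


def smote(X, y, k: int = 5, rng: np.random.Generator | None = None):
    """Plain SMOTE: every minority point is a seed; synthetics are uniform
    interpolations toward one of its k nearest minority neighbors."""
    rng = np.random.default_rng() if rng is None else rng
    X, y, minority, majority = _split_classes(X, y)
    X_min = X[y == minority]
    n_new = int(np.sum(y == majority) - len(X_min))
    if len(X_min) < 2:
        raise ResamplingError(f"minority class has {len(X_min)} sample(s); need >= 2")
    if n_new <= 0:
        return X.copy(), y.copy()
    nn_idx, _ = _minority_neighbors(X_min, k)
    synth = _interpolate(X_min, np.arange(len(X_min)), nn_idx, n_new, rng)
    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.full(n_new, minority, dtype=int)])
    return X_out, y_out


def _neighborhood_majority_counts(X, y, minority: int, m: int) -> np.ndarray:
    """For each minority point, count majority members among its m nearest
    neighbors in the whole dataset (self excluded)."""
    m_eff = min(m, len(X) - 1)
    nn = NearestNeighbors(n_neighbors=m_eff + 1).fit(X)
    idx = nn.kneighbors(X[y == minority], return_distance=False)[:, 1:]
    maj = (y[idx] != minority).sum(axis=1)
    return maj, m_eff


def borderline_smote(
    X, y, k: int = 5, m: int = 10, rng: np.random.Generator | None = None
):
    """Borderline-SMOTE: interpolate only from the DANGER set.

    A minority point with m' majority members among its m nearest neighbors is
    in DANGER iff m/2 <= m' < m; m' = m marks it as noise and m' < m/2 as safe,
    both excluded.  An empty DANGER set means the dataset cannot be balanced
    by this method: the input is returned unchanged, flagged in the report.
    """
    rng = np.random.default_rng() if rng is None else rng
    X, y, minority, majority = _split_classes(X, y)
    X_min = X[y == minority]
    if len(X_min) < 2:
        raise ResamplingError(f"minority class has {len(X_min)} sample(s); need >= 2")
    before = _counts(y)
    n_new = int(np.sum(y == majority) - len(X_min))
    if n_new <= 0:
        return X.copy(), y.copy(), OversampleReport("borderline", before, before, True)

    maj_counts, m_eff = _neighborhood_majority_counts(X, y, minority, m)
    danger = np.where((maj_counts >= m_eff / 2) & (maj_counts < m_eff))[0]
    if danger.size == 0:
        return X.copy(), y.copy(), OversampleReport("borderline", before, before, False)

    nn_idx, _ = _minority_neighbors(X_min, k)
    synth = _interpolate(X_min, danger, nn_idx, n_new, rng)
    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.full(n_new, minority, dtype=int)])
    return X_out, y_out, OversampleReport("borderline", before, _counts(y_out), True)


def svm_smote(
    X,
    y,
    k: int = 5,
    m: int = 10,
    C: float = 1.0,
    rng: np.random.Generator | None = None,
):
    """SVM-SMOTE: seeds are the minority support vectors of a linear SVM.

    Support vectors whose entire m-neighborhood is majority are discarded as
    noise.  Around each remaining seed, new points are interpolated toward a
    minority neighbor when the seed's neighborhood is majority-dense (more
    than half majority) and extrapolated away from it (step capped at the
    segment length) otherwise, which expands the minority region toward the
    decision boundary.
    """
    rng = np.random.default_rng() if rng is None else rng
    X, y, minority, majority = _split_classes(X, y)
    X_min = X[y == minority]
    if len(X_min) < 2 or int(np.sum(y == majority)) < 2:
        raise ResamplingError("both classes need >= 2 samples")
    before = _counts(y)
    n_new = int(np.sum(y == majority) - len(X_min))
    if n_new <= 0:
        return X.copy(), y.copy(), OversampleReport("svmsmote", before, before, True)

    try:
        clf = SVC(kernel="linear", C=C).fit(X, y)
    except Exception as err:  # pragma: no cover - sklearn failures are rare
        raise ResamplingError(f"SVM fit failed: {err}")
    sv = clf.support_[y[clf.support_] == minority]
    # map support-vector rows into minority-array positions
    min_rows = np.where(y == minority)[0]
    pos_of = {int(r): i for i, r in enumerate(min_rows)}
    seeds_min = np.array([pos_of[int(r)] for r in sv], dtype=int)

    maj_counts, m_eff = _neighborhood_majority_counts(X, y, minority, m)
    keep = maj_counts[seeds_min] < m_eff  # drop all-majority neighborhoods (noise)
    seeds_min = seeds_min[keep]
    if seeds_min.size == 0:
        return X.copy(), y.copy(), OversampleReport("svmsmote", before, before, False)

    nn_idx, _ = _minority_neighbors(X_min, k)
    dense = maj_counts > m_eff / 2  # per minority point: majority-dense neighborhood?
    picks = rng.integers(len(seeds_min), size=n_new)
    synth = np.empty((n_new, X.shape[1]))
    for row, s in enumerate(picks):
        seed = seeds_min[s]
        nbr = X_min[nn_idx[seed][rng.integers(nn_idx.shape[1])]]
        lam = rng.random()
        if dense[seed]:
            synth[row] = X_min[seed] + lam * (nbr - X_min[seed])
        else:
            synth[row] = X_min[seed] - lam * (nbr - X_min[seed])
    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.full(n_new, minority, dtype=int)])
    return X_out, y_out, OversampleReport("svmsmote", before, _counts(y_out), True)


_METHODS = ("smote", "borderline", "svmsmote")


def balance_all(
    tasks: Sequence[BinaryTask],
    methods: Iterable[str] = _METHODS,
    k: int = 5,
    m: int = 10,
    rng: np.random.Generator | None = None,
) -> list[BalancedDataset]:
    """Oversample every (task x method) pair.

    Pairs a method cannot balance are still returned (with
    ``report.balanced = False``) so the feasibility pattern can be reported,
    but callers should train only on the balanced ones.
    """
    rng = np.random.default_rng() if rng is None else rng
    out = []
    for task in tasks:
        n_orig = len(task.y)
        for method in methods:
            if method == "smote":
                Xb, yb = smote(task.X, task.y, k=k, rng=rng)
                report = OversampleReport(
                    "smote",
                    _counts(task.y),
                    _counts(yb),
                    balanced=len(set(_counts(yb).values())) == 1,
                )
            elif method == "borderline":
                Xb, yb, report = borderline_smote(task.X, task.y, k=k, m=m, rng=rng)
            elif method == "svmsmote":
                Xb, yb, report = svm_smote(task.X, task.y, k=k, m=m, rng=rng)
            else:
                raise ValueError(f"unknown method {method!r}; known: {_METHODS}")
            mask = np.zeros(len(yb), dtype=bool)
            mask[:n_orig] = True
            out.append(
                BalancedDataset(
                    class_label=task.class_label,
                    method=method,
                    X=Xb,
                    y=yb,
                    report=report,
                    original_mask=mask,
                )
            )
    return out
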