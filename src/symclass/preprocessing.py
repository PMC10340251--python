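"""Feature preprocessing: scaling, linearity audit, PCA reduction and
one-vs-rest task decomposition.

The intended inputs are wide expression tables (tens of thousands of probes,
~150 samples).  Features are standardized to zero mean and unit (population)
variance, audited for approximate linear structure, and compressed with PCA to
the smallest number of components whose cumulative explained variance reaches
a target (default 99%).  A multiclass target is ordinal-encoded and then split
into one binary one-vs-rest task per class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

__all__ = [
    "ScalerParams",
    "PCAModel",
    "BinaryTask",
    "fit_scaler",
    "transform",
    "linearity_audit",
    "fit_pca",
    "project",
    "ordinal_encode",
    "ordinal_decode",
    "one_hot_tasks",
]


@dataclass
class ScalerParams:
    mean: np.ndarray
    std: np.ndarray  # population standard deviation; zero for constant columns


@dataclass
class PCAModel:
    """PCA truncated at the cumulative explained-variance target.

    ``components`` is features x k (loadings); the sign convention makes the
    largest-magnitude loading of each component positive so refits are
    reproducible.
    """

    components: np.ndarray
    explained_variance_ratio: np.ndarray
    k: int
    target: float
    mean: np.ndarray


@dataclass
class BinaryTask:
    """One one-vs-rest dataset: PC features plus a 0/1 target."""

    class_label: int
    X: np.ndarray
    y: np.ndarray

    @property
    def n_positive(self) -> int:
        return int(np.sum(self.y == 1))

    @property
    def n_negative(self) -> int:
        return int(np.sum(self.y == 0))


def _as_float_matrix(X) -> np.ndarray:
    X = np.asarray(X)
    try:
        X = X.astype(float)
    except (TypeError, ValueError) as err:
        raise ValueError(f"non-numeric data in feature matrix: {err}")
    if X.ndim != 2:
        raise ValueError("X must be 2-D (samples x features)")
    return X


def fit_scaler(X) -> ScalerParams:
    X = _as_float_matrix(X)
    return ScalerParams(mean=X.mean(axis=0), std=X.std(axis=0))


def transform(X, params: ScalerParams) -> np.ndarray:
    """Standardize: (x - mean) / std; constant columns map to zero."""
    X = _as_float_matrix(X)
    std = np.where(params.std > 0, params.std, 1.0)
    return (X - params.mean) / std


def linearity_audit(X) -> tuple[np.ndarray, float, float]:
    """Per-feature R-squared of an ordinary least-squares fit of the feature
    against the sample index 0..N-1.

    A high mean R-squared indicates the features mostly follow a linear trend
    across the (ordered) samples, which is used to justify a linear
    dimensionality reduction.  Zero-variance features get R-squared 1.
    Returns ``(r2 per feature, mean, std)``.
    """
    X = _as_float_matrix(X)
    n = X.shape[0]
    if n < 3:
        raise ValueError("linearity audit needs at least 3 samples")
    t = np.arange(n, dtype=float)
    tc = t - t.mean()
    Xc = X - X.mean(axis=0)
    ss_tot = np.sum(Xc**2, axis=0)
    slope_num = tc @ Xc
    ss_reg = slope_num**2 / np.sum(tc**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(ss_tot > 0, ss_reg / np.where(ss_tot > 0, ss_tot, 1.0), 1.0)
    r2 = np.clip(r2, 0.0, 1.0)
    return r2, float(r2.mean()), float(r2.std())


def fit_pca(X_scaled, target: float = 0.99) -> PCAModel:
    """Fit PCA (via SVD) and keep the minimal number of leading components
    whose cumulative explained-variance ratio reaches ``target``."""
    if not (0.0 < target <= 1.0):
        raise ValueError(f"target must be in (0, 1], got {target}")
    X_scaled = _as_float_matrix(X_scaled)
    n, p = X_scaled.shape
    pca = PCA(n_components=min(n, p), svd_solver="full")
    pca.fit(X_scaled)
    ratios = pca.explained_variance_ratio_
    cum = np.cumsum(ratios)
    k = int(np.searchsorted(cum, target - 1e-12) + 1)
    k = min(k, len(ratios))
    comps = pca.components_[:k].copy()
    # sign convention: make the largest-magnitude loading of each component
    # positive so repeated fits agree regardless of SVD sign ambiguity
    flip = np.sign(comps[np.arange(k), np.argmax(np.abs(comps), axis=1)])
    flip[flip == 0] = 1.0
    comps *= flip[:, None]
    return PCAModel(
        components=comps.T,
        explained_variance_ratio=ratios[:k].copy(),
        k=k,
        target=target,
        mean=pca.mean_.copy(),
    )


def project(X_scaled, model: PCAModel) -> np.ndarray:
    X_scaled = _as_float_matrix(X_scaled)
    if X_scaled.shape[1] != model.components.shape[0]:
        raise ValueError(
            f"feature count {X_scaled.shape[1]} does not match PCA model "
            f"({model.components.shape[0]})"
        )
    return (X_scaled - model.mean) @ model.components


def ordinal_encode(
    labels, mapping: dict | None = None
) -> tuple[np.ndarray, dict]:
    """Encode string labels as integers.

    Without an explicit ``mapping``, codes follow first-seen order.  With one
    (e.g. a fixed label -> integer table), unseen labels raise a ``KeyError``.
    """
    labels = list(labels)
    if mapping is None:
        mapping = {}
        for lab in labels:
            if lab not in mapping:
                mapping[lab] = len(mapping)
    codes = np.empty(len(labels), dtype=int)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            raise KeyError(f"label {lab!r} not in mapping {sorted(mapping)}")
        codes[i] = mapping[lab]
    return codes, dict(mapping)


def ordinal_decode(codes, mapping: dict) -> list:
    inverse = {v: k for k, v in mapping.items()}
    return [inverse[int(c)] for c in codes]


def one_hot_tasks(y_int, X_pc) -> list[BinaryTask]:
    """Decompose a multiclass target into one-vs-rest binary tasks.

    Task ``c`` labels samples of class ``c`` as 1 and all others as 0.
    Classes without positives are excluded with a warning.
    """
    y_int = np.asarray(y_int, dtype=int)
    X_pc = _as_float_matrix(X_pc)
    if X_pc.shape[0] != y_int.shape[0]:
        raise ValueError("X and y have different sample counts")
    classes = np.unique(y_int)
    if classes.size < 2:
        raise ValueError("need at least 2 classes for one-vs-rest decomposition")
    tasks = []
    for c in classes:
        y_bin = (y_int == c).astype(int)
        if y_bin.sum() == 0:
            warnings.warn(f"class {c} has no positive samples; task excluded")
            continue
        tasks.append(BinaryTask(class_label=int(c), X=X_pc, y=y_bin))
    return tasks
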