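"""Tabular and artifact I/O.

Tables are CSV/TSV with a header row, samples as rows, optionally gzipped.
Reports and manifests are JSON; PCA models persist as a loadings-matrix CSV
plus a JSON metadata sidecar; evolved expressions use the one-per-line text
format of :mod:`symclass.expressions`.
"""

from __future__ import annotations

import dataclasses
import gzip
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocessing import PCAModel

__all__ = [
    "DataError",
    "read_table",
    "write_table",
    "write_report",
    "save_pca_model",
    "load_pca_model",
]


class DataError(ValueError):
    pass


def _open_text(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "r")


def _sep_for(path: Path) -> str:
    name = str(path)
    if name.endswith(".gz"):
        name = name[:-3]
    return "\t" if name.endswith((".tsv", ".tab")) else ","


def read_table(path, class_column: str | None = None):
    """Read a samples x features table.

    Returns ``(X, feature_names, labels)`` where ``labels`` is None unless
    ``class_column`` names a column to split off as the class labels.  All
    feature cells must be numeric; the first offending row/column is named in
    the error.  Duplicate header names and ragged rows are rejected.
    """
    path = Path(path)
    sep = _sep_for(path)
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise DataError(f"duplicate column header(s): {dupes}")
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.ParserError as err:
        raise DataError(f"malformed table {path}: {err}")
    df.columns = header

    labels = None
    if class_column is not None:
        if class_column not in df.columns:
            raise DataError(
                f"class column {class_column!r} not found; columns start with "
                f"{list(df.columns[:5])}"
            )
        labels = df[class_column].astype(str).to_numpy()
        df = df.drop(columns=[class_column])

    coerced = df.apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna() & df.notna()
    if bad.to_numpy().any():
        rows, cols = np.where(bad.to_numpy())
        raise DataError(
            f"non-numeric value {df.iat[rows[0], cols[0]]!r} at row {rows[0]}, "
            f"column {df.columns[cols[0]]!r}"
        )
    if coerced.isna().to_numpy().any():
        rows, cols = np.where(coerced.isna().to_numpy())
        raise DataError(
            f"missing value at row {rows[0]}, column {df.columns[cols[0]]!r}"
        )
    return coerced.to_numpy(dtype=float), list(df.columns), labels


def write_table(path, X, feature_names=None, labels=None, class_column="class"):
    X = np.asarray(X)
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(X.shape[1])]
    df = pd.DataFrame(X, columns=feature_names)
    if labels is not None:
        df[class_column] = labels
    df.to_csv(path, sep=_sep_for(Path(path)), index=False)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_report(obj, path) -> None:
    """Serialize a dataclass / dict tree (numpy-aware) to JSON."""
    with open(path, "w") as fh:
        json.dump(_jsonable(obj), fh, indent=2)


def save_pca_model(model: PCAModel, loadings_path, meta_path) -> None:
    pd.DataFrame(
        model.components, columns=[f"PC{i}" for i in range(model.k)]
    ).to_csv(loadings_path, index=False)
    write_report(
        {
            "k": model.k,
            "target": model.target,
            "explained_variance_ratio": model.explained_variance_ratio,
            "mean": model.mean,
        },
        meta_path,
    )


def load_pca_model(loadings_path, meta_path) -> PCAModel:
    comps = pd.read_csv(loadings_path).to_numpy(dtype=float)
    with open(meta_path) as fh:
        meta = json.load(fh)
    return PCAModel(
        components=comps,
        explained_variance_ratio=np.asarray(meta["explained_variance_ratio"]),
        k=int(meta["k"]),
        target=float(meta["target"]),
        mean=np.asarray(meta["mean"]),
    )
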