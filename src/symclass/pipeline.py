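"""End-to-end pipeline orchestration.

Stages: standardize -> linearity audit -> PCA at the cumulative-variance
target -> ordinal encode -> one-vs-rest decomposition -> oversample each task
with each sampler -> per balanced (class x method) pair, random hyperparameter
search with 5-fold-CV training -> pool best expression sets into per-class
majority-vote ensembles -> evaluate on the original (imbalanced) data ->
decision-tree stacking.

:func:`run_stages` is the in-memory engine used by tests and scripts;
:func:`run_pipeline` wraps it with file I/O and writes a provenance manifest.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import ensemble as ens
from . import evaluation as ev
from . import expressions as ex
from . import io as sio
from . import preprocessing as pp
from . import resampling as rs
from . import rhvs
from .synthetic import SyntheticSpec, generate

__all__ = ["PipelineConfig", "PipelineResult", "run_stages", "run_pipeline"]

_DEFAULT_METHODS = ("smote", "borderline", "svmsmote")


@dataclass
class PipelineConfig:
    input_path: str | None = None
    output_dir: str = "symclass_out"
    class_column: str = "class"
    pca_target: float = 0.99
    oversamplers: tuple[str, ...] = _DEFAULT_METHODS
    ranges: rhvs.HyperRanges = field(default_factory=rhvs.HyperRanges.reduced)
    rhvs_iters: int = 5
    gate: float = 0.99
    seed: int = 0
    holdout_stacking: bool = False


@dataclass
class PipelineResult:
    audit_mean: float
    audit_std: float
    pca_model: pp.PCAModel
    class_mapping: dict
    tasks: list
    balanced: list
    best_sets: dict  # (class_label, method) -> SESet
    rhvs_results: dict
    ensembles: dict
    ensemble_reports: dict  # class -> MetricsReport on the original data
    single_se_summaries: dict  # class -> mean ACC of the pooled individual SEs
    stacked_reports: dict
    resolved_labels: np.ndarray
    conflicts: list


def run_stages(
    X,
    labels,
    config: PipelineConfig,
    rng: np.random.Generator | None = None,
) -> PipelineResult:
    """Run the full method in memory on a numeric matrix and label vector."""
    rng = np.random.default_rng(config.seed) if rng is None else rng

    scaler = pp.fit_scaler(X)
    X_scaled = pp.transform(X, scaler)
    _, audit_mean, audit_std = pp.linearity_audit(X)
    pca_model = pp.fit_pca(X_scaled, config.pca_target)
    X_pc = pp.project(X_scaled, pca_model)

    y_int, mapping = pp.ordinal_encode([str(l) for l in labels])
    tasks = pp.one_hot_tasks(y_int, X_pc)
    balanced = rs.balance_all(tasks, config.oversamplers, rng=rng)

    best_sets: dict[tuple[int, str], ev.SESet] = {}
    rhvs_results = {}
    for ds in balanced:
        if not ds.report.balanced:
            continue
        X_tr, X_te, y_tr, y_te = ev.split_70_30(ds.X, ds.y, rng)
        task = pp.BinaryTask(class_label=ds.class_label, X=X_tr, y=y_tr)
        result = rhvs.run_rhvs(
            task, config.ranges, gate=config.gate, max_iters=config.rhvs_iters, rng=rng
        )
        result.best_set.method = ds.method
        # held-out 30% metrics for the winning set
        result.best_set.holdout = ev.evaluate_on(result.best_set, X_te, y_te)[1]
        best_sets[(ds.class_label, ds.method)] = result.best_set
        rhvs_results[(ds.class_label, ds.method)] = result

    ensembles = ens.build_ensembles(best_sets)

    ensemble_reports, single_summaries, predictions = {}, {}, {}
    for class_label, model in ensembles.items():
        y_bin = (y_int == class_label).astype(int)
        report, _cm = ev.evaluate_on(model, X_pc, y_bin)
        ensemble_reports[class_label] = report
        accs = [
            ev.compute_metrics(y_bin, ex.evaluate(t, X_pc))[0].acc
            for t in model.expressions
        ]
        single_summaries[class_label] = float(np.mean(accs))
        predictions[class_label] = ens.majority_vote(model, X_pc)

    stacked_model, stacked_reports = ens.stack_with_tree(
        ensembles, X_pc, y_int, rng, holdout_only=config.holdout_stacking
    )
    resolved, conflicts = ens.resolve_multiclass(predictions)

    return PipelineResult(
        audit_mean=audit_mean,
        audit_std=audit_std,
        pca_model=pca_model,
        class_mapping=mapping,
        tasks=tasks,
        balanced=balanced,
        best_sets=best_sets,
        rhvs_results=rhvs_results,
        ensembles=ensembles,
        ensemble_reports=ensemble_reports,
        single_se_summaries=single_summaries,
        stacked_reports=stacked_reports,
        resolved_labels=resolved,
        conflicts=conflicts,
    )


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> dict:
    """File-based entry point: read the input table, run every stage, persist
    artifacts under ``output_dir`` and return the run manifest."""
    if config.input_path is None:
        raise ValueError("pipeline config needs an input_path")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    X, feature_names, labels = sio.read_table(config.input_path, config.class_column)
    if labels is None:
        raise sio.DataError(f"class column {config.class_column!r} yielded no labels")
    rng = np.random.default_rng(config.seed)
    t0 = time.time()
    result = run_stages(X, labels, config, rng)

    sio.write_report(
        {"mean_r2": result.audit_mean, "std_r2": result.audit_std},
        out / "linearity_audit.json",
    )
    sio.save_pca_model(result.pca_model, out / "pca_loadings.csv", out / "pca_meta.json")
    sio.write_report(
        [ds.report for ds in result.balanced], out / "oversample_reports.json"
    )

    per_class = {}
    for (class_label, method), se_set in result.best_sets.items():
        ex.write_expression_file(
            out / f"se_class{class_label}_{method}.txt",
            se_set.expressions,
            header=f"class {class_label}, oversampler {method}, seed {config.seed}",
        )
        per_class.setdefault(class_label, {})[method] = {
            "train": se_set.train_summary(),
            "test": se_set.test_summary(),
            "lengths": se_set.lengths,
            "average_length": se_set.average_length,
        }
    sio.write_report(per_class, out / "per_class_reports.json")

    ensemble_manifest = {
        cl: {
            "n_expressions": len(m.expressions),
            "vote_threshold": m.vote_threshold,
            "methods": m.methods,
            "metrics": result.ensemble_reports[cl],
        }
        for cl, m in result.ensembles.items()
    }
    sio.write_report(ensemble_manifest, out / "ensembles.json")
    sio.write_report(result.stacked_reports, out / "stacked_reports.json")

    manifest = {
        "config": asdict(config),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "n_samples": int(X.shape[0]),
        "n_features": int(X.shape[1]),
        "n_components": result.pca_model.k,
        "class_mapping": result.class_mapping,
        "classes": sorted(result.ensembles),
        "n_balanced_datasets": sum(ds.report.balanced for ds in result.balanced),
        "unresolved_samples": len(result.conflicts),
        "runtime_s": round(time.time() - t0, 2),
        "artifacts": sorted(p.name for p in out.iterdir()),
    }
    sio.write_report(manifest, out / "manifest.json")
    return manifest


def synth_to_csv(spec: SyntheticSpec, table_path, truth_path=None) -> None:
    """Write a synthetic dataset (and optional ground-truth sidecar) to disk."""
    X, labels, truth = generate(spec)
    names = [f"g{i}" for i in range(X.shape[1])]
    sio.write_table(table_path, X, names, labels=[f"class_{l}" for l in labels])
    if truth_path is not None:
        sio.write_report(
            {
                "spec": asdict(spec),
                "class_means": truth.class_means,
                "trend_weights": truth.trend_weights,
            },
            truth_path,
        )
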