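"""Random hyperparameter value search (RHVS).

Hyperparameter combinations for the GPSC engine are drawn uniformly from
per-field ranges (integers uniform, reals uniform, the parsimony coefficient
and stop criterion log-uniform because their ranges span decades).  The four
genetic-operation probabilities are resampled jointly until their sum lands in
[0.999, 1.0].  Each sampled configuration is trained with 5-fold CV; the
search stops as soon as all five mean training metrics clear a quality gate
(default 0.99), otherwise the configuration with the best mean training
accuracy wins after ``max_iters`` draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .engine import GPSCConfig
from .evaluation import SESet, five_fold_train
from .preprocessing import BinaryTask

__all__ = ["HyperRanges", "SearchError", "sample_config", "run_rhvs", "RHVSResult"]


class SearchError(RuntimeError):
    pass


@dataclass
class HyperRanges:
    """(lo, hi) sampling ranges for each engine hyperparameter.

    Defaults are the published search ranges for the full-scale study; the
    :meth:`reduced` profile shrinks the population/generation budgets for
    desk-scale runs while keeping the same structure.
    """

    size_pop: tuple[int, int] = (1000, 2000)
    depth_init: tuple[int, int] = (3, 18)
    gen_num: tuple[int, int] = (200, 300)
    const_range: tuple[float, float] = (-10000.0, 10000.0)
    size_tour: tuple[int, int] = (100, 500)
    crit_stop: tuple[float, float] = (1e-6, 1e-3)
    p_crossover: tuple[float, float] = (0.001, 0.3)
    p_hoist: tuple[float, float] = (0.001, 0.3)
    p_subtree: tuple[float, float] = (0.9, 1.0)
    p_point: tuple[float, float] = (0.001, 0.3)
    parsimony: tuple[float, float] = (1e-5, 1e-4)
    max_samples: tuple[float, float] = (0.99, 1.0)
    op_sum_range: tuple[float, float] = (0.999, 1.0)

    def __post_init__(self):
        for name, (lo, hi) in asdict(self).items():
            if lo > hi:
                raise ValueError(f"{name}: lo {lo} > hi {hi}")

    @classmethod
    def reduced(
        cls,
        size_pop=(80, 160),
        gen_num=(8, 16),
        size_tour=(8, 24),
        depth_init=(2, 5),
    ) -> "HyperRanges":
        """Desk-scale profile: same search structure, small GP budgets."""
        return cls(
            size_pop=size_pop,
            gen_num=gen_num,
            size_tour=size_tour,
            depth_init=depth_init,
        )

    @classmethod
    def from_json(cls, path) -> "HyperRanges":
        with open(path) as fh:
            data = json.load(fh)
        return cls(**{k: tuple(v) for k, v in data.items()})

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def _log_uniform(rng, lo: float, hi: float) -> float:
    if lo <= 0:
        raise ValueError("log-uniform range must be positive")
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


#: joint draws attempted for the operation probabilities.  The published
#: ranges leave only ~1.5e-4 probability mass in the required sum window, so
#: a generous vectorized budget keeps the per-config failure chance negligible.
_MAX_OP_DRAWS = 200_000


def sample_config(ranges: HyperRanges, rng: np.random.Generator) -> GPSCConfig:
    """Draw one engine configuration from the ranges.

    The four operation probabilities are drawn jointly (vectorized) until
    their sum lands in ``op_sum_range``; exhausting the draw budget raises
    ``SearchError``.  The tournament size is clipped to the population size.
    """
    size_pop = int(rng.integers(ranges.size_pop[0], ranges.size_pop[1] + 1))
    gen_num = int(rng.integers(ranges.gen_num[0], ranges.gen_num[1] + 1))
    size_tour = min(
        int(rng.integers(ranges.size_tour[0], ranges.size_tour[1] + 1)), size_pop
    )
    d1 = int(rng.integers(ranges.depth_init[0], ranges.depth_init[1] + 1))
    d2 = int(rng.integers(ranges.depth_init[0], ranges.depth_init[1] + 1))
    depth_init = (min(d1, d2), max(d1, d2))
    c1 = rng.uniform(*ranges.const_range)
    c2 = rng.uniform(*ranges.const_range)
    const_range = (min(c1, c2), max(c1, c2))

    lo_s, hi_s = ranges.op_sum_range
    draws = np.column_stack(
        [
            rng.uniform(*ranges.p_crossover, size=_MAX_OP_DRAWS),
            rng.uniform(*ranges.p_subtree, size=_MAX_OP_DRAWS),
            rng.uniform(*ranges.p_hoist, size=_MAX_OP_DRAWS),
            rng.uniform(*ranges.p_point, size=_MAX_OP_DRAWS),
        ]
    )
    sums = draws.sum(axis=1)
    ok = np.where((sums >= lo_s) & (sums <= hi_s))[0]
    if ok.size == 0:
        raise SearchError(
            f"no operation-probability draw summed into [{lo_s}, {hi_s}] "
            f"after {_MAX_OP_DRAWS} attempts"
        )
    p_cross, p_sub, p_hoist, p_point = draws[ok[0]]

    return GPSCConfig(
        size_pop=size_pop,
        gen_num=gen_num,
        size_tour=size_tour,
        depth_init=depth_init,
        p_crossover=float(p_cross),
        p_subtree=float(p_sub),
        p_hoist=float(p_hoist),
        p_point=float(p_point),
        crit_stop=_log_uniform(rng, *ranges.crit_stop),
        max_samples=float(rng.uniform(*ranges.max_samples)),
        const_range=const_range,
        parsimony=_log_uniform(rng, *ranges.parsimony),
    )


@dataclass
class RHVSResult:
    best_set: SESet
    best_config: GPSCConfig
    iterations: int
    gate_met: bool
    #: per-iteration (config, mean train metrics) audit trail
    history: list = field(default_factory=list)


def run_rhvs(
    task: BinaryTask,
    ranges: HyperRanges,
    gate: float = 0.99,
    max_iters: int = 50,
    rng: np.random.Generator | None = None,
) -> RHVSResult:
    """Sample configurations until the training-quality gate is met.

    Per iteration: sample a configuration, run 5-fold CV training on the task,
    and accept if every mean training metric (ACC, AUC, precision, recall, F1)
    exceeds ``gate``.  If the gate is never met, the iteration with the
    highest mean training accuracy is returned.
    """
    if max_iters < 1:
        raise ValueError("max_iters must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    best: tuple[float, SESet, GPSCConfig] | None = None
    history = []
    for it in range(1, max_iters + 1):
        cfg = sample_config(ranges, rng)
        se_set = five_fold_train(task.X, task.y, cfg, rng)
        se_set.class_label = task.class_label
        means = se_set.mean_train_metrics()
        history.append((cfg, means))
        if all(v > gate for v in means.values()):
            return RHVSResult(se_set, cfg, it, True, history)
        if best is None or means["acc"] > best[0]:
            best = (means["acc"], se_set, cfg)
    return RHVSResult(best[1], best[2], max_iters, False, history)
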