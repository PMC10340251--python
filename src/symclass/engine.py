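"""Evolutionary loop of the genetic-programming symbolic classifier (GPSC).

A population of expression trees is evolved to minimize the logistic loss of
``sigmoid(tree(X))`` against a binary target.  Selection is by tournament with
parsimony pressure (the raw loss of a candidate is penalized by a coefficient
times its node count, which counters bloat); variation uses crossover plus
subtree, hoist and point mutation; evolution stops at a generation limit or
when any member's raw loss drops below a preset threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit

from . import expressions as ex

__all__ = [
    "GPSCConfig",
    "EvolutionResult",
    "sigmoid",
    "log_loss",
    "fitness",
    "tournament_select",
    "crossover",
    "subtree_mutation",
    "hoist_mutation",
    "point_mutation",
    "breed",
    "evolve",
    "classify",
]

_LOGLOSS_EPS = 1e-15


@dataclass
class GPSCConfig:
    """One hyperparameter combination for a GPSC run.

    Field names follow the conventional symbols: population size (SizePop),
    generation limit (GenNum), tournament size (SizeTour), initial-depth range
    (DepthInit), the four genetic-operation probabilities, early-stop loss
    threshold (CritStop), per-generation subsample fraction (maxSamp),
    constant range (RangeConst) and parsimony coefficient (ParsCoef).
    """

    size_pop: int = 1000
    gen_num: int = 200
    size_tour: int = 100
    depth_init: tuple[int, int] = (3, 18)
    p_crossover: float = 0.01
    p_subtree: float = 0.95
    p_hoist: float = 0.01
    p_point: float = 0.03
    crit_stop: float = 1e-6
    max_samples: float = 1.0
    const_range: tuple[float, float] = (-10000.0, 10000.0)
    parsimony: float = 5e-5
    point_rate: float = 0.05  # per-node replacement probability in point mutation

    def validate(self) -> None:
        if self.size_pop < 2:
            raise ValueError("size_pop must be >= 2")
        if not (1 <= self.size_tour <= self.size_pop):
            raise ValueError("size_tour must be in [1, size_pop]")
        lo, hi = self.depth_init
        if lo > hi or lo < 1:
            raise ValueError(f"invalid depth_init {self.depth_init}")
        p_sum = self.p_crossover + self.p_subtree + self.p_hoist + self.p_point
        if p_sum > 1.0 + 1e-12:
            raise ValueError(f"operation probabilities sum to {p_sum} > 1")
        if not (0.0 < self.max_samples <= 1.0):
            raise ValueError("max_samples must be in (0, 1]")
        if self.parsimony < 0:
            raise ValueError("parsimony must be >= 0")
        if self.gen_num < 1:
            raise ValueError("gen_num must be >= 1")

    @property
    def p_reproduction(self) -> float:
        """Residual probability: verbatim copy of a tournament winner."""
        return max(
            0.0, 1.0 - (self.p_crossover + self.p_subtree + self.p_hoist + self.p_point)
        )


@dataclass
class EvolutionResult:
    best_tree: tuple
    best_fitness: float
    generations_run: int
    stop_reason: str  # "generation_limit" | "crit_stop"
    fitness_history: list[float] = field(default_factory=list)
    mean_length_history: list[float] = field(default_factory=list)


def sigmoid(x):
    """Logistic function 1 / (1 + exp(-x))."""
    return expit(np.asarray(x, dtype=float))


def log_loss(y, p) -> float:
    """Mean binary cross-entropy with probabilities clipped to [eps, 1-eps]."""
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: y {y.shape} vs p {p.shape}")
    p = np.clip(p, _LOGLOSS_EPS, 1.0 - _LOGLOSS_EPS)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def _raw_loss(tree, X, y) -> float:
    return log_loss(y, sigmoid(ex.evaluate(tree, X)))


def fitness(tree, X, y, max_samples: float = 1.0, rng=None) -> float:
    """Raw loss of a tree on a without-replacement subsample of the rows."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    m = math.ceil(max_samples * n)
    if m < 1:
        raise ValueError("subsample is empty")
    if m >= n:
        return _raw_loss(tree, X, y)
    if rng is None:
        raise ValueError("rng required when max_samples < 1")
    rows = rng.choice(n, size=m, replace=False)
    return _raw_loss(tree, X[rows], y[rows])


def tournament_select(
    population: Sequence,
    raw_fitnesses: Sequence[float],
    cfg: GPSCConfig,
    rng: np.random.Generator,
    lengths: Sequence[int] | None = None,
) -> tuple:
    """Pick ``size_tour`` members without replacement; return the one with the
    lowest parsimony-penalized fitness (raw + ParsCoef * length).

    Ties go to the shorter tree, then to the earlier population index.
    """
    n = len(population)
    if cfg.size_tour > n:
        raise ValueError(f"size_tour {cfg.size_tour} exceeds population {n}")
    entrants = rng.choice(n, size=cfg.size_tour, replace=False)
    if lengths is None:
        lengths = [ex.length(population[i]) for i in entrants]
        entrant_lengths = lengths
    else:
        entrant_lengths = [lengths[i] for i in entrants]
    best = None
    for idx, ln in zip(entrants, entrant_lengths):
        key = (raw_fitnesses[idx] + cfg.parsimony * ln, ln, idx)
        if best is None or key < best:
            best = key
    return population[best[2]]


def crossover(winner, donor, rng: np.random.Generator):
    """Replace a uniformly chosen subtree of ``winner`` with a uniformly chosen
    subtree of ``donor``; parents are unmodified."""
    i = int(rng.integers(ex.length(winner)))
    j = int(rng.integers(ex.length(donor)))
    return ex.replace_subtree(winner, i, ex.get_subtree(donor, j))


def subtree_mutation(winner, cfg: GPSCConfig, rng: np.random.Generator, n_vars: int):
    """Replace a random subtree with a freshly grown tree (grow method, depth
    drawn from the configured initial-depth range)."""
    d = int(rng.integers(cfg.depth_init[0], cfg.depth_init[1] + 1))
    fresh = ex.build_grow(d, n_vars, cfg.const_range, rng)
    i = int(rng.integers(ex.length(winner)))
    return ex.replace_subtree(winner, i, fresh)


def hoist_mutation(winner, rng: np.random.Generator):
    """Pick a random subtree, then a random subtree of it, and hoist the inner
    one into the outer one's place — child length never exceeds the parent's."""
    i = int(rng.integers(ex.length(winner)))
    outer = ex.get_subtree(winner, i)
    j = int(rng.integers(ex.length(outer)))
    return ex.replace_subtree(winner, i, ex.get_subtree(outer, j))


def point_mutation(winner, cfg: GPSCConfig, rng: np.random.Generator, n_vars: int):
    """Independently replace nodes (probability ``point_rate``) with same-kind
    tokens: function -> same-arity function, variable -> variable, constant ->
    constant.  Length and depth are preserved."""

    def rec(node):
        kind = node[0]
        mutate = rng.random() < cfg.point_rate
        if kind == "x":
            if mutate and n_vars > 0:
                return ("x", int(rng.integers(n_vars)))
            return node
        if kind == "c":
            if mutate:
                return ("c", float(rng.uniform(*cfg.const_range)))
            return node
        children = tuple(rec(ch) for ch in node[1:])
        name = kind
        if mutate:
            group = ex.ARITY_GROUPS[ex.FUNCTION_SET[kind].arity]
            name = group[rng.integers(len(group))]
        return (name, *children)

    return rec(winner)


def classify(tree, X) -> np.ndarray:
    """Binary labels: 1 iff sigmoid(raw) >= 0.5, i.e. raw output >= 0."""
    return (ex.evaluate(tree, X) >= 0.0).astype(int)


def breed(
    population: Sequence,
    raw_fitnesses,
    cfg: GPSCConfig,
    rng: np.random.Generator,
    n_vars: int,
    lengths: Sequence[int] | None = None,
) -> list:
    """Fill the next generation: per slot, draw one genetic operation with the
    configured probabilities (residual probability = verbatim copy of a
    tournament winner) applied to tournament winner(s)."""
    if lengths is None:
        lengths = [ex.length(t) for t in population]
    cuts = np.cumsum([cfg.p_crossover, cfg.p_subtree, cfg.p_hoist, cfg.p_point])
    new_pop = []
    for _ in range(len(population)):
        r = rng.random()
        winner = tournament_select(population, raw_fitnesses, cfg, rng, lengths)
        if r < cuts[0]:
            donor = tournament_select(population, raw_fitnesses, cfg, rng, lengths)
            child = crossover(winner, donor, rng)
        elif r < cuts[1]:
            child = subtree_mutation(winner, cfg, rng, n_vars)
        elif r < cuts[2]:
            child = hoist_mutation(winner, rng)
        elif r < cuts[3]:
            child = point_mutation(winner, cfg, rng, n_vars)
        else:
            child = winner
        new_pop.append(child)
    return new_pop


def evolve(
    cfg: GPSCConfig,
    X,
    y,
    rng: np.random.Generator,
    log_file=None,
) -> EvolutionResult:
    """Run the GPSC loop and return the best-ever tree.

    Per generation the whole population is scored on one shared row subsample
    (fraction ``max_samples``, redrawn each generation); the generation's best
    member is re-scored on the full training data to track the best-ever tree,
    and evolution stops once the minimum raw loss reaches ``crit_stop`` or the
    generation limit is hit.  ``log_file`` (optional, text mode) receives one
    CSV line per generation: generation, min raw loss, mean raw loss, mean length.
    """
    cfg.validate()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    labels = np.unique(y)
    if not np.all(np.isin(labels, (0.0, 1.0))):
        raise ValueError(f"target must be binary 0/1, found values {labels}")
    n, n_vars = X.shape
    m = math.ceil(cfg.max_samples * n)

    population = ex.ramped_half_and_half(
        cfg.size_pop, cfg.depth_init, n_vars, cfg.const_range, rng
    )
    best_tree, best_fit = None, math.inf
    history: list[float] = []
    mean_lengths: list[float] = []
    stop_reason = "generation_limit"
    generations_run = 0

    if log_file is not None:
        log_file.write("generation,min_raw_fitness,mean_raw_fitness,mean_length\n")

    for gen in range(cfg.gen_num):
        if m < n:
            rows = rng.choice(n, size=m, replace=False)
            Xg, yg = X[rows], y[rows]
        else:
            Xg, yg = X, y
        raw = np.array([_raw_loss(t, Xg, yg) for t in population])
        lengths = [ex.length(t) for t in population]
        generations_run = gen + 1
        history.append(float(raw.min()))
        mean_lengths.append(float(np.mean(lengths)))
        if log_file is not None:
            log_file.write(
                f"{gen},{raw.min():.6g},{raw.mean():.6g},{np.mean(lengths):.3f}\n"
            )

        # best-ever is tracked on the full training data for stable selection
        order = np.lexsort((np.arange(len(population)), lengths, raw))
        gen_best = population[order[0]]
        full_fit = raw[order[0]] if m >= n else _raw_loss(gen_best, X, y)
        if full_fit < best_fit:
            best_tree, best_fit = gen_best, float(full_fit)

        if raw.min() <= cfg.crit_stop:
            stop_reason = "crit_stop"
            break
        if gen == cfg.gen_num - 1:
            break

        population = breed(population, raw, cfg, rng, n_vars, lengths)

    return EvolutionResult(
        best_tree=best_tree,
        best_fitness=best_fit,
        generations_run=generations_run,
        stop_reason=stop_reason,
        fitness_history=history,
        mean_length_history=mean_lengths,
    )
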