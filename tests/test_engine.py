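"""GPSC engine: fitness, selection, genetic operators, evolution loop."""

import itertools
import math

import numpy as np
import pytest

from symclass import engine as en
from symclass import expressions as ex
from symclass.synthetic import generate_separable_binary


def small_cfg(**kw):
    base = dict(
        size_pop=30,
        gen_num=5,
        size_tour=5,
        depth_init=(2, 4),
        p_crossover=0.1,
        p_subtree=0.7,
        p_hoist=0.1,
        p_point=0.05,
        crit_stop=1e-8,
        max_samples=1.0,
        const_range=(-5.0, 5.0),
        parsimony=1e-4,
    )
    base.update(kw)
    return en.GPSCConfig(**base)


class TestSigmoidLogLoss:
    def test_sigmoid_values(self):
        assert en.sigmoid(0.0) == 0.5
        assert en.sigmoid(40.0) == pytest.approx(1.0, abs=1e-12)
        x = np.linspace(-20, 20, 101)
        np.testing.assert_allclose(en.sigmoid(x) + en.sigmoid(-x), 1.0, atol=1e-12)
        assert np.all(np.diff(en.sigmoid(x)) > 0)

    def test_log_loss_closed_forms(self):
        assert en.log_loss([1], [0.5]) == pytest.approx(math.log(2), abs=1e-12)
        y = np.array([0.0, 1.0, 1.0, 0.0])
        assert en.log_loss(y, y) <= 1e-14

    def test_log_loss_matches_per_sample_sum(self, rng):
        """Brute-force per-sample summation oracle."""
        for _ in range(20):
            n = int(rng.integers(1, 20))
            y = rng.integers(0, 2, size=n).astype(float)
            p = rng.uniform(1e-6, 1 - 1e-6, size=n)
            oracle = -sum(
                yi * math.log(pi) + (1 - yi) * math.log(1 - pi)
                for yi, pi in zip(y, p)
            ) / n
            assert en.log_loss(y, p) == pytest.approx(oracle, abs=1e-12)

    def test_log_loss_length_mismatch(self):
        with pytest.raises(ValueError):
            en.log_loss([0, 1], [0.5])


class TestFitness:
    def test_full_sample_deterministic(self, rng):
        X = rng.normal(size=(30, 3))
        y = (X[:, 0] > 0).astype(float)
        t = ("x", 0)
        assert en.fitness(t, X, y, 1.0) == en.fitness(t, X, y, 1.0)

    def test_constant_zero_tree_gives_ln2(self, rng):
        X = rng.normal(size=(25, 2))
        y = rng.integers(0, 2, size=25).astype(float)
        assert en.fitness(("c", 0.0), X, y, 1.0) == pytest.approx(math.log(2), abs=1e-12)

    def test_saturated_separator_near_zero(self):
        X = np.array([[50.0], [-50.0], [45.0], [-60.0]])
        y = np.array([1.0, 0.0, 1.0, 0.0])
        t = ("x", 0)  # raw |output| >= 40 on every row
        assert en.fitness(t, X, y, 1.0) <= 1e-14

    def test_subsample_needs_rng(self, rng):
        X = rng.normal(size=(10, 2))
        y = (X[:, 0] > 0).astype(float)
        with pytest.raises(ValueError):
            en.fitness(("x", 0), X, y, 0.5, rng=None)


class TestTournament:
    def test_size_one_returns_sampled(self, rng):
        pop = [("c", float(i)) for i in range(10)]
        raw = list(np.linspace(1, 2, 10))
        cfg = small_cfg(size_pop=10, size_tour=1)
        got = en.tournament_select(pop, raw, cfg, np.random.default_rng(0))
        assert got in pop

    def test_parsimony_prefers_shorter_on_ties(self):
        short = ("x", 0)
        t = ("x", 0)  # long chain of nested adds, ~500 nodes
        for _ in range(249):
            t = ("add", t, ("x", 0))
        pop = [short, t]
        raw = [0.3, 0.3]
        cfg = small_cfg(size_pop=2, size_tour=2, parsimony=1e-4)
        got = en.tournament_select(pop, raw, cfg, np.random.default_rng(1))
        assert got == short

    def test_zero_parsimony_matches_argmin_oracle(self):
        """Exhaustive check against argmin-over-entrants on a 10-member pool."""
        gen = np.random.default_rng(5)
        pop = [("c", float(i)) for i in range(10)]
        raw = list(gen.uniform(0, 1, size=10))
        cfg = small_cfg(size_pop=10, size_tour=4, parsimony=0.0)
        for trial in range(50):
            seed = 100 + trial
            got = en.tournament_select(pop, raw, cfg, np.random.default_rng(seed))
            entrants = np.random.default_rng(seed).choice(10, size=4, replace=False)
            oracle = pop[min(entrants, key=lambda i: (raw[i], 1, i))]
            assert got == oracle

    def test_oversized_tournament_rejected(self):
        cfg = small_cfg(size_pop=30, size_tour=31)
        with pytest.raises(ValueError):
            en.tournament_select([("x", 0)] * 3, [0.1] * 3, cfg, np.random.default_rng(0))


class TestOperators:
    def test_crossover_terminal_parents(self, rng):
        child = en.crossover(("x", 0), ("c", 3.0), rng)
        assert child == ("c", 3.0)

    def test_crossover_length_conservation(self, random_trees):
        gen = np.random.default_rng(8)
        trees = random_trees(40, seed=10)
        for a, b in zip(trees[::2], trees[1::2]):
            seed = int(gen.integers(2**31))
            child = en.crossover(a, b, np.random.default_rng(seed))
            r2 = np.random.default_rng(seed)
            i = int(r2.integers(ex.length(a)))
            j = int(r2.integers(ex.length(b)))
            removed = ex.get_subtree(a, i)
            inserted = ex.get_subtree(b, j)
            assert ex.length(child) == ex.length(a) - ex.length(removed) + ex.length(inserted)

    def test_crossover_reproducible_and_nonmutating(self, random_trees):
        a, b = random_trees(2, seed=11)
        a0, b0 = a, b
        c1 = en.crossover(a, b, np.random.default_rng(4))
        c2 = en.crossover(a, b, np.random.default_rng(4))
        assert c1 == c2 and a == a0 and b == b0

    def test_hoist_on_terminal_is_identity(self, rng):
        assert en.hoist_mutation(("x", 1), rng) == ("x", 1)

    def test_hoist_never_deepens(self, random_trees):
        gen = np.random.default_rng(13)
        for t in random_trees(500, seed=12):
            child = en.hoist_mutation(t, gen)
            assert ex.depth(child) <= ex.depth(t)
            assert ex.length(child) <= ex.length(t)

    def test_point_mutation_preserves_shape(self, random_trees):
        cfg = small_cfg(point_rate=0.3)
        gen = np.random.default_rng(14)
        for t in random_trees(500, seed=13):
            child = en.point_mutation(t, cfg, gen, n_vars=5)
            assert ex.length(child) == ex.length(t)
            assert ex.depth(child) == ex.depth(t)
            ex.validate_tree(child, 5)

    def test_subtree_mutation_valid(self, random_trees):
        cfg = small_cfg()
        gen = np.random.default_rng(15)
        for t in random_trees(100, seed=14):
            child = en.subtree_mutation(t, cfg, gen, n_vars=5)
            ex.validate_tree(child, 5)


class TestBreeding:
    def test_pure_reproduction_introduces_no_new_structures(self, random_trees):
        """With all operator probabilities 0, every child is a verbatim copy
        of some current member."""
        pop = random_trees(20, seed=16)
        raw = list(np.linspace(0.1, 0.9, 20))
        cfg = small_cfg(
            size_pop=20, p_crossover=0, p_subtree=0, p_hoist=0, p_point=0
        )
        child_pop = en.breed(pop, raw, cfg, np.random.default_rng(2), n_vars=5)
        assert all(child in pop for child in child_pop)


class TestEvolve:
    def test_rejects_nonbinary_target(self, rng):
        X = rng.normal(size=(20, 2))
        with pytest.raises(ValueError):
            en.evolve(small_cfg(), X, np.arange(20), rng)

    def test_generous_crit_stop_halts_first_generation(self, rng):
        X = rng.normal(size=(30, 2))
        y = (X[:, 0] > 0).astype(int)
        res = en.evolve(small_cfg(crit_stop=100.0), X, y, rng)
        assert res.stop_reason == "crit_stop"
        assert res.generations_run == 1

    def test_gen_num_one_runs_single_generation(self, rng):
        X = rng.normal(size=(30, 2))
        y = (X[:, 0] > 0).astype(int)
        res = en.evolve(small_cfg(gen_num=1), X, y, rng)
        assert res.generations_run == 1
        assert len(res.fitness_history) == 1

    def test_bit_reproducible(self):
        X, y = generate_separable_binary(60, "threshold", seed=20)
        r1 = en.evolve(small_cfg(), X, y, np.random.default_rng(77))
        r2 = en.evolve(small_cfg(), X, y, np.random.default_rng(77))
        assert r1.best_tree == r2.best_tree
        assert r1.fitness_history == r2.fitness_history

    def test_best_fitness_monotone_with_full_sampling(self):
        X, y = generate_separable_binary(80, "linear", seed=21)
        res = en.evolve(small_cfg(gen_num=8, max_samples=1.0), X, y,
                        np.random.default_rng(3))
        running = np.minimum.accumulate(res.fitness_history)
        # best-ever raw fitness never increases generation over generation
        assert np.all(np.diff(running) <= 1e-12)
        assert res.best_fitness <= res.fitness_history[0] + 1e-12

    def test_evolution_log_written(self, tmp_path, rng):
        X = rng.normal(size=(30, 2))
        y = (X[:, 0] > 0).astype(int)
        log = tmp_path / "evo.csv"
        with open(log, "w") as fh:
            en.evolve(small_cfg(gen_num=3, crit_stop=0.0), X, y,
                      np.random.default_rng(0), log_file=fh)
        lines = log.read_text().strip().splitlines()
        assert lines[0].startswith("generation,")
        assert len(lines) >= 2


from conftest import BLOAT_BASE, bloat_prone_task  # noqa: E402


class TestBloatControl:
    def test_parsimony_reduces_mean_length(self):
        """Parsimony pressure at the strong end of the published coefficient
        range yields smaller populations than no pressure (mean over seeds)."""
        X, y = bloat_prone_task()
        final = {0.0: [], 1e-4: []}
        for pars in final:
            for seed in range(1, 7):
                res = en.evolve(
                    en.GPSCConfig(**BLOAT_BASE, parsimony=pars), X, y,
                    np.random.default_rng(seed),
                )
                final[pars].append(res.mean_length_history[-1])
        assert np.mean(final[1e-4]) < np.mean(final[0.0])


class TestClassify:
    def test_zero_raw_is_positive(self):
        X = np.zeros((3, 1))
        assert list(en.classify(("x", 0), X)) == [1, 1, 1]

    def test_min_of_positives_is_positive(self):
        t = ex.parse_text("min(X0, X13, X3, X4)", 14)
        X = np.full((2, 14), 2.0)
        assert list(en.classify(t, X)) == [1, 1]

    def test_matches_sigmoid_threshold(self, rng):
        t = ("sub", ("x", 0), ("c", 0.3))
        X = rng.normal(size=(50, 1))
        raw = ex.evaluate(t, X)
        np.testing.assert_array_equal(
            en.classify(t, X), (en.sigmoid(raw) >= 0.5).astype(int)
        )
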