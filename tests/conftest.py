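import numpy as np
import pytest

from symclass import expressions as ex


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_tree(rng, n_vars=5, max_depth=5, const_range=(-10.0, 10.0)):
    """A random grow-method tree, used across property tests."""
    depth = int(rng.integers(1, max_depth + 1))
    return ex.build_grow(depth, n_vars, const_range, rng)


def bloat_prone_task(seed=0, n=150):
    """A boundary the function set can only fit with sizeable trees, so the
    population keeps growing when selection ignores size."""
    gen = np.random.default_rng(seed)
    X = gen.normal(size=(n, 6))
    y = ((X[:, 0] * X[:, 1] + np.sin(3 * X[:, 2])) > 0).astype(int)
    return X, y


#: evolution settings for the bloat-control comparisons
BLOAT_BASE = dict(
    size_pop=100, gen_num=20, size_tour=10, depth_init=(3, 7),
    p_crossover=0.35, p_subtree=0.55, p_hoist=0.02, p_point=0.05,
    crit_stop=0.0, const_range=(-5, 5),
)


@pytest.fixture
def random_trees():
    """Factory producing n random trees from a fixed seed."""

    def make(n, seed=0, n_vars=5, max_depth=5):
        gen = np.random.default_rng(seed)
        return [random_tree(gen, n_vars=n_vars, max_depth=max_depth) for _ in range(n)]

    return make
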