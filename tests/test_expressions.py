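"""Expression trees: protected functions, builders, evaluation, text format."""

import math

import numpy as np
import pytest

from symclass import expressions as ex


class TestApplyFunction:
    @pytest.mark.parametrize(
        "name,args,expected",
        [
            ("div", (6, 3), 2.0),
            ("div", (1, 0), 1.0),  # protected-division fallback
            ("div", (5, 1e-4), 1.0),  # |denominator| under the guard
            ("min", (3, -2), -2.0),
            ("max", (3, -2), 3.0),
            ("sqrt", (-4,), 2.0),  # magnitude convention
            ("cbrt", (-8,), -2.0),  # sign-preserving cube root
            ("log", (0,), 0.0),  # guarded logarithm
            ("abs", (-3.5,), 3.5),
        ],
    )
    def test_protected_values(self, name, args, expected):
        assert ex.apply_function(name, *args) == pytest.approx(expected)

    def test_unknown_name_rejected(self):
        with pytest.raises(KeyError):
            ex.apply_function("foo", 1.0)

    def test_arity_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ex.apply_function("add", 1.0)

    @pytest.mark.parametrize("name", sorted(ex.FUNCTION_SET))
    def test_agrees_with_plain_math_in_domain(self, name):
        """On a dense in-domain grid, protection must be invisible."""
        plain = {
            "add": np.add, "sub": np.subtract, "mul": np.multiply,
            "div": np.divide, "log": np.log, "log2": np.log2,
            "log10": np.log10, "sqrt": np.sqrt, "cbrt": np.cbrt,
            "abs": np.abs, "sin": np.sin, "cos": np.cos, "tan": np.tan,
            "min": np.minimum, "max": np.maximum,
        }[name]
        spec = ex.FUNCTION_SET[name]
        grid = np.linspace(0.01, 5.0, 113)  # positive, away from guards
        if spec.arity == 1:
            got = ex.apply_function(name, grid)
            np.testing.assert_allclose(got, plain(grid), atol=1e-12)
        else:
            a, b = np.meshgrid(grid[::4], grid[::4])
            got = ex.apply_function(name, a.ravel(), b.ravel())
            np.testing.assert_allclose(got, plain(a.ravel(), b.ravel()), atol=1e-12)

    def test_protection_never_produces_nonfinite(self, rng):
        hostile = np.array([0.0, -0.0, 1e-9, -1e-9, 1e12, -1e12, math.pi / 2])
        for name, spec in ex.FUNCTION_SET.items():
            args = [hostile] * spec.arity
            out = ex.apply_function(name, *args)
            assert np.all(np.isfinite(out)), name


class TestBuilders:
    def test_full_depth_one_is_terminal(self, rng):
        t = ex.build_full(1, 3, (-1, 1), rng)
        assert ex.length(t) == 1 and ex.depth(t) == 1

    def test_full_binary_only_is_perfect_tree(self, rng):
        binary = [n for n, s in ex.FUNCTION_SET.items() if s.arity == 2]
        t = ex.build_full(3, 3, (-1, 1), rng, functions=binary)
        assert ex.length(t) == 7  # 2^3 - 1
        assert ex.depth(t) == 3

    def test_full_all_leaves_at_requested_depth(self, rng):
        for _ in range(20):
            d = int(rng.integers(1, 6))
            t = ex.build_full(d, 4, (-1, 1), rng)
            assert ex.depth(t) == d
            # every leaf at exactly depth d: no terminal shallower
            def leaf_depths(node, level=1):
                if node[0] in ("x", "c"):
                    yield level
                else:
                    for ch in node[1:]:
                        yield from leaf_depths(ch, level + 1)
            assert set(leaf_depths(t)) == {d}

    def test_depth_lt_one_rejected(self, rng):
        with pytest.raises(ValueError):
            ex.build_full(0, 3, (-1, 1), rng)
        with pytest.raises(ValueError):
            ex.build_grow(0, 3, (-1, 1), rng)

    def test_grow_respects_limit_and_varies(self):
        gen = np.random.default_rng(7)
        depths = {ex.depth(ex.build_grow(6, 4, (-1, 1), gen)) for _ in range(1000)}
        assert max(depths) <= 6
        assert len(depths) >= 2  # shape diversity

    def test_builders_deterministic(self):
        a = ex.build_full(4, 5, (-2, 2), np.random.default_rng(3))
        b = ex.build_full(4, 5, (-2, 2), np.random.default_rng(3))
        assert a == b
        a = ex.build_grow(5, 5, (-2, 2), np.random.default_rng(3))
        b = ex.build_grow(5, 5, (-2, 2), np.random.default_rng(3))
        assert a == b

    def test_ramped_cohorts(self, rng):
        pop = ex.ramped_half_and_half(2, (3, 3), 3, (-1, 1), rng)
        assert len(pop) == 2
        full, grow = pop
        assert ex.depth(full) == 3  # full member at exact depth
        assert ex.depth(grow) <= 3

    def test_ramped_depth_range(self):
        gen = np.random.default_rng(11)
        pop = ex.ramped_half_and_half(1000, (3, 18), 10, (-1, 1), gen)
        assert len(pop) == 1000
        assert all(1 <= ex.depth(t) <= 18 for t in pop)
        assert max(ex.depth(t) for t in pop) == 18  # full cohorts reach the top

    def test_ramped_reproducible(self):
        a = ex.ramped_half_and_half(50, (2, 6), 4, (-1, 1), np.random.default_rng(9))
        b = ex.ramped_half_and_half(50, (2, 6), 4, (-1, 1), np.random.default_rng(9))
        assert a == b

    def test_ramped_bad_args(self, rng):
        with pytest.raises(ValueError):
            ex.ramped_half_and_half(1, (2, 4), 3, (-1, 1), rng)
        with pytest.raises(ValueError):
            ex.ramped_half_and_half(10, (4, 2), 3, (-1, 1), rng)


class TestEvaluate:
    def test_min_chain(self):
        t = ex.parse_text("min(X0, X13, X3, X4)", 14)
        row = np.zeros((1, 14))
        row[0, [0, 13, 3, 4]] = [1, 2, 3, 4]
        assert ex.evaluate(t, row)[0] == 1.0

    def test_constant_tree(self):
        t = ("c", 2.5)
        out = ex.evaluate(t, np.random.default_rng(0).normal(size=(8, 3)))
        np.testing.assert_array_equal(out, np.full(8, 2.5))

    def test_nested_min_max_hand_value(self):
        t = ex.parse_text("min(X0, X13, X4, sub(X3, max(X1, X44)))", 45)
        row = np.zeros((1, 45))
        row[0, [0, 13, 4, 3, 1, 44]] = [0, 0, 0, 5, 1, 2]
        assert ex.evaluate(t, row)[0] == 0.0  # min(0,0,0, 5-2)

    def test_variable_out_of_range(self):
        with pytest.raises(ValueError):
            ex.evaluate(("x", 3), np.zeros((2, 3)))

    def test_never_nonfinite_on_random_trees(self, random_trees):
        """Protection + clipping keep every output finite."""
        gen = np.random.default_rng(42)
        trees = random_trees(2000, seed=1, n_vars=4, max_depth=6)
        for i, t in enumerate(trees):
            X = gen.normal(scale=10.0 ** gen.integers(-3, 4), size=(5, 4))
            out = ex.evaluate(t, X)
            assert np.all(np.isfinite(out)), ex.to_text(t)


class TestLengthDepth:
    def test_terminal(self):
        assert ex.length(("x", 0)) == 1
        assert ex.depth(("c", 1.0)) == 1

    def test_min_chain_counts(self):
        t = ex.parse_text("min(X0, X13, X3, X4)", 14)
        assert ex.length(t) == 7  # 3 binary mins + 4 leaves
        t10 = ex.parse_text("min(X0, X13, X4, sub(X3, max(X1, X44)))", 45)
        assert ex.length(t10) == 11

    def test_depth_length_bounds(self, random_trees):
        for t in random_trees(300, seed=2):
            d, l = ex.depth(t), ex.length(t)
            assert d <= l <= 2**d - 1


class TestTextRoundTrip:
    def test_round_trip_structure_and_outputs(self, random_trees):
        gen = np.random.default_rng(0)
        X = gen.normal(size=(10, 5))
        for t in random_trees(100, seed=3):
            back = ex.parse_text(ex.to_text(t), 5)
            assert back == t
            np.testing.assert_array_equal(ex.evaluate(back, X), ex.evaluate(t, X))

    def test_unknown_function_is_parse_error(self):
        with pytest.raises(ex.ParseError):
            ex.parse_text("foo(X0)", 3)

    def test_error_carries_position(self):
        with pytest.raises(ex.ParseError) as err:
            ex.parse_text("add(X0, $)", 3)
        assert err.value.position == 8

    def test_variable_index_checked(self):
        with pytest.raises(ex.ParseError):
            ex.parse_text("X7", 3)

    def test_nary_sugar_binary_only_elsewhere(self):
        with pytest.raises(ex.ParseError):
            ex.parse_text("add(X0, X1, X2)", 3)

    def test_expression_file_round_trip(self, tmp_path, random_trees):
        trees = random_trees(10, seed=4)
        path = tmp_path / "se.txt"
        ex.write_expression_file(path, trees, header="fixture")
        assert ex.read_expression_file(path, 5) == trees


class TestSubtreeOps:
    def test_get_replace_round_trip(self, random_trees):
        for t in random_trees(50, seed=5):
            n = ex.length(t)
            for i in range(n):
                sub = ex.get_subtree(t, i)
                assert ex.replace_subtree(t, i, sub) == t

    def test_replace_changes_length_consistently(self, rng, random_trees):
        (t,) = random_trees(1, seed=6)
        new = ("c", 7.0)
        i = int(rng.integers(ex.length(t)))
        removed = ex.get_subtree(t, i)
        out = ex.replace_subtree(t, i, new)
        assert ex.length(out) == ex.length(t) - ex.length(removed) + 1
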