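"""Expression trees for symbolic classification.

A candidate classifier is a closed-form mathematical expression — a tree whose
internal nodes are protected elementary functions and whose leaves are input
variables ``Xi`` or real constants.  "Protected" means every function is total
on the reals: division guards against near-zero denominators, logarithms and
square roots act on magnitudes, and every node's output is clipped to a fixed
magnitude, so evaluating any tree on finite data always yields finite numbers.

Trees are immutable nested tuples:

* ``("x", i)`` — input variable ``Xi`` (0-based column index),
* ``("c", v)`` — real constant,
* ``(name, child, ...)`` — a call of the protected function ``name``.

The module also provides the three classical tree initializers (full, grow,
ramped half-and-half) and a plain-text serialization used to persist evolved
expressions and to load published ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "FunctionSpec",
    "FUNCTION_SET",
    "ARITY_GROUPS",
    "CLIP_LIMIT",
    "DIV_GUARD",
    "LOG_GUARD",
    "apply_function",
    "evaluate",
    "length",
    "depth",
    "iter_subtrees",
    "get_subtree",
    "replace_subtree",
    "random_terminal",
    "build_full",
    "build_grow",
    "ramped_half_and_half",
    "to_text",
    "parse_text",
    "ParseError",
    "read_expression_file",
    "write_expression_file",
]

#: every node output is clipped to this magnitude so products/tangents cannot
#: overflow into inf during evolution.
CLIP_LIMIT = 1e12
#: |denominator| below this returns the protected-division fallback 1.
DIV_GUARD = 1e-3
#: |argument| below this returns 0 from the protected logarithms.
LOG_GUARD = 1e-3


def _clip(v: np.ndarray) -> np.ndarray:
    return np.clip(v, -CLIP_LIMIT, CLIP_LIMIT)


def _p_div(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    safe = np.abs(b) > DIV_GUARD
    return np.where(safe, np.divide(a, np.where(safe, b, 1.0)), 1.0)


def _p_log(base_log: Callable[[np.ndarray], np.ndarray]) -> Callable:
    def f(x):
        x = np.asarray(x, dtype=float)
        mag = np.abs(x)
        safe = mag > LOG_GUARD
        return np.where(safe, base_log(np.where(safe, mag, 1.0)), 0.0)

    return f


def _p_sqrt(x):
    return np.sqrt(np.abs(np.asarray(x, dtype=float)))


def _p_cbrt(x):
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.abs(x) ** (1.0 / 3.0)


@dataclass(frozen=True)
class FunctionSpec:
    """One member of the protected function set."""

    name: str
    arity: int
    fn: Callable[..., np.ndarray]


_SPECS = [
    FunctionSpec("add", 2, lambda a, b: np.asarray(a, float) + b),
    FunctionSpec("sub", 2, lambda a, b: np.asarray(a, float) - b),
    FunctionSpec("mul", 2, lambda a, b: np.asarray(a, float) * b),
    FunctionSpec("div", 2, _p_div),
    FunctionSpec("log", 1, _p_log(np.log)),
    FunctionSpec("log2", 1, _p_log(np.log2)),
    FunctionSpec("log10", 1, _p_log(np.log10)),
    FunctionSpec("sqrt", 1, _p_sqrt),
    FunctionSpec("cbrt", 1, _p_cbrt),
    FunctionSpec("abs", 1, lambda x: np.abs(np.asarray(x, float))),
    FunctionSpec("sin", 1, lambda x: np.sin(np.asarray(x, float))),
    FunctionSpec("cos", 1, lambda x: np.cos(np.asarray(x, float))),
    FunctionSpec("tan", 1, lambda x: np.tan(np.asarray(x, float))),
    FunctionSpec("min", 2, lambda a, b: np.minimum(np.asarray(a, float), b)),
    FunctionSpec("max", 2, lambda a, b: np.maximum(np.asarray(a, float), b)),
]

FUNCTION_SET: dict[str, FunctionSpec] = {s.name: s for s in _SPECS}
_FUNCTION_NAMES = tuple(FUNCTION_SET)
#: names grouped by arity, for arity-preserving point mutation.
ARITY_GROUPS: dict[int, tuple[str, ...]] = {
    a: tuple(s.name for s in _SPECS if s.arity == a) for a in {s.arity for s in _SPECS}
}


class ParseError(ValueError):
    """Malformed expression text; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


def apply_function(name: str, *args):
    """Apply the protected function ``name`` to scalar or array arguments.

    Raises ``KeyError`` for an unknown name and ``ValueError`` on an arity
    mismatch.  Output is clipped to ``CLIP_LIMIT`` like every tree node.
    """
    try:
        spec = FUNCTION_SET[name]
    except KeyError:
        raise KeyError(f"unknown function {name!r}; known: {sorted(FUNCTION_SET)}")
    if len(args) != spec.arity:
        raise ValueError(f"{name} expects {spec.arity} argument(s), got {len(args)}")
    out = _clip(np.asarray(spec.fn(*args), dtype=float))
    if out.ndim == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# structure


def length(tree) -> int:
    """Total node count, leaves included."""
    if tree[0] in ("x", "c"):
        return 1
    return 1 + sum(length(ch) for ch in tree[1:])


def depth(tree) -> int:
    """Maximum root-to-leaf edge count plus one (a lone terminal has depth 1)."""
    if tree[0] in ("x", "c"):
        return 1
    return 1 + max(depth(ch) for ch in tree[1:])


def iter_subtrees(tree):
    """Yield every subtree in preorder (the tree itself first)."""
    stack = [tree]
    while stack:
        node = stack.pop()
        yield node
        if node[0] not in ("x", "c"):
            stack.extend(reversed(node[1:]))


def get_subtree(tree, index: int):
    """Return the subtree at preorder position ``index`` (root is 0)."""
    for i, sub in enumerate(iter_subtrees(tree)):
        if i == index:
            return sub
    raise IndexError(f"subtree index {index} out of range (length {length(tree)})")


def replace_subtree(tree, index: int, new):
    """Return a copy of ``tree`` with the preorder-``index`` subtree replaced."""

    def rec(node, i):
        if i == index:
            return new, i + length(node) - 1
        if node[0] in ("x", "c"):
            return node, i
        children = []
        j = i
        for ch in node[1:]:
            ch2, j = rec(ch, j + 1)
            children.append(ch2)
        return (node[0], *children), j

    out, last = rec(tree, 0)
    if last < index:
        raise IndexError(f"subtree index {index} out of range (length {length(tree)})")
    return out


def _validate_indices(tree, n_features: int):
    for sub in iter_subtrees(tree):
        if sub[0] == "x" and not (0 <= sub[1] < n_features):
            raise ValueError(
                f"variable X{sub[1]} out of range for {n_features} feature(s)"
            )


def evaluate(tree, X) -> np.ndarray:
    """Evaluate ``tree`` row-wise on ``X`` (samples x features).

    Every node output is protected and clipped, so the result is finite for
    finite input.  Raises ``ValueError`` if the tree references a variable
    index outside the feature count.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D samples x features array")
    _validate_indices(tree, X.shape[1])

    def rec(node):
        kind = node[0]
        if kind == "x":
            return X[:, node[1]]
        if kind == "c":
            return np.full(X.shape[0], float(node[1]))
        spec = FUNCTION_SET[kind]
        return _clip(spec.fn(*[rec(ch) for ch in node[1:]]))

    return np.asarray(rec(tree), dtype=float)


# ---------------------------------------------------------------------------
# random construction


def random_terminal(n_vars: int, const_range, rng: np.random.Generator):
    """Draw a leaf: a variable with odds ``n_vars : 1`` against a constant."""
    if n_vars > 0 and rng.random() < n_vars / (n_vars + 1):
        return ("x", int(rng.integers(n_vars)))
    lo, hi = const_range
    return ("c", float(rng.uniform(lo, hi)))


def _function_names(functions) -> tuple[str, ...]:
    if functions is None:
        return _FUNCTION_NAMES
    names = tuple(functions)
    for nm in names:
        if nm not in FUNCTION_SET:
            raise KeyError(f"unknown function {nm!r}")
    return names


def build_full(depth_: int, n_vars: int, const_range, rng, functions=None):
    """Full method: only functions until ``depth_``; every leaf at that depth."""
    if depth_ < 1:
        raise ValueError("depth must be >= 1")
    names = _function_names(functions)
    if depth_ == 1:
        return random_terminal(n_vars, const_range, rng)
    name = names[rng.integers(len(names))]
    spec = FUNCTION_SET[name]
    return (
        name,
        *(
            build_full(depth_ - 1, n_vars, const_range, rng, functions)
            for _ in range(spec.arity)
        ),
    )


#: probability of descending with a function node (rather than closing with a
#: terminal) at a non-limit level of the grow method.
GROW_P_FUNCTION = 0.6


def build_grow(max_depth: int, n_vars: int, const_range, rng, functions=None):
    """Grow method: terminals may appear before the depth limit."""
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    names = _function_names(functions)
    if max_depth == 1 or rng.random() >= GROW_P_FUNCTION:
        return random_terminal(n_vars, const_range, rng)
    name = names[rng.integers(len(names))]
    spec = FUNCTION_SET[name]
    return (
        name,
        *(
            build_grow(max_depth - 1, n_vars, const_range, rng, functions)
            for _ in range(spec.arity)
        ),
    )


def ramped_half_and_half(
    pop_size: int, depth_range, n_vars: int, const_range, rng, functions=None
):
    """Classical mixed initializer.

    Depths are ramped as evenly as possible over ``[lo, hi]``; within each
    depth cohort half the members are built with the full method and half with
    grow (odd cohorts give the extra member to grow).
    """
    lo, hi = depth_range
    if lo > hi or lo < 1:
        raise ValueError(f"invalid depth range ({lo}, {hi})")
    if pop_size < 2:
        raise ValueError("pop_size must be >= 2")
    depths = list(range(lo, hi + 1))
    base, extra = divmod(pop_size, len(depths))
    population = []
    for i, d in enumerate(depths):
        cohort = base + (1 if i < extra else 0)
        n_full = cohort // 2
        for _ in range(n_full):
            population.append(build_full(d, n_vars, const_range, rng, functions))
        for _ in range(cohort - n_full):
            population.append(build_grow(d, n_vars, const_range, rng, functions))
    return population


# ---------------------------------------------------------------------------
# text serialization


def to_text(tree) -> str:
    """Serialize to the function-call syntax, e.g. ``min(X0, add(X1, 2.5))``."""
    kind = tree[0]
    if kind == "x":
        return f"X{tree[1]}"
    if kind == "c":
        return repr(float(tree[1]))
    return f"{kind}({', '.join(to_text(ch) for ch in tree[1:])})"


def _tokenize(text: str):
    tokens = []  # (kind, value, position)
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
            continue
        if ch in "(),":
            tokens.append((ch, ch, i))
            i += 1
            continue
        if ch.isalpha() or ch == "_":
            j = i
            while j < n and (text[j].isalnum() or text[j] == "_"):
                j += 1
            tokens.append(("name", text[i:j], i))
            i = j
            continue
        if ch in "+-." or ch.isdigit():
            j = i + 1
            while j < n and (text[j] in ".eE+-" or text[j].isdigit()):
                # only allow +/- right after an exponent marker
                if text[j] in "+-" and text[j - 1] not in "eE":
                    break
                j += 1
            try:
                value = float(text[i:j])
            except ValueError:
                raise ParseError(f"bad number {text[i:j]!r}", i)
            tokens.append(("number", value, i))
            i = j
            continue
        raise ParseError(f"unexpected character {ch!r}", i)
    tokens.append(("end", "", n))
    return tokens


def parse_text(text: str, n_vars: int):
    """Parse the serialized syntax back into a tree.

    ``Xi`` tokens must satisfy ``i < n_vars``.  N-ary ``min``/``max`` calls are
    accepted as sugar and desugared into nested binary calls, i.e.
    ``min(a, b, c)`` becomes ``min(a, min(b, c))``.
    """
    tokens = _tokenize(text)
    pos = 0

    def peek():
        return tokens[pos]

    def take(kind):
        nonlocal pos
        tok = tokens[pos]
        if tok[0] != kind:
            raise ParseError(f"expected {kind!r}, found {tok[1]!r}", tok[2])
        pos += 1
        return tok

    def expr():
        kind, value, at = peek()
        if kind == "number":
            take("number")
            return ("c", float(value))
        if kind != "name":
            raise ParseError(f"expected expression, found {value!r}", at)
        take("name")
        if value.startswith("X") and value[1:].isdigit():
            idx = int(value[1:])
            if idx >= n_vars:
                raise ParseError(f"variable X{idx} out of range (n_vars={n_vars})", at)
            return ("x", idx)
        if value not in FUNCTION_SET:
            raise ParseError(f"unknown function {value!r}", at)
        spec = FUNCTION_SET[value]
        take("(")
        args = [expr()]
        while peek()[0] == ",":
            take(",")
            args.append(expr())
        take(")")
        if len(args) != spec.arity:
            if value in ("min", "max") and len(args) > 2:
                node = args[-1]
                for a in reversed(args[:-1]):
                    node = (value, a, node)
                return node
            raise ParseError(
                f"{value} expects {spec.arity} argument(s), got {len(args)}", at
            )
        return (value, *args)

    tree = expr()
    end = peek()
    if end[0] != "end":
        raise ParseError(f"trailing input {end[1]!r}", end[2])
    return tree


def read_expression_file(path, n_vars: int) -> list:
    """Read one expression per line; blank lines and ``#`` comments ignored."""
    trees = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            trees.append(parse_text(line, n_vars))
    return trees


def write_expression_file(path, trees: Sequence, header: str | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            for ln in header.splitlines():
                fh.write(f"# {ln}\n")
        for t in trees:
            fh.write(to_text(t) + "\n")


def _check_finite_constants(tree):
    for sub in iter_subtrees(tree):
        if sub[0] == "c" and not math.isfinite(sub[1]):
            raise ValueError("non-finite constant in tree")


def validate_tree(tree, n_features: int | None = None) -> None:
    """Check structural invariants: arity, finite constants, variable range."""
    for sub in iter_subtrees(tree):
        kind = sub[0]
        if kind in ("x", "c"):
            continue
        spec = FUNCTION_SET.get(kind)
        if spec is None:
            raise ValueError(f"unknown function {kind!r} in tree")
        if len(sub) - 1 != spec.arity:
            raise ValueError(f"{kind} node has {len(sub) - 1} children, wants {spec.arity}")
    _check_finite_constants(tree)
    if n_features is not None:
        _validate_indices(tree, n_features)
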