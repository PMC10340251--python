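# Methods

This note records the model, the conventions chosen where the method leaves
room, the synthetic data the package is validated on, and what those
validations do and do not show.

## Expression model and protected function set

A classifier candidate is an expression tree over input variables `Xi`
(principal-component features), real constants, and fifteen protected
functions. Protection makes every function total on the reals so evolution
never produces NaN/inf:

| function | rule |
|---|---|
| `div(a, b)` | `a / b` if `abs(b) > 1e-3`, else `1` |
| `log, log2, log10` | `log(abs(x))` if `abs(x) > 1e-3`, else `0` |
| `sqrt(x)` | `sqrt(abs(x))` |
| `cbrt(x)` | `sign(x) * abs(x)^(1/3)` |
| `tan(x)` | passed through |
| all nodes | outputs clipped to `[-1e12, 1e12]` |

The guard constants are conventional for symbolic-classifier work, not
published values; they are module constants (`DIV_GUARD`, `LOG_GUARD`,
`CLIP_LIMIT`). The clip bound keeps products and tangents finite while being
far outside any data scale that matters after standardization. `min`/`max`
have arity 2 internally; the text parser accepts n-ary calls as sugar and
desugars them into right-nested binary calls (node counts do not depend on
the nesting direction). Tree *length* counts every node including leaves, so
published per-expression length tables correspond to plain node counts.

Terminal sampling draws a variable with odds `n_vars : 1` against a constant
(constants uniform on the configured range): with ~150 input components a
terminal is almost always a variable, which matches how the published
expressions look. The grow initializer descends with probability 0.6 per
level; the full initializer uses only function nodes until the target depth.
Ramped half-and-half ramps depths evenly over the configured range and splits
each depth cohort half full / half grow (odd cohort: extra grow member).

## Fitness, selection, and the evolutionary loop

Raw fitness of a tree is the logistic LogLoss of `sigmoid(tree(X))` with
probabilities clipped at `1e-15`. Classification thresholds the sigmoid at
0.5 (equivalently the raw output at 0, with 0 counted positive). Each
generation scores the whole population on one shared row subsample of
fraction `maxSamp` (redrawn per generation) so members are comparable within
a generation; the generation's best member is re-scored on the full training
data and the best-ever tree is tracked on that full-data score, which makes
model selection stable under subsampling.

Tournament selection samples `SizeTour` members without replacement and
returns the minimizer of `raw + ParsCoef * length`; ties break to the shorter
tree, then the earlier population index, making runs bit-reproducible under a
fixed seed. Offspring are produced per slot by drawing one operation with
probabilities `(CrossValue, SubMute, HoistMute, PointMute)`; the residual
probability (the hyperparameter search constrains the four to sum into
[0.999, 1.0]) is reproduction — a verbatim copy of a tournament winner.
Point mutation replaces each node independently with probability 0.05
(`point_rate`, exposed in the config) by a same-kind token, preserving shape;
hoist mutation lifts a subtree of a subtree into its place and can only
shrink; subtree mutation grows a fresh tree with depth drawn from the
initial-depth range. Evolution stops at the generation limit or as soon as
any member's raw (subsample) fitness reaches `CritStop`.

## Hyperparameter search

The search samples uniformly from per-field ranges (population 1000–2000,
generations 200–300, tournament 100–500, initial depth 3–18, constants
±10000, crossover/hoist/point 0.001–0.3, subtree 0.9–1.0, row fraction
0.99–1.0); the parsimony coefficient (1e-5–1e-4) and stop criterion
(1e-6–1e-3) are sampled log-uniformly because their ranges span decades and
selection is sensitive to their order of magnitude. The four operation
probabilities are drawn jointly until their sum lands in [0.999, 1.0]; that
window holds only ~1.5e-4 of the mass, so the rejection loop is vectorized
with a 200,000-draw budget (failure probability ~e^-30). Tournament size uses
the absolute published range and is clipped to the population size. A sampled
configuration is accepted when all five mean training metrics of its
5-fold-CV run exceed the gate (default 0.99); otherwise the best mean
training accuracy wins after `max_iters` (default 50) draws. A reduced
profile (`HyperRanges.reduced()`) keeps the same structure with desk-scale
budgets (population 80–160, generations 8–16, tournament 8–24, depth 2–5)
for tests and examples.

## Preprocessing

Standardization uses the population standard deviation; zero-variance
columns map to zero. The linearity audit regresses each feature on the
sample index 0..N−1 — an unusual diagnostic, kept deliberately because it is
the audit this method prescribes; zero-variance features are defined to have
R² = 1. PCA runs on the standardized matrix via full SVD; `k` is the minimal
component count whose cumulative explained-variance ratio reaches the target
(read as "≥ target"), and each component's largest-magnitude loading is made
positive so refits are sign-stable. One-vs-rest decomposition produces one
binary task per class; classes without positives are dropped with a warning.

## Oversampling conventions

All three samplers interpolate `x + λ(x_nn − x)`, `λ ~ U(0,1)`, between a
minority seed and one of its `k = 5` nearest minority neighbours (`k` reduced
to `count − 1` for tiny classes) until counts are exactly equal, and always
preserve the original rows as a prefix of the output. They differ in the
seed set: SMOTE uses every minority point; Borderline-SMOTE screens each
minority point's `m = 10` nearest neighbours in the whole dataset and seeds
only the DANGER set (`m/2 ≤ majority-neighbours < m`; all-majority
neighbourhoods are noise, minority-dominated ones are safe); SVM-SMOTE seeds
the minority support vectors of a linear soft-margin SVM (`C = 1`,
a simple faithful default), discarding vectors whose whole neighbourhood is
majority, and extrapolates away from the neighbour (step capped at the
segment length) when the seed's neighbourhood is not majority-dense.
"Cannot balance" is operationalized as an empty seed set: the input is
returned unchanged and flagged, and such (class × method) pairs are excluded
from training — reproducing the published partial-feasibility pattern
qualitatively. Distances are Euclidean on the already-scaled PC features.

## Evaluation protocol

Splits and folds are stratified — with balanced inputs stratification is
nearly a no-op, but it stabilizes tiny classes. Summary σ
over the five folds is the population standard deviation — a fixed
convention so panels are reproducible. AUC is the rank-based area under the
ROC curve computed on sigmoid scores, not on thresholded labels; undefined
metric ratios (zero denominators) return 0 with a warning. Ensembles report
AUC on the vote fraction, a graded score.

## Ensembles and stacking

Per class, the best five-expression sets of all feasible samplers are pooled;
the vote threshold is ⌈n/2⌉ (8 of 15), which also resolves the even-count tie
to the positive label — the published rule only states the odd case. The
stacker appends the class's vote vector to the PC features, splits 70:30,
fits a default CART tree (Gini, best splitter, unlimited depth,
`min_samples_split = 2`) on the 70% part and — matching the published
protocol — reports metrics on the *entire* dataset, training rows included.
That protocol leaks training data into its headline numbers, so
`stack_with_tree(..., holdout_only=True)` provides an honest 30%-only mode;
the default remains the faithful one. Multiclass resolution assigns a sample
to the unique claiming class and reports zero- or multi-claim samples as
unresolved rather than guessing.

## Synthetic data

`SyntheticSpec` defaults encode the study conditions the package targets:
151 samples, class counts 30/41/14/29/30/7, latent rank 20, class-mean
separation 2.0, noise SD 0.3 — and 2000 features rather than the original
~55k, because the PCA contract is rank-driven and the wider matrix adds only
runtime. Samples get latent scores `Z = class_mean + N(0, I)`; a monotone
per-sample trend is carried by the first latent dimension, whose loading
vector has constant magnitude and random signs across features so every
feature inherits a comparable trend share; the remaining loadings are a
random orthonormal complement, and the mixed signal is scaled by
`sqrt(p / r)` so per-feature signal variance stays of order one above the
noise floor. The internal trend gain (13.0 at `trend_strength = 1.0`) was
set by a calibration sweep so the default audit lands near mean R² ≈ 0.87;
the spread across features (σ ≈ 0.04) is tighter than a real microarray's.
With `noise_sd = 0` the data are exactly rank *r* and PCA at 99% recovers
*k = r* (provided no single direction dominates; a strong trend can absorb
the last percent of variance and shave one or two components).

What the generator does *not* model: probe-level correlation structure,
batch effects, heavy-tailed expression noise, or any biological pathway
structure. Passing tests therefore demonstrate that the machinery behaves as
specified on data with the assumed shape, not that the method attains any
particular accuracy on real expression data.

`generate_separable_binary` provides rules exactly representable in the
function set (threshold, linear, min-rule) for parameter-recovery
experiments; `generate_minority_geometry` provides the isolated / embedded /
interleaved minority layouts that drive the oversampling feasibility tests.

## Desk-scale budgets and stochastic checks

The full-scale search (population up to 2000, 300 generations, ~55k
features) is a multi-hour computation; all shipped tests and the acceptance
script run the same code at reduced sizes chosen as desk-scale defaults:
600–2000 features, latent rank 10–20, population 80–300, 8–30 generations,
one search iteration per (class × sampler). The end-to-end improvement
property ("pooled vote ≥ mean single expression; stacking within 0.02 of the
vote") is asserted on macro-averages over classes, per seed, in at least 8 of
10 seeds: per-class-per-seed comparisons multiply six noisy events and would
test the conjunction, which the underlying effect — reported per class on a
single dataset — does not claim. The bloat-control comparison uses a
boundary (`x0·x1 + sin(3·x2) > 0`) that the function set can only fit with
sizeable trees, because on trivially separable tasks populations collapse to
short trees with or without pressure; the comparison runs the strong end of
the published coefficient range (1e-4) against zero, averaged over fixed
seeds, since the penalty at 1e-5 (~1e-3 loss units on 100-node trees) is
below the loss resolution of desk-scale populations.

## Known limitations

* Expression evaluation is recursive NumPy, fast for ~150-sample tables but
  not vectorized across population members; full-scale runs are CPU-bound.
* The SVM-SMOTE extrapolation step and neighbourhood-density rule follow the
  method's verbal description; the original implementation details differ in
  unpublished ways, so only qualitative behaviour is matched.
* The stacker's default evaluation protocol intentionally reproduces the
  published (leaky) procedure; use the holdout mode for honest estimates.
* Multi-hour full-range searches are supported but untested at full scale in
  this repository.
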