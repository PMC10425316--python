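# Methods

## Problem setting

The package classifies samples of a dense biomarker table (rows = children,
columns = continuous protein levels, binary label ASD/TD) and cleans the
table first: wrapper feature selection removes uninformative analytes,
GA-based outlier rejection removes invalid training rows. Both the filters
and the diagnostic layer treat the classifier as a black box scored on a
validation split, so the package is organised around one three-way
stratified split (train/validation/test) drawn once per run: the filters
are driven by train + validation, the feature mask is then applied to all
three parts, the row mask to the training part, and the ensemble is
trained, selected and tested on the same split. The split proportions
default to 60/20/20; a 10-fold stratified CV helper is provided for
protocol-style evaluation.

Label convention: ASD is the positive class (encoded 1) everywhere —
precision and recall therefore describe ASD detection.

## Naive-Bayes weight space

KNN on raw biomarker levels conflates measurement scale with evidence.
Features are z-scored with training-split statistics, then a Gaussian
Naive-Bayes model is fitted per (class, feature) with the sample standard
deviation floored at 1e-6. Each feature value is mapped to its normalized
class-conditional evidence, one coordinate per class:

    w_cf(x) = p_c(x_f) / [p_ASD(x_f) + p_TD(x_f)]

computed in log space for numerical safety. The two coordinates of every
feature sum to 1 and are monotone in the density ratio, so Euclidean
distance in this 2·F-dimensional space compares *evidence profiles*. The
transform deliberately omits class priors (keeping the coordinates
symmetric under class imbalance); priors are stored and used only by the
plain-NB predictor that serves as a test oracle. The exact functional form
of the weighting is a design choice of this package: it is the minimal
NB-derived quantity that is bounded, per-feature, and distance-friendly.

## COA prototype generation

The enhanced KNN replaces its training set with N_C generated "New-cases"
per class (default 10, versus ~90 training rows at the default cohort
size), found by a chimp-optimization search in weight space:

- Encoding: agents are flat vectors of dimension A·N_C·Y_D, class-major
  (positive-class block first), then case, then feature. A is the
  weight-space dimension, Y_D = 2.
- Fitness: fraction of training cases correctly diagnosed by a K-NN vote
  (K = 3, clipped to the prototype count with a warning) over the agent's
  decoded New-cases.
- Dynamics: the four best agents (attacker/barrier/chaser/driver) are kept
  as elitist snapshots, replaced only by strictly fitter agents (ties keep
  the incumbent, which makes attacker fitness provably monotone); every
  population member moves each iteration. Moves are either the mean of
  four leader-relative encircling candidates or, with probability 0.5, a
  chaotic relocation. All positions are clipped to per-dimension bounds
  taken from the weighted training data's ranges.
- Coefficients: the attack coefficient decreases linearly, fc = 2 −
  2·itr/Max_itr (the loop counts itr = 1..Max_itr so fc reaches 0 on the
  final iteration); each leader has a pair of dynamic factors whose
  schedules use quartic/cube-root and cubic ramps with deliberately
  heterogeneous exponents (the early-iteration factors can exceed 1). Every random draw is made outside
  the update equations and injected through a coefficient bundle, so each
  equation is unit-testable against pinned values.
- Chaotic map: the quadratic map is applied to the position normalized
  into its bounds, mc_d = |s_d² − u| with u = 1, which keeps mc in [0, 1]
  (a literal unnormalized square would not be); the relocation maps mc
  back into the bounds per dimension. Degenerate dimensions (equal bounds)
  get mc = 0.
- Stopping: a fixed iteration budget (default 100); no other criterion.
- The prototype set must be strictly smaller than the training set
  (v < Q); configurations violating this are rejected.

## Filter objectives

The headline fitness of a candidate mask is deliberately simple and is
what the public scoring functions report: validation accuracy of the
weighted-KNN base classifier (K = 3) on the masked data, minus a sparsity
penalty of 0.01 × kept-fraction for feature masks; row masks keeping fewer
than two rows of either class score 0.

Accuracy alone, however, is a step function: on a strongly separable panel
many masks tie at the same validation accuracy, and the argmax is then
decided by the sparsity penalty alone — which actively *shrinks* the
feature set and leaves outliers alone. The search objectives (not the
reported scores) therefore add continuous refinement terms:

- BGWO adds 0.02 × a neighbourhood margin — the mean squared-distance
  contrast between each validation sample's 3 nearest other-class and 3
  nearest same-class training neighbours in the masked weight space. The
  term is additive over features in expectation (every feature with real
  class signal raises it; pure-noise features do not), and its weight keeps
  it below one validation sample's worth of accuracy, so it only
  arbitrates between equal-accuracy masks.
- BGA adds 0.2 × a log-compressed margin computed against a *fixed*
  reference set (all original training rows) with only the NB weighting
  refit on the kept rows: corrupted rows inflate the fitted
  class-conditional scales, so each rejected corrupted row raises the
  margin, while the fixed reference prevents the term from being inflated
  by pruning neighbours, and the log compression saturates the
  variance-tightening reward once the scales are clean. A retention reward
  of 0.15 × kept-fraction makes pruning a valid row always cost more than
  the residual margin jitter. After the GA, up to three greedy single-bit
  sweeps refine the best mask, started from both the GA's winner and the
  all-keep baseline (memetic refinement; the second start guards against
  a GA basin that already discarded valid rows).

The weights were chosen from the measured margin landscape on the
synthetic generator (per-corrupted-row margin gain ≫ per-clean-row drift ≫
margin noise); they are configuration fields, and setting the margin and
retention weights to 0 recovers the plain accuracy objectives.

Both optimizers are elitist and fully seeded; mask evaluations are cached
by bit pattern.

## Ensemble selection

"Ensemble" here is single-winner selection, not vote pooling: all members
are fitted on the training split, scored on the validation split, and the
test split is diagnosed by the argmax-accuracy member only, with ties
resolved by the declared member order (SVM, DLA, EKNN). Members are thin
adapters over a common fit/predict contract; a member that raises is
excluded with a warning and the ensemble proceeds with the rest. The SVM
adapter is a linear-kernel SVC with C = 16; the DLA slot is a feed-forward
multilayer perceptron (one hidden layer of 64 units, learning rate 0.01)
standing in for a recurrent network, since the surrounding contract only
requires fit/predict; a logistic-regression adapter is bundled as an
always-available lightweight member. All adapters standardize features
internally.

## Synthetic generator

The generator emulates the target cohort's shape: 154 samples in two
near-balanced classes (76/78), 50 features of which 15 informative, 10%
outlier rows. Informative features are class-conditional Gaussians with
unit variance and a standardized mean gap `effect_size` (default 2.0);
noise features are N(0, 1) in both classes; feature order is shuffled.
Outliers are either label flips or feature corruptions drawn uniformly
from [μ + 6σ, μ + 10σ] of the clean per-feature marginal — far outside the
clean range, so recovery experiments have unambiguous ground truth.

What it does not emulate: protein–protein correlation structure, batch or
assay effects, heavy-tailed marginals, missingness, or label noise that is
correlated with the features. Passing recovery tests therefore show that
the optimizers find planted structure of this idealized kind, not that
they would identify the analytes a clinical panel would select.

Two consequences of the idealized signal strength are worth noting. First,
with a per-feature standardized gap of 2 the panel is close to separable,
so validation accuracy saturates — this is precisely why the filter
objectives need the continuous refinement terms above. Second, corrupted
rows are assigned labels with no feature support; evaluation splits that
contain them reward a model for memorising corruption, so the outlier
recovery experiment plants corrupted rows in the training part and scores
fitness against the clean validation rows.

## Numerical and protocol choices

- Stratified splitting allocates per-class counts by largest remainder, so
  every part's class proportion is within one sample of the global one and
  the three parts are an exact partition; k-fold CV delegates to stratified
  K-fold with shuffling.
- KNN ties (even K, split vote) fall back to the nearest neighbour's
  label; equal distances are resolved by stable index order.
- Undefined metric ratios (0/0) report 0 with a logged warning. Micro/macro
  averaging pools one-vs-rest over the two classes; for single-label binary
  prediction micro precision = micro recall = accuracy, asserted as an
  invariant. F1 is the harmonic mean of macro precision and macro recall.
- The neighbour count K defaults to 3 and `select_k` chooses K in [1, 5]
  by validation error with ties to the smallest K.
- Defaults for the optimizers: population 20, 100 iterations (all three
  metaheuristics), sized so the full pipeline runs in seconds-to-tens of
  seconds on one core at the default cohort scale; the test suite uses
  smaller budgets where the property under test does not depend on
  convergence.
- Loading rejects missing and non-numeric cells outright (no imputation)
  and requires exactly two label values; CSV round-trips preserve float64
  exactly (`%.17g` on write, round-trip parsing on read).

## Limitations

- The BGA's literal "probabilities re-drawn each generation" mode makes
  the search trajectory seed-sensitive; fixed probabilities are supported
  for benchmarking.
- The weighting formula and both filter fitness functions are
  package-defined choices (see above); other defensible choices exist and
  would select different masks on saturated panels.
- The margin refinement terms assume a corrupted-row model in which
  outliers distort the fitted class-conditional scales; outliers that
  mimic the clean distributions (e.g. pure label noise) are only visible
  to the accuracy term.
- With two classes and K = 3 the micro-averaged measures are redundant
  with accuracy; they are reported for completeness of the measure set.
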