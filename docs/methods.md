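# Methods

## Model and procedure

`msbgwo` implements wrapper feature selection by binary grey wolf
optimization. A solution is a 0/1 inclusion mask over the D features.
Fitness is minimized and couples two objectives:

    fit = (1 − α) · S/D − α · AvgAcc

with `S` the number of selected features, `AvgAcc` the mean accuracy of
a k-nearest-neighbour classifier over stratified k-fold cross-validation
restricted to the selected columns, and α the accuracy weight. An
equivalent formulation penalizes the error rate, `(1−α)·S/D + α·(1−AvgAcc)`;
the two differ by the constant α and induce identical rankings, so the
choice is immaterial to the search (asserted in the test suite).

Each iteration of the optimizer:

1. computes the encircling coefficient `a` (linear decay `2 − 2t/T` for
   the BGWO2 baseline, quadratic `2(1 − t²/T²)` for MSBGWO — the
   quadratic stays above the linear schedule everywhere, prolonging
   exploration);
2. moves every wolf toward the best-so-far alpha/beta/delta solutions
   (`D_l = |C·x_l − x|`, `x_i = x_l − A·D_l`, average of the three
   guides), with fresh per-dimension coefficient draws `A ∈ [−a, a]`,
   `C ∈ [0, 2]` per guide per wolf;
3. binarizes through `S(x) = 1/(1+e^{−10(x−0.5)})` against the fixed
   threshold 0.5 (strict inequality; the measure-zero tie maps to 0)
   and re-evaluates;
4. (MSBGWO only) sorts the pack by fitness, pairs master m with slave
   m + N/2, and moves every slave toward its master by
   `x_n = x_M − A₄·ω·|C₄·x_M − x_S|`, binarized against per-dimension
   uniform thresholds, replacing the slave unconditionally;
5. records the best-so-far fitness, giving a non-increasing convergence
   trace by construction (leaders are retained across iterations).

### Assumptions and conventions

- The absolute value in all distance terms follows the canonical
  continuous grey wolf optimizer; ω scales the master–slave distance.
- The master–slave step runs after the whole-population update on the
  re-evaluated pack; slaves are re-evaluated immediately so the next
  iteration's leaders see current fitnesses. Alternative orderings are
  plausible; this one is fixed for reproducibility.
- Initial masks are independent Bernoulli(0.5) draws; all-zero masks
  are re-drawn at initialization. If binarization later empties a wolf,
  the fitness layer returns a finite sentinel (2.0, strictly above the
  reachable fitness range (−1, 1)) instead of failing, keeping the
  population dynamics alive.
- Packs smaller than three fill the leader triple by repeating the
  worst available member.
- One seeded `numpy.random.Generator` drives each run; draws are
  consumed in a fixed order (init; per wolf: r₁/r₂ per guide; per
  slave: r₁/r₂ then thresholds), so runs replay bit-identically.

## Fitness evaluation

- Stratified folds (class proportions preserved) are required: the
  target cohorts have 60–77 samples and plain random folds can produce
  single-class training partitions. Fold assignment is seeded and
  computed once per evaluator, so every mask in a run is scored against
  the same partition.
- KNN uses Euclidean distance, majority vote. Deterministic tie-breaks:
  equidistant neighbours resolve toward the lowest training-sample
  index (stable argsort); vote ties resolve toward class 1. The vote is
  hand-coded for exactly this reason; scikit-learn's classifier is used
  only as an independent cross-check on tie-free data in the tests.
- Precision/recall/F-measure are computed from confusion counts pooled
  over folds (rather than macro-averaged per fold), since the defining
  formulas operate on raw counts. The positive class is the label
  coded 1 (the lexicographically larger or user-designated label).
  Zero-denominator cases return 0 with a warning.
- Reports are memoized by mask bits; re-evaluating an unchanged wolf is
  a cache hit. Final reported metrics re-run the CV from scratch, so
  published numbers never depend on the cache.

## Parameters

| Parameter | Default | Meaning |
| --- | --- | --- |
| N (`n_wolves`) | 10 | pack size; must be even for master–slave pairing |
| T (`n_iterations`) | 100 | iteration budget |
| ω (`omega`) | 0.1 | fraction of the master–slave distance a slave travels |
| α (`alpha`) | 0.8 | accuracy weight in the fitness (0.8 ⇒ 1% accuracy ≈ 4% of D features) |
| k (`knn_k`) | 5 | KNN neighbour count |
| folds | 10 | stratified CV folds |
| runs | 10 | repeats per optimizer in the comparison protocol |

The sigmoid slope (10) and midpoint (0.5) are fixed constants of the
transfer function, deliberately not exposed.

## Synthetic data

`generate_synthetic` emulates the shape of two-class microarray/proteomic
cohorts: n instances, D features with D ≫ n achievable, a small planted
subset of informative features, min–max normalized columns. Noise
features are standard normal for all samples; planted features are
Gaussian with class-conditional means 0 and `effect` at unit variance,
i.e. a pure mean-shift signal of `effect` within-class standard
deviations. Labels follow `class_balance`; planted positions are drawn
at random and returned as ground truth.

Defaults (n = 62, D = 50, 5 informative, effect = 2, balanced classes)
are the study conditions used throughout the tests: 62 instances is a
typical small cohort, D = 50 keeps repeated 10-fold CV runs fast while
preserving the needle-in-haystack structure, and effect = 2 gives a
strong but not trivial signal. What this model does **not** capture:
microarray marginals are heavy-tailed and correlated, informative genes
co-express in blocks, and batch effects exist. Passing the recovery
tests therefore demonstrates correct optimizer mechanics and selection
behaviour under a clean planted model, not expected accuracy on real
expression data.

Normalization is global (fit on the full dataset before CV) as a
deliberate fidelity choice matching the usual preprocessing description
of this protocol, although per-fold normalization is statistically
cleaner.

## Experiment protocol and statistics

Each variant runs `runs` times from seeds derived as
`crc32(base_seed:variant:run:stream)` — a pure function, so adding a
variant never perturbs another's streams. Per-run metrics come from
re-evaluating the run's best mask with the full CV. Variants are
compared with the two-sided Wilcoxon rank-sum (Mann–Whitney) test on
per-run accuracies: runs are independent, so the rank-sum form (not the
paired signed-rank) is appropriate. Midranks handle ties; the normal
approximation supplies z and p; the degenerate all-identical case
returns p = 1 explicitly. The tests bracket this approximation against
an exhaustive permutation oracle: the discrete null has a probability
atom at the observed statistic, so the continuous approximation is
required to land within that atom's bounds (±0.03 smooth-tail slack).

## Numerical choices and edge cases

- Strict `>` at the binarization threshold; `S(0.5) = 0.5` maps to 0.
- `float64` saturates the sigmoid tails beyond |x−0.5| ≳ 3.7 (values
  indistinguishable from 0/1); harmless, since only the comparison
  against thresholds in (0,1) matters.
- Constant feature columns min–max-normalize to all-zeros with a
  warning.
- CSV round-trips are exact: floats are written with shortest
  round-trip representation and parsed with `float_precision="round_trip"`.
- Accuracy spread in summaries is the sample standard deviation
  (ddof = 1), defined as 0 for a single run.

## Problem sizes in the shipped checks

The test suite and the acceptance script use the default synthetic
conditions (62 × 50, 5 planted): single runs at T = 50 for recovery
checks (5 seeds) and the full protocol (2 variants × 10 runs at
T = 100) for the comparison tables. On this scale a full protocol run
takes a few seconds.

## Known limitations

- Only two-class problems; multi-class metrics and generators are out
  of scope.
- The comparator metaheuristics of the usual benchmark tables (binary
  GA, binary PSO, DE, SCA) are not implemented; the comparison
  machinery is generic over the two shipped variants.
- Wrapper selection with KNN inherits KNN's sensitivity to correlated
  redundant features; the fitness only penalizes subset size, not
  redundancy.
- Global normalization leaks fold statistics into training; kept for
  protocol fidelity (see above).
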