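# Methods

## Continuous optimizer

The core engine minimizes a box-bounded objective with a population of
`pop_size` agents (default 30) under a fixed budget of objective
evaluations (`max_evals`, default 300,000). A generation consists of

1. population evaluation (one objective call per agent);
2. Gaussian mutation `x′ = x ∘ (1 + g)`, `g ~ N(0, 1)` drawn per
   coordinate, with greedy acceptance — a mutant replaces its parent only
   on strict improvement, ties keep the incumbent;
3. on stagnation (best-so-far fitness unimproved for `patience`
   consecutive generations, default 5) a Levy escape `x′ = x ∘ (1 +
   Levy(β))` with the same greedy rule, after which the stagnation counter
   resets;
4. the SMA position update (ranking, oscillation weights, three-branch
   coordinate move), clipped to the box.

Both operators can be disabled independently (giving the plain-SMA, GSMA
and LSMA ablations; disabling both reproduces plain SMA draw-for-draw),
and `levy_mode="always"` fires the Levy step every generation for users
who prefer the untriggered variant. Stagnation-triggered is the default
because the escape operator exists to leave local optima; firing it while
the search is still improving only spends budget.

### Numerical and bookkeeping choices

- **Budget accounting.** Every operator evaluation is charged against
  `max_evals`; the run stops when the remaining budget cannot cover one
  population evaluation, so total calls land in
  `(max_evals − pop_size, max_evals]`. The `a`/`b` schedules need a
  generation horizon; it is derived from the budget at the per-generation
  baseline cost (`pop_size · (1 + gaussian [+ always-on levy])`).
  Triggered Levy evaluations consume extra budget, so the realized
  generation count can fall short of the horizon; the schedule argument is
  capped there.
- **Schedules.** `a = arctanh(1 − t/max_t)` diverges at `t = 0`; `t` runs
  from 1 and the arctanh argument is clamped to `1 − 1/max_t`.
  `b = 1 − t/max_t`. Both vanish in the final generation, which makes the
  contraction branch `vc·x` collapse agents onto the origin — on
  functions whose optimum sits at the origin (sphere, Rastrigin,
  Griewank, Ackley) the best agent underflows to exactly zero, which is
  why published means of `0.00E+00` are reproduced exactly rather than
  approximately.
- **Weights.** Base-10 logarithm with `ε = 2.2e−16` added to `bF − wF`;
  the ratio is clamped at zero from below because the ε guard can flip its
  sign when `bF ≈ wF` at double precision (degenerate populations then get
  unit weights). "Better half" is the first `⌈n/2⌉` ranks.
- **Randomness discipline.** One `numpy` generator per run, seeded from
  the config; `r`, the partner indices `X_A`/`X_B`, `vb` and `vc` are all
  drawn per coordinate; partners are drawn with replacement from the whole
  population.
- **Restarts.** With probability `z = 0.03` an agent reinitialises with
  *one* shared uniform draw across coordinates — restarts land on the
  diagonal of the box, as in the reference implementation of the
  algorithm. This is load-bearing, not cosmetic: on Schwefel-type
  landscapes with a deceptive second basin per coordinate, a diagonal
  restart periodically places an agent with *every* coordinate in the
  global basin, and the coordinate-wise partner mixing of the guided
  branch then migrates those coordinates into the incumbent. With
  independent per-coordinate restarts the same implementation stalls
  ~3.5 % above the Schwefel optimum at any budget.
- **Bound handling.** Clipping. The multiplicative operators fix the
  all-zero position (`0 ∘ (1 + g) = 0`); this is a property of the
  operators as defined, documented rather than patched.

### Benchmark registry

F1–F23 with their conventional ranges and reference minima; constants for
the foxholes, Kowalik, Hartmann and Shekel functions are the canonical
De Jong / Dixon–Szegő tables. The six-hump camel-back is implemented in
its standard form (`−2.1·x1⁴`); a common misprint of that table writes
`x1²`, but the accompanying reference minimum (−1.0316) identifies the
standard function. The Hartmann-3 range is `[0, 1]³` (its printed minimum
is attained there; the `[1, 3]` sometimes printed cannot produce −3.86).
The Ackley evaluation order is fixed (`−20·exp(·) − exp(·) + 20 + e`),
giving a deterministic double-precision floor of `4.4409e−16` at the
origin. F7's additive `U[0, 1)` noise draws from an explicit RNG stream so
runs stay reproducible. Minimizers of the fixed-dimension functions were
refined numerically from the literature starting points against these
exact evaluators and are frozen with per-function certified tolerances
(the printed reference minima are rounded; e.g. foxholes prints `1` for
0.998004).

## Feature selection (BGLSMA)

The selector searches a continuous box `[−4, 4]^D` (D = number of genes).
Before each fitness evaluation an agent is binarized with one fresh
uniform threshold per agent: gene `j` is selected iff
`T(x_j) ≤ rand`, `T(x) = 1/(1 + e^(−2x))`. Two consequences drive the
method's behaviour:

- the mask is the *bottom slice of the coordinate ordering*, so mask size
  is directly searchable — small thresholds probe very sparse masks, and
  the sparsity term of the fitness decides how sparse is viable. A
  per-gene independent draw would pin every selection probability near
  `1 − T(x)` and make sparse masks unreachable at realistic budgets;
- the box `[−4, 4]` spans per-gene selection probabilities from ~3·10⁻⁴
  to ~1. A `[0, 1]` box would floor the probability at `1 − T(1) = 0.12`,
  i.e. a hard lower bound of ~12 % of all genes in expectation.

Masks that come out empty are repaired by switching one uniformly chosen
bit on (a 1-NN classifier needs at least one feature); repair keeps the
budget accounting exact, unlike rejection.

Fitness is `0.95·E + 0.05·R/D` with `E` the error rate (the weighting is
only coherent when both terms are costs, so `E` is error, not accuracy).
`E` comes from stratified 10-fold cross-validation of 1-NN with Euclidean
distance, restricted to the masked genes. The fold partition is drawn once
per run from the seed and reused for every evaluation, so fitness
comparisons between agents are paired; the reported best mask's fitness
therefore recomputes bit-exactly from the mask, the fold seed and the
data. The 1-NN error itself is a vectorised Gram-matrix computation
(cross-checked in the tests against scikit-learn's estimator on identical
folds) because the wrapper calls it tens of thousands of times per run;
fold construction uses scikit-learn's `StratifiedKFold`, and the fold
count shrinks with a warning when the rarest class cannot populate every
fold. Whether the published protocol wrapped the whole search in an outer
CV or only scored subsets with an inner CV is not stated; here the CV is
inner (subset scoring) only, so reported errors are in-search estimates,
not out-of-sample estimates of the selected panel.

## Synthetic expression data

The generator emulates the "few samples × thousands of genes" regime
(62–308 samples, 2,000–15,010 genes, 2–26 classes): background genes are
i.i.d. `N(0, noise_sd²)`; each of `n_informative` planted genes carries a
`+effect_size` mean shift in exactly one class, classes assigned
round-robin, so the between-class contrast on a planted gene equals the
effect size by construction and wrapper recall is well defined. Labels are
balanced up to remainder. `block_corr` optionally gives background genes
block-equicorrelated noise for harder instances. The model deliberately
omits heavy-tailed intensities, batch effects and pathway-level gene-gene
correlation, so passing recovery tests demonstrate the *search* works, not
that real microarray panels are this easy.

Two study-condition choices worth stating explicitly:

- the marker-recovery experiment (60 × 200, 5 planted genes, effect 4)
  uses **4 classes**: with one-class-per-gene planting, ≥ 3 planted genes
  are then necessary for zero error, so "recovered ≥ 3 of 5" measures
  recall of genes the optimum actually needs. With 2 classes all planted
  genes are mutually redundant and a sparsity-seeking wrapper legitimately
  keeps one;
- the Colon-scale sparsity check (62 × 2000) uses effect size 4, i.e.
  strong marker genes, mirroring datasets that are separable by one or two
  genes; with weak diffuse effects no sparse accurate subset exists and a
  sparse selector has nothing to find.

## Comparison harness

Per (algorithm, function) cell: final best fitnesses over `n_runs` seeded
runs (seeds `base_seed … base_seed + n_runs − 1`), summarised as Avg/Std.
Pairwise comparison uses the two-sided Wilcoxon signed-rank test at 0.05
(zeros dropped by default, Pratt handling behind a flag; exact null
distribution up to 25 untied pairs, tie-corrected normal approximation
without continuity correction otherwise; fewer than five informative pairs
returns a tie). Overall comparison uses Friedman average rank values over
the Avg table with mid-ranks for ties. Externally produced result vectors
can be injected from CSV and compared with the same statistics;
re-implementing third-party competitor algorithms is out of scope.

## Problem sizes used by the shipped checks

The test suite reproduces the published benchmark cells with 3 seeded runs
per function at the full 300,000-evaluation budget (the published
protocol's 30 runs are a robustness measure, not a different estimator;
three runs of this implementation already have zero or near-zero spread on
the reproduced cells). Recovery experiments use 10 seeds at 10,000
evaluations. `scripts/acceptance.py` uses the same sizes and finishes in
about a minute.

## Known limitations

- The contraction branch biases search toward the origin; on
  origin-optimal benchmarks this flatters the results (exact zeros). It is
  part of the algorithm's definition and retained as such.
- Charging operator evaluations to the budget roughly halves the number of
  SMA generations relative to an implementation that fixes iterations;
  published results computed under iteration-fixed accounting will show
  slightly different convergence curves at equal nominal budgets.
- Wrapper CV error is an in-search quantity; panels intended for use
  should be re-validated on held-out data.
- The Levy stability index β is fixed per run (no schedule); adaptive
  schedules and restart strategies are out of scope.
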