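# Methods

## The simulation model

A design is an ordered list of steps. Data-stage steps (population,
potential outcomes, sampling, assignment, measurement, reveal) transform a
units-by-variables table and may only add columns (or drop rows, for
sampling); inquiry and estimator steps emit result rows without touching
the data. One simulation run executes the steps in declared order:

1. draw the population and its latent variables;
2. add one potential-outcome column per condition
   (`Y_Z_0`, `Y_Z_1`, …);
3. compute each estimand *a<sup>M</sup>* on the table as it stands at the
   inquiry's position — inquiries declared before sampling therefore see
   the full population, and deleting the data-strategy steps cannot change
   them; an inquiry declared after sampling defines a sample-level
   estimand (used by the sampling-bias diagnosand, which needs both);
4. realize the data the researcher would see (sampling restricts the
   table; assignment adds condition and probability columns; measurement
   adds `*_obs` columns, never overwriting the latent ones; reveal selects
   each unit's potential outcome by its assigned condition);
5. apply the estimators to the realized data only.

**Seeding.** One master seed; run *i* uses a substream derived by counter
(`SeedSequence(seed, spawn_key=(0, i))`), so any run is reproducible
independently of how many runs are requested. The bootstrap uses a
separate substream. Identical `(design, m, seed, n_bootstrap)` give
byte-identical output tables.

**Bootstrap.** Diagnosand uncertainty is estimated by the nonparametric
bootstrap over *whole simulation runs* (default 100 replicates): rows of
the simulation table are resampled run-by-run, never individually, so
within-run dependence between estimators or estimands is preserved.
`n_bootstrap=0` marks the SE unavailable rather than failing.

**Failure handling.** A singular or otherwise unfittable estimator inside
one run raises a recoverable failure that is recorded as a missing
estimate row and counted — diagnosands such as the probability of
producing a result at all need failure rates, so failures must not abort
the study. Structural errors (an inquiry naming a missing column, an
estimator applied to an empty sample) abort the run with a message naming
the problem.

**Undefined conditional diagnosands.** The Type-S rate and exaggeration
ratio condition on significance; runs excluded by the condition (and
significant runs whose estimand is exactly zero, for which a ratio or a
wrong sign is undefined) are counted in `n_undefined`. When no run
qualifies the diagnosand is NaN with `n_undefined = m`, not an error.

## Estimators

* **Difference in means** — Neyman variance s²_t/n_t + s²_c/n_c, Welch–
  Satterthwaite degrees of freedom, two-sided t test, 95% t interval. An
  arm with one unit returns the estimate with the SE marked unavailable.
* **Least squares** — statsmodels WLS; HC2 heteroskedasticity-robust
  covariance by default (the standard choice for randomized designs, and
  what the coverage diagnosand evaluates), cluster-robust on request.
  Block fixed effects enter as indicator columns. The
  regression-discontinuity answer interacts the treatment with a
  fourth-order polynomial of the cutoff-centered running variable and
  reads the treatment coefficient.
  A `cov="classical"` option reads the conventional model-based variance
  instead; the blocked design's IPW answer uses it deliberately (below).
* **Inverse-probability weights** — w = Z/p + (1−Z)/(1−p); a unit with
  p ∈ {0, 1} is unweightable and raises an error.
* **Beta-binomial posterior** — prior shape by moment matching
  (a = μ(μ(1−μ)/σ² − 1)); estimate = posterior mean, central 95% credible
  interval in the CI fields, posterior SD in the auxiliary fields. A mean
  of 0.50 with SD 0.29 reproduces the uniform Beta(1, 1); SD 0.11 gives
  the informative Beta(9.8, 9.8).
* **Matching** — 1-nearest-neighbour with replacement on Mahalanobis
  distance, ties broken by lowest control index for determinism; the SE is
  the matched-pair approximation sd(pair differences)/√n_treated, which
  ignores control re-use (documented simplification of the
  Abadie–Imbens variance). Zero-variance covariates trigger a Euclidean
  fallback with a warning.
* **Split-sample discovery** — stage 1 fits a treatment × moderator
  interaction per candidate on a random training split and selects the
  smallest interaction p-value if below α (one concrete "preferred
  procedure"; the selection rule is a plain function and can be swapped);
  stage 2 re-estimates on the holdout. "Result produced" means stage-1
  discovery *and* a significant stage-2 estimate. The unprincipled
  analogue selects and estimates on the full data.

## Qualitative strategies

**Process tracing.** Clues (CPOs) have likelihoods Pr(E|H) and Pr(E|¬H);
the posterior is exact Bayes over the joint clue distribution. Two clues
may be correlated: the joint Bernoulli cell p₁₁ = p₁p₂ + ρ√(p₁q₁p₂q₂),
clipped to the Fréchet bounds with a warning when ρ is infeasible for the
marginals — a concrete stand-in for the unspecified notion of clues
"arising from the same process". Strategy quality is the expected absolute
posterior error, computed by enumerating truth × evidence patterns (no
Monte Carlo needed; the catalogue's declared design confirms it by
simulation). Test classification uses documented thresholds: hoop if
Pr(E|H) ≥ 0.9, smoking gun if Pr(E|¬H) ≤ 0.1, doubly decisive if both,
else straw-in-the-wind.

**Crisp-set QCA.** Case data are coded into a 2^k truth table; a
configuration is positive when its consistency strictly exceeds 0.5 (the
same majority rule as the regression answer's predicted-probability
threshold; both exposed), a remainder when unobserved. Remainders default
to `exclude` (treated as negative); `dont_care` makes them available for
Quine–McCluskey merging. Minimization finds prime implicants by iterative
pairwise merging and then an exact minimal cover (essential primes first,
Petrick-style exhaustive search over the rest — feasible through ~6
causes — with literal-count and lexicographic tie-breaks; a greedy cover
beyond that, documented). Expressions are canonical (no subsumed
implicants, sorted rendering), so semantic equality can also be checked by
truth-table expansion. The saturated-regression answer fits outcome shares
per configuration exactly (least squares on configuration indicators) and
codes positives above 0.5 before minimizing.

## The design catalogue: defaults and why

Magnitudes the source designs leave unstated are exposed parameters with
illustrative defaults chosen once to put each design in the regime it is
meant to study:

* `blocked_hetero` — block sizes 40…200, assignment probabilities
  0.5…0.05 (larger blocks rarer treatment), block effects 0.1…0.9
  (correlated with size), unit noise SD 2. The probabilities are steep
  enough that the weighting trade-off is visible above Monte Carlo noise:
  BFE's bias is ≈ −0.12 while IPW's variance penalty exceeds that bias
  squared. The IPW answer reads conventional weighted-least-squares
  uncertainty (`cov="classical"`): mistaking IPW weights for precision
  weights is precisely the common practice whose biased variance
  estimates produce undercoverage and overstated power; HC2 sandwich SEs
  would largely repair the intervals and hide the phenomenon.
* `factorial_vs_three_arm` — main effects 0.3, noise SD 1, n = 96
  (divisible by both 4 and 3). The no-interaction regression absorbs
  exactly half the interaction into the treatment-1 coefficient in the
  factorial design and none of it in the three-arm design.
* `truncation_replication` — 50 catchment areas × 20 households, ~10%
  baseline infant mortality (threshold −1.38 on latent health =
  community N(0, 0.4) + family N(0, 1)), treatment shifting the survival
  threshold by 0.6 only for infants under the age cutoff (older infants'
  survival is treatment-independent, making them an observable
  always-survivor stratum), weight loading 1.0 on health plus unit noise,
  weight effect 0.2. At these values the survival effect is ≈ 3.3
  percentage points: detectable about a quarter of the time at 50
  clusters (exaggeration ratio ≈ 1.8) and most of the time at 187
  (≈ 1.1). Community-based-organisation presence is Bernoulli(0.56) per
  cluster, optionally loading on community health
  (`cbo_health_coef`) for the "correlated" replicator model.
* `bayes_descriptive` — the latent success probability is drawn uniformly
  each run (the truth distribution is unstated in the source; uniform
  makes "truth far from the prior mean" a regular event), n = 20 units.
* `likely_voter_survey` — turnout 0.5, support 0.55 among voters vs 0.40
  among non-voters, 30% of non-voters overreport; all illustrative and
  exposed.

## What the generators do and do not emulate

The synthetic models capture the structural features the diagnoses turn
on — confounding by construction, heterogeneous probabilities, selection
through survival, misreporting — under clean parametric noise
(normal/Bernoulli, independence across units except where declared).
They do not emulate real-data features such as heavy tails, item
nonresponse, interference between units, or cluster-size imbalance.
Passing diagnoses therefore certify the *logic* of an answer strategy
under the declared model, not its performance on any particular dataset;
that is the intended use — the framework's point is to make such model
conjectures explicit and easy to vary.

## Numerical choices

* Tests are two-sided at α = 0.05 throughout (matching s = 1(p ≤ 0.05));
  the conditioning level of Type-S/exaggeration is the same α as power.
* Standard deviations use the m−1 denominator; the identity
  rmse² = bias² + sd²·(m−1)/m then holds exactly and is tested to 1e-10.
* The imbalance metric is the mean absolute standardized mean difference
  (pooled-SD denominator); any other distance can be recorded through a
  custom statistic step.
* Probability-based assignment uses floor + random-remainder allocation
  (complete-randomization semantics), never independent coin flips.
* Design comparison calls a difference a tie when it is within 2 combined
  bootstrap SEs; verdicts follow the home-ground-dominance / robustness /
  model-plausibility ladder.
* Simulation sizes in the test suite (m between 200 and 5000 per
  diagnosis, 4000 draws against the exact N=6 enumeration, 20 repetitions
  for the bootstrap-scaling check) were chosen so Monte Carlo error is
  small against the effects being tested while the full suite stays quick
  to run.

## Known limitations

* Estimands are computed by position in the step order; there is no
  dependency graph or do-calculus — interventions are limited to declared
  condition sets.
* All diagnosands are simulation-based; nothing is derived analytically.
* The exact QMC cover is exponential in the worst case and switches to a
  greedy cover above ~6 causes or ~20 candidate primes.
* Clue correlation is pairwise only (two CPOs); more clues require
  conditional independence given the hypothesis.
* The matching SE is a documented approximation (see above), adequate for
  the bias/RMSE orderings the catalogue diagnoses, not for exact coverage
  statements about matching estimators.
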