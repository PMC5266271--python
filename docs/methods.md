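# Methods

This note documents the statistical content of `quartetri`: the design and
inference procedures it implements, the choices made where the procedure
admits more than one reasonable reading, what the synthetic-data generator
does and does not emulate, and the package's known limitations.

## Design: greedy quartet matching

Covariates are standardized once, on the full pre-matching sample, by the
sample mean and the n−1 sample standard deviation; constant columns map to
zeros (they carry no distance information and must not divide by zero).
Standardizing once up front — rather than re-standardizing as the pool
shrinks — keeps the metric a fixed function of the data, so the partition
depends on the random draw order only through the procedure itself. Binary
covariates are standardized identically to continuous ones: on the
standardized scale every covariate contributes one squared difference, which
is what "equal weight" means here.

The matcher is greedy, not optimal: draw a seed unit uniformly from the
pool, attach the nearest remaining unit to *that seed unit* three times,
emit the quartet. A documented variant (`neighbor="centroid"`) measures
distance to the running mean of the growing quartet instead; the seed-unit
criterion is the default because it is the more literal reading of
"matched to the first". Nearest-neighbor ties break on the lowest unit
identifier so that the whole design is a pure function of (data, seed).
Unit counts not divisible by 4 leave r < 4 units excluded, with a logged
warning listing them.

Arms are allocated as an independent uniform permutation of the four
factorial conditions within each block. One named seed drives matching and
allocation through independent `SeedSequence` substreams.

## Estimation

The block fixed-effects linear probability model is solved by within-block
demeaning (Frisch–Waugh): demean y and the regressors inside each block,
solve the small least-squares problem, then recover the constant (the
first-appearing block is the reference) and the B−1 block effects from the
block means. This is algebraically identical to the explicit
dummy-variable OLS — the test suite cross-checks every coefficient against
statsmodels' dummy solve — but is O(n·k) instead of O(n·(B+k)²) and stable
at any block count.

Two identities matter and are enforced by tests at 1e-10:

* with 2 treated / 2 control per block, β̂ equals the across-block average
  of within-block treated-minus-control means (and hence, with uniformly
  balanced blocks, the pooled difference in means);
* residuals sum to zero within every block, and fitted values plus
  residuals reproduce the outcome exactly.

In the interaction model the two prior-knowledge flags enter raw
(uncentered) together with their products with the indicator, so the
indicator's coefficient is the treatment effect at know = (0, 0). A flag
with no variation contributes a zero (demeaned) column; it is dropped with
coefficient 0, which reduces the model to the plain block-FE fit rather
than failing. Genuinely collinear regressors (e.g. two identical flags)
raise an estimation error.

Deliberately absent: standard errors of any kind. OLS sampling variance is
invalid for binary outcomes, and cluster-robust corrections are biased at
62 clusters; all inference runs through the randomization distribution.

## Randomization inference

The permutation null holds everything fixed except the main-effect
indicator, which is re-drawn per block from the 6 admissible
two-treated/two-control patterns. Conventions:

* **p-value**: raw proportion #{permuted ≥ observed}/M, one-sided
  "greater" by default (the hypothesized direction is a knowledge gain).
  No plus-one correction — a statistic above every permuted value reports
  p = 0 — with the conservative (count+1)/(M+1) variant available via
  `plus_one=True` for users who need guaranteed level.
* **Ties** count toward rejection (≥, not >), compared with a 1e-12
  absolute slack so that bit-level round-off from different summation
  orders cannot flip a genuine tie.
* **Exact vs sampled**: exact enumeration of all 6^B assignments is
  allowed up to B = 8 (6⁸ ≈ 1.7M evaluations) and refused beyond with a
  pointer to sampling; sampled mode draws M independent assignments and
  does not inject the observed one.
* The generic path re-evaluates the statistic in full per permutation
  (including complete refits of the interaction model). For the block-FE
  slope on balanced quartets there is an exact closed form — the slope is
  (Σ demeaned outcomes over treated units)/B, so each block contributes one
  of 6 precomputable values — which `ri_pvalue_block_fe` evaluates
  vectorized over permutations. This is the same number the refit produces
  (tests assert exact agreement on full enumerations), not an
  approximation.

### Discreteness and conservatism

On binary outcomes the block-FE slope is lattice-valued: each block's
contribution is an integer count of correct treated answers (shifted by
the block mean), so β̂ moves on a grid of spacing 1/B. Ties between the
observed and permuted statistics are therefore common — the less variation
the outcome has, the coarser the grid — and with ties counting toward
rejection the p-values are *conservative*: stochastically larger than
uniform, with type-I error below nominal (in the package's own sharp-null
calibration at n = 248 and the default base rates, per-cell rejection
rates at α = 0.05 fall around 0.024–0.058, and the p-value distribution
visibly departs from uniform for outcomes with base rates near 0 or 1).
This is a property of exact discrete randomization tests, not an
implementation artifact: rerunning the identical pipeline with a
continuous outcome gives mean p ≈ 0.51 and a clean Kolmogorov–Smirnov
uniformity pass. Users should read these p-values as valid but
conservative, and should expect the conservatism to be most pronounced
exactly where the pre-registered low-variation screen (modal share ≥ 95%,
inclusive, computed on the full sample) would discard the outcome anyway.

## Synthetic data

The generator emulates the two tables the analysis consumes.

**Baseline** (9 covariates): household size (1 + Poisson(4)), head age
(normal 45 ± 12, clipped to 18–90, integer), head gender (Bernoulli 0.25),
potato area (lognormal), past potato extension (Bernoulli 0.30), log yield
(normal 7 ± 0.8), log welfare per capita (normal 13 ± 0.7), distance to
input dealer (gamma, right-skewed), credit access (Bernoulli 0.35). These
marginals are plausible stand-ins for a smallholder potato-farming
population — the source study does not publish covariate distributions —
and the design stage accepts any named covariate set, so the exact list
(nine here; the study describes ten characteristics while enumerating
nine) is not load-bearing. An optional latent cluster structure
(`n_clusters`, `cluster_sep` in SD units on the continuous columns) gives
matching-quality tests ground truth to recover.

**Outcomes** are generated additively on the probability scale:
base rate + direct shift (featured treatment) + cross shift (the
"general-knowledge" channel of the non-featured treatment) + prior-
knowledge main shifts + knowledge-by-treatment interactions, clamped to
[0.01, 0.99] with every clamp counted and logged. Additive-on-probability
generation is chosen over logistic because the estimator is a linear
probability model: the configured shift *is* the estimand, so recovery
experiments compare like with like. Default magnitudes sit near the
motivating trial's point estimates (base 0.60 and a +0.28 storage-video
shift for the first storage question, etc.); the knowledge-by-treatment
interaction defaults to zero since the trial treats interactions as
underpowered. Note the defaults imply clamping in the both-treatments arm
for the first storage question (0.60 + 0.28 + 0.28 > 0.99): with both
large shifts active the additive truth necessarily saturates, which is why
parameter-recovery experiments use a truth containing only the shift under
test.

What the generator does **not** emulate: attrition, non-compliance,
spillovers between units, enumerator effects, covariate-dependent prior
knowledge (available as a knob only in the sense that flags could be set
by the caller), or any dependence between the quiz questions beyond the
shared treatment. Passing tests therefore demonstrate the correctness and
calibration of the *procedure* under clean conditions, not robustness of
the substantive findings to field complications.

## Experiment sizes

The packaged validation experiments use: 500 replications at M = 2,000
permutations for sharp-null calibration, 400 replications for parameter
recovery (per-study SD of β̂ ≈ 0.06, so the Monte-Carlo SE of the mean is
≈ 0.003 against a ±0.02 bound), exact enumeration at B = 5 (7,776
assignments) against M = 50,000 samples for the exact-vs-sampled
agreement check, and M = 10,000 (the original analysis's choice) for
replication runs. These sizes make every validation conclusion
statistically sharp while keeping a full test run in well under a minute
per experiment.

## Known limitations

* The matcher is greedy; it does not minimize total within-block distance
  globally, and no optimal-matching or Mahalanobis option is provided.
* Randomization p-values are conservative on coarse binary outcomes (see
  above); no mid-p or randomized-tie variant is offered because the
  package mirrors the original tie convention.
* The interaction table's published column layout is ambiguous; the
  package implements one specification — indicator, two raw flags, two
  products, block fixed effects — for any (outcome, effect) pair, and the
  replication layer maps it onto the published columns via a configurable
  mapping (`TABLE3_MAPPING`).
* Confidence intervals by test inversion and studentized statistics are
  out of scope; so is inference on interaction effects.
* The deposited-file reader assumes complete quiz responses; the
  permissive `drop_incomplete` mode logs and drops, but any resulting
  short block is a structural error, by design.
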