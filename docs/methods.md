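# Methods

This note records the statistical model behind `tailsplit`, the concrete
choices made where the procedure is genuinely open, and what the synthetic
experiments do and do not demonstrate.

## Model and procedure

The latent resistance `R > 0` is observed only through binary exceedance
indicators at experimenter-chosen stress levels. The target is the
`alpha`-quantile of `R` at `alpha ≈ 10⁻³`, attacked on the reciprocal scale
`R~ = 1/R` as the `(1-alpha)`-quantile `q~_{1-alpha}`, with
`q_alpha = 1/q~_{1-alpha}`.

The rare event `{R~ > q~_{1-alpha}}` is split into `m` nested events with
conditional probabilities near a target `p`; the conservative stage count
is `m = ceil(log alpha / log p)` (5 at `alpha = 10⁻³`, `p = 0.25`). Stage j
samples `K` Bernoulli indicators of exceedance over `s~_j` under the true
law truncated above `s~_{j-1}` (the synthetic stand-in for trials on
weakened specimens), re-estimates the model, and places the next threshold
at the `(1-p)`-quantile of the estimated conditional law. The final
threshold is the quantile estimate.

Two families are implemented for `R~`:

* **GPD(c, a), c > 0.** Threshold stability is exact: the excess above `s`
  is GPD(c, a + c·s), so any stage estimate determines the initial pair by
  `a_T = a_j - c·s~_j`. The exponential boundary `c = 0` is excluded from
  the model class (memoryless excesses carry no information across
  thresholds); the exponential distribution still appears inside the
  comparators, which are defined on it.
* **Weibull(scale, shape).** The conditional log-survival across
  thresholds obeys the scale-free identity
  `log P(R~ > t | R~ > s) = ((t/s)^shape - 1) · log P(R~ > s)` and its
  three-level iterate, so the threshold recursion and the shape update
  never need the scale.

### Stage estimation (GPD)

A single stage observes one Bernoulli probability; the two GPD parameters
are unidentified stage-wise, and the joint Bernoulli likelihood is
extremely flat (the package exposes this diagnostic:
one level with n = 200 observations leaves the within-1-log-unit region of
the likelihood spanning more than half the tail-index search box). The
dual-criterion estimator therefore:

1. restricts candidates to the **admissible set** — initial-scale pairs
   `(c, a)` whose implied conditional exceedance probability at the current
   stage lies in the Wald interval
   `p^ ± z_{1-γ/2}·sqrt(p^(1-p^)/(K-1))` (confidence level `1-γ = 0.8` by
   default; note the `K-1` denominator);
2. minimizes over that set the absolute discrepancy between the previously
   realized threshold increment `s~_{j-1} - s~_{j-2}` and the
   `(1-p^_{j-1})`-quantile of the candidate's conditional law above
   `s~_{j-2}`.

Candidates are searched on a log-spaced 200×200 grid over
`c ∈ [0.05, 5]`, `a ∈ [0.05, 20]`, followed by Nelder–Mead refinement in
log-coordinates penalized to the admissible set. Ties break toward smaller
`c`, then smaller `a` (parsimony toward lighter tails); the whole
optimization is deterministic so replicas differ only through their data.
The published displays write the admissibility probability with bare
`(c, a)` but condition the same pair to `a + c·s~_{j-2}` in the backward
quantile; the only coherent reading — used here — is that candidates live
on the initial scale and are conditioned to whichever threshold each
criterion needs.

Degenerate stage data (`p^ ∈ {0, 1}`) is Anscombe-shrunk to
`(Σ + 0.5)/(K + 1)` before logs and intervals (raw values are kept in the
stage record); an empty admissible set triggers one retry with `γ` halved,
then an error carrying the partial stage records.

**Stage 1** is identifiability-limited (one probability, two parameters).
Among grid points matching the stage-1 interval, the point closest in
log-coordinates to the center of the search box is taken — a neutral
surrogate for the expert judgment the design assumes at the first level.
After stage 1, the per-stage level is re-solved so the design still reaches
`alpha`: `p_adj = (alpha/p^_1)^{1/(m-1)}`, clipped to (0.01, 0.99); the
attained level `p^_1 · p_adj^{m-1}` is reported with every run.

**ML baseline.** The comparison estimator maximizes the cumulative product
of stage Bernoulli likelihoods over the same box (per-stage-only ML is
unidentified). Its role is to exhibit the dispersion that the backward
constraint removes.

### Stage estimation (Weibull)

The shape is initialized at the geometric center of the configured bracket
([0.1, 10] → 1.0; a shape cannot be identified from a single Bernoulli
level) and, from stage 2 on, re-estimated from the accumulated
`(threshold, p^)` history: each consecutive threshold triple gives one
identity in the shape alone, solved by bracketed root finding (one triple)
or summed-squared-log-discrepancy minimization (several). The next
threshold inverts the three-level identity at the estimated shape. With
`s~_0 = 0` the two-level identity is the first case of the three-level one,
so the recursion is uniform in j.

## Comparators

* **Staircase (Dixon–Mood up-and-down).** Level +δ after survival, −δ
  after failure, floored at 0 for the nonnegative exponential latent model
  (trials at the floor always survive and carry no likelihood weight).
  Parameters are estimated by quantal-response maximum likelihood: the
  exponential rate by bracketed root finding on the score, the Gaussian
  pair by probit likelihood with σ box-constrained to [10⁻³, 10³]. Records
  with no failures, no survivals, or no survivals at positive levels are
  degenerate (the score has no interior root) and are reported as failed
  replicas — about 5% at the exponential study settings, where δ = 15 is
  large relative to the distribution and the walk collapses onto the
  levels {0, 15}.

  At those settings the quantal MLE is close to unbiased for the rate
  (mean relative error ≈ +0.03 over 1000 replicas). This is a property of
  the estimator, not a defect: a correctly specified binary-response MLE
  on (level, outcome) pairs has no mechanism for the large biases
  sometimes quoted for staircase studies, which originate in the
  closed-form moment approximations historically used to summarize
  up-and-down data rather than in the likelihood itself.

* **CRM.** Failure probability at the prior level carries a Beta(k, n−k+1)
  prior, read as "k failures expected in n trials" (defaults k=2, n=10);
  after each batch the posterior pools all failures and trials; the
  implied exponential rate is summarized by the Monte-Carlo mean of
  `−log(1−π)/s` over L = 1000 posterior draws, and the next level is the
  grid point whose model failure probability is closest to the target. The
  level grid for the study scenarios is 10 equally spaced levels from
  `q_target/5` to `2·q_target` — a grid centered on the anticipated
  quantile magnitude. At `alpha = 10⁻³` and K = 50 per iteration
  essentially no failures occur near the target, the posterior stays at
  the prior's scale, and the selection collapses to the lowest grid level:
  the estimate is biased low by ≈ 80%, and the bias shrinks only when the
  cumulative trial count is large enough to drag the posterior mean below
  `alpha` at the low levels.

* **de Valk (complete data).** The idealized benchmark observes the full
  sample. The estimate extrapolates from the intermediate order statistic
  `X_{n-l:n}` using harmonic tail sums, with `l = floor(n/10)` by default.
  For the study scenarios the tail-regularity function is *known*
  (`θ = 1`, `g(x) = c·x` for a GPD; `θ = 0`, `g = 1/shape` for a Weibull)
  and the true slope is plugged in, matching the benchmark's role as an
  upper bound under ideal information; a Hill-estimated slope is available
  (`g_slope="estimate"`) but roughly triples the dispersion and inflates
  the mean through the exponentiated estimation noise.

## Misspecification bounds

When the true law only approaches a GPD in the tail, departures are
modelled by the weighted sup-norm neighborhood
`sup_x |F̄(x) − Ḡ(x)|·w(x) ≤ ε` with the default weight `w(x) = 1 + x`
(increasing, diverging; for the unit GPD it makes the relative-error
kernel constant). The package provides the exact bracket of conditional
survival ratios, the first-order band `[1 − u(s,x)·ε, 1 + u(s,x)·ε]` with
`u(s,x) = (1+cs/a)^{1/c}/w(s) + (1+cx/a)^{1/c}/w(x)` (symmetric in its
arguments; agreement with the exact bracket is O(ε²)), and the smallest
threshold meeting a prescribed relative-error tolerance, found by
bracketed search on [0, 10⁶]. For `c ≤ 1` the kernel term grows with `s`
and the constraint is decided at `s = 0`; interior thresholds exist only
for heavy tails `c > 1`.

## Synthetic data and what the experiments show

All data are generated internally: stage outcomes as Bernoulli draws with
the closed-form conditional success probability of the true model, and
complete samples by inverse-CDF transforms of uniforms. Randomness flows
from a single root seed through fixed-key child streams per (replica,
stage), so replicas are independent, pooling is associative, and changing
one stage's trial count cannot perturb another's draws.

The study-condition defaults are `alpha = 10⁻³`, `p = 0.25`, `m = 5`,
`K = 50`, `γ = 0.2`, with the first threshold at the true
`(1-p)`-quantile — the "well-informed expert" choice; replica counts are
400 for the splitting grids and 1000 for the staircase, with a scale
factor for desk-speed runs. At those conditions the dual-criterion design
reproduces the qualitative and most quantitative signatures of the
published study: systematic underestimation of the extreme quantile
(mean relative error ≈ −0.2 for GPD(0.8, 1.5)), degradation with heavier
tails, and an interquartile range far below the ML baseline's.

The generator emulates ideal conditions the physical experiment cannot
guarantee: exactly i.i.d. trials, perfectly realized conditional laws
(machined specimens exactly following the truncated distribution), a true
model inside the assumed family, and a well-placed first threshold.
Passing tests therefore validate the procedure's internal consistency and
its behaviour under the stated model, not robustness to real laboratory
deviations — the misspecification module quantifies only the first step of
that gap.

## Numerical choices

* Survival/quantile round trips are exact in formula; in double precision
  they are meaningful only while the survival mass is representable
  (`sf` within ~[1e-7, 1-1e-7] through the `1-u` interface).
* The Gamma-mixture check uses adaptive quadrature on [0, ∞) at absolute
  tolerance 10⁻⁹ (identity-checking path, not a hot path); the mixing law
  is Gamma with shape `1/c` and rate `a/c`.
* Thresholds, probabilities and estimates are logged to CSV at 9
  significant digits, '.' decimal separator, no grouping.
* The stage-log reader validates the fixed header and per-replica
  threshold monotonicity; reads are pure observation and never feed back
  into estimation.

## Known limitations

* Stage-1 estimation is a documented convention, not an identified
  estimate; designs with a badly placed `s~_1` lean entirely on the
  p-adjustment.
* The Weibull design estimates only the shape; its final quantile is the
  last threshold, so scale errors at stage 1 propagate multiplicatively.
* The CRM reproduction is qualitative by construction: the original
  study's prior pseudo-counts, Monte-Carlo size and level grid are not
  published.
* Negative tail indices (bounded support), stable-law mixtures for the
  Weibull, and goodness-of-fit testing for domain-of-attraction selection
  are out of scope.
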