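# Methods

## Model and quantities

A practice is a binary cultural trait observed on growers partitioned
into G groups (regions). For one practice, let `n_g` be the number of
non-missing responses in group g, `p_g` the adoption frequency among
them, `w_g = n_g / N` and `p̄ = Σ w_g p_g`. Cultural F_ST is the
between-group share of total adoption variance,

    F_ST = Σ_g w_g (p_g − p̄)² / ( p̄ (1 − p̄) ).

Size weights are the default because they make the estimator identical
to the raw-data variance decomposition (law of total variance:
between + within = p̄(1 − p̄)); an equal-weight option (`w_g = 1/G`) is
provided for designs where regions are the unit of interest regardless
of sample size. When `p̄ ∈ {0, 1}` there is no variance to partition and
F_ST is reported as *undefined* (NaN), never coerced to 0 — "no
variation" and "no differentiation" are different statements, and
coercion would silently feed the boundary condition downstream.

The multilevel-selection boundary condition is

    group benefit / individual cost > (1 − F_ST) / F_ST.

`mls_threshold` evaluates the right-hand side: +∞ at F_ST = 0, 1 at
F_ST = 0.5, 0 at F_ST = 1, undefined for undefined F_ST. It is strictly
decreasing on (0, 1] and exactly invertible (F_ST = 1/(1 + threshold)).

Expert economics: each expert rates individual cost, individual benefit
and public environmental benefit on 1–7 Likert scales. Net private cost
is differenced *within* rater (cost − benefit, range [−6, 6]) before
averaging; differencing after averaging would not be equivalent under
item non-response, and the within-rater difference is the quantity with
a coherent frame of reference. Public benefit is averaged on its raw
scale. Likert means are ordinal summaries: the package deliberately
never forms a benefit/cost ratio from them, which is why the scope
figure places practices *on* the boundary curve (their minimum required
ratio) rather than at measured ratios. The sign of the mean net private
cost classifies the regime: positive → group selection required;
negative → individual selection possible; an exact 0 is reported as
BOUNDARY rather than assigned to a side.

## Estimators

**Naive.** Plug-in of the observed frequencies. It describes the
sampled groups; as an estimate of the differentiation of the process
that generated them it is biased toward zero, for two reasons: the
within-group sampling noise inflates the denominator's share, and — more
importantly with few groups — a variance taken around the sample grand
mean loses the factor `1 − Σ w_g²` (≈ (G−1)/G), exactly as in Bessel's
correction.

**Corrected.** A method-of-moments estimator of the superpopulation
differentiation F, defined as Var(p_g) / (μ(1−μ)) for group frequencies
with mean μ. With `v_g = p_g(1−p_g)/(n_g−1)` (unbiased for the sampling
variance of `p_g`):

    σ̂² = [ Σ w_g (p_g − p̄)² − Σ w_g (1 − w_g) v_g ] / (1 − Σ w_g²),
    D̂  = p̄ (1 − p̄) + Σ w_g² (σ̂² + v_g),

both unbiased for σ² and μ(1−μ) respectively. Their ratio is still
biased downward at small G (Jensen's inequality plus the
numerator–denominator covariance: the denominator contains `σ̂²/G`
explicitly), so a second-order delta-method correction is subtracted:

    bias ≈ − Cov(σ̂², D̂)/D̂² + σ̂² Var(D̂)/D̂³,

with the required variance, third central moment and excess kurtosis of
the group-frequency distribution evaluated in closed form under the
Beta (Balding–Nichols) model at the plug-in estimates (μ̂, F̂). The
correction vanishes smoothly at F̂ = 0 and is skipped when the floored
numerator is exactly zero; the final estimate is clipped to [0, 1].
Degenerate anchors are preserved exactly: identical group frequencies
give 0, groups fixed at 0 and 1 give 1.

Validated by simulation at G = 3, n_g = 270, p̄ = 0.4 (the
`recover` harness): mean bias is about −0.001, −0.002 and −0.010 at
generating F of 0.05, 0.15 and 0.30, versus −0.011, −0.042 and −0.087
for the naive estimator. Note the corrected estimate typically *exceeds*
the naive one — the two answer different questions (process inference
vs. sample description) — and with only three groups its replicate-level
variance is necessarily large (RMSE ≈ 0.2 at F = 0.3); the correction
fixes the mean, not the spread. A delete-one-group jackknife was
evaluated as an alternative and rejected: at G = 3 it overshoots,
interacts badly with the [0, 1] clipping and roughly doubles the
variance.

The corrected estimator requires `n_g ≥ 2` everywhere (default group
eligibility threshold is 1 for the naive estimator, 2 for the
corrected); groups below threshold are excluded with a logged warning,
and fewer than two eligible groups is an error.

**Permutation test.** Group labels are permuted over growers with
non-missing responses for that practice; the between-group sum of
squares (a monotone transform of F_ST, since the total variance is
permutation-invariant) is the test statistic, and the p-value uses the
add-one correction `(1 + #{stat_perm ≥ stat_obs}) / (1 + n_perm)`, which
is valid for any number of permutations. Ties are counted as exceedances
(comparison with a 1e−12 slack against float noise). Calibration is
checked at 3 groups × 30 growers, p = 0.4, 500 datasets × 200
permutations — sizes chosen to keep the check fast while leaving the
statistic effectively continuous; the measured null rejection rate at
α = 0.05 is ≈ 0.044–0.048.

**Missingness policy.** Per-practice pairwise deletion: a grower is
excluded only for the practices they did not answer; an expert is
excluded from a practice's net-cost mean if either the cost or the
private-benefit item is missing, and from the public mean if the public
item is missing. `min_raters` (default 3) guards against practices with
too few usable experts.

## Synthetic data

`generate_study` emulates the two surveys at the study's scale
(defaults: 3 groups of 274 growers = 822, 44 practices, 120 experts).
Per practice: group frequencies from the Beta construction
(Beta(p̄(1−F)/F, (1−p̄)(1−F)/F), mean p̄, variance F·p̄(1−p̄); F = 0
degenerates to all groups at p̄), grower indicators as independent
Bernoulli draws, Likert items as rounded, clamped normal draws with a
shared σ (default 1.5 — roughly one scale step of spread, typical of
7-point expert panels), and completely-at-random missingness at a
single rate (default 0.02, a token level of item non-response) applied
to both adoption cells and rating items. When per-practice parameters
are not supplied they are drawn once from the master seed with grand
means spanning [0.2, 0.8], targets [0.01, 0.4] and Likert means [2, 6],
covering the qualitative range of interest.

Seed policy: one master seed; every (sampler, practice) pair derives its
own stream via `SeedSequence(seed, spawn_key=(stream, practice))`, so
adding a practice never perturbs earlier practices' draws and all
outputs are pure functions of the config.

What the generator does *not* emulate: spatially or environmentally
structured adoption, network-based social learning, informative
(non-random) missingness, ordinal-logit Likert response styles, or
correlated practices. Passing recovery and calibration tests therefore
shows the estimators behave correctly under the stated sampling model,
not that real surveys satisfy that model.

## Numerical choices

- Estimates are clipped to [0, 1]; the corrected numerator is floored at
  0 before the ratio is formed.
- The Beta-moment evaluation clips F̂ into [1e−12, 1 − 1e−9] to avoid
  degenerate shape parameters; both ends are continuous limits.
- The boundary curve is drawn on F_ST ∈ [0.02, 1.0] with 200 points
  (the threshold explodes below 0.02 and would dominate the axis);
  practices with F_ST = 0 are listed in the table but omitted from the
  scope figure with a logged notice, since their threshold is infinite.
- The cost–benefit figure scales marker *area* linearly with F_ST with
  a small floor so F_ST = 0 practices stay visible.
- Scope tables are written with 17 significant digits so a write/read
  round trip is lossless for float64.
- Validation problem sizes (500 replicates for recovery, 500 × 200 for
  permutation calibration, 1000 instances for the oracle identity) keep
  the whole validation suite in the tens of seconds while making the
  Monte-Carlo error small against the tolerances checked.

## Known limitations

- With G = 3 groups any estimate of superpopulation differentiation has
  large replicate variance; per-practice corrected estimates should be
  read as bias-reduced, not precise.
- The equal-weight option breaks the exact oracle identity (which holds
  for size weights); it is provided for design questions, not for the
  variance-decomposition interpretation.
- The permutation test assumes exchangeability of growers across groups
  under the null; clustered sampling within regions would invalidate it.
- No hierarchical F-statistics, no multi-allelic traits, no bootstrap
  confidence intervals, no forward-time selection dynamics.
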