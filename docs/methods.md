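# Methods

This note documents the generative model, the nine inference procedures,
the numerical choices, and the limits of what the simulations can show.

## Data-generating process

Each replication draws a fresh design (random-X): predictors are i.i.d.
standard normal; in two-predictor models the second predictor is mixed to
population correlation r = 0.10 via a Cholesky step. The outcome is
`y_i = x_iᵀβ + u_i σ_i` with true coefficients (intercept first) of
(0, 0), (0, 0.8), (0, 0, 0.3) or (0, 0.8, 0.3) for models 1–4.

**Non-normal errors.** `u` is a Fleishman power-method variate: a cubic
polynomial `a + bZ + cZ² + dZ³` of a standard normal Z whose coefficients
solve four moment equations (mean 0, variance 1, target skewness and excess
kurtosis). The solver starts from a heuristic point, retries from two
fallbacks, and always reports the `b > 0` branch; the mirrored solution
`(−b, c, −d)` has identical first four moments, so the choice is a
convention, not a constraint. Feasibility requires excess kurtosis
≥ skew² − 2; infeasible targets raise immediately. Residual tolerance is
1e−10 on all three equations.

**Constrained sampling.** Each replication's u-vector is redrawn until its
empirical moment-based skewness g₁ = m₃/m₂^{3/2} and excess kurtosis
g₂ = m₄/m₂² − 3 both land inside per-distribution bounds: [−1, 1] × [−1, 1]
(normal), [1, 3] × [6, 8] (moderate, targets 2/7), [2, 4] × [19, 23]
(severe, targets 3/21). The estimators are the plain moment versions
without small-sample bias correction; the choice is isolated in
`sample_skew_kurtosis` and swappable. Acceptance rates vary enormously:
near 1 for the normal condition at n ≥ 100, ~4% for moderate at n = 25,
~0.2% for severe at n = 50, and 0 (within a 10,000-attempt cap) for severe
at n = 25 — which is why that cell is excluded from the design rather than
special-cased. The attempt cap turns a would-be infinite loop into a
diagnosable error; attempts per accepted draw are recorded.

**Heteroskedasticity.** `σ_i = exp(g · x_het,i / 2)`, i.e. error variance
`exp(g · x_het,i)`; the square root is taken because the design specifies
the variance function. g = 0 reduces exactly to the homoskedastic model.
`x_het` is the predictor of interest in models 1–2 and the other predictor
in models 3–4, which is what separates "the SE for β₁ is wrong" from "the
errors are heteroskedastic but β₁'s SE is nearly fine".

## Inference procedures

All methods target the slope of the first predictor (index 1), two-sided at
α = .05; CI methods also record whether the interval covers the truth.

- **Classical.** `SE² = σ̂²[(XᵀX)⁻¹]₁₁`, σ̂² = RSS/(n−p); t and CI from
  t(n−p). The fit itself uses a QR decomposition, but (XᵀX)⁻¹ is
  materialized because the classical and sandwich formulas consume it.
- **HC3 / HC4.** Sandwich covariance with weights `r_i²/(1−h_ii)²` (HC3) or
  `r_i²/(1−h_ii)^{δ_i}`, `δ_i = min(4, n h_ii/p)` (HC4). The reference
  distribution is t(n−p), matching the convention of comparing these
  statistics against the t-distribution with the model's residual degrees
  of freedom; the study's own test-statistic archives show the HC t under
  severe violations is, if anything, lighter-tailed than t(n−p), so a
  normal reference would only make the tests more liberal. Leverages within
  1e−12 of 1 raise rather than silently blowing up a weight.
- **Pairs bootstrap.** n cases resampled with replacement, OLS refit per
  draw; fits are batched through the normal equations. Numerically singular
  resamples are redrawn (cap 100 per slot) — with continuous predictors
  this is a measure-zero event, but the guard keeps n = 25 runs alive.
- **Wild bootstrap.** `y*_i = ŷ_i + r_i/(1−h_ii)·v*_i` with Rademacher
  signs; X never changes, so all B draws reduce to one matrix product. The
  `1/(1−h_ii)` transform is the deleted-residual (HC3-flavoured) variant.
- **Bootstrap p-value.** `p = (#{t*_b² ≥ t²}+1)/(B+1)` with t the original
  classical statistic. Each draw is studentized by its own refit's
  conventional SE (bootstrap-t). This reading was chosen over a pooled
  denominator (one SD of all B coefficients) on two grounds: the
  per-resample definition is the one under which the resampled t*
  distribution inherits the original statistic's scale inflation, making
  the procedure robust rather than a relabelled classical test; and only
  this reading reproduces the documented qualitative behaviour of the pairs
  p-value (HC-like rates under heteroskedasticity, distinctly conservative
  rates under homoskedastic non-normality). The pooled variant remains
  available via `bootstrap_p_value(..., denominator="pooled")`.
- **Percentile CI.** Order statistics at 2.5%/97.5% read with the Weibull
  plotting position (index (B+1)q, linear interpolation). Software differs
  in this dialect; the effect is O(1/B) and the `method` argument accepts
  any numpy quantile dialect.
- **BCa CI.** Efron's interval: bias term `z₀ = Φ⁻¹(#{β* < β̂}/B)`,
  acceleration from the jackknife skewness of leave-one-out slopes
  (computed exactly via the rank-one downdate
  `β(−i) = β̂ − (XᵀX)⁻¹x_i r_i/(1−h_ii)`), adjusted levels mapped through
  Φ, bounds read from the same bootstrap distribution. Degenerate corners:
  if every β* falls on one side of β̂, the bias fraction is clamped half a
  count from the edge and the replication flagged (not fatal — long runs
  keep going and flags are counted, with a 1%-of-replications abort
  threshold); a zero jackknife spread falls back to the plain percentile
  interval, flagged.

## Harness and reproducibility

Replication i of a scenario uses the RNG substream `default_rng([seed, i])`,
so any single replication is reproducible in isolation and aggregates are
independent of execution order. Each scenario solves its Fleishman
coefficients once. Both bootstrap schemes share one resampling pass per
replication across their three inference modes, mirroring how a single
bootstrap run is read out three ways in practice. Bootstrap distributions
are discarded after each replication; only summaries are retained.

Aggregates per scenario × method: rejection rate, coverage rate (CI
methods), mean and SD of the slope estimates (the SD is the "simulated SE"
benchmark), mean estimated SE (classical/HC only), flagged-replication
count, and mean rejection-sampling attempts. For a true null slope, a CI
method's reject flag equals the complement of its covers flag replication
by replication — this identity is asserted in tests.

## Classification and tables

Rejection rates under true nulls are graded against Bradley's stringent
[0.9α, 1.1α] and liberal [0.5α, 1.5α] bands, coverage against
[.945, .955] / [.925, .975], power against .80/.90. Band edges are
inclusive of the tighter class (with a 1e−12 float guard). The guidance
tables collapse "heteroskedastic" over g ∈ {0.5, 1, 2} and "non-normal"
over the moderate and severe shapes, and list each method at the worst
class it attains across the collapsed sub-scenarios — a listing therefore
guarantees the class over the whole cell. The collapsing rule is a genuine
design choice (a majority rule would read better but guarantee less) and is
kept worst-case.

## Problem sizes

Defaults follow the full design (10,000 replications, B = 1,000). The
analysis drivers and the reproduction script scale selected dimensions
down — analytic-SE scenarios run at 5,000–10,000 replications, bootstrap
scenarios at ~1,000 replications × B = 1,000 — chosen so the whole
reproduction completes in minutes on one CPU while keeping the Monte-Carlo
SE of a rate near 0.3–1 percentage point. Tolerances in the end-to-end
tests are ~3 Monte-Carlo SEs at the stated replication count, widened by
0.01 where a result depends on the constrained-sampling dialect.

## What the generator does and does not emulate

The generator reproduces the factorial study conditions: exponential
single-predictor variance functions, Fleishman-shaped i.i.d. errors,
normal predictors with fixed small correlation, random-X sampling. It does
not emulate measurement error in predictors, dependent errors, butterfly or
non-monotone variance patterns, heavy-tailed symmetric error families, more
than two predictors, or fixed-X designs. Conclusions from passing tests
therefore speak to these specific violation shapes; distributions outside
the Fleishman feasible region (e.g. high skew with modest kurtosis) are not
representable here at all.

## Known limitations

- The severe error shape at n = 25 is unreachable under constrained
  sampling by construction; the framework raises rather than substituting
  a different shape.
- The percentile/BCa bounds depend on the quantile dialect at O(1/B);
  cross-software comparisons should fix the dialect first.
- The BCa implementation is the standard Efron construction; software
  packages differ in small details of the acceleration estimator, which
  can shift borderline rejection rates by a point or two at B = 1,000.
- Unconstrained sampling (the robustness-check switch) is supported but
  its results are not part of the standard summaries.
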