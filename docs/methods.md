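# Methods

## The problem

Multiple imputation (MI) fills each missing value with m draws from a
predictive model, analyzes the m completed datasets, and pools estimates
with Rubin's rules. The two-sample Kolmogorov–Smirnov (KS) test has been
proposed as an automated screen for imputation-model misspecification:
compare the observed values of an incompletely observed variable with its
imputed values and flag small p-values. `ksdiag` implements that protocol
and a factorial Monte Carlo study that measures whether the flags track
actual estimation error (bias/RMSE of a regression coefficient of
interest) — they largely do not, because under missingness-at-random the
imputed distribution is *supposed* to differ from the observed one.

## Data-generating model

Each replicate draws a covariate X of size n = 500 from a skew-t
distribution and an outcome Y = βX + e with β = 1 and e ~ N(0, 1).

- **Skew-normal**: density 2φ(z)Φ(αz). Sampling uses the exact
  representation Z = δ|U₀| + √(1−δ²)U₁ with δ = α/√(1+α²) and U₀, U₁
  independent standard normals. This is rejection-free, so the number of
  uniforms consumed per variate is fixed — important for reproducible
  substreams.
- **Skew-t(α, υ)**: Z/√(W/υ) with W ~ χ²(υ) independent of Z. The
  chi-square is scaled by its degrees of freedom, so α = 0 recovers the
  ordinary Student t, and (α=0, υ=1000) is indistinguishable from N(0,1)
  at the study's sample sizes — the *null* (correctly specified) scenario.
- X is used exactly as constructed (no centering or rescaling before
  forming Y), so increasing α changes both the shape *and* the spread of X;
  at α = 5 the variance of X is roughly 0.39 versus 1 at α = 0, which by
  itself inflates the sampling SD of the slope. The rise of RMSE with α
  therefore combines imputation-model misspecification with this scale
  effect; the study design treats the cell as a whole.

Design grid: α ∈ {0, 2, 5} (none / moderate / strong skew), υ ∈ {3, 1000}
(heavy / light tails).

## Missingness mechanisms

Missingness is imposed on X only; Y is always complete.

- **MCAR**: exactly round(n·p) positions masked by simple random sampling
  without replacement. The exact-count design fixes the observed/missing
  split, which stabilizes the KS sample sizes across replicates.
- **MAR**: logit p(X missing) = ζ + ηY, masked by independent Bernoulli
  draws. η = 0.2 ("mild", exp(0.2) ≈ 1.22, a 22% odds increase per unit Y)
  or η = 1 ("strong", exp(1) ≈ 2.72-fold odds). The intercept ζ is
  calibrated on each replicate's realized y by bisection on ζ ∈ [−50, 50]
  until the mean of expit(ζ + ηy) is within 10⁻⁸ of the target, so the
  *expected* missing fraction equals the target while the realized fraction
  varies. Per-replicate calibration (rather than one population ζ per
  scenario) keeps each replicate self-contained and reproducible from its
  own substream; at n = 500 the two choices differ negligibly.

Target rates: 20%, 50%, 80%. A Bernoulli mask leaving fewer than 3
observed values (possible in principle at 80%) signals the driver to redraw
the whole replicate on the next attempt substream; redraws are counted and
reported per scenario. No MNAR mechanisms are provided.

## Imputation and pooling

With one incomplete continuous variable, joint multivariate-normal
imputation is identical to univariate Bayesian linear-regression imputation
of X on Y, so the engine draws directly from the exact posterior under the
standard noninformative prior (flat on the coefficients and log σ):

1. fit OLS of observed x on (1, y): coefficients β̂, residual sum RSS,
   ν = n_obs − 2;
2. σ²\* = RSS / χ²(ν);
3. (a\*, b\*) ~ N(β̂, σ²\*(Z′Z)⁻¹);
4. each missing x ← a\* + b\*y + σ\*ε, ε ~ N(0,1).

Exact draws sidestep MCMC burn-in and convergence checks and are
distributionally equivalent to data-augmentation implementations of the
same model. Imputed values are not truncated or rounded. m = 20 by
default.

The target analysis is OLS of Y on X per completed dataset (closed-form
simple regression; cross-checked against statsmodels in the tests). Rubin's
rules pool the m slopes: q̄ = mean, W = mean sampling variance, B = sample
variance of the slopes, T = W + (1 + 1/m)B, with classical degrees of
freedom (m−1)(1 + W/((1+1/m)B))², infinite when B = 0. The small-sample
(Barnard–Rubin) df adjustment is omitted: at n = 500 and 20% missing the
classical df are in the hundreds and the adjustment is immaterial; 95%
interval coverage in the null MCAR scenario is verified at 94–95% over
1000 replicates.

## The KS diagnostic

Within each imputation j, the test compares the full observed-x vector
(n_obs values, identical across j) with that imputation's drawn values
(n_mis values). D = sup|F_obs − F_imp| is computed exactly over the pooled
order statistics, handling ties with no continuity correction. The p-value
is the asymptotic Kolmogorov series Q(λ) = 2Σ(−1)^{k−1}exp(−2k²λ²) at
λ = √n_e·D, n_e = n_obs·n_mis/(n_obs+n_mis), truncated when terms fall
below 10⁻¹² and clamped to [0, 1]. No finite-sample correction is applied
(scipy's `ks_2samp` asymptotic mode adds one; the tests compare against
scipy's uncorrected `kolmogorov` function). At the study's sample sizes
(≥ 100 per side) the asymptotic approximation is comfortably adequate; the
method is recorded in each result so CSV reports are self-describing.

The m p-values are summarized by the median (headline — the p-values are
highly skewed), with min, max and the fraction below a threshold (default
0.05) alongside. Alternatives provided for comparison: a single pooled
test of observed versus all m·n_mis imputed values (inflates the effective
sample size with m — demonstrated in a test); mean/variance discrepancy
flags (|mean difference| > 2 SD_obs, variance ratio outside [0.5, 2]); and
flagging the fraction of variables with the smallest p-values (ties broken
by name for determinism).

## Simulation driver and seeding

A scenario cell is (α, υ, mechanism, p) plus n, m, reps and a global seed.
Each cell derives a root entropy as CRC-32 of its sorted label string;
replicate r, attempt a uses `SeedSequence([seed, crc, r, a])`. Consequences:
any cell or single replicate can be rerun in isolation bit-identically,
row order never affects results, and regeneration after a degenerate mask
cannot disturb later replicates.

Per scenario the driver reports bias δ (mean pooled slope − β), the
empirical SD of the pooled slope, RMSE = √(δ² + SD²) (an exact identity by
construction, asserted for every row), and medians over replicates of the
per-replicate p-value summaries. The full per-replicate table is retained
and written alongside, so all summaries are recomputable without
re-simulation.

## Problem sizes

The defaults are the study conditions: n = 500, m = 20, 1000 replicates,
and the 54-cell factorial. One thousand replicates of a cell take about
two seconds on one core (the whole pipeline is vectorized over draws and
imputations), so the full grid at 1000 replicates is a few-minute run. The
test suite exercises the reference scenarios at the full 1000 replicates
and the complete factorial at 200 replicates, which preserves every
qualitative ordering of interest; examples use 100-replicate slices.

## What the generator does and does not emulate

The synthetic data match the evaluation design: a single incomplete
continuous covariate, a fully observed outcome, linear relation, known
true β. Real applications differ in ways that make the diagnostic *harder*
to interpret, not easier: many incomplete variables (multiple testing),
mixed types and semi-continuous scales, imputation models with auxiliary
variables, and unknown truth. Passing tests here show the protocol and its
failure modes under controlled conditions; they do not certify the KS
screen for production imputation pipelines — indeed the central result is
that the screen conflates mechanism with misspecification.

## Numerical and design notes

- Calibration tolerance 10⁻⁸ on the mean missingness probability;
  bisection bracket ±50 on the logit scale; at most 200 iterations
  (unreachable for finite y).
- `fit_ols` refuses constant x (zero spread) and fewer than 3 points;
  the imputer refuses constant observed y — both raise a dedicated
  degenerate-design error rather than returning NaNs.
- One spec-level tension is resolved in favor of usability: the pooled
  diagnostic accepts a single imputation (where it coincides with the
  per-imputation test), while Rubin pooling requires m ≥ 2.
- The reported odds factor for η = 1 is exp(1) ≈ 2.72; descriptions of
  this as a "2.8-fold" increase round inconsistently, and no attempt is
  made to force that figure.
- The "50% paradox" — median KS p-values dipping at 50% missing relative
  to 20% and 80% — is a power phenomenon: at fixed n the 50:50
  observed:imputed split maximizes n_e, so the KS test detects a given
  distributional difference most easily there. It therefore appears in
  every cell where observed and imputed genuinely differ (all MAR cells;
  MCAR with α > 0, where the normal imputation model is misspecified) and
  is asserted there in the tests. In the MCAR null cell there is no
  difference to detect, p-values are near-uniform at every split, and no
  stable ordering exists (checked at 1000 replicates: medians ≈
  0.54/0.57/0.55 at 20/50/80%).
- Under MCAR the *median* KS p-values sit slightly above 0.5 and the
  α = 0 cells are not flagged; the diagnostic behaves as intended only in
  this regime.

## Known limitations

- Single-covariate setting only: no chained equations, no multivariate or
  binary imputation, no truncation/rounding rules for bounded scales.
- The asymptotic p-value is anti-conservative for very small samples
  (n_e < ~20); the CLI accepts arbitrary CSVs, so reports include the
  method label, but no exact-distribution fallback is implemented.
- Posterior-predictive checking and cross-validation diagnostics are out
  of scope.
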