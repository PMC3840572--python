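# ksdiag

**Kolmogorov–Smirnov diagnostics for multiple imputation, evaluated by
simulation.**

Multiple imputation (MI) replaces each missing value with *m* > 1 draws from
a predictive distribution, analyzes each completed dataset, and pools the
results with Rubin's rules. Checking whether the imputation model is
adequate is hard; one proposed screen is the two-sample Kolmogorov–Smirnov
(KS) test comparing the distribution of observed values with the
distribution of imputed values, flagging variables with small p-values.

`ksdiag` implements that diagnostic protocol and the Monte Carlo machinery
to evaluate it: does a small KS p-value actually indicate a problem with MI
inference? The library lets you reproduce the central finding — under
missingness that depends on an observed outcome (MAR), imputed values
*should* differ from observed ones, so the KS test flags even perfectly
calibrated imputations — and explore its sensitivity to skewness, tail
weight, the missingness mechanism and the missing-data fraction.

## What's inside

- **`ksdiag.skewt`** — covariate generation: skew-normal draws via the
  exact representation `Z = δ|U₀| + √(1−δ²)U₁` with `δ = α/√(1+α²)` (density
  `2φ(z)Φ(αz)`), skew-t draws `Z/√(W/υ)` with `W ~ χ²(υ)`, and the outcome
  model `Y = βX + e`, `e ~ N(0, σ²)`.
- **`ksdiag.missingness`** — MCAR masking (exact count, without
  replacement) and MAR masking via `logit p(X missing) = ζ + ηY`, with ζ
  calibrated by bisection so the expected missing fraction hits the target.
- **`ksdiag.mi`** — proper Bayesian regression imputation of X given Y
  (exact posterior draws under the uniform prior: `σ²* ~ RSS/χ²(n−2)`,
  coefficients from `N(β̂, σ²*(Z'Z)⁻¹)`), per-imputation OLS, and Rubin's
  rules: `q̄ = mean(q̂ⱼ)`, `T = W + (1 + 1/m)B`.
- **`ksdiag.diagnostics`** — the exact two-sample KS statistic
  `D = sup|F_obs − F_imp|` with the asymptotic Kolmogorov p-value
  `Q(√n_e·D)`, the m-p-value summarization protocol (min / median / max /
  fraction below a threshold), a pooled-imputations variant, and the
  mean/variance-discrepancy and most-extreme-fraction flagging rules.
- **`ksdiag.simulate`** — the factorial driver: 3 skewness levels × 2 tail
  weights × 3 mechanisms × 3 missing fractions, with per-scenario and
  per-replicate seeded substreams so every cell reruns bit-identically in
  isolation.

## Worked example

```python
import numpy as np
from ksdiag import (GenerationConfig, MissingnessSpec, generate_dataset,
                    impose_mar, impute_normal, fit_ols, rubin_pool, diagnose)

rng = np.random.default_rng(2)
data = generate_dataset(GenerationConfig(n=500), rng)           # X ~ N(0,1), Y = X + e
masked = impose_mar(data, MissingnessSpec.mar_strong(0.2), rng) # high-Y rows lose X
imps = impute_normal(masked, m=20, rng=rng)                     # proper imputation
pooled = rubin_pool([fit_ols(imps.completed_x[j], imps.y) for j in range(20)])
summary = diagnose(imps, threshold=0.05)
print(pooled.qbar, summary.p_median, summary.prop_below)
```

Running `python examples/ks_diagnostic.py` (same scenario) prints:

```
MCAR: median KS p = 5.18e-01  (min 2.19e-01, max 9.88e-01; 0% of 20 below 0.05)
MAR strong: median KS p = 2.81e-10  (min 1.15e-13, max 2.66e-06; 100% of 20 below 0.05)
```

Both runs impute a genuinely normal covariate with a correctly specified
normal model; only the missingness mechanism differs. Under MCAR the
observed and imputed distributions agree and the median p-value is
unremarkable. Under strong MAR the deleted X values came from high-Y rows,
the imputations correctly reconstruct that shifted distribution, and every
single KS test "flags" — a failure of the diagnostic, not of the
imputation. `examples/mini_grid.py` extends this to a slice of the full
factorial, showing RMSE rising with skewness while the KS p-values track
the mechanism instead of the error.

## Command line

```sh
ksdiag simulate --mechanism mcar --mechanism mar-strong --prop 0.2 \
    --reps 200 --seed 0 --out results/    # scenarios.csv + replicates.csv
ksdiag diagnose imputations.csv            # long format: imp,row,x,y,was_missing
ksdiag diagnose --observed obs.csv --imputed imp1.csv --imputed imp2.csv \
    --pooled --stuart --extreme-fraction 0.1
```

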