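"""A desk-scale slice of the factorial simulation study.

Runs the light-tailed (df=1000) MCAR and MAR-strong cells at 20% missing
across the three skewness levels, 100 replicates each, and prints the
metrics that drive the study's conclusions: RMSE of the pooled slope rises
with skewness (the imputation model is normal, the data are not), while the
median KS p-value collapses under MAR regardless of whether the estimate is
biased.
"""

from ksdiag import ScenarioSpec, run_scenario

print(f"{'mechanism':>11} {'alpha':>5} {'bias':>8} {'rmse':>7} {'median KS p':>12}")
for mechanism in ("mcar", "mar-strong"):
    for alpha in (0.0, 2.0, 5.0):
        spec = ScenarioSpec.from_labels(
            alpha=alpha, df=1000.0, mechanism=mechanism, prop=0.2,
            n=500, m=20, reps=100, seed=0,
        )
        m = run_scenario(spec).metrics
        print(f"{mechanism:>11} {alpha:>5.0f} {m.bias:>8.4f} {m.rmse:>7.4f} "
              f"{m.ks_median_of_medians:>12.2e}")
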