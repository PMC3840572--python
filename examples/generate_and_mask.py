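"""Generate a skewed covariate, impose outcome-dependent missingness.

Draws X from a skew-t distribution with moderate skewness, forms the linear
outcome Y = X + noise, then deletes X values with probability that rises
with Y (logit p = zeta + eta*Y), calibrating the intercept zeta to hit a
20% missing rate.
"""

import numpy as np
from scipy.special import expit

from ksdiag import (
    GenerationConfig,
    MissingnessSpec,
    SkewTSpec,
    calibrate_zeta,
    generate_dataset,
    impose_mar,
    odds_scale,
)

rng = np.random.default_rng(0)

config = GenerationConfig(n=500, beta=1.0, skewt=SkewTSpec(alpha=2.0, df=1000.0))
data = generate_dataset(config, rng)
print(f"covariate: n={data.n}, mean={data.x.mean():.3f}, skew to the right")

spec = MissingnessSpec.mar_strong(target_prop=0.2)
zeta = calibrate_zeta(data.y, spec.eta, spec.target_prop)
print(f"calibrated zeta = {zeta:.4f} so that mean expit(zeta + {spec.eta}*y) = 0.2")
print(f"odds of missingness multiply by {odds_scale(spec.eta):.3f} per unit Y")

masked = impose_mar(data, spec, rng)
print(f"realized missing fraction: {masked.realized_prop:.3f} ({masked.n_missing} of {data.n})")
gap = data.y[masked.mask].mean() - data.y[~masked.mask].mean()
print(f"mean Y among missing minus observed: {gap:.3f}  (positive: high-Y rows vanish)")
print(f"check: mean predicted prob = {expit(zeta + spec.eta * data.y).mean():.6f}")
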