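"""Missingness mechanisms for the covariate X.

Two mechanisms are supported:

* **MCAR** — missing completely at random: an exact count round(n*p) of
  entries is masked by simple random sampling without replacement, so the
  observed/missing split is fixed at the target rate.
* **MAR** — missing at random, depending on the fully observed outcome
  through the logistic model  logit p(X missing) = zeta + eta*Y.  Each entry
  is masked by an independent Bernoulli draw, so the realized proportion
  varies around the target.  The intercept zeta is calibrated empirically on
  the realized outcome vector so that the *expected* missing fraction equals
  the target.

The study grid uses eta = 0.2 ("MAR mild", a 22% odds increase per unit Y)
and eta = 1 ("MAR strong"), at target rates 20%, 50% and 80%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .skewt import Dataset

__all__ = [
    "MissingnessSpec",
    "MaskedDataset",
    "DegenerateMaskError",
    "calibrate_zeta",
    "impose_mcar",
    "impose_mar",
    "impose_missingness",
    "odds_scale",
]

#: Minimum observed X values required downstream (imputation model residual df).
MIN_OBSERVED = 3

_ZETA_BRACKET = 50.0
_CALIBRATION_TOL = 1e-8
_MAX_BISECT = 200


class DegenerateMaskError(RuntimeError):
    """Raised when a Bernoulli mask leaves fewer observed values than usable.

    Callers running replicated simulations should treat this as a signal to
    redraw the replicate on a fresh substream rather than abort.
    """


@dataclass(frozen=True)
class MissingnessSpec:
    """Mechanism, dependence strength and target rate of missingness in X.

    Parameters
    ----------
    mechanism : {"mcar", "mar"}
        Missingness model.  ``eta`` and ``zeta`` are ignored under MCAR.
    target_prop : float
        Intended fraction of X missing, strictly between 0 and 1.
    eta : float
        Log-odds increase in the probability of missingness per unit
        increase in Y (0 under MCAR).
    zeta : float or None
        Logistic intercept.  ``None`` means "calibrate on the sample at
        masking time"; a number fixes it.
    """

    mechanism: str
    target_prop: float
    eta: float = 0.0
    zeta: float | None = None

    def __post_init__(self) -> None:
        if self.mechanism not in ("mcar", "mar"):
            raise ValueError(f"mechanism must be 'mcar' or 'mar', got {self.mechanism!r}")
        if not 0.0 < self.target_prop < 1.0:
            raise ValueError(f"target_prop must be in (0, 1), got {self.target_prop}")

    @classmethod
    def mcar(cls, target_prop: float) -> "MissingnessSpec":
        return cls(mechanism="mcar", target_prop=target_prop)

    @classmethod
    def mar_mild(cls, target_prop: float) -> "MissingnessSpec":
        """MAR with eta = 0.2: 22% higher odds of missingness per unit Y."""
        return cls(mechanism="mar", target_prop=target_prop, eta=0.2)

    @classmethod
    def mar_strong(cls, target_prop: float) -> "MissingnessSpec":
        """MAR with eta = 1: e-fold (~2.7x) higher odds per unit Y."""
        return cls(mechanism="mar", target_prop=target_prop, eta=1.0)


@dataclass(frozen=True)
class MaskedDataset:
    """A dataset plus the boolean missingness indicator for X (True = missing)."""

    data: Dataset
    mask: np.ndarray
    realized_prop: float

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", mask)
        if mask.shape != self.data.x.shape:
            raise ValueError("mask must match the data length")
        n_obs = int((~mask).sum())
        if n_obs < MIN_OBSERVED:
            raise DegenerateMaskError(
                f"only {n_obs} observed X values remain; need at least {MIN_OBSERVED}"
            )
        if self.realized_prop != mask.sum() / mask.size:
            raise ValueError("realized_prop must equal the exact masked fraction")

    @property
    def n(self) -> int:
        return self.data.n

    @property
    def n_missing(self) -> int:
        return int(self.mask.sum())

    @property
    def n_observed(self) -> int:
        return self.n - self.n_missing

    @property
    def x_observed(self) -> np.ndarray:
        return self.data.x[~self.mask]

    def to_frame(self) -> pd.DataFrame:
        x = self.data.x.copy()
        x[self.mask] = np.nan
        return pd.DataFrame({"x": x, "y": self.data.y, "miss": self.mask.astype(int)})

    def to_csv(self, path) -> None:
        """CSV with columns x (empty where masked), y, miss (0/1)."""
        self.to_frame().to_csv(path, index=False)


def odds_scale(eta: float) -> float:
    """Multiplicative change in the odds of missingness per unit increase in Y.

    exp(eta): e.g. eta = 0.2 gives 1.2214, a 22% increase in odds.
    """
    return math.exp(eta)


def calibrate_zeta(y: np.ndarray, eta: float, target_prop: float) -> float:
    """Solve for the logistic intercept hitting the target missingness rate.

    Finds zeta such that mean_i expit(zeta + eta*y[i]) = target_prop to
    within 1e-8.  The mean probability is strictly increasing in zeta, so a
    plain bisection on [-50, 50] converges for any finite outcome vector.
    """
    if not 0.0 < target_prop < 1.0:
        raise ValueError(f"target_prop must be in (0, 1), got {target_prop}")
    y = np.asarray(y, dtype=float)

    def mean_prob(zeta: float) -> float:
        return float(np.mean(expit(zeta + eta * y)))

    lo, hi = -_ZETA_BRACKET, _ZETA_BRACKET
    for _ in range(_MAX_BISECT):
        mid = 0.5 * (lo + hi)
        diff = mean_prob(mid) - target_prop
        if abs(diff) <= _CALIBRATION_TOL:
            return mid
        if diff < 0.0:
            lo = mid
        else:
            hi = mid
    raise ArithmeticError(
        f"zeta calibration did not reach tolerance {_CALIBRATION_TOL} "
        f"within {_MAX_BISECT} bisections"
    )


def impose_mcar(data: Dataset, target_prop: float, rng: np.random.Generator) -> MaskedDataset:
    """Mask exactly round(n*target_prop) entries of X, chosen uniformly.

    The mask is independent of both x and y.  Raises ``ValueError`` if the
    exact count would leave fewer than three observed values.
    """
    n = data.n
    k = round(n * target_prop)
    if n - k < MIN_OBSERVED:
        raise ValueError(
            f"masking {k} of {n} entries leaves fewer than {MIN_OBSERVED} observed"
        )
    mask = np.zeros(n, dtype=bool)
    if k > 0:
        mask[rng.choice(n, size=k, replace=False)] = True
    return MaskedDataset(data=data, mask=mask, realized_prop=k / n)


def impose_mar(data: Dataset, spec: MissingnessSpec, rng: np.random.Generator) -> MaskedDataset:
    """Mask X by independent Bernoulli draws with logit p = zeta + eta*y.

    If ``spec.zeta`` is None the intercept is calibrated on this sample's y
    so the expected missing fraction equals ``spec.target_prop``.  A draw
    leaving fewer than three observed values raises ``DegenerateMaskError``
    (the caller redraws the replicate).
    """
    if spec.mechanism != "mar":
        raise ValueError(f"impose_mar requires a MAR spec, got {spec.mechanism!r}")
    zeta = spec.zeta
    if zeta is None:
        zeta = calibrate_zeta(data.y, spec.eta, spec.target_prop)
    p = expit(zeta + spec.eta * data.y)
    mask = rng.random(data.n) < p
    return MaskedDataset(data=data, mask=mask, realized_prop=mask.sum() / data.n)


def impose_missingness(
    data: Dataset, spec: MissingnessSpec, rng: np.random.Generator
) -> MaskedDataset:
    """Dispatch to the mechanism named in ``spec``."""
    if spec.mechanism == "mcar":
        return impose_mcar(data, spec.target_prop, rng)
    return impose_mar(data, spec, rng)
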