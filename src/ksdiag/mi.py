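"""Proper normal-model multiple imputation of X given Y, and Rubin pooling.

With a single incomplete continuous variable, joint multivariate-normal
imputation reduces exactly to Bayesian simple linear regression of X on Y.
Each imputation draws the full parameter vector from its posterior under the
standard noninformative (uniform on coefficients and log sigma) prior:

    sigma^2* ~ RSS / chi-square(n_obs - 2)
    (a*, b*) ~ N((a_hat, b_hat), sigma^2* (Z'Z)^{-1})

and then imputes each missing x as a* + b**y + sigma* * eps with standard
normal eps.  Drawing from the exact posterior makes the imputation "proper"
(parameter uncertainty is propagated) without any MCMC burn-in decisions.

The target analysis is OLS of Y on X per completed dataset, pooled by
Rubin's rules: point estimate = mean of the m slopes, total variance
T = W + (1 + 1/m) B with W the mean squared standard error and B the
between-imputation sample variance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .missingness import MIN_OBSERVED, MaskedDataset

__all__ = [
    "ImputationSet",
    "RegressionFit",
    "PooledEstimate",
    "DegenerateDesignError",
    "impute_normal",
    "fit_ols",
    "rubin_pool",
]


class DegenerateDesignError(ValueError):
    """Raised when a regression design is constant (zero spread)."""


@dataclass(frozen=True)
class ImputationSet:
    """m completed versions of X sharing the observed values.

    ``completed_x`` has shape (m, n); all rows agree exactly where ``mask``
    is False.  ``y`` is carried along for per-imputation analysis and export.
    """

    completed_x: np.ndarray
    mask: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        cx = np.asarray(self.completed_x, dtype=float)
        mask = np.asarray(self.mask, dtype=bool)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "completed_x", cx)
        object.__setattr__(self, "mask", mask)
        object.__setattr__(self, "y", y)
        if cx.ndim != 2:
            raise ValueError("completed_x must be a 2-d (m, n) array")
        if cx.shape[0] < 1:
            raise ValueError("need at least one imputation")
        if mask.shape != (cx.shape[1],) or y.shape != (cx.shape[1],):
            raise ValueError("mask and y must have length n")
        obs = cx[:, ~mask]
        if obs.size and not (obs == obs[0]).all():
            raise ValueError("imputations disagree on observed positions")

    @property
    def m(self) -> int:
        return self.completed_x.shape[0]

    @property
    def n(self) -> int:
        return self.completed_x.shape[1]

    @property
    def x_observed(self) -> np.ndarray:
        return self.completed_x[0, ~self.mask]

    def imputed_values(self, j: int) -> np.ndarray:
        """The drawn values of imputation ``j`` (missing positions only)."""
        return self.completed_x[j, self.mask]

    def to_long_frame(self) -> pd.DataFrame:
        """Long interchange format: imp (1..m), row, x, y, was_missing."""
        m, n = self.completed_x.shape
        return pd.DataFrame(
            {
                "imp": np.repeat(np.arange(1, m + 1), n),
                "row": np.tile(np.arange(n), m),
                "x": self.completed_x.ravel(),
                "y": np.tile(self.y, m),
                "was_missing": np.tile(self.mask.astype(int), m),
            }
        )

    def to_csv(self, path) -> None:
        self.to_long_frame().to_csv(path, index=False)

    @classmethod
    def from_long_frame(cls, frame: pd.DataFrame) -> "ImputationSet":
        """Rebuild from the long interchange format written by ``to_csv``."""
        frame = frame.sort_values(["imp", "row"])
        imps = frame["imp"].unique()
        n = frame["row"].nunique()
        cx = frame["x"].to_numpy(float).reshape(len(imps), n)
        first = frame[frame["imp"] == imps[0]]
        return cls(
            completed_x=cx,
            mask=first["was_missing"].to_numpy() > 0,
            y=first["y"].to_numpy(float),
        )


@dataclass(frozen=True)
class RegressionFit:
    """Slope of a simple linear regression with its sampling variance."""

    beta_hat: float
    var_hat: float
    df_resid: int

    def __post_init__(self) -> None:
        if self.var_hat < 0:
            raise ValueError("var_hat must be non-negative")


@dataclass(frozen=True)
class PooledEstimate:
    """Rubin's-rules combination of m per-imputation slope estimates."""

    qbar: float
    W: float
    B: float
    T: float
    df_rubin: float
    m: int

    @property
    def se(self) -> float:
        return math.sqrt(self.T)

    def confidence_interval(self, level: float = 0.95) -> tuple[float, float]:
        """Two-sided t interval on Rubin's degrees of freedom."""
        from scipy.stats import norm, t

        if math.isinf(self.df_rubin):
            crit = norm.ppf(0.5 + level / 2)
        else:
            crit = t.ppf(0.5 + level / 2, self.df_rubin)
        half = crit * self.se
        return self.qbar - half, self.qbar + half


def impute_normal(
    masked: MaskedDataset, m: int, rng: np.random.Generator
) -> ImputationSet:
    """Draw m proper imputations of the missing X values conditional on Y.

    Requires at least three observed X values (two coefficients plus one
    residual df) and non-constant observed Y.
    """
    if m < 1:
        raise ValueError(f"need at least 1 imputation, got {m}")
    x, y, mask = masked.data.x, masked.data.y, masked.mask
    obs = ~mask
    n_obs = int(obs.sum())
    if n_obs < MIN_OBSERVED:
        raise ValueError(f"need at least {MIN_OBSERVED} observed X values, got {n_obs}")

    completed = np.tile(x, (m, 1))
    n_mis = masked.n_missing
    if n_mis == 0:
        return ImputationSet(completed_x=completed, mask=mask, y=y)

    y_obs, x_obs = y[obs], x[obs]
    if np.ptp(y_obs) == 0.0:
        raise DegenerateDesignError("observed y is constant; imputation model is degenerate")

    z = np.column_stack([np.ones(n_obs), y_obs])
    ztz = z.T @ z
    coef_hat = np.linalg.solve(ztz, z.T @ x_obs)
    resid = x_obs - z @ coef_hat
    rss = float(resid @ resid)
    nu = n_obs - 2

    # Posterior draws, vectorized over the m imputations.
    sigma2_star = rss / rng.chisquare(nu, size=m)
    sigma_star = np.sqrt(sigma2_star)
    chol = np.linalg.cholesky(np.linalg.inv(ztz))
    coef_star = coef_hat + sigma_star[:, None] * (rng.standard_normal((m, 2)) @ chol.T)

    y_mis = y[mask]
    eps = rng.standard_normal((m, n_mis))
    completed[:, mask] = (
        coef_star[:, :1] + coef_star[:, 1:] * y_mis[None, :] + sigma_star[:, None] * eps
    )
    return ImputationSet(completed_x=completed, mask=mask, y=y)


def fit_ols(x: np.ndarray, y: np.ndarray) -> RegressionFit:
    """Simple linear regression of y on x with intercept.

    Returns the slope, its classical sampling variance s^2/Sxx, and the
    n - 2 residual degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3 or y.size != n:
        raise ValueError("need equal-length x and y with at least 3 points")
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    if sxx == 0.0:
        raise DegenerateDesignError("x is constant; slope undefined")
    beta = float(xc @ yc) / sxx
    resid = yc - beta * xc
    rss = float(resid @ resid)
    s2 = rss / (n - 2)
    return RegressionFit(beta_hat=beta, var_hat=s2 / sxx, df_resid=n - 2)


def rubin_pool(fits: Sequence[RegressionFit]) -> PooledEstimate:
    """Combine m slope estimates by Rubin's rules.

    qbar = mean estimate; W = mean sampling variance; B = sample variance of
    the estimates; T = W + (1 + 1/m)B.  The degrees of freedom are Rubin's
    classical (m-1)(1 + W/((1+1/m)B))^2, infinite when B = 0.
    """
    m = len(fits)
    if m < 2:
        raise ValueError(f"need at least 2 fits to pool, got {m}")
    q = np.array([f.beta_hat for f in fits], dtype=float)
    u = np.array([f.var_hat for f in fits], dtype=float)
    qbar = float(q.mean())
    w = float(u.mean())
    b = float(q.var(ddof=1))
    t = w + (1.0 + 1.0 / m) * b
    if b == 0.0:
        df = math.inf
    else:
        df = (m - 1) * (1.0 + w / ((1.0 + 1.0 / m) * b)) ** 2
    return PooledEstimate(qbar=qbar, W=w, B=b, T=t, df_rubin=df, m=m)
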