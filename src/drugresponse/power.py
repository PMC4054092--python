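"""Power transformation of the drug-sensitivity phenotype.

Log IC50 panels are typically skewed; before ridge fitting the phenotype is
mapped toward normality with a parametric power transform whose exponent is
chosen by profile maximum likelihood. Two families are supported:

``yeo_johnson``
    Handles negative values natively (log IC50 values from micromolar screens
    are frequently negative); the default.
``boxcox_offset``
    Classic Box-Cox after shifting the phenotype by ``max(0, 1 - min(y))`` so
    every value is at least 1.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, special, stats
from sklearn.base import BaseEstimator

__all__ = [
    "PhenotypePowerTransform",
    "fit_power_transform",
    "apply_power_transform",
    "invert_power_transform",
]

_FAMILIES = ("yeo_johnson", "boxcox_offset")


def _yeojohnson_inverse(z: np.ndarray, lmbda: float) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    pos = z >= 0
    if abs(lmbda) > 1e-12:
        out[pos] = np.power(z[pos] * lmbda + 1.0, 1.0 / lmbda) - 1.0
    else:
        out[pos] = np.expm1(z[pos])
    if abs(lmbda - 2.0) > 1e-12:
        out[~pos] = 1.0 - np.power(1.0 - (2.0 - lmbda) * z[~pos], 1.0 / (2.0 - lmbda))
    else:
        out[~pos] = -np.expm1(-z[~pos])
    return out


class PhenotypePowerTransform(BaseEstimator):
    """Profile-ML power transform of a 1-D phenotype.

    The exponent ``lambda_`` maximizes the normal profile log-likelihood of
    the transformed values over a grid on [-3, 3] with step 0.01, refined by
    bounded scalar optimization between the bracketing grid points.

    Fitted attributes: ``lambda_``, ``offset_`` (box-cox family only, else 0),
    ``loglik_profile_`` (the (lambda, loglik) grid).
    """

    def __init__(self, family: str = "yeo_johnson", min_n: int = 10):
        self.family = family
        self.min_n = min_n

    def _loglik(self, lmbda: float, y: np.ndarray) -> float:
        if self.family == "boxcox_offset":
            return float(stats.boxcox_llf(lmbda, y))
        return float(stats.yeojohnson_llf(lmbda, y))

    def fit(self, y: np.ndarray) -> "PhenotypePowerTransform":
        if self.family not in _FAMILIES:
            raise ValueError(f"family must be one of {_FAMILIES}")
        y = np.asarray(y, dtype=float).ravel()
        if len(y) < self.min_n:
            raise ValueError(f"need at least {self.min_n} observations")
        if not np.all(np.isfinite(y)):
            raise ValueError("phenotype contains non-finite values")
        if np.ptp(y) == 0.0:
            raise ValueError("phenotype is constant; cannot fit a power transform")
        if self.family == "boxcox_offset":
            self.offset_ = float(max(0.0, 1.0 - np.min(y)))
            y_work = y + self.offset_
        else:
            self.offset_ = 0.0
            y_work = y
        grid = np.round(np.arange(-300, 301)) / 100.0
        lls = np.array([self._loglik(l, y_work) for l in grid])
        k = int(np.argmax(lls))
        lo = grid[max(k - 1, 0)]
        hi = grid[min(k + 1, len(grid) - 1)]
        res = optimize.minimize_scalar(
            lambda l: -self._loglik(l, y_work), bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-6},
        )
        refined = float(res.x)
        self.lambda_ = (
            refined if self._loglik(refined, y_work) >= lls[k] else float(grid[k])
        )
        self.loglik_profile_ = np.column_stack([grid, lls])
        return self

    def transform(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        if self.family == "boxcox_offset":
            shifted = y + self.offset_
            if np.any(shifted <= 0.0):
                raise ValueError(
                    "box-cox input must exceed -offset (got value <= "
                    f"{-self.offset_:g})"
                )
            return special.boxcox(shifted, self.lambda_)
        return stats.yeojohnson(y, lmbda=self.lambda_)

    def inverse_transform(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        if self.family == "boxcox_offset":
            return special.inv_boxcox(z, self.lambda_) - self.offset_
        return _yeojohnson_inverse(z, self.lambda_)


def fit_power_transform(
    y: np.ndarray, family: str = "yeo_johnson"
) -> PhenotypePowerTransform:
    """Fit and return a :class:`PhenotypePowerTransform`."""
    return PhenotypePowerTransform(family=family).fit(y)


def apply_power_transform(pt: PhenotypePowerTransform, y: np.ndarray) -> np.ndarray:
    return pt.transform(y)


def invert_power_transform(pt: PhenotypePowerTransform, z: np.ndarray) -> np.ndarray:
    return pt.inverse_transform(z)
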