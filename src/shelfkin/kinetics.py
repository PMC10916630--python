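"""Zero- and first-order storage kinetics.

A quality index C(t) during storage is modelled either as

* zero order:  C0 − C = k·t  (linear drift), or
* first order: ln(C0/C) = k·t  (exponential growth/decay),

and the rate constant k (d⁻¹) is estimated by ordinary least squares on the
linearised form — C on t for order 0, ln C on t for order 1.  k is reported
as a magnitude with a separate ±1 ``direction`` because the same first-order
form is applied both to indices that grow during storage (sedimentation
rate, particle size) and to ones that decay (viscosity, sensory score).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core_io import DomainError, FitError, StorageSeries

logger = logging.getLogger("shelfkin")

#: |Δr²| below which the two orders are considered tied.
_ORDER_TIE_TOL = 1e-9


@dataclass(frozen=True)
class KineticFit:
    """Fitted kinetic model for one storage series.

    ``k`` is the magnitude of the linearised slope (d⁻¹); ``direction`` is
    +1 for a growing index and −1 for a decaying one; ``C0_hat`` is the
    fitted (or fixed) initial value; ``r_squared`` is the coefficient of
    determination of the linearised regression.
    """

    order: int
    k: float
    direction: int
    C0_hat: float
    r_squared: float

    def __post_init__(self) -> None:
        if self.order not in (0, 1):
            raise ValueError(f"order must be 0 or 1, got {self.order}")
        if self.k < 0:
            raise ValueError(f"rate constant must be >= 0, got {self.k}")
        if not -1e-12 <= self.r_squared <= 1 + 1e-12:
            raise ValueError(f"r_squared outside [0, 1]: {self.r_squared}")
        if self.order == 1 and not self.C0_hat > 0:
            raise ValueError(f"first-order C0 must be > 0, got {self.C0_hat}")

    def predict(self, times: np.ndarray) -> np.ndarray:
        """Evaluate the fitted trajectory at the given times (days)."""
        t = np.asarray(times, dtype=float)
        s = self.direction * self.k
        if self.order == 0:
            return self.C0_hat + s * t
        return self.C0_hat * np.exp(s * t)


def _linear_fit(t: np.ndarray, y: np.ndarray, fix_intercept: float | None):
    """OLS of y on t; optionally through a fixed intercept.

    Returns (slope, intercept, r_squared).  With a fixed intercept the slope
    is the least-squares solution of (y − b0) = slope·t and r² is computed
    against the mean of y (clipped at 0).  A constant response is a perfect
    zero-slope fit, so r² = 1 there.
    """
    if np.ptp(t) == 0:
        raise FitError("zero time-variance: all time points identical")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if fix_intercept is None:
        if ss_tot == 0.0:
            return 0.0, float(y[0]), 1.0
        res = stats.linregress(t, y)
        return float(res.slope), float(res.intercept), float(res.rvalue**2)
    slope = float(np.dot(t, y - fix_intercept) / np.dot(t, t))
    if ss_tot == 0.0:
        return slope, fix_intercept, 1.0
    ss_res = float(np.sum((y - (fix_intercept + slope * t)) ** 2))
    return slope, fix_intercept, max(0.0, 1.0 - ss_res / ss_tot)


def fit_rate_constant(series: StorageSeries, order: int, fix_C0: bool = False) -> KineticFit:
    """Fit one kinetic order to a series by linearised least squares.

    With ``fix_C0`` the intercept is pinned to the first measured value (the
    convention in which C0 is treated as known) and only the slope is fit;
    otherwise both are estimated.

    Raises
    ------
    DomainError
        Order 1 requested with non-positive values (log undefined).
    FitError
        Degenerate time design.
    """
    t = series.times
    if order == 0:
        y = series.values
        b0 = series.C0 if fix_C0 else None
        slope, intercept, r2 = _linear_fit(t, y, b0)
        c0_hat = intercept
    elif order == 1:
        if np.any(series.values <= 0):
            raise DomainError(
                f"first-order fit needs strictly positive values "
                f"({series.index_name}@{series.temperature} K)"
            )
        y = np.log(series.values)
        b0 = float(np.log(series.C0)) if fix_C0 else None
        slope, intercept, r2 = _linear_fit(t, y, b0)
        c0_hat = float(np.exp(intercept))
    else:
        raise ValueError(f"order must be 0 or 1, got {order}")
    direction = 1 if slope >= 0 else -1
    fit = KineticFit(order=order, k=abs(slope), direction=direction,
                     C0_hat=c0_hat, r_squared=min(r2, 1.0))
    logger.debug(
        "fit %s@%g K order=%d fix_C0=%s: k=%g dir=%+d r2=%.6f",
        series.index_name, series.temperature, order, fix_C0, fit.k, direction, r2,
    )
    return fit


def select_order(series: StorageSeries, fix_C0: bool = False) -> KineticFit:
    """Fit both orders and return the one with the higher linearised r².

    Ties (|Δr²| < 1e-9) resolve to first order, the form storage-stability
    indices of protein beverages are generally found to follow.
    """
    fit0 = fit_rate_constant(series, 0, fix_C0=fix_C0)
    fit1 = fit_rate_constant(series, 1, fix_C0=fix_C0)
    if abs(fit1.r_squared - fit0.r_squared) < _ORDER_TIE_TOL:
        chosen = fit1
    else:
        chosen = fit1 if fit1.r_squared > fit0.r_squared else fit0
    logger.info(
        "order selection %s@%g K: r2(0)=%.6f r2(1)=%.6f -> order %d",
        series.index_name, series.temperature, fit0.r_squared, fit1.r_squared, chosen.order,
    )
    return chosen
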