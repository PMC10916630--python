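"""Arrhenius and Eyring (transition-state) analysis of storage rate constants.

Given rate constants k(T) for one quality index at several storage
temperatures, this module estimates

* the Arrhenius activation energy Ea from OLS of ln k on 1/T
  (k = A0·exp(−Ea/RT));
* the transition-state parameters at each temperature:

    ΔH* = Ea − R·T
    ΔS* = R·(ln k − ln(k_b/h) − ln T − 1) + Ea/T
    ΔG* = ΔH* − T·ΔS*

* a linear regression of ΔG* (kJ/mol) on T, used downstream to interpolate
  the activation barrier — and hence the rate constant — at any storage
  temperature.

Rate-unit convention
--------------------
The Eyring expression pairs k with k_b/h in SI, so k should strictly be in
s⁻¹.  Storage studies, however, routinely insert the numeric value of k in
d⁻¹ directly; published ΔS*/ΔG* tables for beverage stability are only
reproducible that way.  ``per_day_numeric`` (default) follows that practice;
``per_second_SI`` divides k by 86 400 first for a dimensionally consistent
analysis.  The convention is stamped into every output row.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .core_io import DEFAULT_CONSTANTS, DomainError, FitError, PhysicalConstants

logger = logging.getLogger("shelfkin")

SECONDS_PER_DAY = 86_400.0

CONVENTIONS = ("per_day_numeric", "per_second_SI")


@dataclass(frozen=True)
class ArrheniusFit:
    """Activation energy Ea (J/mol), pre-exponential A0 (d⁻¹), and fit r²."""

    Ea: float
    A0: float
    r_squared: float

    def __post_init__(self) -> None:
        if not self.A0 > 0:
            raise ValueError(f"A0 must be > 0, got {self.A0}")
        if not -1e-12 <= self.r_squared <= 1 + 1e-12:
            raise ValueError(f"r_squared outside [0, 1]: {self.r_squared}")

    def rate_at(self, temperature: float, constants: PhysicalConstants = DEFAULT_CONSTANTS) -> float:
        """k(T) = A0·exp(−Ea/RT), d⁻¹."""
        return self.A0 * np.exp(-self.Ea / (constants.R_gas * temperature))


@dataclass(frozen=True)
class EyringRow:
    """Transition-state parameters for one index at one temperature.

    ΔH* and ΔG* in J/mol, ΔS* in J/(mol·K); ``k`` keeps its d⁻¹ input units
    and ``convention`` records how it entered the Eyring expression.
    """

    temperature: float
    k: float
    Ea: float
    dH: float
    dS: float
    dG: float
    convention: str = "per_day_numeric"


@dataclass(frozen=True)
class GibbsTempFit:
    """OLS of ΔG* (kJ/mol) on temperature (K): slope kJ/(mol·K), intercept kJ/mol."""

    slope: float
    intercept: float
    r_squared: float

    def gibbs_at(self, temperature: float) -> float:
        """Interpolated ΔG* in kJ/mol."""
        return self.slope * temperature + self.intercept


def fit_arrhenius(
    rates: Sequence[tuple[float, float]],
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> ArrheniusFit:
    """OLS of ln k on 1/T; Ea = −slope·R, A0 = exp(intercept).

    Duplicate temperatures with conflicting k are collapsed to their
    geometric mean with a warning.  Any k ≤ 0 is a domain error.
    """
    if any(k <= 0 for _, k in rates):
        raise DomainError("all rate constants must be > 0 for the Arrhenius fit")
    by_T: dict[float, list[float]] = {}
    for T, k in rates:
        by_T.setdefault(float(T), []).append(float(k))
    for T, ks in by_T.items():
        if len(ks) > 1 and np.ptp(ks) > 0:
            warnings.warn(
                f"duplicate temperature {T} K with conflicting k {ks}; "
                f"collapsing to geometric mean", stacklevel=2,
            )
    temps = np.array(sorted(by_T))
    if len(temps) < 2:
        raise FitError(f"need >= 2 distinct temperatures, got {len(temps)}")
    lnk = np.array([np.mean(np.log(by_T[T])) for T in temps])
    if np.ptp(lnk) == 0:
        # temperature-independent rates: zero activation energy, perfect fit
        fit = ArrheniusFit(Ea=0.0, A0=float(np.exp(lnk[0])), r_squared=1.0)
    else:
        res = stats.linregress(1.0 / temps, lnk)
        fit = ArrheniusFit(
            Ea=-float(res.slope) * constants.R_gas,
            A0=float(np.exp(res.intercept)),
            r_squared=float(res.rvalue**2),
        )
    logger.info(
        "arrhenius fit on %d temperatures: Ea=%.4g J/mol A0=%.4g d^-1 r2=%.4f",
        len(temps), fit.Ea, fit.A0, fit.r_squared,
    )
    return fit


def eyring_parameters(
    temperature: float,
    k: float,
    Ea: float,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    convention: str = "per_day_numeric",
) -> EyringRow:
    """Transition-state ΔH*, ΔS*, ΔG* from one (T, k, Ea) triple.

    ``Ea`` (J/mol) is an input rather than recomputed so that a row can be
    evaluated from independently reported activation energies.  Under
    ``per_day_numeric`` the numeric value of k in d⁻¹ enters the entropy
    expression directly; under ``per_second_SI`` k is first converted to s⁻¹.
    """
    if not temperature > 0:
        raise DomainError(f"temperature must be > 0 K, got {temperature}")
    if not k > 0:
        raise DomainError(f"rate constant must be > 0, got {k}")
    if convention not in CONVENTIONS:
        raise ValueError(f"convention must be one of {CONVENTIONS}, got {convention!r}")
    k_num = k if convention == "per_day_numeric" else k / SECONDS_PER_DAY
    R = constants.R_gas
    dH = Ea - R * temperature
    dS = R * (
        np.log(k_num) - np.log(constants.k_b / constants.h_planck) - np.log(temperature) - 1.0
    ) + Ea / temperature
    dG = dH - temperature * dS
    return EyringRow(
        temperature=temperature, k=k, Ea=Ea,
        dH=float(dH), dS=float(dS), dG=float(dG), convention=convention,
    )


def eyring_rate(row: EyringRow, constants: PhysicalConstants = DEFAULT_CONSTANTS) -> float:
    """Invert the transition-state relation: (k_b·T/h)·e^{ΔS*/R}·e^{−ΔH*/(R·T)}.

    Returns k in the row's input units (d⁻¹); exact round-trip of
    :func:`eyring_parameters`.
    """
    R = constants.R_gas
    T = row.temperature
    k_num = (constants.k_b * T / constants.h_planck) * np.exp(row.dS / R) * np.exp(-row.dH / (R * T))
    return float(k_num if row.convention == "per_day_numeric" else k_num * SECONDS_PER_DAY)


def fit_gibbs_temperature(points: Sequence[tuple[float, float]]) -> GibbsTempFit:
    """OLS of ΔG* (kJ/mol) on temperature (K) over >= 2 distinct temperatures."""
    temps = np.array([T for T, _ in points], dtype=float)
    gibbs = np.array([g for _, g in points], dtype=float)
    if len(np.unique(temps)) < 2:
        raise FitError("need >= 2 distinct temperatures for the Gibbs-temperature fit")
    res = stats.linregress(temps, gibbs)
    r2 = 1.0 if np.ptp(gibbs) == 0 else float(res.rvalue**2)
    fit = GibbsTempFit(slope=float(res.slope), intercept=float(res.intercept), r_squared=r2)
    logger.info(
        "gibbs-temperature fit on %d points: slope=%.4g kJ/(mol K) intercept=%.4g kJ/mol r2=%.4f",
        len(points), fit.slope, fit.intercept, fit.r_squared,
    )
    return fit
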