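"""Sensory-score linkage and combined shelf-life prediction.

The shelf-life model couples three fitted pieces for one *key* quality index:

1. a linear sensory link SS = a·C + b between the index value C and the
   panel sensory score SS (fit over all storage temperatures pooled);
2. a linear ΔG*–temperature regression (kJ/mol on K), which via the
   transition-state relation k(T) = (k_b·T/h)·exp(−ΔG*(T)/(R·T)) yields the
   storage rate constant at any temperature;
3. the first-order trajectory C(t) = C0·exp(±k·t) of the key index.

Composing them gives SS(t, T) = a·C0·exp(±k(T)·t) + b, and the shelf life is
the closed-form storage time at which SS crosses the acceptance threshold
(default 80 points on a 100-point scale):

    t_shelf = ln((b − SS_lim)/(−a·C0)) / (±k(T))

Prediction accuracy against observed shelf lives is summarised by the
standard error of prediction Se and the residual variation coefficient
Ve = 100·Se/ȳ, with Ve < 15 % the usual adequacy rule for beverages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .core_io import (
    DEFAULT_CONSTANTS,
    DomainError,
    PairingError,
    PhysicalConstants,
    StorageSeries,
)
from .thermokinetics import SECONDS_PER_DAY, CONVENTIONS, GibbsTempFit

logger = logging.getLogger("shelfkin")


@dataclass(frozen=True)
class SensoryFit:
    """Linear sensory link for one index: SS = slope·C + intercept, with fit r²."""

    index_name: str
    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        if not -1e-12 <= self.r_squared <= 1 + 1e-12:
            raise ValueError(f"r_squared outside [0, 1]: {self.r_squared}")


@dataclass(frozen=True)
class ValidationStats:
    """Prediction-error summary: Se (days), Ve (%), n, predictor count, pass flag."""

    Se: float
    Ve: float
    n: int
    k_pred: int
    acceptable: bool


@dataclass(frozen=True)
class ShelfLifeModel:
    """Combined kinetic–sensory shelf-life model for one key index.

    ``direction`` is +1 when the key index grows during storage (e.g.
    sedimentation rate) and −1 when it decays; a solvable model needs the
    sensory score to *decline* with storage, i.e. sensory.slope·direction < 0.
    """

    sensory: SensoryFit
    gibbs: GibbsTempFit
    C0: float
    constants: PhysicalConstants = DEFAULT_CONSTANTS
    convention: str = "per_day_numeric"
    threshold: float = 80.0
    direction: int = 1

    def __post_init__(self) -> None:
        if not self.C0 > 0:
            raise DomainError(f"initial index value C0 must be > 0, got {self.C0}")
        if self.convention not in CONVENTIONS:
            raise ValueError(f"convention must be one of {CONVENTIONS}")
        if self.direction not in (1, -1):
            raise ValueError(f"direction must be +1 or -1, got {self.direction}")
        if self.sensory.slope * self.direction >= 0:
            raise DomainError(
                "unsolvable model: sensory score must decline with storage "
                f"(sensory slope {self.sensory.slope:+g}, index direction {self.direction:+d})"
            )

    @property
    def initial_score(self) -> float:
        """SS at t = 0: slope·C0 + intercept."""
        return self.sensory.slope * self.C0 + self.sensory.intercept


def _pool_pairs(
    sensory: StorageSeries | Sequence[StorageSeries],
    index: StorageSeries | Sequence[StorageSeries],
) -> tuple[np.ndarray, np.ndarray, str]:
    sens = [sensory] if isinstance(sensory, StorageSeries) else list(sensory)
    idx = [index] if isinstance(index, StorageSeries) else list(index)
    s_map = {(s.temperature, t): v for s in sens for t, v in zip(s.times, s.values)}
    i_map = {(s.temperature, t): v for s in idx for t, v in zip(s.times, s.values)}
    unmatched = sorted(set(s_map) ^ set(i_map))
    if unmatched:
        raise PairingError(
            f"sensory and index series disagree on {len(unmatched)} (temperature, time) "
            f"point(s), e.g. {unmatched[:4]}"
        )
    keys = sorted(s_map)
    x = np.array([i_map[k] for k in keys])
    y = np.array([s_map[k] for k in keys])
    return x, y, idx[0].index_name


def fit_sensory_regression(
    sensory: StorageSeries | Sequence[StorageSeries],
    index: StorageSeries | Sequence[StorageSeries],
) -> SensoryFit:
    """OLS of sensory score on index value over all pooled (temperature, time) pairs.

    The two inputs must cover exactly the same (temperature, time) support;
    one regression is fit across all temperatures together, matching the
    practice of reporting a single sensory link per index.
    """
    x, y, index_name = _pool_pairs(sensory, index)
    if len(x) < 3:
        raise PairingError(f"need >= 3 paired points, got {len(x)}")
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        # degenerate: constant score or constant index -> no explanatory power
        slope = 0.0
        intercept = float(np.mean(y))
        r2 = 0.0
    else:
        res = stats.linregress(x, y)
        slope, intercept, r2 = float(res.slope), float(res.intercept), float(res.rvalue**2)
    logger.info("sensory link for %s on %d pairs: slope=%.5g intercept=%.5g r2=%.4f",
                index_name, len(x), slope, intercept, r2)
    return SensoryFit(index_name=index_name, slope=slope, intercept=intercept, r_squared=r2)


def select_key_index(fits: Sequence[SensoryFit]) -> SensoryFit:
    """Pick the sensory link with the highest r²; ties break lexicographically."""
    if not fits:
        raise ValueError("no sensory fits to select from")
    best = sorted(fits, key=lambda f: (-f.r_squared, f.index_name))[0]
    logger.info("key index: %s (r2=%.4f of %d candidates)", best.index_name,
                best.r_squared, len(fits))
    return best


def rate_from_gibbs(model: ShelfLifeModel, temperature: float) -> float:
    """Storage rate constant k(T) in d⁻¹ from the ΔG*–temperature regression.

    k = (k_b·T/h)·exp(−1000·(slope·T + intercept)/(R·T)); the regression is
    in kJ/mol, hence the ×1000 bridge to R in J/(mol·K).  Under
    ``per_day_numeric`` the transition-state rate is read directly as d⁻¹;
    under ``per_second_SI`` it is s⁻¹ and converted.
    """
    if not temperature > 0:
        raise DomainError(f"temperature must be > 0 K, got {temperature}")
    c = model.constants
    dG_J = 1000.0 * model.gibbs.gibbs_at(temperature)
    k = (c.k_b * temperature / c.h_planck) * np.exp(-dG_J / (c.R_gas * temperature))
    if model.convention == "per_second_SI":
        k *= SECONDS_PER_DAY
    return float(k)


def predict_sensory(model: ShelfLifeModel, t: float, temperature: float) -> float:
    """SS(t, T) = slope·C0·exp(direction·k(T)·t) + intercept."""
    if t < 0:
        raise DomainError(f"storage time must be >= 0, got {t}")
    k = rate_from_gibbs(model, temperature)
    return float(
        model.sensory.slope * model.C0 * np.exp(model.direction * k * t)
        + model.sensory.intercept
    )


def solve_shelf_life(model: ShelfLifeModel, temperature: float) -> float:
    """Closed-form storage time at which SS(t, T) reaches the threshold.

    Inverting SS(t) = slope·C0·exp(direction·k·t) + intercept gives
    t = ln((threshold − intercept)/(slope·C0)) / (direction·k(T)).  A
    threshold equal to SS(0) gives 0 days; a threshold above SS(0) — product
    already unacceptable at t = 0 — is a domain error, as is a threshold the
    score never reaches (at or below the asymptote of a decaying-index model).
    """
    ss0 = model.initial_score
    if model.threshold > ss0:
        raise DomainError(
            f"threshold {model.threshold} exceeds the initial sensory score {ss0:.4f}"
        )
    arg = (model.threshold - model.sensory.intercept) / (model.sensory.slope * model.C0)
    if arg <= 0.0:
        raise DomainError(
            f"threshold {model.threshold} is never reached: the sensory score "
            f"approaches {model.sensory.intercept:.4f} asymptotically"
        )
    k = rate_from_gibbs(model, temperature)
    if k == 0:
        raise DomainError("zero rate constant: sensory score never reaches the threshold")
    t = float(np.log(arg) / (model.direction * k))
    logger.info("shelf life at %g K: k=%.5g d^-1, SS0=%.3f, t=%.3f d",
                temperature, k, ss0, t)
    return t


def validate_predictions(
    observed: Sequence[float], predicted: Sequence[float], k_pred: int
) -> ValidationStats:
    """Standard error of prediction and residual variation coefficient.

    Se = sqrt(Σ(yᵢ − ŷᵢ)²/(n − k − 1)) with k the number of prediction
    factors; Ve = 100·Se/ȳ (% of the mean observed value).  ``acceptable``
    applies the Ve < 15 % beverage adequacy rule.
    """
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ValueError("observed and predicted must be equal-length 1-D sequences")
    n = len(y)
    dof = n - k_pred - 1
    if dof <= 0:
        raise DomainError(
            f"no residual degrees of freedom: n={n}, predictors={k_pred} (need n > k+1)"
        )
    se = float(np.sqrt(np.sum((y - yhat) ** 2) / dof))
    ve = 100.0 * se / float(np.mean(y))
    return ValidationStats(Se=se, Ve=ve, n=n, k_pred=k_pred, acceptable=ve < 15.0)
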