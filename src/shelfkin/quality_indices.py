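"""Closed-form colloidal quality/stability indices.

Three classical measures of dispersion stability for protein beverages:

* centrifugal sedimentation rate (CSR) — sediment mass after centrifugation
  as a percentage of the sample mass, w₁ = 100·(m₂ − m₁)/m₀;
* stability coefficient — absorbance ratio R = A₂/A₁ of a diluted sample
  after vs before centrifugation (≤ 1 for stable dispersions);
* Stokes sedimentation velocity — v = g·(ρ₁ − ρ₂)·d²/(18η) for a particle
  settling in a viscous medium, reported in nm/s.

Inputs use the bench units the measurements are made in (mg, g/cm³, cm,
Pa·s); the Stokes formula is evaluated in SI internally.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

from .core_io import DEFAULT_CONSTANTS, DomainError, PhysicalConstants

logger = logging.getLogger("shelfkin")


@dataclass(frozen=True)
class MassReading:
    """Centrifugation masses: sample m0, empty tube m1, tube plus sediment m2 (mg)."""

    m0: float
    m1: float
    m2: float

    def __post_init__(self) -> None:
        if not self.m0 > 0:
            raise DomainError(f"sample mass m0 must be > 0, got {self.m0}")
        if self.m1 < 0:
            raise DomainError(f"tube mass m1 must be >= 0, got {self.m1}")


@dataclass(frozen=True)
class AbsorbancePair:
    """Absorbance before (A1) and after (A2) centrifugation, dimensionless."""

    A1: float
    A2: float

    def __post_init__(self) -> None:
        if not self.A1 > 0:
            raise DomainError(f"pre-centrifugation absorbance A1 must be > 0, got {self.A1}")
        if self.A2 < 0:
            raise DomainError(f"supernatant absorbance A2 must be >= 0, got {self.A2}")


@dataclass(frozen=True)
class ParticleSystem:
    """Stokes-law inputs: densities ρ1, ρ2 (g/cm³), diameter d (cm), viscosity η (Pa·s)."""

    rho_particle: float
    rho_medium: float
    diameter: float
    viscosity: float

    def __post_init__(self) -> None:
        if not self.rho_particle > 0 or not self.rho_medium > 0:
            raise DomainError("densities must be > 0")
        if not 0 < self.diameter < 1.0:
            raise DomainError(f"diameter must be in (0, 1) cm, got {self.diameter}")
        if not self.viscosity > 0:
            raise DomainError(f"viscosity must be > 0 Pa·s, got {self.viscosity}")


def centrifugal_sedimentation_rate(reading: MassReading) -> float:
    """Sediment mass as a percentage of sample mass: 100·(m2 − m1)/m0."""
    if reading.m2 < reading.m1:
        raise DomainError(
            f"negative sediment: tube-plus-sediment mass {reading.m2} mg is below "
            f"empty-tube mass {reading.m1} mg"
        )
    return 100.0 * (reading.m2 - reading.m1) / reading.m0


def stability_coefficient(pair: AbsorbancePair) -> float:
    """Absorbance ratio A2/A1; warns (does not fail) above 1.

    A ratio slightly above 1 can arise from measurement noise even though a
    stable dispersion should not exceed 1.
    """
    r = pair.A2 / pair.A1
    if r > 1.0:
        warnings.warn(
            f"stability coefficient {r:.4g} > 1; expected <= 1 for a stable dispersion",
            stacklevel=2,
        )
    return r


def stokes_sedimentation_velocity(
    system: ParticleSystem, constants: PhysicalConstants = DEFAULT_CONSTANTS
) -> float:
    """Stokes settling velocity v = g·(ρ1 − ρ2)·d²/(18η), returned in nm/s.

    Densities arrive in g/cm³ and diameter in cm (bench convention); both are
    converted to SI before the formula is applied, and the m/s result is
    scaled to nm/s.  The sign follows the density difference: negative means
    the particle rises (creaming).
    """
    delta_rho = (system.rho_particle - system.rho_medium) * 1000.0  # g/cm³ -> kg/m³
    d_m = system.diameter / 100.0  # cm -> m
    v_ms = constants.g * delta_rho * d_m**2 / (18.0 * system.viscosity)
    logger.debug(
        "stokes: drho=%g kg/m³ d=%g m eta=%g Pa·s -> v=%g m/s",
        delta_rho, d_m, system.viscosity, v_ms,
    )
    return v_ms * 1e9
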