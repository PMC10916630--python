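"""Synthetic storage-stability data with the statistical structure the
analysis assumes.

Each quality index follows its kinetic law exactly — exponential
C(t) = C0·exp(±k·t) for first order, linear for zero order — and noise is
layered on top: multiplicative lognormal on index values (keeps them
positive and matches log-linear fitting) and additive Gaussian on sensory
points (clipped to the 0–100 panel scale).  The default configuration
reproduces the reference RBFM soymilk study design: three storage
temperatures (25/35/45 °C), 11 sampling points (a day-0 control plus 10
sampling groups), and 6 parallel replicate bottles per point.

Everything is seed-deterministic: one ``numpy`` SeedSequence is spawned per
(index, temperature) group and per replicate, so identical configs give
identical data and replicates are statistically independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from . import reference
from .core_io import ConfigError, StorageSeries
from .kinetics import fit_rate_constant
from .thermokinetics import eyring_parameters, fit_arrhenius

logger = logging.getLogger("shelfkin")


@dataclass(frozen=True)
class IndexSpec:
    """Kinetic generating law for one quality index.

    ``rate_by_temperature`` maps storage temperature (K) to the rate
    constant k (d⁻¹); ``direction`` is +1 for growth, −1 for decay;
    ``sensory_link`` is the (slope, intercept) of the linear sensory
    coupling, or None for indices without one.
    """

    order: int
    C0: float
    direction: int
    rate_by_temperature: Mapping[float, float]
    sensory_link: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.order not in (0, 1):
            raise ConfigError(f"order must be 0 or 1, got {self.order}")
        if not self.C0 > 0:
            raise ConfigError(f"C0 must be > 0, got {self.C0}")
        if self.direction not in (1, -1):
            raise ConfigError(f"direction must be +1 or -1, got {self.direction}")
        if any(k < 0 for k in self.rate_by_temperature.values()):
            raise ConfigError("rate constants must be >= 0")

    def trajectory(self, temperature: float, times: np.ndarray) -> np.ndarray:
        """Noiseless C(t) at one temperature."""
        k = self.rate_by_temperature[temperature]
        s = self.direction * k
        if self.order == 0:
            return self.C0 + s * np.asarray(times, dtype=float)
        return self.C0 * np.exp(s * np.asarray(times, dtype=float))


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator configuration: kinetic specs, schedule, noise, replication, seed.

    Defaults are the reference study conditions: RBFM soymilk rate
    constants and initial values at 298.15/308.15/318.15 K, 11 sampling
    points over a 20-day span (which keeps every noiseless trajectory inside
    its observed index range), lognormal σ = 0.05 on index values, additive
    σ = 0.5 points on sensory scores, 6 replicates.
    """

    indices: Mapping[str, IndexSpec] = field(default_factory=lambda: default_index_specs())
    temperatures: tuple[float, ...] = reference.TEMPERATURES_K
    schedule: tuple[float, ...] = tuple(float(t) for t in range(0, 22, 2))
    noise_sigma: float = 0.05
    sensory_noise: float = 0.5
    replicates: int = 6
    seed: int = 0
    #: index whose link generates the (single) sensory-score observable;
    #: "auto" picks CSR when present, else the first linked index, else none
    sensory_source: str | None = "auto"

    def __post_init__(self) -> None:
        if self.sensory_source is not None and self.sensory_source != "auto":
            spec = self.indices.get(self.sensory_source)
            if spec is None or spec.sensory_link is None:
                raise ConfigError(
                    f"sensory_source {self.sensory_source!r} must name an index "
                    f"with a sensory link"
                )
        if self.noise_sigma < 0 or self.sensory_noise < 0:
            raise ConfigError("noise sigmas must be >= 0")
        if self.replicates < 1:
            raise ConfigError(f"replicates must be >= 1, got {self.replicates}")
        if len(self.schedule) < 2 or np.any(np.diff(self.schedule) <= 0) or self.schedule[0] < 0:
            raise ConfigError("schedule must be >= 2 strictly increasing times starting at >= 0")
        for name, spec in self.indices.items():
            missing = [T for T in self.temperatures if T not in spec.rate_by_temperature]
            if missing:
                raise ConfigError(f"index {name!r} lacks rate constants for {missing}")
            if spec.order == 0:
                tail = spec.trajectory(max(self.temperatures,
                                           key=lambda T: spec.rate_by_temperature[T]),
                                       np.array(self.schedule))
                if np.any(tail <= 0):
                    raise ConfigError(
                        f"zero-order spec for {name!r} crosses zero within the schedule"
                    )


def resolve_sensory_source(config: SyntheticConfig) -> str | None:
    """Concrete sensory-source index for a config, or None if none is linkable."""
    if config.sensory_source != "auto":
        return config.sensory_source
    linked = [n for n in sorted(config.indices) if config.indices[n].sensory_link is not None]
    if not linked:
        return None
    return "CSR" if "CSR" in linked else linked[0]


def default_index_specs() -> dict[str, IndexSpec]:
    """First-order specs for the three reference indices with sensory links."""
    return {
        name: IndexSpec(
            order=1,
            C0=reference.INITIAL_VALUES[name],
            direction=reference.DIRECTIONS[name],
            rate_by_temperature=dict(reference.RATE_CONSTANTS[name]),
            sensory_link=reference.SENSORY_LINKS[name],
        )
        for name in sorted(reference.RATE_CONSTANTS)
    }


def _group_rng(seed: int, *tags: str) -> np.random.Generator:
    # stable sub-stream per (index, temperature, ...) label set
    key = [int.from_bytes(t.encode(), "little") % (2**32) for t in tags]
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def generate_storage_series(
    config: SyntheticConfig, emit: str = "means"
) -> list[StorageSeries]:
    """Generate index series for every (index, temperature) in the config.

    ``emit`` selects ``"means"`` (replicate-averaged series, the form the
    kinetic fits consume), ``"replicates"`` (one series per bottle, index
    names suffixed ``#r``), or ``"both"``.
    """
    if emit not in ("means", "replicates", "both"):
        raise ValueError(f"emit must be means|replicates|both, got {emit!r}")
    times = np.array(config.schedule)
    out: list[StorageSeries] = []
    for name in sorted(config.indices):
        spec = config.indices[name]
        for T in config.temperatures:
            clean = spec.trajectory(T, times)
            rng = _group_rng(config.seed, name, f"{T:.6f}")
            reps = np.empty((config.replicates, len(times)))
            for r in range(config.replicates):
                if config.noise_sigma == 0:
                    reps[r] = clean
                elif spec.order == 1:
                    reps[r] = clean * np.exp(rng.normal(0.0, config.noise_sigma, len(times)))
                else:
                    reps[r] = clean + rng.normal(0.0, config.noise_sigma, len(times))
            if emit in ("replicates", "both"):
                for r in range(config.replicates):
                    out.append(StorageSeries(f"{name}#{r}", T, times.copy(), reps[r]))
            if emit in ("means", "both"):
                out.append(StorageSeries(name, T, times.copy(), reps.mean(axis=0)))
    logger.info("generated %d synthetic series (emit=%s, seed=%d)", len(out), emit, config.seed)
    return out


def generate_sensory_series(
    index_series: StorageSeries,
    link: tuple[float, float],
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> StorageSeries:
    """Sensory scores SS(t) = slope·C(t) + intercept + N(0, σ²), clipped to [0, 100]."""
    slope, intercept = link
    if not np.isfinite(slope) or not np.isfinite(intercept):
        raise ConfigError("sensory link coefficients must be finite")
    rng = _group_rng(seed, "sensory", index_series.index_name, f"{index_series.temperature:.6f}")
    ss = slope * index_series.values + intercept
    if noise_sigma > 0:
        ss = ss + rng.normal(0.0, noise_sigma, len(ss))
    return StorageSeries(
        index_name="sensory_score",
        temperature=index_series.temperature,
        times=index_series.times.copy(),
        values=np.clip(ss, 0.0, 100.0),
    )


def recovery_experiment(config: SyntheticConfig, replications: int) -> dict:
    """Parameter-recovery harness: generator → kinetics → thermodynamics.

    For each replication (with a seed laddered from ``config.seed``) the
    mean series are fit, the activation energy is re-estimated per index,
    and ΔG* is recomputed at every temperature.  Relative errors are taken
    against the generating constants (for Ea and ΔG*, against the values
    implied by an exact Arrhenius/Eyring pass over the noiseless rates).

    Returns a nested dict ``{parameter: {"median": .., "q95": ..}}`` of
    absolute relative errors, pooled over indices and temperatures.
    """
    if replications < 1:
        raise ValueError(f"replications must be >= 1, got {replications}")
    truth_k = {
        (n, T): config.indices[n].rate_by_temperature[T]
        for n in config.indices for T in config.temperatures
    }
    truth_Ea = {
        n: fit_arrhenius([(T, truth_k[(n, T)]) for T in config.temperatures]).Ea
        for n in config.indices
    }
    truth_dG = {
        (n, T): eyring_parameters(T, truth_k[(n, T)], truth_Ea[n]).dG
        for n in config.indices for T in config.temperatures
    }
    errs: dict[str, list[float]] = {"k": [], "Ea": [], "dG": []}
    for rep in range(replications):
        cfg = replace(config, seed=config.seed + rep)
        fits: dict[tuple[str, float], float] = {}
        for s in generate_storage_series(cfg, emit="means"):
            # fit the generating order: recovery measures estimation error,
            # not order selection (k has different units across orders)
            order = config.indices[s.index_name].order
            fits[(s.index_name, s.temperature)] = fit_rate_constant(s, order).k
        for n in config.indices:
            arr = fit_arrhenius([(T, fits[(n, T)]) for T in config.temperatures])
            errs["Ea"].append(abs(arr.Ea - truth_Ea[n]) / abs(truth_Ea[n]))
            for T in config.temperatures:
                k_hat = fits[(n, T)]
                errs["k"].append(abs(k_hat - truth_k[(n, T)]) / truth_k[(n, T)])
                dG_hat = eyring_parameters(T, k_hat, arr.Ea).dG
                errs["dG"].append(abs(dG_hat - truth_dG[(n, T)]) / abs(truth_dG[(n, T)]))
    report = {
        p: {"median": float(np.median(v)), "q95": float(np.quantile(v, 0.95))}
        for p, v in errs.items()
    }
    logger.info("recovery experiment (%d replications): %s", replications, report)
    return report
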