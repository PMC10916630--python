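"""Data model, physical constants, and CSV/config I/O.

The central container is :class:`StorageSeries`: one quality index (centrifugal
sedimentation rate, viscosity, particle size, or sensory score) measured over
storage time at a single absolute temperature.  Everything downstream — kinetic
fitting, Arrhenius/Eyring analysis, shelf-life prediction — consumes and
produces these series or flat result records.

Units are fixed package-wide: temperature in kelvin, time in days, rate
constants in d⁻¹.  Celsius exists only at the CLI boundary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("shelfkin")

SERIES_COLUMNS = ["temperature_K", "time_d", "index", "value"]

#: Index names recognised by the analysis stages.
KNOWN_INDICES = ("CSR", "viscosity", "particle_size", "sensory_score")


class ShelfkinError(Exception):
    """Base class for package errors."""


class DataFormatError(ShelfkinError, ValueError):
    """Malformed input table: missing columns, unparsable cells, short groups."""


class ConfigError(ShelfkinError, ValueError):
    """Invalid run configuration."""


class DomainError(ShelfkinError, ValueError):
    """Input outside the physical/mathematical domain of a formula."""


class FitError(ShelfkinError, ValueError):
    """A regression could not be performed (degenerate design)."""


class PairingError(ShelfkinError, ValueError):
    """Two series could not be matched on their (temperature, time) support."""


@dataclass(frozen=True)
class PhysicalConstants:
    """Physical constants used by the sedimentation and transition-state formulas.

    Attributes
    ----------
    g : float
        Gravitational acceleration, m/s².
    R_gas : float
        Molar gas constant, J/(mol·K).
    k_b : float
        Boltzmann constant, J/K.
    h_planck : float
        Planck constant, J·s.
    """

    g: float = 9.80
    R_gas: float = 8.314
    k_b: float = 1.38e-23
    h_planck: float = 6.626e-34

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v <= 0:
                raise DomainError(f"constant {f.name} must be finite and > 0, got {v}")


DEFAULT_CONSTANTS = PhysicalConstants()


@dataclass(frozen=True)
class StorageSeries:
    """One quality index measured over storage time at one temperature.

    ``times`` (days) must be strictly increasing, start at ≥ 0 and match
    ``values`` in length (≥ 2).  ``values`` carry the index's own units
    (%, mPa·s, μm or sensory points).
    """

    index_name: str
    temperature: float
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or values.ndim != 1 or len(times) != len(values):
            raise DataFormatError(
                f"times and values must be 1-D and equal length "
                f"({len(times)} vs {len(values)}) for {self.index_name}"
            )
        if len(times) < 2:
            raise DataFormatError(
                f"series {self.index_name}@{self.temperature} K needs >= 2 points, "
                f"got {len(times)}"
            )
        if times[0] < 0 or np.any(np.diff(times) <= 0):
            raise DataFormatError(
                f"times must be strictly increasing and start at >= 0 "
                f"for {self.index_name}@{self.temperature} K"
            )
        if not self.temperature > 0:
            raise DomainError(f"temperature must be > 0 K, got {self.temperature}")
        if not np.all(np.isfinite(values)):
            raise DataFormatError(
                f"non-finite values in series {self.index_name}@{self.temperature} K"
            )

    @property
    def C0(self) -> float:
        """Initial measured value (first element)."""
        return float(self.values[0])

    def __len__(self) -> int:
        return len(self.times)


def read_series_csv(path: str | Path, expected_header: bool = True) -> list[StorageSeries]:
    """Read a long-format storage table into one series per (index, temperature).

    The file must be comma-separated UTF-8 with header
    ``temperature_K,time_d,index,value``.  Rows are grouped exactly on the
    numeric temperature value and sorted by time within each group.

    Raises
    ------
    DataFormatError
        On missing columns, non-numeric cells (reported with their row
        number) or a group with fewer than two rows.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"index": str} if expected_header else None)
    missing = [c for c in SERIES_COLUMNS if c not in df.columns]
    if missing:
        raise DataFormatError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")
    for col in ("temperature_K", "time_d", "value"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna()]
        if len(bad):
            # +2: header line plus 1-based numbering
            raise DataFormatError(
                f"{path}: non-numeric '{col}' at data row {bad[0] + 2}: {df[col][bad[0]]!r}"
            )
        df[col] = coerced
    out: list[StorageSeries] = []
    for (index_name, temp), grp in df.groupby(["index", "temperature_K"], sort=True):
        grp = grp.sort_values("time_d")
        if len(grp) < 2:
            raise DataFormatError(
                f"{path}: group ({index_name}, {temp} K) has {len(grp)} row(s); need >= 2"
            )
        out.append(
            StorageSeries(
                index_name=str(index_name),
                temperature=float(temp),
                times=grp["time_d"].to_numpy(),
                values=grp["value"].to_numpy(),
            )
        )
    logger.info("read %d series (%d rows) from %s", len(out), len(df), path)
    return out


def write_series_csv(series: Iterable[StorageSeries], path: str | Path) -> None:
    """Write series back to the long CSV dialect of :func:`read_series_csv`."""
    rows = []
    for s in sorted(series, key=lambda s: (s.index_name, s.temperature)):
        for t, v in zip(s.times, s.values):
            rows.append({"temperature_K": s.temperature, "time_d": t, "index": s.index_name, "value": v})
    pd.DataFrame(rows, columns=SERIES_COLUMNS).to_csv(path, index=False, float_format="%.10g")


def write_results(records: Sequence[Mapping[str, Any]], path: str | Path) -> None:
    """Write flat result records as a deterministic CSV.

    Rows are sorted by ``index_name`` then ``temperature`` when those fields
    exist; column order follows the first record.  Floats keep >= 6
    significant digits, so two runs on the same input are byte-identical.
    """
    records = [dict(r) for r in records]
    if not records:
        Path(path).write_text("\n")
        logger.info("wrote empty results table to %s", path)
        return
    columns = list(records[0].keys())
    df = pd.DataFrame(records, columns=columns)
    sort_cols = [c for c in ("index_name", "temperature") if c in df.columns]
    if sort_cols:
        df = df.sort_values(sort_cols, kind="mergesort")
    df.to_csv(path, index=False, float_format="%.10g")
    logger.info("wrote %d records (%d columns) to %s", len(df), len(columns), path)


@dataclass(frozen=True)
class RunConfig:
    """Run-wide configuration: constant overrides, conventions, threshold, seed."""

    constants: PhysicalConstants = DEFAULT_CONSTANTS
    eyring_rate_convention: str = "per_day_numeric"
    threshold: float = 80.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.eyring_rate_convention not in ("per_day_numeric", "per_second_SI"):
            raise ConfigError(
                f"eyring_rate_convention must be per_day_numeric or per_second_SI, "
                f"got {self.eyring_rate_convention!r}"
            )
        if not self.threshold > 0:
            raise ConfigError(f"sensory threshold must be > 0, got {self.threshold}")


_CONSTANT_KEYS = ("g", "R_gas", "k_b", "h_planck")
_CONFIG_KEYS = _CONSTANT_KEYS + ("eyring_rate_convention", "threshold", "seed")


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML or JSON mapping into a :class:`RunConfig`.

    Unknown keys are rejected.  An ``R_gas`` override far from 8.314 (e.g. the
    value 8314 sometimes quoted in J/mol·K with a slipped decimal point) is
    accepted but logged as a warning.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text) if text.strip() else {}
    if data is None:
        data = {}
    if not isinstance(data, Mapping):
        raise ConfigError(f"{path}: config must be a mapping, got {type(data).__name__}")
    unknown = sorted(set(data) - set(_CONFIG_KEYS))
    if unknown:
        raise ConfigError(f"{path}: unknown config key(s): {unknown}")
    const_overrides = {k: float(data[k]) for k in _CONSTANT_KEYS if k in data}
    if "R_gas" in const_overrides and abs(const_overrides["R_gas"] - 8.314) > 1.0:
        logger.warning(
            "R_gas override %.6g differs strongly from 8.314 J/(mol·K); "
            "proceeding as requested", const_overrides["R_gas"],
        )
    constants = replace(DEFAULT_CONSTANTS, **const_overrides)
    cfg = RunConfig(
        constants=constants,
        eyring_rate_convention=str(data.get("eyring_rate_convention", "per_day_numeric")),
        threshold=float(data.get("threshold", 80.0)),
        seed=int(data.get("seed", 0)),
    )
    logger.info(
        "config loaded: convention=%s threshold=%g seed=%d",
        cfg.eyring_rate_convention, cfg.threshold, cfg.seed,
    )
    return cfg


def celsius_to_kelvin(t_c: float) -> float:
    return t_c + 273.15
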