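"""End-to-end orchestration: series → kinetic fits → thermodynamics → shelf life.

``run_pipeline`` is a thin, stateless composition of the library stages.
Every stage writes its results CSV into the output directory and the run
is summarised in a JSON manifest (config snapshot, input digests, seed,
per-stage output paths) from which a rerun reproduces all outputs
bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from ._version import __version__
from .core_io import (
    RunConfig,
    ShelfkinError,
    StorageSeries,
    read_series_csv,
    write_results,
    write_series_csv,
)
from .kinetics import select_order
from .shelf_life import (
    SensoryFit,
    ShelfLifeModel,
    fit_sensory_regression,
    select_key_index,
    solve_shelf_life,
    rate_from_gibbs,
)
from .synthetic_data import (
    SyntheticConfig,
    generate_sensory_series,
    generate_storage_series,
    resolve_sensory_source,
)
from .thermokinetics import eyring_parameters, fit_arrhenius, fit_gibbs_temperature

logger = logging.getLogger("shelfkin")


class StageError(ShelfkinError):
    """A pipeline stage failed; carries the stage name and offending series."""

    def __init__(self, stage: str, detail: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {detail}")


@dataclass
class RunManifest:
    """Record of one pipeline run, sufficient to reproduce it."""

    version: str
    seed: int
    convention: str
    threshold: float
    input_digests: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    config: RunConfig,
    out_dir: str | Path,
    input_csv: str | Path | None = None,
    synthetic: SyntheticConfig | None = None,
) -> RunManifest:
    """Run the full analysis on a series CSV or a synthetic configuration.

    Stages: (1) load or generate storage series (synthetic runs also derive
    sensory series from each index's link); (2) first/zero-order kinetic fit
    per (index, temperature); (3) Arrhenius + transition-state parameters and
    the ΔG*–temperature regression per index; (4) sensory linkage, key-index
    selection and shelf-life solving at every input temperature; (5) results
    CSVs plus a JSON manifest.  If no sensory series are present, stage 4 is
    skipped and noted in the manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        version=__version__,
        seed=config.seed,
        convention=config.eyring_rate_convention,
        threshold=config.threshold,
    )

    # -- stage 1: input -------------------------------------------------
    if (input_csv is None) == (synthetic is None):
        raise StageError("input", "provide exactly one of input_csv or synthetic config")
    if input_csv is not None:
        series = read_series_csv(input_csv)
        manifest.input_digests[str(input_csv)] = _sha256(Path(input_csv))
    else:
        series = generate_storage_series(synthetic, emit="means")
        # the sensory score is a single observable, generated from the
        # designated source index's link at each temperature
        src = resolve_sensory_source(synthetic)
        if src is not None:
            link = synthetic.indices[src].sensory_link
            series = series + [
                generate_sensory_series(s, link, synthetic.sensory_noise, synthetic.seed)
                for s in series
                if s.index_name == src
            ]
        input_path = out / "series.csv"
        write_series_csv(series, input_path)
        manifest.input_digests[str(input_path)] = _sha256(input_path)
        manifest.outputs["series"] = str(input_path)

    index_series = [s for s in series if s.index_name != "sensory_score"]
    sensory_series = [s for s in series if s.index_name == "sensory_score"]

    # -- stage 2: kinetics ----------------------------------------------
    fits: dict[tuple[str, float], object] = {}
    for s in index_series:
        try:
            fits[(s.index_name, s.temperature)] = select_order(s)
        except ShelfkinError as e:
            raise StageError("kinetics", f"{s.index_name}@{s.temperature} K: {e}") from e
    kin_path = out / "kinetic_fits.csv"
    write_results(
        [
            {"index_name": n, "temperature": T, "order": f.order, "k": f.k,
             "direction": f.direction, "C0_hat": f.C0_hat, "r_squared": f.r_squared}
            for (n, T), f in fits.items()
        ],
        kin_path,
    )
    manifest.outputs["kinetic_fits"] = str(kin_path)

    # -- stage 3: thermodynamics ----------------------------------------
    index_names = sorted({n for n, _ in fits})
    eyring_rows, gibbs_fits = [], {}
    for name in index_names:
        rates = sorted((T, f.k) for (n, T), f in fits.items() if n == name)
        try:
            arr = fit_arrhenius(rates, config.constants)
            rows = [
                eyring_parameters(T, k, arr.Ea, config.constants,
                                  config.eyring_rate_convention)
                for T, k in rates
            ]
        except ShelfkinError as e:
            raise StageError("thermokinetics", f"{name}: {e}") from e
        gibbs_fits[name] = fit_gibbs_temperature([(r.temperature, r.dG / 1000.0) for r in rows])
        eyring_rows += [
            {"index_name": name, "temperature": r.temperature, "k": r.k, "Ea": r.Ea,
             "dH": r.dH, "dS": r.dS, "dG": r.dG, "convention": r.convention}
            for r in rows
        ]
    thermo_path = out / "eyring_rows.csv"
    write_results(eyring_rows, thermo_path)
    gibbs_path = out / "gibbs_temperature_fits.csv"
    write_results(
        [
            {"index_name": n, "slope": g.slope, "intercept": g.intercept,
             "r_squared": g.r_squared}
            for n, g in sorted(gibbs_fits.items())
        ],
        gibbs_path,
    )
    manifest.outputs["eyring_rows"] = str(thermo_path)
    manifest.outputs["gibbs_temperature_fits"] = str(gibbs_path)

    # -- stage 4: sensory link + shelf life ------------------------------
    if not sensory_series:
        manifest.notes.append("no sensory series in input: shelf-life stage skipped")
        logger.warning("shelf-life stage skipped: no sensory series")
    else:
        sens_fits = []
        for name in index_names:
            idx = [s for s in index_series if s.index_name == name]
            try:
                sens_fits.append(fit_sensory_regression(sensory_series, idx))
            except ShelfkinError as e:
                raise StageError("sensory_link", f"{name}: {e}") from e
        sens_path = out / "sensory_fits.csv"
        write_results(
            [
                {"index_name": f.index_name, "slope": f.slope,
                 "intercept": f.intercept, "r_squared": f.r_squared}
                for f in sens_fits
            ],
            sens_path,
        )
        manifest.outputs["sensory_fits"] = str(sens_path)

        key = select_key_index(sens_fits)
        key_dir = 1 if key.slope < 0 else -1  # score must decline with storage
        key_C0 = min(
            (s for s in index_series if s.index_name == key.index_name),
            key=lambda s: s.temperature,
        ).C0
        model = ShelfLifeModel(
            sensory=key, gibbs=gibbs_fits[key.index_name], C0=key_C0,
            constants=config.constants, convention=config.eyring_rate_convention,
            threshold=config.threshold, direction=key_dir,
        )
        temps = sorted({s.temperature for s in index_series})
        shelf_path = out / "shelf_life.csv"
        write_results(
            [
                {"index_name": key.index_name, "temperature": T,
                 "k": rate_from_gibbs(model, T), "SS0": model.initial_score,
                 "shelf_life_d": solve_shelf_life(model, T)}
                for T in temps
            ],
            shelf_path,
        )
        manifest.outputs["shelf_life"] = str(shelf_path)
        manifest.notes.append(f"key index: {key.index_name} (r2={key.r_squared:.4f})")

    manifest.save(out / "manifest.json")
    manifest.outputs["manifest"] = str(out / "manifest.json")
    return manifest
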