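"""Reading/writing observed series, configs and run artifacts.

File formats:

* observed series CSV — columns ``time_min,species,value,scale`` with
  ``scale`` in {normalized, uM}; rows grouped by species, times strictly
  increasing per species.
* model config YAML — every numeric key carries an explicit unit suffix
  (``aaph_mM``, ``curcumin_uM``, ``curcumin_ug_per_ml``, ``horizon_min``,
  ``k_C_per_uM_min``, ...); concentrations quoted in mM or µg/ml are
  converted to the internal µM basis on load and the conversion is logged.
* fit report — flat ``key=value`` text file.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .estimation import FitResult, ObservedSeries, OBSERVABLE_SPECIES
from .model import DosingScheme, ModelConfig, RateConstants, SpeciesState
from .units import mM_to_uM, ug_per_ml_to_uM

__all__ = [
    "ParseError",
    "RunConfig",
    "read_timeseries_csv",
    "write_timeseries_csv",
    "load_model_config",
    "write_fit_report",
    "write_run_log",
]

logger = logging.getLogger("radscav")

REQUIRED_COLUMNS = ("time_min", "species", "value", "scale")


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run (for logging/reproduction)."""

    subcommand: str
    inputs: dict[str, str] = field(default_factory=dict)
    out_dir: str = "."
    overrides: dict[str, Any] = field(default_factory=dict)
    seed: int | None = None
    verbosity: int = 0


def read_timeseries_csv(path) -> list[ObservedSeries]:
    """Parse an observed-series CSV into per-species series.

    Raises :class:`ParseError` naming the 1-based file line of the first
    malformed row (missing column, negative value, duplicate/non-monotone
    time within a species, unknown species or scale).
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    # +2: one for the header line, one for 0-based indexing
    lines = df.index.to_numpy() + 2

    bad = ~np.isfinite(pd.to_numeric(df["value"], errors="coerce"))
    if bad.any():
        raise ParseError(f"{path}: non-numeric value on line {lines[bad][0]}")
    if (df["value"] < 0).any():
        raise ParseError(
            f"{path}: negative value on line {lines[(df['value'] < 0).to_numpy()][0]}"
        )
    unknown = ~df["species"].isin(OBSERVABLE_SPECIES)
    if unknown.any():
        raise ParseError(
            f"{path}: unknown species {df['species'][unknown].iloc[0]!r} "
            f"on line {lines[unknown.to_numpy()][0]}"
        )
    bad_scale = ~df["scale"].isin(["normalized", "uM"])
    if bad_scale.any():
        raise ParseError(f"{path}: bad scale on line {lines[bad_scale.to_numpy()][0]}")

    series = []
    for species, group in df.groupby("species", sort=False):
        t = group["time_min"].to_numpy(float)
        non_increasing = np.diff(t) <= 0
        if non_increasing.any():
            line = lines[group.index.to_numpy()[1:][non_increasing][0]]
            raise ParseError(
                f"{path}: duplicated or non-increasing time_min for species "
                f"{species!r} on line {line}"
            )
        scales = group["scale"].unique()
        if len(scales) > 1:
            raise ParseError(f"{path}: mixed scales within species {species!r}")
        series.append(
            ObservedSeries(
                species=str(species),
                times=t,
                values=group["value"].to_numpy(float),
                scale=str(scales[0]),
            )
        )
    return series


def write_timeseries_csv(path, series: list[ObservedSeries]) -> None:
    frames = [
        pd.DataFrame(
            {"time_min": s.times, "species": s.species, "value": s.values, "scale": s.scale}
        )
        for s in series
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.10g")


def load_model_config(path) -> ModelConfig:
    """Build a :class:`ModelConfig` from a YAML file with unit-suffixed keys."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {
        "aaph_mM", "aaph_uM", "curcumin_uM", "curcumin_ug_per_ml",
        "monoacrylate_uM", "horizon_min", "k_A_per_min", "k_el_per_min",
        "k_C_per_uM_min", "k_CM_per_uM_min", "mode", "rtol",
        "atol_radical_uM", "atol_slow_uM", "boluses", "rate_segments",
        "literal_radical_generation",
    }
    unknown = set(raw) - known
    if unknown:
        raise ParseError(f"{path}: unknown config keys {sorted(unknown)}")

    aaph_uM = 0.0
    if "aaph_mM" in raw:
        aaph_uM = mM_to_uM(raw["aaph_mM"])
        logger.info("converted aaph %.6g mM -> %.6g uM", raw["aaph_mM"], aaph_uM)
    elif "aaph_uM" in raw:
        aaph_uM = float(raw["aaph_uM"])
    curcumin_uM = 0.0
    if "curcumin_ug_per_ml" in raw:
        curcumin_uM = ug_per_ml_to_uM(raw["curcumin_ug_per_ml"])
        logger.info(
            "converted curcumin %.6g ug/ml -> %.6g uM (MW 368.38)",
            raw["curcumin_ug_per_ml"], curcumin_uM,
        )
    elif "curcumin_uM" in raw:
        curcumin_uM = float(raw["curcumin_uM"])

    k = RateConstants(
        k_A=float(raw.get("k_A_per_min", RateConstants.k_A)),
        k_el=float(raw.get("k_el_per_min", RateConstants.k_el)),
        k_C=float(raw.get("k_C_per_uM_min", RateConstants.k_C)),
        k_CM=float(raw.get("k_CM_per_uM_min", RateConstants.k_CM)),
    )
    dosing = DosingScheme(
        boluses=tuple(
            (float(b["time_min"]), str(b["species"]), float(b["amount_uM"]))
            for b in raw.get("boluses", [])
        ),
        rate_segments=tuple(
            (
                float(s["t_start_min"]), float(s["t_end_min"]),
                str(s["species"]), float(s["rate_uM_per_min"]),
            )
            for s in raw.get("rate_segments", [])
        ),
    )
    kwargs: dict[str, Any] = {}
    if "rtol" in raw:
        kwargs["rtol"] = float(raw["rtol"])
    if "atol_radical_uM" in raw:
        kwargs["atol_radical"] = float(raw["atol_radical_uM"])
    if "atol_slow_uM" in raw:
        kwargs["atol_slow"] = float(raw["atol_slow_uM"])
    return ModelConfig(
        rate_constants=k,
        initial_state=SpeciesState(
            C_A=aaph_uM, C_C=curcumin_uM, C_CM=float(raw.get("monoacrylate_uM", 0.0))
        ),
        horizon=float(raw.get("horizon_min", 1440.0)),
        dosing=dosing,
        mode=str(raw.get("mode", "full-stiff")),
        literal_radical_generation=bool(raw.get("literal_radical_generation", False)),
        **kwargs,
    )


def write_fit_report(path, result: FitResult) -> None:
    with open(path, "w") as fh:
        for key, value in result.as_flat_dict().items():
            fh.write(f"{key}={value}\n")


def write_run_log(out_dir, run: RunConfig, resolved: dict[str, Any]) -> Path:
    """Persist the resolved parameter set so a run can be reproduced exactly."""
    out = Path(out_dir) / f"{run.subcommand}_run.json"
    payload = {
        "subcommand": run.subcommand,
        "inputs": run.inputs,
        "overrides": run.overrides,
        "seed": run.seed,
        "resolved": resolved,
    }
    with open(out, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
    return out
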