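"""Readers and writers: series CSV, parameter JSON, fit-result JSON, config files.

Series CSV contract: columns ``time`` (ISO 8601 date-times or decimal
hours), ``pa``, ``na`` on the instrument scale, optional ``day``.  ISO
time stamps derive day labels from the date; decimal-hour time stamps
require an explicit ``day`` column, because night boundaries cannot be
derived from a bare number.  Missing ratings are empty cells and flagged
invalid.  Lines starting with ``#`` are provenance comments and ignored.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .optimize import FitResult
from .potentials import ModelParameters, params_from_dict
from .series import AffectTimeSeries, rescale_series

__all__ = [
    "read_series_csv",
    "write_series_csv",
    "write_fit_result",
    "read_fit_result",
    "load_params",
    "save_params",
    "read_config",
]


def read_series_csv(
    path, instrument_min: float = 0.0, instrument_max: float = 100.0
) -> AffectTimeSeries:
    """Read, validate and rescale an affect time-series CSV."""
    df = pd.read_csv(path, comment="#")
    for col in ("time", "pa", "na"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")

    time_raw = df["time"]
    numeric = pd.to_numeric(time_raw, errors="coerce")
    if numeric.notna().all():
        if "day" not in df.columns:
            raise ValueError(
                f"{path}: decimal-hour time stamps require an explicit 'day' column"
            )
        t = numeric.to_numpy(dtype=float)
        day = df["day"].to_numpy(dtype=int)
    else:
        stamps = pd.to_datetime(time_raw, format="ISO8601")
        origin = stamps.iloc[0].normalize()
        t = ((stamps - origin) / pd.Timedelta(hours=1)).to_numpy(dtype=float)
        if "day" in df.columns:
            day = df["day"].to_numpy(dtype=int)
        else:
            day = ((stamps.dt.normalize() - origin) / pd.Timedelta(days=1)).astype(int).to_numpy()

    if np.any(np.diff(t) <= 0):
        bad = (np.flatnonzero(np.diff(t) <= 0) + 1).tolist()
        raise ValueError(f"{path}: time stamps not strictly increasing at rows {bad}")

    frame = pd.DataFrame({"time": t, "pa": df["pa"], "na": df["na"], "day": day})
    return rescale_series(frame, instrument_min, instrument_max)


def write_series_csv(series: AffectTimeSeries, path, provenance: dict | None = None) -> None:
    """Write a unit-scale series; provenance goes into a leading comment."""
    with open(path, "w") as fh:
        if provenance:
            fh.write("# " + json.dumps(provenance) + "\n")
        series.to_frame().to_csv(fh, index=False)


def save_params(params: ModelParameters, path) -> None:
    Path(path).write_text(json.dumps(params.to_dict(), indent=1) + "\n")


def load_params(path) -> ModelParameters:
    return params_from_dict(json.loads(Path(path).read_text()))


def write_fit_result(result: FitResult, path) -> None:
    """Serialize a fit: named parameters, NLL, trace, full config echo."""
    payload = {
        "model_id": result.model_id,
        "parameters": result.params.to_dict(),
        "nll": result.nll,
        "trace": np.asarray(result.trace).tolist(),
        "n_evaluations": result.n_evaluations,
        "config": {
            "pop_size": result.config.pop_size,
            "cr": result.config.cr,
            "generations": result.config.generations,
            "mutation_weight": result.config.mutation_weight,
            "seed": result.config.seed,
            "prior_scales": result.config.prior_scales,
        },
        "likelihood_options": {
            "grid_n": result.options.grid_n,
            "initial_mode": result.options.initial_mode,
            "night_mode": result.options.night_mode,
            "density_floor": result.options.density_floor,
            "step_cap": result.options.step_cap,
        },
        "software_version": __version__,
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_fit_result(path) -> dict:
    """Read back a fit-result JSON; 'parameters' reload via params_from_dict."""
    return json.loads(Path(path).read_text())


def read_config(path) -> dict:
    """Plain-text ``key=value`` configuration (one per line, '#' comments)."""
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}: malformed config line {line!r}")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out
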