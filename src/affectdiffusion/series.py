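"""Affect time series: irregularly sampled bivariate ratings on the unit square."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["AffectTimeSeries", "rescale_series"]


@dataclass
class AffectTimeSeries:
    """Time-ordered observations of (positive, negative) affect.

    ``t`` are strictly increasing time stamps in hours, ``x`` the unit-square
    positions (shape (N, 2); NaN where invalid), ``day`` integer day labels
    (a change in label marks a night) and ``valid`` flags marking answered
    beeps.  Invalid (missing) observations are retained in sequence so gaps
    can be bridged.
    """

    t: np.ndarray
    x: np.ndarray
    day: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.day = np.asarray(self.day, dtype=int)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.t)
        if self.x.shape != (n, 2) or len(self.day) != n or len(self.valid) != n:
            raise ValueError("t, x, day and valid must have matching lengths")
        if n and np.any(np.diff(self.t) <= 0):
            raise ValueError("time stamps must be strictly increasing")
        xv = self.x[self.valid]
        if xv.size and (np.any(xv < 0) or np.any(xv > 1)):
            raise ValueError("valid observations must lie in the closed unit square")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.t, "pa": self.x[:, 0], "na": self.x[:, 1], "day": self.day}
        )


def rescale_series(
    raw: pd.DataFrame,
    instrument_min: float,
    instrument_max: float,
    pa_cols=("pa",),
    na_cols=("na",),
    time_col: str = "time",
    day_col: str | None = "day",
) -> AffectTimeSeries:
    """Build a unit-square series from instrument-scale ratings.

    Multiple positive/negative item columns are averaged first; the averages
    are then mapped affinely, x = (raw - min) / (max - min), and clamped into
    [0, 1].  ``time`` must already be in decimal hours.  Rows with any
    missing item are flagged invalid but kept in sequence.  Values outside
    the instrument range raise a validation error listing the offending rows.
    """
    if not instrument_max > instrument_min:
        raise ValueError("instrument_max must exceed instrument_min")
    for col in (*pa_cols, *na_cols, time_col):
        if col not in raw.columns:
            raise ValueError(f"missing required column {col!r}")

    pa = raw[list(pa_cols)].mean(axis=1, skipna=False).to_numpy(dtype=float)
    na = raw[list(na_cols)].mean(axis=1, skipna=False).to_numpy(dtype=float)
    values = raw[list(pa_cols) + list(na_cols)].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        bad = np.any((values < instrument_min) | (values > instrument_max), axis=1)
    if bad.any():
        rows = np.flatnonzero(bad).tolist()
        raise ValueError(
            f"ratings outside instrument range [{instrument_min}, {instrument_max}] "
            f"in rows {rows}"
        )

    span = instrument_max - instrument_min
    x = np.column_stack([(pa - instrument_min) / span, (na - instrument_min) / span])
    x = np.clip(x, 0.0, 1.0)
    valid = ~np.isnan(x).any(axis=1)

    t = raw[time_col].to_numpy(dtype=float)
    if day_col is not None and day_col in raw.columns:
        day = raw[day_col].to_numpy(dtype=int)
    else:
        day = np.floor(t / 24.0).astype(int)
    return AffectTimeSeries(t=t, x=x, day=day, valid=valid)
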