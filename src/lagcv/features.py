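"""Build the network's input design matrix from a daily series.

Every predictor becomes one input neuron: calendar one-hots (year, month,
day type), distributed temperature lags 0..max_lag, lagged death counts
1..max_lag (the same-day outcome never enters the design), and the
current-day pollutant levels.  With the default five-year series and
max_lag = 30 this is 5 + 12 + 3 + 31 + 30 + 2 = 83 columns.

The leading ``max_lag`` days lack a full lag history and are dropped rather
than zero-padded: an undefined exposure history must not be fabricated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_timeseries import DailySeries

logger = logging.getLogger("lagcv")

FEATURE_GROUPS = (
    "year",
    "month",
    "day_type",
    "temperature_lags",
    "mortality_lags",
    "pollutants",
)


@dataclass(frozen=True)
class FeatureMatrix:
    """Aligned design matrix X, outcome y and per-row dates."""

    X: pd.DataFrame
    y: pd.Series
    row_dates: pd.DatetimeIndex
    groups: dict[str, list[str]]
    continuous: tuple[str, ...]

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    @property
    def n_rows(self) -> int:
        return len(self.X)


@dataclass(frozen=True)
class ScalingRecord:
    """Centers/scales for the continuous columns, learned on a row subset."""

    center: dict[str, float]
    scale: dict[str, float]

    def apply(self, X: pd.DataFrame) -> pd.DataFrame:
        out = X.copy()
        for col, c in self.center.items():
            if col in out.columns:
                out[col] = (out[col] - c) / self.scale[col]
        return out


def build_feature_matrix(
    series: DailySeries,
    max_lag: int = 30,
    include: tuple[str, ...] = FEATURE_GROUPS,
    holidays: tuple | list = (),
) -> FeatureMatrix:
    """Expand a DailySeries into the network input matrix.

    ``include`` switches whole feature groups on/off; unknown names raise.
    ``holidays`` is a user-supplied list of holiday dates (the third day-type
    indicator; weekday/weekend are derived from the calendar).
    """
    unknown = set(include) - set(FEATURE_GROUPS)
    if unknown:
        raise ValueError(f"unknown feature group(s): {', '.join(sorted(unknown))}")
    f = series.frame
    n = len(f)
    if max_lag >= n:
        raise ValueError(f"max_lag={max_lag} must be smaller than the series ({n})")

    dates = f.index
    death = f["death"].to_numpy(dtype=float)
    temp = f["temperature"].to_numpy(dtype=float)
    holiday_set = {pd.Timestamp(h).normalize() for h in holidays}

    blocks: list[pd.DataFrame] = []
    groups: dict[str, list[str]] = {}
    continuous: list[str] = []

    rows = slice(max_lag, n)
    row_dates = dates[rows]

    if "year" in include:
        years = sorted(dates.year.unique())
        blk = pd.DataFrame(
            {f"year_{y}": (row_dates.year == y).astype(float) for y in years},
            index=row_dates,
        )
        blocks.append(blk)
        groups["year"] = list(blk.columns)
    if "month" in include:
        blk = pd.DataFrame(
            {f"month_{m:02d}": (row_dates.month == m).astype(float) for m in range(1, 13)},
            index=row_dates,
        )
        blocks.append(blk)
        groups["month"] = list(blk.columns)
    if "day_type" in include:
        is_holiday = np.array([d in holiday_set for d in row_dates.normalize()])
        is_weekend = np.asarray(row_dates.dayofweek >= 5) & ~is_holiday
        is_weekday = ~is_holiday & ~is_weekend
        blk = pd.DataFrame(
            {
                "weekday": is_weekday.astype(float),
                "weekend": is_weekend.astype(float),
                "holiday": is_holiday.astype(float),
            },
            index=row_dates,
        )
        blocks.append(blk)
        groups["day_type"] = list(blk.columns)
    if "temperature_lags" in include:
        cols = {
            f"temp_lag_{k:02d}": temp[max_lag - k : n - k] for k in range(max_lag + 1)
        }
        blk = pd.DataFrame(cols, index=row_dates)
        blocks.append(blk)
        groups["temperature_lags"] = list(blk.columns)
        continuous += list(blk.columns)
    if "mortality_lags" in include and max_lag >= 1:
        cols = {
            f"death_lag_{k:02d}": death[max_lag - k : n - k]
            for k in range(1, max_lag + 1)
        }
        blk = pd.DataFrame(cols, index=row_dates)
        blocks.append(blk)
        groups["mortality_lags"] = list(blk.columns)
        continuous += list(blk.columns)
    if "pollutants" in include:
        cols = {
            name: f[name].to_numpy(dtype=float)[rows]
            for name in ("o3", "pm25")
            if name in f.columns
        }
        blk = pd.DataFrame(cols, index=row_dates)
        blocks.append(blk)
        groups["pollutants"] = list(blk.columns)
        continuous += list(blk.columns)

    if not blocks:
        raise ValueError("no feature groups selected")
    X = pd.concat(blocks, axis=1)
    y = pd.Series(death[rows], index=row_dates, name="death")
    return FeatureMatrix(
        X=X, y=y, row_dates=row_dates, groups=groups, continuous=tuple(continuous)
    )


def standardize(
    fm: FeatureMatrix, stats_from: np.ndarray | list | None = None
) -> tuple[FeatureMatrix, ScalingRecord]:
    """Center/scale continuous columns by statistics of ``stats_from`` rows.

    ``stats_from`` holds positional row indices (default: all rows) — in CV
    use this is the fold's training rows, so validation rows are scaled by
    training statistics only.  Indicator columns are returned untouched; a
    zero-spread continuous column is left unscaled with a warning.
    """
    if stats_from is None:
        stats_from = np.arange(fm.n_rows)
    stats_from = np.asarray(stats_from, dtype=int)
    if stats_from.size == 0:
        raise ValueError("stats_from must be non-empty")
    center: dict[str, float] = {}
    scale: dict[str, float] = {}
    sub = fm.X.iloc[stats_from]
    for col in fm.continuous:
        mu = float(sub[col].mean())
        sd = float(sub[col].std(ddof=0))
        if sd == 0.0:
            logger.warning("column %s has zero spread; left unscaled", col)
            continue
        center[col] = mu
        scale[col] = sd
    record = ScalingRecord(center=center, scale=scale)
    scaled = FeatureMatrix(
        X=record.apply(fm.X),
        y=fm.y,
        row_dates=fm.row_dates,
        groups=fm.groups,
        continuous=fm.continuous,
    )
    return scaled, record
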