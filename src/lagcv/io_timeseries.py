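"""Reading, validating and writing daily environmental/health time series.

The raw input is a CSV with one row per calendar day carrying an all-cause
death count, the daily mean temperature and daily mean pollutant
concentrations (O3, PM2.5, optionally CO/PM10/SO2).  Rows with a missing
required field are dropped (the omission policy used for the motivating
Taipei 2012-2016 series, where the missing rate was low) and the number of
dropped rows is logged and recorded on the returned object.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("lagcv")

REQUIRED_COLUMNS = ("death", "temperature", "o3", "pm25")
OPTIONAL_COLUMNS = ("co", "pm10", "so2")

SCHEMES = ("five_fold", "lobo", "tb")


class FormatError(ValueError):
    """The file does not have the expected columns/shape."""


class ValidationError(ValueError):
    """The data violate a DailySeries invariant."""


@dataclass(frozen=True)
class DailySeries:
    """A validated daily series of deaths, temperature and pollutants.

    ``frame`` is indexed by a strictly increasing ``DatetimeIndex`` named
    ``date``.  Calendar gaps (from omitted incomplete days) are permitted but
    counted in ``n_gaps``; lag operations downstream are positional, i.e. a
    lag of k means "k rows earlier".
    """

    frame: pd.DataFrame
    n_dropped: int = 0

    def __post_init__(self) -> None:
        f = self.frame
        if not isinstance(f.index, pd.DatetimeIndex):
            raise ValidationError("DailySeries frame must be indexed by date")
        if f.index.has_duplicates:
            dup = f.index[f.index.duplicated()][0]
            raise ValidationError(f"duplicated date {dup.date()}")
        if not f.index.is_monotonic_increasing:
            bad = int(np.argmin(np.diff(f.index.values).astype("int64") > 0)) + 1
            raise ValidationError(
                f"dates not increasing: row {bad} ({f.index[bad].date()})"
            )
        if "death" in f.columns:
            d = f["death"].to_numpy(dtype=float)
            d = d[~np.isnan(d)]  # NaN marks covariate-only (burn-in) rows
            if np.any(~np.isfinite(d)) or np.any(d < 0) or np.any(d % 1 != 0):
                raise ValidationError("death must be a non-negative integer count")
        if "temperature" in f.columns and not np.all(
            np.isfinite(f["temperature"].to_numpy(dtype=float))
        ):
            raise ValidationError("temperature must be finite")
        for col in ("o3", "pm25", "co", "pm10", "so2"):
            if col in f.columns and np.any(f[col].to_numpy(dtype=float) < 0):
                raise ValidationError(f"{col} must be non-negative")

    @property
    def n_days(self) -> int:
        return len(self.frame)

    @property
    def dates(self) -> pd.DatetimeIndex:
        return self.frame.index

    @property
    def n_gaps(self) -> int:
        """Number of missing calendar days inside the covered span."""
        if len(self.frame) < 2:
            return 0
        span = (self.frame.index[-1] - self.frame.index[0]).days + 1
        return int(span - len(self.frame))

    @property
    def is_contiguous(self) -> bool:
        return self.n_gaps == 0

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.frame)


def read_daily_csv(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    date_column: str = "date",
    on_missing: str = "drop",
) -> DailySeries:
    """Read and validate a daily-series CSV.

    Parameters
    ----------
    column_map
        Mapping from file column names to the canonical names
        (``death``, ``temperature``, ``o3``, ``pm25``, ...).
    on_missing
        ``"drop"`` (default) removes rows with any missing required field and
        logs the count; ``"error"`` raises instead.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path)
    if column_map:
        raw = raw.rename(columns=column_map)
        if date_column in column_map:
            date_column = column_map[date_column]
    if date_column not in raw.columns:
        raise FormatError(f"missing date column {date_column!r}")
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")

    raw["date"] = pd.to_datetime(raw[date_column], format="ISO8601")
    keep = ["date"] + [
        c for c in REQUIRED_COLUMNS + OPTIONAL_COLUMNS if c in raw.columns
    ]
    raw = raw[keep]
    for c in keep[1:]:
        raw[c] = pd.to_numeric(raw[c], errors="coerce")

    complete = raw[list(REQUIRED_COLUMNS)].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped and on_missing == "error":
        raise ValidationError(f"{n_dropped} row(s) with missing required fields")
    if n_dropped:
        logger.warning("omitted %d incomplete row(s) from %s", n_dropped, path.name)
    data = raw[complete].set_index("date")
    data.index.name = "date"
    series = DailySeries(frame=data, n_dropped=n_dropped)
    if series.n_gaps:
        logger.warning("%d calendar day(s) absent inside the span", series.n_gaps)
    return series


def write_daily_csv(series: DailySeries, path: str | Path) -> Path:
    """Write a DailySeries back to CSV in the same schema read_daily_csv expects."""
    path = Path(path)
    out = series.frame.reset_index()
    out["date"] = out["date"].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)
    return path


def write_report(results, path: str | Path) -> Path:
    """Write a grid/PR report as CSV, one row per hyperparameter cell.

    ``results`` may be a :class:`~lagcv.harness.GridResult` or a DataFrame.
    Floats are written at full ``repr`` precision so the file round-trips
    losslessly through :func:`read_report`.
    """
    table = getattr(results, "table", results)
    if not isinstance(table, pd.DataFrame):
        raise TypeError("results must be a GridResult or DataFrame")
    if table.empty:
        raise ValueError("refusing to write an empty report")
    out = table.copy()
    scheme = getattr(results, "scheme", None)
    if scheme is not None and "scheme" not in out.columns:
        out.insert(0, "scheme", scheme)
    out.to_csv(path, index=False, float_format="%.17g")
    return Path(path)


def read_report(path: str | Path) -> pd.DataFrame:
    """Read a report written by :func:`write_report`."""
    df = pd.read_csv(path)
    if df.empty:
        raise FormatError(f"empty report {path}")
    return df


@dataclass(frozen=True)
class RunConfig:
    """Run-level configuration; every CLI flag maps onto one field."""

    train_fraction: float = 0.70
    n_folds: int = 5
    max_lag: int = 30
    max_iterations: int = 50_000
    seed: int = 0
    hidden_layout: tuple[int, ...] = (12, 12)
    scheme: str = "five_fold"
    n_permutations: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.max_lag < 0:
            raise ValueError("max_lag must be >= 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if any(w < 1 for w in self.hidden_layout):
            raise ValueError("hidden layer widths must be >= 1")
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}")
        object.__setattr__(self, "hidden_layout", tuple(self.hidden_layout))

    def replace(self, **kw) -> "RunConfig":
        return dataclasses.replace(self, **kw)


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Load a YAML config file; keyword overrides win over file keys."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    unknown = set(data) - {f.name for f in dataclasses.fields(RunConfig)}
    if unknown:
        raise FormatError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    data.update({k: v for k, v in overrides.items() if v is not None})
    if "hidden_layout" in data and isinstance(data["hidden_layout"], (list, str)):
        v = data["hidden_layout"]
        data["hidden_layout"] = tuple(
            int(x) for x in (v.split(",") if isinstance(v, str) else v)
        )
    return RunConfig(**data)
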