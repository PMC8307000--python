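"""Weekly pheromone-trap captures: aggregation and DD-axis transformation.

Raw monitoring data are one row per trap and check date. Per area and year,
weekly means and standard errors over the traps present that week are
computed, and the weekly series is then re-keyed from calendar dates to the
cumulative degree days accrued by each check date.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidInputError, MissingWeatherError
from .thermal import DDSeries

__all__ = [
    "TrapCatchSeries",
    "DDCatchSeries",
    "aggregate_traps",
    "to_dd_axis",
    "read_catch_csv",
]

RAW_COLUMNS = {"area", "year", "check_date", "trap_id", "catch_count"}
AGG_COLUMNS = {"area", "year", "check_date", "mean_catch", "se", "n_traps"}


@dataclass
class TrapCatchSeries:
    """Weekly mean catches per trap (±SE) for one area-year.

    ``data`` has columns ``check_date`` (strictly increasing), ``mean_catch``,
    ``se`` and ``n_traps``. A weekly catch is anchored to its check date, the
    end of the exposure week.
    """

    area: str
    year: int
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        df = self.data
        need = {"check_date", "mean_catch", "se", "n_traps"}
        if not need.issubset(df.columns):
            raise InvalidInputError(f"trap series needs columns {sorted(need)}")
        dates = pd.to_datetime(df["check_date"])
        if not dates.is_monotonic_increasing or dates.duplicated().any():
            raise InvalidInputError("check dates must be strictly increasing")
        if (df["mean_catch"] < 0).any() or (df["se"] < 0).any():
            raise InvalidInputError("mean_catch and se must be non-negative")
        if (df["n_traps"] < 1).any():
            raise InvalidInputError("n_traps must be >= 1")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def total_moths(self) -> float:
        """Season total across traps, sum of mean_catch * n_traps."""
        return float((self.data["mean_catch"] * self.data["n_traps"]).sum())


@dataclass
class DDCatchSeries:
    """Weekly catches keyed by cumulative DD at the check date.

    ``data`` keeps ``check_date`` alongside ``cumulative_dd`` (strictly
    increasing), ``mean_catch``, ``se`` and ``n_traps`` so downstream stages
    can report both axes.
    """

    area: str
    year: int
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        dd = self.data["cumulative_dd"].to_numpy()
        if len(dd) > 1 and not (np.diff(dd) > 0).all():
            raise InvalidInputError("cumulative_dd must be strictly increasing")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def total_moths(self) -> float:
        return float((self.data["mean_catch"] * self.data["n_traps"]).sum())


def aggregate_traps(raw: pd.DataFrame) -> list[TrapCatchSeries]:
    """Aggregate per-trap weekly counts into per-area-year weekly means.

    ``raw`` has columns area, year, check_date, trap_id, catch_count. Per
    week: mean over the traps reporting that week, SE = sample standard
    deviation / sqrt(n); SE is 0 when a single trap reports. Weeks where no
    trap reports a count are omitted with a warning.
    """
    if not RAW_COLUMNS.issubset(raw.columns):
        raise InvalidInputError(f"per-trap data needs columns {sorted(RAW_COLUMNS)}")
    counts = raw["catch_count"]
    if (counts.dropna() < 0).any():
        raise InvalidInputError("catch counts must be non-negative")

    raw = raw.copy()
    raw["check_date"] = pd.to_datetime(raw["check_date"])
    out = []
    for (area, year), grp in raw.groupby(["area", "year"], sort=True):
        rows = []
        for date, week in grp.groupby("check_date", sort=True):
            vals = week["catch_count"].dropna().to_numpy(float)
            if len(vals) == 0:
                warnings.warn(
                    f"{area} {year}: no reporting traps on {date.date()}; week omitted",
                    stacklevel=2,
                )
                continue
            n = len(vals)
            se = float(np.std(vals, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
            rows.append((date, float(vals.mean()), se, n))
        df = pd.DataFrame(rows, columns=["check_date", "mean_catch", "se", "n_traps"])
        out.append(TrapCatchSeries(area=str(area), year=int(year), data=df))
    return out


def to_dd_axis(series: TrapCatchSeries, dds: DDSeries) -> DDCatchSeries:
    """Re-key a weekly catch series by cumulative DD at each check date."""
    lookup = dds.data["cumulative_dd"]
    dd_vals = []
    for date in pd.to_datetime(series.data["check_date"]):
        if date not in lookup.index:
            raise MissingWeatherError(
                f"{series.area} {series.year}: no weather for check date {date.date()}"
            )
        dd_vals.append(float(lookup.loc[date]))
    df = series.data.copy()
    df.insert(1, "cumulative_dd", dd_vals)
    return DDCatchSeries(area=series.area, year=series.year, data=df.reset_index(drop=True))


def read_catch_csv(path) -> list[TrapCatchSeries]:
    """Read trap catches from CSV, per-trap or pre-aggregated layout.

    Per-trap layout: ``area,year,check_date,trap_id,catch_count`` (aggregated
    here). Pre-aggregated layout: ``area,year,check_date,mean_catch,se,n_traps``.
    """
    df = pd.read_csv(path, parse_dates=["check_date"])
    cols = set(df.columns)
    if RAW_COLUMNS.issubset(cols):
        return aggregate_traps(df)
    if AGG_COLUMNS.issubset(cols):
        out = []
        for (area, year), grp in df.groupby(["area", "year"], sort=True):
            grp = grp.sort_values("check_date").reset_index(drop=True)
            out.append(
                TrapCatchSeries(
                    area=str(area),
                    year=int(year),
                    data=grp[["check_date", "mean_catch", "se", "n_traps"]],
                )
            )
        return out
    raise InvalidInputError(
        "catch CSV must have per-trap columns "
        f"{sorted(RAW_COLUMNS)} or aggregated columns {sorted(AGG_COLUMNS)}"
    )
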