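"""Degree-day accumulation from daily min/max temperatures.

The daily temperature course is modelled as a single sine wave fitted to the
day's minimum and maximum. Degree days (DD) are the area between the lower
development threshold and the sine curve, with the curve capped at the upper
threshold (horizontal cutoff: development proceeds at its maximal rate above
the upper threshold, it is not reduced). Accumulation restarts every
1 January, which serves as the biofix for the forecast model downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidConfigError, InvalidInputError, NotReachedError, UnfillableGapError

__all__ = [
    "DDParams",
    "TemperatureSeries",
    "DDSeries",
    "single_day_dd",
    "accumulate_dd",
    "date_at_dd",
    "fill_missing",
    "read_weather_csv",
]

DEFAULT_LOWER = 7.2
DEFAULT_UPPER = 32.2


@dataclass(frozen=True)
class DDParams:
    """Thresholds for the degree-day computation.

    Parameters
    ----------
    lower : float
        Lower development threshold in degrees Celsius.
    upper : float
        Upper development threshold in degrees Celsius.
    cutoff : str
        Cutoff rule above the upper threshold; only ``"horizontal"`` is
        supported.
    """

    lower: float = DEFAULT_LOWER
    upper: float = DEFAULT_UPPER
    cutoff: str = "horizontal"

    def __post_init__(self):
        if not np.isfinite(self.lower) or not np.isfinite(self.upper):
            raise InvalidConfigError("thresholds must be finite")
        if self.lower >= self.upper:
            raise InvalidConfigError(
                f"lower threshold ({self.lower}) must be below upper ({self.upper})"
            )
        if self.cutoff != "horizontal":
            raise InvalidConfigError(f"unsupported cutoff {self.cutoff!r}; only 'horizontal'")

    @property
    def span(self) -> float:
        """Maximum attainable daily degree days, ``upper - lower``."""
        return self.upper - self.lower


@dataclass
class TemperatureSeries:
    """Daily min/max temperatures for one weather station.

    ``data`` is indexed by calendar date (datetime64, daily) with float
    columns ``tmin`` and ``tmax`` in degrees Celsius. Invariants —
    tmin <= tmax on every day, strictly increasing dates — are checked at
    construction.
    """

    station_id: str
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        df = self.data
        if not {"tmin", "tmax"}.issubset(df.columns):
            raise InvalidInputError("temperature data needs 'tmin' and 'tmax' columns")
        if len(df) == 0:
            raise InvalidInputError("temperature series is empty")
        if not df.index.is_monotonic_increasing or df.index.has_duplicates:
            raise InvalidInputError("dates must be strictly increasing")
        finite = np.isfinite(df["tmin"].to_numpy()) & np.isfinite(df["tmax"].to_numpy())
        if not finite.all():
            bad = df.index[~finite][0]
            raise InvalidInputError(f"non-finite temperature on {bad.date()}")
        if (df["tmin"] > df["tmax"]).any():
            bad = df.index[(df["tmin"] > df["tmax"]).to_numpy()][0]
            raise InvalidInputError(f"tmin > tmax on {bad.date()}")

    def __len__(self) -> int:
        return len(self.data)

    def to_csv(self, path) -> None:
        out = self.data.rename(columns={"tmin": "tmin_C", "tmax": "tmax_C"})
        out.index.name = "date"
        out.to_csv(path, float_format="%.6g", date_format="%Y-%m-%d")


@dataclass
class DDSeries:
    """Per-day and cumulative degree days on the calendar axis.

    ``data`` is indexed by date with columns ``daily_dd`` and
    ``cumulative_dd``; the cumulative sum restarts at every 1 January.
    ``partial_year`` is set when the series does not start on 1 January, in
    which case cumulative values for the first year are lower bounds.
    """

    station_id: str
    data: pd.DataFrame = field(repr=False)
    partial_year: bool = False

    def to_csv(self, path) -> None:
        out = self.data[["daily_dd", "cumulative_dd"]].copy()
        out.index.name = "date"
        out.to_csv(path, float_format="%.6f", date_format="%Y-%m-%d")


def _sine_dd_vec(tmin: np.ndarray, tmax: np.ndarray, params: DDParams) -> np.ndarray:
    """Vectorised six-case closed form of the clipped single-sine integral.

    With m = (tmin+tmax)/2 and a = (tmax-tmin)/2 the daily curve is
    T(t) = m + a*sin(2*pi*t); the result is the integral over one period of
    max(0, min(T, upper) - lower).
    """
    lower, upper = params.lower, params.upper
    m = (tmin + tmax) / 2.0
    a = (tmax - tmin) / 2.0

    out = np.empty_like(m)
    below = tmax <= lower
    above = tmin >= upper
    inside = (tmin >= lower) & (tmax <= upper) & ~below
    cut_low = (tmin < lower) & (tmax > lower) & (tmax <= upper)
    cut_up = (tmin >= lower) & (tmin < upper) & (tmax > upper)
    cut_both = (tmin < lower) & (tmax > upper)

    out[below] = 0.0
    out[above] = upper - lower
    out[inside] = m[inside] - lower

    if cut_low.any():
        mm, aa = m[cut_low], a[cut_low]
        t1 = np.arcsin((lower - mm) / aa)
        out[cut_low] = ((mm - lower) * (np.pi / 2 - t1) + aa * np.cos(t1)) / np.pi
    if cut_up.any():
        mm, aa = m[cut_up], a[cut_up]
        t2 = np.arcsin((upper - mm) / aa)
        out[cut_up] = (
            (mm - lower) * (t2 + np.pi / 2)
            + (upper - lower) * (np.pi / 2 - t2)
            - aa * np.cos(t2)
        ) / np.pi
    if cut_both.any():
        mm, aa = m[cut_both], a[cut_both]
        t1 = np.arcsin((lower - mm) / aa)
        t2 = np.arcsin((upper - mm) / aa)
        out[cut_both] = (
            (mm - lower) * (t2 - t1)
            + aa * (np.cos(t1) - np.cos(t2))
            + (upper - lower) * (np.pi / 2 - t2)
        ) / np.pi
    # guard against sign noise at the case boundaries
    return np.clip(out, 0.0, upper - lower)


def single_day_dd(tmin: float, tmax: float, params: DDParams | None = None) -> float:
    """Degree days accrued on one day, single-sine method with horizontal cutoff.

    Parameters
    ----------
    tmin, tmax : float
        Daily minimum and maximum temperature (Celsius), ``tmin <= tmax``.
    params : DDParams, optional
        Thresholds; defaults to lower 7.2 °C, upper 32.2 °C.

    Returns
    -------
    float
        Degree days in ``[0, params.upper - params.lower]``.
    """
    params = params or DDParams()
    if not (np.isfinite(tmin) and np.isfinite(tmax)):
        raise InvalidInputError("temperatures must be finite")
    if tmin > tmax:
        raise InvalidInputError(f"tmin ({tmin}) exceeds tmax ({tmax})")
    return float(_sine_dd_vec(np.asarray([tmin], float), np.asarray([tmax], float), params)[0])


def accumulate_dd(series: TemperatureSeries, params: DDParams | None = None) -> DDSeries:
    """Accumulate degree days over a temperature series.

    The cumulative sum restarts at zero on every 1 January; 1 January itself
    contributes its own daily DD (biofix day inclusive). A series starting
    after 1 January of its first year yields a ``partial_year`` flag and a
    warning, because cumulative values for that year are lower bounds.
    """
    params = params or DDParams()
    df = series.data
    daily = _sine_dd_vec(df["tmin"].to_numpy(float), df["tmax"].to_numpy(float), params)
    out = pd.DataFrame({"daily_dd": daily}, index=df.index)
    out["cumulative_dd"] = out.groupby(out.index.year)["daily_dd"].cumsum()

    first = df.index[0]
    partial = not (first.month == 1 and first.day == 1)
    if partial:
        warnings.warn(
            f"series for {series.station_id} starts {first.date()}, after 1 January; "
            "cumulative DD for the first year are lower bounds",
            stacklevel=2,
        )
    return DDSeries(station_id=series.station_id, data=out, partial_year=partial)


def date_at_dd(dds: DDSeries, target: float, year: int) -> pd.Timestamp:
    """First date in ``year`` whose cumulative DD reaches ``target``.

    Raises
    ------
    NotReachedError
        If the year's final cumulative DD stays below ``target``.
    """
    if target < 0:
        raise InvalidInputError("target DD must be non-negative")
    sub = dds.data[dds.data.index.year == year]
    if len(sub) == 0:
        raise NotReachedError(f"no degree-day data for year {year}")
    hit = sub.index[sub["cumulative_dd"].to_numpy() >= target]
    if len(hit) == 0:
        raise NotReachedError(
            f"{target:.1f} DD never reached in {year} "
            f"(season total {sub['cumulative_dd'].iloc[-1]:.1f} DD)"
        )
    return hit[0]


def fill_missing(series: TemperatureSeries, max_gap: int = 3) -> TemperatureSeries:
    """Fill short runs of missing days by linear interpolation.

    The series is reindexed to daily frequency; gaps of at most ``max_gap``
    consecutive missing days are filled by interpolating tmin and tmax
    separately. Longer gaps raise :class:`UnfillableGapError` naming the gap.
    """
    df = series.data.asfreq("D")
    missing = df["tmin"].isna() | df["tmax"].isna()
    if not missing.any():
        return TemperatureSeries(series.station_id, df)

    # locate runs of consecutive missing days
    m = missing.to_numpy()
    edges = np.flatnonzero(np.diff(np.concatenate(([0], m.view(np.int8), [0]))))
    for start, stop in zip(edges[::2], edges[1::2]):
        if stop - start > max_gap:
            a, b = df.index[start], df.index[stop - 1]
            raise UnfillableGapError(
                f"{stop - start}-day weather gap {a.date()}..{b.date()} exceeds "
                f"max_gap={max_gap}",
                gap_start=a,
                gap_end=b,
            )
    filled = df.interpolate(method="time", limit_area="inside")
    if filled["tmin"].isna().any() or filled["tmax"].isna().any():
        raise UnfillableGapError("missing values at series edge cannot be interpolated")
    return TemperatureSeries(series.station_id, filled)


def read_weather_csv(path, station_id: str | None = None) -> TemperatureSeries:
    """Read a weather CSV with header ``date,tmin_C,tmax_C`` (ISO dates)."""
    df = pd.read_csv(path, parse_dates=["date"])
    expected = {"date", "tmin_C", "tmax_C"}
    if not expected.issubset(df.columns):
        raise InvalidInputError(f"weather CSV must have columns {sorted(expected)}")
    df = df.set_index("date").rename(columns={"tmin_C": "tmin", "tmax_C": "tmax"})
    return TemperatureSeries(station_id or str(path), df[["tmin", "tmax"]])
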