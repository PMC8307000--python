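"""Flight segmentation of weekly capture series on the DD axis.

A season's capture curve is split into flights at the minima between
successive peaks. The boundary week (the minimum) closes the earlier flight;
the later flight's first member week is the following check date, but both
flights share the boundary's cumulative-DD value so flight durations
telescope: minimum-to-minimum DD spans, the operational adult-to-adult
generation time. Boundaries that a year fails to resolve (overlapping
flights) are imputed from the same boundary in the other years of the area.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import InsufficientDataError, InvalidInputError
from .traps import DDCatchSeries

__all__ = [
    "FlightSegment",
    "GenerationDurationRecord",
    "smooth_series",
    "detect_peaks",
    "split_at_minima",
    "segment_season",
    "reconcile_across_years",
    "duration_table",
    "segments_to_frame",
]

DEFAULT_SMOOTH_WINDOW = 3
DEFAULT_PROMINENCE_FRAC = 0.15


@dataclass
class FlightSegment:
    """One detected flight period.

    ``start_week``/``end_week`` are the first/last check dates whose catches
    belong to the flight. ``dd_start``/``dd_end`` are the flight's span on the
    cumulative-DD axis; interior boundaries are shared between neighbouring
    flights so that durations sum to the season span. ``complete`` is False
    for a first flight whose start was not observed (catches already present,
    and falling, at the first check) and for a last flight whose end was not
    observed.
    """

    flight_order: int
    start_week: pd.Timestamp
    end_week: pd.Timestamp
    dd_start: float
    dd_end: float
    complete: bool = True
    unsplit: bool = False
    imputed_boundary: bool = False

    @property
    def duration_dd(self) -> float:
        return self.dd_end - self.dd_start


@dataclass(frozen=True)
class GenerationDurationRecord:
    province: str
    area: str
    year: int
    flight_order: int
    duration_dd: float


def smooth_series(series: DDCatchSeries, window: int = DEFAULT_SMOOTH_WINDOW) -> DDCatchSeries:
    """Centred moving average of mean_catch; endpoints use shrunken windows."""
    if window < 1 or window % 2 == 0:
        raise InvalidInputError("smoothing window must be odd and >= 1")
    df = series.data.copy()
    if window > 1:
        df["mean_catch"] = (
            df["mean_catch"].rolling(window, center=True, min_periods=1).mean()
        )
    return DDCatchSeries(area=series.area, year=series.year, data=df)


def detect_peaks(
    series: DDCatchSeries, min_prominence_frac: float = DEFAULT_PROMINENCE_FRAC
) -> list[int]:
    """Indices of local maxima with prominence >= frac * max(mean_catch).

    Plateau peaks report their first index. An all-zero series yields an
    empty list, as does a monotone one (endpoints are never peaks).
    """
    if not 0 < min_prominence_frac <= 1:
        raise InvalidInputError("min_prominence_frac must be in (0, 1]")
    y = series.data["mean_catch"].to_numpy(float)
    top = y.max() if len(y) else 0.0
    if top <= 0:
        return []
    idx, props = find_peaks(y, prominence=min_prominence_frac * top, plateau_size=1)
    return [int(i) for i in props["left_edges"]] if len(idx) else []


def _boundary_indices(y: np.ndarray, peaks: list[int]) -> list[int]:
    """Minimum between each consecutive peak pair; ties pick the earliest week."""
    bounds = []
    for a, b in zip(peaks[:-1], peaks[1:]):
        inner = y[a + 1 : b]
        if len(inner) == 0:
            bounds.append(a)  # adjacent peaks: boundary at the earlier peak
        else:
            bounds.append(a + 1 + int(np.argmin(inner)))
    return bounds


def split_at_minima(
    series: DDCatchSeries,
    peaks: list[int],
    smoothed: DDCatchSeries | None = None,
) -> list[FlightSegment]:
    """Split a season into flights at the minima between consecutive peaks.

    The minimum is located on ``smoothed`` (default: the raw series); flight
    extents and DD endpoints come from the raw series. The first flight starts
    at the first week with a nonzero catch and the last flight ends at the
    last such week. Without any peak a single segment flagged ``unsplit`` is
    returned; an all-zero season yields no segments.
    """
    df = series.data
    raw = df["mean_catch"].to_numpy(float)
    nz = np.flatnonzero(raw > 0)
    if len(nz) == 0:
        return []
    first_i, last_i = int(nz[0]), int(nz[-1])

    dates = pd.to_datetime(df["check_date"]).reset_index(drop=True)
    dd = df["cumulative_dd"].to_numpy(float)
    start_observed = first_i > 0
    end_observed = last_i < len(raw) - 1

    if len(peaks) == 0:
        return [
            FlightSegment(
                flight_order=1,
                start_week=dates[first_i],
                end_week=dates[last_i],
                dd_start=float(dd[first_i]),
                dd_end=float(dd[last_i]),
                complete=start_observed and end_observed,
                unsplit=True,
            )
        ]

    yb = (series if smoothed is None else smoothed).data["mean_catch"].to_numpy(float)
    if len(yb) != len(raw):
        raise InvalidInputError("smoothed series length differs from raw series")
    bounds = _boundary_indices(yb, sorted(peaks))

    segments = []
    seg_start_i, seg_start_dd = first_i, float(dd[first_i])
    for order, b in enumerate(bounds + [last_i], start=1):
        is_last = order == len(bounds) + 1
        segments.append(
            FlightSegment(
                flight_order=order,
                start_week=dates[seg_start_i],
                end_week=dates[b],
                dd_start=seg_start_dd,
                dd_end=float(dd[b]),
                complete=(order > 1 or start_observed) and (not is_last or end_observed),
            )
        )
        seg_start_i, seg_start_dd = b + 1, float(dd[b])
    return segments


def segment_season(
    series: DDCatchSeries,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    min_prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
) -> list[FlightSegment]:
    """Smooth, detect peaks and split one season's series into flights."""
    sm = smooth_series(series, smooth_window)
    peaks = detect_peaks(sm, min_prominence_frac)
    return split_at_minima(series, peaks, smoothed=sm)


def _order_preserving_match(values: list[float], slots: list[float]) -> list[int]:
    """Assign each value to a distinct slot, order preserved, min total |diff|.

    Small dynamic programme over (value index, slot index); returns the slot
    index chosen for each value.
    """
    m, k = len(values), len(slots)
    inf = float("inf")
    cost = np.full((m + 1, k + 1), inf)
    cost[0, :] = 0.0
    choice = np.zeros((m + 1, k + 1), dtype=bool)
    for i in range(1, m + 1):
        for j in range(1, k + 1):
            skip = cost[i, j - 1]
            take = cost[i - 1, j - 1] + abs(values[i - 1] - slots[j - 1])
            if take <= skip:
                cost[i, j], choice[i, j] = take, True
            else:
                cost[i, j] = skip
    # backtrack
    out = []
    i, j = m, k
    while i > 0:
        if choice[i, j]:
            out.append(j - 1)
            i -= 1
        j -= 1
    return out[::-1]


def reconcile_across_years(
    segmentations: dict[int, list[FlightSegment]],
    series_by_year: dict[int, DDCatchSeries],
) -> tuple[dict[int, list[FlightSegment]], list[str]]:
    """Impute boundaries a year failed to resolve from the other years.

    The expected number of boundaries is the maximum resolved in any year of
    the area. For a deficient year, its detected boundaries are matched to
    the cross-year median boundary positions (order-preserving, minimum total
    DD distance); each unmatched position is imputed at the median DD of that
    boundary across the years that resolved it, splitting the containing
    segment at the last check date at or below the imputed DD. Imputed
    boundaries are flagged on both adjacent flights. Returns the adjusted
    segmentations and a list of unresolved-boundary messages.
    """
    if len(segmentations) < 2:
        raise InsufficientDataError("cross-year reconciliation needs >= 2 years")

    def boundaries(segs):
        return [s.dd_end for s in segs[:-1]]

    n_bounds = {yr: len(boundaries(segs)) for yr, segs in segmentations.items()}
    k = max(n_bounds.values())
    unresolved = []
    if k == 0:
        unresolved.append("no year resolved any flight boundary")
        return dict(segmentations), unresolved

    full_years = [yr for yr, n in n_bounds.items() if n == k]
    ref = [
        float(np.median([boundaries(segmentations[yr])[j] for yr in full_years]))
        for j in range(k)
    ]

    adjusted = {}
    for yr, segs in sorted(segmentations.items()):
        if n_bounds[yr] == k or not segs:
            adjusted[yr] = [replace(s) for s in segs]
            continue
        own = boundaries(segs)
        matched = set(_order_preserving_match(own, ref)) if own else set()
        missing_dd = [ref[j] for j in range(k) if j not in matched]
        adjusted[yr] = _insert_boundaries(segs, missing_dd, series_by_year[yr], yr, unresolved)
    return adjusted, unresolved


def _insert_boundaries(segs, missing_dd, series, year, unresolved):
    df = series.data
    dd = df["cumulative_dd"].to_numpy(float)
    dates = pd.to_datetime(df["check_date"]).reset_index(drop=True)
    out = [replace(s) for s in segs]
    for v in sorted(missing_dd):
        host_i = next(
            (i for i, s in enumerate(out) if s.dd_start <= v < s.dd_end), None
        )
        if host_i is None:
            unresolved.append(
                f"year {year}: imputed boundary at {v:.1f} DD falls outside all flights"
            )
            continue
        host = out[host_i]
        inside = np.flatnonzero(
            (dd <= v) & (dates >= host.start_week) & (dates < host.end_week)
        )
        if len(inside) == 0:
            unresolved.append(
                f"year {year}: no check week available to place boundary at {v:.1f} DD"
            )
            continue
        b = int(inside[-1])
        earlier = replace(
            host, end_week=dates[b], dd_end=float(v), imputed_boundary=True, unsplit=False
        )
        later = replace(
            host,
            start_week=dates[b + 1] if b + 1 < len(dates) else dates[b],
            dd_start=float(v),
            imputed_boundary=True,
            unsplit=False,
        )
        out[host_i : host_i + 1] = [earlier, later]
    for order, s in enumerate(out, start=1):
        s.flight_order = order
    return out


def duration_table(
    segmentations: dict[tuple[str, int], list[FlightSegment]],
    province_of: dict[str, str],
) -> list[GenerationDurationRecord]:
    """One duration record per complete flight.

    A first flight whose start was unobserved (catch curve already descending
    at the first check) and a last flight whose end was unobserved are
    excluded, as are unsplit segments.
    """
    records = []
    for (area, year), segs in sorted(segmentations.items()):
        province = province_of.get(area)
        if province is None:
            warnings.warn(f"area {area!r} has no province mapping; skipped", stacklevel=2)
            continue
        for s in segs:
            if not s.complete or s.unsplit:
                continue
            records.append(
                GenerationDurationRecord(
                    province=province,
                    area=area,
                    year=year,
                    flight_order=s.flight_order,
                    duration_dd=s.duration_dd,
                )
            )
    return records


def segments_to_frame(
    segmentations: dict[tuple[str, int], list[FlightSegment]],
    province_of: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Tabulate flight segments for CSV output."""
    rows = []
    for (area, year), segs in sorted(segmentations.items()):
        for s in segs:
            rows.append(
                {
                    "province": (province_of or {}).get(area, ""),
                    "area": area,
                    "year": year,
                    "flight_order": s.flight_order,
                    "start_date": s.start_week.date(),
                    "end_date": s.end_week.date(),
                    "dd_start": round(s.dd_start, 3),
                    "dd_end": round(s.dd_end, 3),
                    "duration_dd": round(s.duration_dd, 3),
                    "complete": s.complete,
                    "imputed_boundary": s.imputed_boundary,
                }
            )
    return pd.DataFrame(rows)
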