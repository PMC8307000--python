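"""Fixed-offset multivoltine forecast on the degree-day axis.

The forecast predicts the first moth catch at a fixed cumulative DD after
1 January (the biofix offset, default 126 DD) and successive generations at a
fixed egg-to-egg generation time (default 535 DD). An optional host
development delay (60 DD for larvae feeding on apple instead of peach) widens
every generation window.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd
import yaml

from .errors import InvalidConfigError, NotReachedError
from .thermal import DDSeries, date_at_dd

__all__ = [
    "PhenologyModelParams",
    "GenerationWindow",
    "effective_generation_dd",
    "generation_windows",
    "windows_to_calendar",
    "windows_to_frame",
    "APPLE_DELAY_DD",
]

APPLE_DELAY_DD = 60.0


@dataclass(frozen=True)
class PhenologyModelParams:
    """Constants of the degree-day forecast model.

    biofix_dd : cumulative DD after 1 January at which the first catch is
        predicted (default 126).
    generation_dd : egg-to-egg generation time in DD (default 535).
    host_delay_dd : extra DD per generation for development on the slower
        host (0 for peach, 60 for apple).
    n_generations : number of generation windows to project (default 5).
    """

    biofix_dd: float = 126.0
    generation_dd: float = 535.0
    host_delay_dd: float = 0.0
    n_generations: int = 5

    def __post_init__(self):
        if self.biofix_dd < 0:
            raise InvalidConfigError("biofix_dd must be >= 0")
        if self.generation_dd <= 0:
            raise InvalidConfigError("generation_dd must be > 0")
        if self.host_delay_dd < 0:
            raise InvalidConfigError("host_delay_dd must be >= 0")
        if self.n_generations < 1:
            raise InvalidConfigError("n_generations must be >= 1")

    @classmethod
    def for_host(cls, host: str, **kwargs) -> "PhenologyModelParams":
        """Parameters for ``host`` in {'peach', 'apple'}."""
        host = host.lower()
        if host == "peach":
            return cls(host_delay_dd=0.0, **kwargs)
        if host == "apple":
            return cls(host_delay_dd=APPLE_DELAY_DD, **kwargs)
        raise InvalidConfigError(f"unknown host {host!r}; expected 'peach' or 'apple'")

    @classmethod
    def from_file(cls, path) -> "PhenologyModelParams":
        """Load parameters from a YAML/JSON mapping; absent keys keep defaults."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {"biofix_dd", "generation_dd", "host_delay_dd", "n_generations"}
        unknown = set(raw) - known
        if unknown:
            raise InvalidConfigError(f"unknown model config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class GenerationWindow:
    """One predicted generation as a half-open DD interval [dd_start, dd_end).

    Calendar dates are filled by :func:`windows_to_calendar`; ``unreached``
    marks windows beyond the season's accumulated DD.
    """

    index: int
    dd_start: float
    dd_end: float
    date_start: pd.Timestamp | None = None
    date_end: pd.Timestamp | None = None
    unreached: bool = False

    @property
    def width_dd(self) -> float:
        return self.dd_end - self.dd_start


def effective_generation_dd(params: PhenologyModelParams) -> float:
    """Width of each predicted generation window: generation_dd + host_delay_dd."""
    return params.generation_dd + params.host_delay_dd


def generation_windows(params: PhenologyModelParams) -> list[GenerationWindow]:
    """Project ``params.n_generations`` half-open windows on the DD axis.

    Window k (1-based) spans [biofix + (k-1)*G, biofix + k*G) with
    G = :func:`effective_generation_dd`; windows tile without gaps.
    """
    g = effective_generation_dd(params)
    return [
        GenerationWindow(
            index=k,
            dd_start=params.biofix_dd + (k - 1) * g,
            dd_end=params.biofix_dd + k * g,
        )
        for k in range(1, params.n_generations + 1)
    ]


def windows_to_calendar(
    windows: list[GenerationWindow], dds: DDSeries, year: int | None = None
) -> list[GenerationWindow]:
    """Attach calendar dates to DD windows via the cumulative DD series.

    Windows whose start (or end) exceeds the season's accumulated DD are
    flagged ``unreached`` with the unreachable date left as None. DD fields
    are never modified.
    """
    if year is None:
        years = sorted(set(dds.data.index.year))
        if len(years) != 1:
            raise InvalidConfigError("year must be given for a multi-year DD series")
        year = years[0]

    out = []
    for w in windows:
        w = replace(w)
        try:
            w.date_start = date_at_dd(dds, w.dd_start, year)
        except NotReachedError:
            w.unreached = True
            out.append(w)
            continue
        try:
            w.date_end = date_at_dd(dds, w.dd_end, year)
        except NotReachedError:
            w.unreached = True
        out.append(w)
    return out


def windows_to_frame(windows: list[GenerationWindow]) -> pd.DataFrame:
    """Tabulate windows for CSV output."""
    return pd.DataFrame(
        {
            "generation": [w.index for w in windows],
            "dd_start": [w.dd_start for w in windows],
            "dd_end": [w.dd_end for w in windows],
            "date_start": [w.date_start.date() if w.date_start is not None else "" for w in windows],
            "date_end": [w.date_end.date() if w.date_end is not None else "" for w in windows],
            "unreached": [w.unreached for w in windows],
        }
    )
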