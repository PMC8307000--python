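"""Comparison of observed flights against predicted generation windows.

Coverage quantifies how much of the season's catch falls inside the
predicted windows; boundary offsets measure, per generation, how far each
observed flight start sits from its rank-matched predicted window start
(positive = observed later than predicted).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .errors import InvalidInputError
from .model import GenerationWindow
from .segmentation import FlightSegment
from .traps import DDCatchSeries

__all__ = ["FitReport", "coverage_score", "boundary_offsets", "plot_dynamics"]


@dataclass
class FitReport:
    """Fit summary for one area-year."""

    area: str
    year: int
    coverage: float | None
    offsets_dd: list[float] = field(default_factory=list)
    count_mismatch: bool = False
    n_flights: int = 0
    n_windows: int = 0

    def to_dict(self) -> dict:
        return {
            "area": self.area,
            "year": self.year,
            "coverage": self.coverage,
            "offsets_dd": self.offsets_dd,
            "count_mismatch": self.count_mismatch,
            "n_flights": self.n_flights,
            "n_windows": self.n_windows,
        }


def coverage_score(
    ddcatch: DDCatchSeries, windows: list[GenerationWindow]
) -> float | None:
    """Fraction of total catches whose DD key falls inside any window.

    Windows are half-open [dd_start, dd_end): a catch exactly on a boundary
    belongs to the later window. Catches are weighted by mean_catch * n_traps
    (total moths); the score is invariant to uniform rescaling of catch
    magnitudes. Returns None (not applicable) for an empty or all-zero
    series.
    """
    if not windows:
        raise InvalidInputError("coverage needs at least one window")
    df = ddcatch.data
    weights = (df["mean_catch"] * df.get("n_traps", 1)).to_numpy(float)
    total = weights.sum()
    if len(df) == 0 or total <= 0:
        return None
    dd = df["cumulative_dd"].to_numpy(float)
    inside = np.zeros(len(dd), dtype=bool)
    for w in windows:
        inside |= (dd >= w.dd_start) & (dd < w.dd_end)
    return float(weights[inside].sum() / total)


def boundary_offsets(
    segments: list[FlightSegment], windows: list[GenerationWindow]
) -> tuple[list[float], bool]:
    """Per-generation offsets between observed and predicted flight starts.

    Flights are matched to windows by rank order; offset_k =
    dd_start(flight k) - dd_start(window k), positive when the observed
    flight starts later than predicted. Returns the offsets for the matched
    ranks plus a flag set when the counts differ (partial offsets).
    """
    k = min(len(segments), len(windows))
    offsets = [segments[i].dd_start - windows[i].dd_start for i in range(k)]
    return offsets, len(segments) != len(windows)


def plot_dynamics(
    series: DDCatchSeries,
    windows: list[GenerationWindow] | None = None,
    segments: list[FlightSegment] | None = None,
    style: str = "dd",
    path=None,
):
    """Season plot in either calendar or DD style.

    ``style="calendar"``: weekly means ± SE against check date with dotted
    vertical lines at flight boundaries. ``style="dd"``: means against
    cumulative DD with the predicted windows shaded. Returns the figure;
    saves to ``path`` when given.
    """
    if style not in ("calendar", "dd"):
        raise InvalidInputError("style must be 'calendar' or 'dd'")
    fig, ax = plt.subplots(figsize=(8, 3.5))
    df = series.data
    if style == "calendar":
        x = df["check_date"]
        ax.set_xlabel("check date")
    else:
        x = df["cumulative_dd"]
        ax.set_xlabel("accumulated degree days")
    if len(df):
        y, se = df["mean_catch"], df["se"]
        ax.plot(x, y, "-o", ms=3, lw=1, color="tab:blue")
        ax.fill_between(x, y - se, y + se, alpha=0.25, color="tab:blue", lw=0)
    if style == "dd" and windows:
        for w in windows:
            ax.axvspan(
                w.dd_start,
                w.dd_end,
                color="tab:orange" if w.index % 2 else "tab:green",
                alpha=0.12,
            )
    if segments:
        for s in segments[:-1]:
            bx = s.end_week if style == "calendar" else s.dd_end
            ax.axvline(bx, ls=":", color="k", lw=1)
    ax.set_ylabel("moths / trap / week")
    ax.set_title(f"{series.area} {series.year}")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
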