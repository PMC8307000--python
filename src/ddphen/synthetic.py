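"""Synthetic weather and trap-catch generation with known ground truth.

Weather: a seasonal cosine for the daily mean temperature (minimum in
mid-January) plus independent Gaussian noise on tmin and tmax. Catches:
per-generation emergence kernels placed on the cumulative-DD axis (Gaussian
in DD, encoding temperature-driven development), integrated over each weekly
check interval and thinned into per-trap counts with negative-binomial noise.
Ground-truth flight boundaries are the minima of the mixture density, so
every downstream stage can be scored against exact DD truth.

Two presets mimic the two field settings: ``girona_like`` (cooler coastal
climate, 4 widely spaced low-abundance generations) and ``lleida_like``
(hotter continental climate, 5 closely spaced high-abundance generations).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import InvalidConfigError
from .thermal import DDSeries, TemperatureSeries
from .traps import TrapCatchSeries, aggregate_traps

__all__ = [
    "ClimateConfig",
    "PopulationConfig",
    "GroundTruth",
    "generate_weather",
    "generate_catches",
    "CLIMATE_PRESETS",
    "POPULATION_PRESETS",
    "scenario",
]


@dataclass(frozen=True)
class ClimateConfig:
    """Parameters of the seasonal temperature generator (degrees Celsius)."""

    annual_mean: float
    annual_amplitude: float
    diurnal_range: float
    noise_sd: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if self.diurnal_range <= 0:
            raise InvalidConfigError("diurnal_range must be > 0")
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be >= 0")


@dataclass(frozen=True)
class PopulationConfig:
    """Parameters of the multivoltine catch generator.

    ``flight_centers_dd`` are the emergence-kernel centres on the
    cumulative-DD axis, ``flight_sd_dd`` the common kernel SD, ``abundance``
    the expected season total per trap for each generation, and
    ``dispersion`` the negative-binomial shape for weekly per-trap counts
    (smaller = more overdispersed).
    """

    n_generations: int
    flight_centers_dd: tuple[float, ...]
    flight_sd_dd: float
    abundance: tuple[float, ...]
    n_traps: int = 20
    dispersion: float = 1.5
    seed: int = 0

    def __post_init__(self):
        centers = tuple(self.flight_centers_dd)
        if len(centers) != self.n_generations or len(self.abundance) != self.n_generations:
            raise InvalidConfigError("centers and abundance must match n_generations")
        if any(b <= a for a, b in zip(centers, centers[1:])):
            raise InvalidConfigError("flight centers must be strictly increasing")
        if any(a < 0 for a in self.abundance):
            raise InvalidConfigError("abundance must be >= 0")
        if self.n_traps < 1:
            raise InvalidConfigError("n_traps must be >= 1")
        if self.flight_sd_dd <= 0 or self.dispersion <= 0:
            raise InvalidConfigError("flight_sd_dd and dispersion must be > 0")


@dataclass(frozen=True)
class GroundTruth:
    """Exact DD truth of a simulated season.

    ``boundaries_dd`` are the mixture-density minima between consecutive
    kernel centres (n_generations - 1 values); ``durations_dd`` the spans
    between consecutive boundaries, i.e. the true durations of the interior
    generations 2..n-1 (the outermost flights have no outer boundary).
    """

    boundaries_dd: tuple[float, ...]
    durations_dd: tuple[float, ...]
    n_generations: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "boundaries_dd": list(self.boundaries_dd),
                    "durations_dd": list(self.durations_dd),
                    "n_generations": self.n_generations,
                },
                fh,
                indent=2,
            )


# Presets calibrated so the March-September means of daily tmin/tmax match
# the two field settings (coastal: 12.4/24.5 C; continental: 11.4/28.1 C).
CLIMATE_PRESETS: dict[str, ClimateConfig] = {
    "girona_like": ClimateConfig(annual_mean=14.83, annual_amplitude=8.0, diurnal_range=12.1),
    "lleida_like": ClimateConfig(annual_mean=15.47, annual_amplitude=9.5, diurnal_range=16.7),
}

# girona_like: 4 generations spaced 626 DD, peaks < ~10 moths/trap/week;
# lleida_like: 5 generations spaced 528 DD, peaks up to ~50/trap/week.
# Abundance pattern: second generation below the first, rising from the third.
POPULATION_PRESETS: dict[str, PopulationConfig] = {
    "girona_like": PopulationConfig(
        n_generations=4,
        flight_centers_dd=(420.0, 1046.0, 1672.0, 2298.0),
        flight_sd_dd=80.0,
        abundance=(12.0, 8.0, 14.0, 16.0),
        n_traps=20,
    ),
    "lleida_like": PopulationConfig(
        n_generations=5,
        flight_centers_dd=(320.0, 848.0, 1376.0, 1904.0, 2432.0),
        flight_sd_dd=80.0,
        abundance=(55.0, 35.0, 65.0, 80.0, 95.0),
        n_traps=20,
    ),
}


def scenario(name: str, seed: int = 0) -> tuple[ClimateConfig, PopulationConfig]:
    """Climate and population configs for a named preset, reseeded."""
    if name not in CLIMATE_PRESETS:
        raise InvalidConfigError(
            f"unknown scenario {name!r}; choose from {sorted(CLIMATE_PRESETS)}"
        )
    return (
        replace(CLIMATE_PRESETS[name], seed=seed),
        replace(POPULATION_PRESETS[name], seed=seed),
    )


def generate_weather(config: ClimateConfig, year: int, station_id: str | None = None) -> TemperatureSeries:
    """One calendar year of daily min/max temperatures.

    Daily mean = annual_mean - annual_amplitude * cos(2*pi*(doy-15)/365)
    (minimum around 15 January); tmin/tmax sit half the diurnal range below/
    above with independent Gaussian noise. Days where noise would invert
    tmin > tmax are redrawn, keeping the stream deterministic for a fixed
    seed.
    """
    rng = np.random.default_rng(config.seed)
    dates = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
    doy = dates.dayofyear.to_numpy(float)
    mean = config.annual_mean - config.annual_amplitude * np.cos(
        2 * np.pi * (doy - 15.0) / 365.0
    )
    half = config.diurnal_range / 2.0
    tmin = mean - half + rng.normal(0.0, config.noise_sd, len(dates))
    tmax = mean + half + rng.normal(0.0, config.noise_sd, len(dates))
    bad = np.flatnonzero(tmin > tmax)
    while len(bad):
        tmin[bad] = mean[bad] - half + rng.normal(0.0, config.noise_sd, len(bad))
        tmax[bad] = mean[bad] + half + rng.normal(0.0, config.noise_sd, len(bad))
        bad = bad[tmin[bad] > tmax[bad]]
    df = pd.DataFrame({"tmin": tmin, "tmax": tmax}, index=dates)
    return TemperatureSeries(station_id or "synthetic", df)


def _mixture_density(x: np.ndarray, pop: PopulationConfig) -> np.ndarray:
    dens = np.zeros_like(x)
    for c, a in zip(pop.flight_centers_dd, pop.abundance):
        dens += a * norm.pdf(x, loc=c, scale=pop.flight_sd_dd)
    return dens


def expected_weekly_catch(pop: PopulationConfig, dd_edges: np.ndarray) -> np.ndarray:
    """Expected per-trap catch in each DD interval of ``dd_edges``.

    Entry w is the kernel mass of every generation between edges w and w+1,
    weighted by abundance.
    """
    edges = np.asarray(dd_edges, float)
    mu = np.zeros(len(edges) - 1)
    for c, a in zip(pop.flight_centers_dd, pop.abundance):
        mu += a * np.diff(norm.cdf((edges - c) / pop.flight_sd_dd))
    return mu


def true_boundaries(pop: PopulationConfig, step: float = 0.25) -> tuple[float, ...]:
    """Mixture-density minima between consecutive kernel centres."""
    bounds = []
    for a, b in zip(pop.flight_centers_dd[:-1], pop.flight_centers_dd[1:]):
        x = np.arange(a, b + step, step)
        bounds.append(float(x[np.argmin(_mixture_density(x, pop))]))
    return tuple(bounds)


def generate_catches(
    pop: PopulationConfig,
    dds: DDSeries,
    area: str = "synthetic",
) -> tuple[TrapCatchSeries, GroundTruth]:
    """Weekly per-trap trap catches for one simulated season.

    Checks fall every 7 days from 7 January. The expected per-trap catch in a
    week is the kernel mass of every generation over that week's DD interval
    times its abundance; per-trap counts are negative-binomial around it.
    """
    cum = dds.data["cumulative_dd"]
    season_total = float(cum.iloc[-1])
    if max(pop.flight_centers_dd) >= season_total:
        raise InvalidConfigError(
            f"flight centre {max(pop.flight_centers_dd):.0f} DD beyond season total "
            f"{season_total:.0f} DD"
        )
    year = int(dds.data.index[0].year)
    checks = pd.date_range(f"{year}-01-07", dds.data.index[-1], freq="7D")
    dd_at = cum.loc[checks].to_numpy(float)

    edges = np.concatenate(([0.0], dd_at))
    mu = expected_weekly_catch(pop, edges)

    rng = np.random.default_rng(pop.seed)
    rows = []
    r = pop.dispersion
    for trap in range(pop.n_traps):
        for w, m in enumerate(mu):
            if m <= 0:
                count = 0
            else:
                count = int(rng.negative_binomial(r, r / (r + m)))
            rows.append((area, year, checks[w], f"T{trap + 1:03d}", count))
    raw = pd.DataFrame(rows, columns=["area", "year", "check_date", "trap_id", "catch_count"])
    series = aggregate_traps(raw)[0]

    bounds = true_boundaries(pop)
    durations = tuple(float(b - a) for a, b in zip(bounds[:-1], bounds[1:]))
    truth = GroundTruth(
        boundaries_dd=bounds, durations_dd=durations, n_generations=pop.n_generations
    )
    return series, truth
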