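import numpy as np
import pandas as pd
import pytest

from ddphen.thermal import DDParams, DDSeries, TemperatureSeries
from ddphen.traps import DDCatchSeries


@pytest.fixture
def params():
    return DDParams()


def make_temperature_series(tmin, tmax, start="2017-01-01", station="test"):
    """TemperatureSeries from per-day tmin/tmax arrays."""
    tmin = np.asarray(tmin, float)
    tmax = np.asarray(tmax, float)
    idx = pd.date_range(start, periods=len(tmin), freq="D")
    return TemperatureSeries(station, pd.DataFrame({"tmin": tmin, "tmax": tmax}, index=idx))


def make_dd_series(daily, start="2017-01-01", station="test"):
    """DDSeries from per-day DD values (cumulative restarts each 1 Jan)."""
    daily = np.asarray(daily, float)
    idx = pd.date_range(start, periods=len(daily), freq="D")
    df = pd.DataFrame({"daily_dd": daily}, index=idx)
    df["cumulative_dd"] = df.groupby(df.index.year)["daily_dd"].cumsum()
    return DDSeries(station, df)


def make_dd_catch(catches, dd=None, se=None, n_traps=1, area="A", year=2017,
                  start="2017-04-03"):
    """Weekly DDCatchSeries from catch values; DD keys default to 100/week."""
    catches = np.asarray(catches, float)
    n = len(catches)
    dd = np.asarray(dd, float) if dd is not None else 100.0 * np.arange(1, n + 1)
    se_arr = np.asarray(se, float) if se is not None else np.zeros(n)
    dates = pd.date_range(start, periods=n, freq="7D")
    df = pd.DataFrame(
        {
            "check_date": dates,
            "cumulative_dd": dd,
            "mean_catch": catches,
            "se": se_arr,
            "n_traps": np.full(n, n_traps),
        }
    )
    return DDCatchSeries(area=area, year=year, data=df)


def quadrature_dd(tmin, tmax, lower=7.2, upper=32.2, n=200_001):
    """Independent oracle: numerical quadrature of the clipped daily sine."""
    t = np.linspace(0.0, 1.0, n)
    temp = (tmin + tmax) / 2.0 + (tmax - tmin) / 2.0 * np.sin(2.0 * np.pi * t)
    return float(np.trapezoid(np.clip(np.minimum(temp, upper) - lower, 0.0, None), t))
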