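"""Heat index via the Rothfusz regression with the NWS adjustments.

The National Weather Service procedure: first evaluate the simple Steadman
average; when that average is 80°F or higher the full Rothfusz regression
applies, with a subtraction for hot/dry air (RH < 13%, 80–112°F) and an
addition for hot/very-humid air (RH > 85%, 80–87°F).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from heatwave_id.calendar_io import HeatIndexGrid, MonitorNetwork, WarmSeasonCalendar

__all__ = ["heat_index_f", "daily_max_heat_index", "read_hourly"]


def heat_index_f(temperature_f, relative_humidity_pct):
    """Heat index (°F) from air temperature (°F) and relative humidity (%).

    Vectorised; scalars in, scalar out.  RH outside [0, 100] raises
    ``ValueError``.
    """
    T = np.asarray(temperature_f, dtype=float)
    RH = np.asarray(relative_humidity_pct, dtype=float)
    if np.any((RH < 0.0) | (RH > 100.0)):
        raise ValueError("relative humidity must lie in [0, 100]")
    if not np.all(np.isfinite(T)):
        raise ValueError("temperature must be finite")

    # Steadman simple formula, already averaged with T
    simple = 0.5 * (T + 61.0 + (T - 68.0) * 1.2 + RH * 0.094)

    hi = -42.379 + 2.04901523 * T + 10.14333127 * RH \
        - 0.22475541 * T * RH - 6.83783e-3 * T ** 2 \
        - 5.481717e-2 * RH ** 2 + 1.22874e-3 * T ** 2 * RH \
        + 8.5282e-4 * T * RH ** 2 - 1.99e-6 * T ** 2 * RH ** 2

    # low-humidity adjustment (hot, dry)
    low = (RH < 13.0) & (T >= 80.0) & (T <= 112.0)
    adj_low = ((13.0 - RH) / 4.0) * np.sqrt(
        np.clip(17.0 - np.abs(T - 85.0), 0.0, None) / 17.0)
    hi = hi - np.where(low, adj_low, 0.0)

    # high-humidity adjustment (hot, humid)
    high = (RH > 85.0) & (T >= 80.0) & (T <= 87.0)
    adj_high = ((RH - 85.0) / 10.0) * ((87.0 - T) / 5.0)
    hi = hi + np.where(high, adj_high, 0.0)

    out = np.where(simple >= 80.0, hi, simple)
    return float(out) if out.ndim == 0 else out


def read_hourly(hourly_path) -> pd.DataFrame:
    """Read hourly.csv (monitor_id,timestamp,temp_f,rh_pct; local timestamps)."""
    df = pd.read_csv(hourly_path, dtype={"monitor_id": str})
    for col in ("monitor_id", "timestamp", "temp_f", "rh_pct"):
        if col not in df.columns:
            raise ValueError(f"hourly file lacks column {col!r}")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


def daily_max_heat_index(hourly_records: pd.DataFrame,
                         calendar: WarmSeasonCalendar,
                         network: MonitorNetwork) -> HeatIndexGrid:
    """Reduce hourly temperature/RH records to a grid of daily maxima.

    Per monitor-day the value is the maximum of ``heat_index_f`` over that
    day's records; days with zero records are masked missing.  Timestamps
    are treated as already local; no minimum number of readings is imposed.
    """
    values = np.full((network.n_monitors, calendar.n_days), np.nan)
    mask = np.zeros_like(values, dtype=bool)
    if len(hourly_records):
        df = hourly_records.copy()
        df["timestamp"] = pd.to_datetime(df["timestamp"])
        df["hi"] = heat_index_f(df["temp_f"].to_numpy(), df["rh_pct"].to_numpy())
        df["date"] = df["timestamp"].dt.floor("D").values.astype("datetime64[D]")
        df = df[[calendar.contains(d) for d in df["date"]]]
        daily = df.groupby(["monitor_id", "date"])["hi"].max()
        for (mon, date), hi in daily.items():
            i = network.index_of(mon)
            j = calendar.t_of_date(date) - 1
            values[i, j] = hi
            mask[i, j] = True
    return HeatIndexGrid(values, mask, calendar, network)
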