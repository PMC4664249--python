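"""Warm-season calendar arithmetic, the monitor/grid data model, and CSV I/O.

The analysis is restricted to warm seasons (April 1 through September 30,
183 days in every year — February never enters).  The day index ``t`` is
1-based and runs only over in-season days, concatenated across years; it is
distinct from the Julian day (day of year).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SEASON_DAYS = 183  # April(30)+May(31)+June(30)+July(31)+Aug(31)+Sep(30)
EARTH_RADIUS_KM = 6371.0


def fahrenheit_to_celsius(values_f):
    """Convert °F to °C (report-time only; all computation is in °F)."""
    return (np.asarray(values_f, dtype=float) - 32.0) * 5.0 / 9.0


@dataclass(frozen=True)
class WarmSeasonCalendar:
    """Bijection between warm-season calendar dates and t ∈ {1..T}.

    Attributes
    ----------
    start_year, end_year : int
        Inclusive year range.
    dates : np.ndarray of datetime64[D], length T
        In-season dates in increasing order; ``dates[t-1]`` is day t.
    years : np.ndarray of int, length T
        Calendar year of each day.
    day_of_year : np.ndarray of int, length T
        Julian day (1-based day of the calendar year).
    day_of_season : np.ndarray of int, length T
        1..183 position within each warm season.
    """

    start_year: int
    end_year: int
    dates: np.ndarray
    years: np.ndarray
    day_of_year: np.ndarray
    day_of_season: np.ndarray
    _date_to_t: dict = field(repr=False, default_factory=dict)

    @property
    def n_days(self) -> int:
        return len(self.dates)

    @property
    def n_years(self) -> int:
        return self.end_year - self.start_year + 1

    def t_of_date(self, date) -> int:
        """1-based day index for an in-season date; KeyError otherwise."""
        key = np.datetime64(date, "D")
        try:
            return self._date_to_t[key]
        except KeyError:
            raise KeyError(f"date {key} is not in the warm season "
                           f"{self.start_year}-{self.end_year}") from None

    def date_of_t(self, t: int):
        if not 1 <= t <= self.n_days:
            raise IndexError(f"t={t} outside 1..{self.n_days}")
        return self.dates[t - 1]

    def contains(self, date) -> bool:
        return np.datetime64(date, "D") in self._date_to_t


def build_calendar(start_year: int, end_year: int) -> WarmSeasonCalendar:
    """Build the warm-season calendar for April 1–September 30 of each year.

    Raises ``ValueError`` if ``start_year > end_year``.
    """
    if start_year > end_year:
        raise ValueError(f"reversed year range: {start_year} > {end_year}")
    chunks = []
    for year in range(start_year, end_year + 1):
        chunks.append(pd.date_range(f"{year}-04-01", f"{year}-09-30", freq="D"))
    idx = chunks[0].append(chunks[1:]) if len(chunks) > 1 else chunks[0]
    dates = idx.values.astype("datetime64[D]")
    years = idx.year.to_numpy()
    day_of_year = idx.dayofyear.to_numpy()
    day_of_season = np.concatenate(
        [np.arange(1, len(c) + 1) for c in chunks])
    date_to_t = {d: t for t, d in enumerate(dates, start=1)}
    return WarmSeasonCalendar(start_year, end_year, dates, years,
                              day_of_year, day_of_season, date_to_t)


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km (Earth radius 6371 km)."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


@dataclass(frozen=True)
class MonitorNetwork:
    """Monitor ids, coordinates (decimal degrees) and region labels."""

    monitor_ids: np.ndarray      # str array, unique
    latitudes: np.ndarray
    longitudes: np.ndarray
    regions: np.ndarray          # str array, one region per monitor

    def __post_init__(self):
        ids = np.asarray(self.monitor_ids)
        if len(np.unique(ids)) != len(ids):
            raise ValueError("monitor ids are not unique")

    @property
    def n_monitors(self) -> int:
        return len(self.monitor_ids)

    @property
    def region_names(self) -> list[str]:
        seen = dict.fromkeys(self.regions.tolist())
        return list(seen)

    def index_of(self, monitor_id: str) -> int:
        hits = np.flatnonzero(self.monitor_ids == monitor_id)
        if len(hits) == 0:
            raise KeyError(f"unknown monitor id {monitor_id!r}")
        return int(hits[0])

    def monitors_in_region(self, region: str) -> np.ndarray:
        """Row indices of the monitors belonging to ``region``."""
        idx = np.flatnonzero(self.regions == region)
        if len(idx) == 0:
            raise KeyError(f"unknown region {region!r}")
        return idx

    def pairwise_distance(self) -> np.ndarray:
        """Symmetric great-circle distance matrix (km), zero diagonal."""
        lat = self.latitudes[:, None]
        lon = self.longitudes[:, None]
        d = haversine_km(lat, lon, self.latitudes[None, :], self.longitudes[None, :])
        np.fill_diagonal(d, 0.0)
        return (d + d.T) / 2.0


@dataclass
class HeatIndexGrid:
    """Monitor × warm-season-day table of daily maximum heat index (°F).

    ``values[i, t-1]`` holds the heat index of monitor i on day t; it is
    NaN wherever ``mask`` is False (missing).  ``mask[i, j]`` is True for
    observed cells.
    """

    values: np.ndarray
    mask: np.ndarray
    calendar: WarmSeasonCalendar
    network: MonitorNetwork

    def __post_init__(self):
        expect = (self.network.n_monitors, self.calendar.n_days)
        if self.values.shape != expect or self.mask.shape != expect:
            raise ValueError(f"grid shape {self.values.shape} does not match "
                             f"monitors × days {expect}")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("observed cells contain non-finite values")

    @property
    def n_monitors(self) -> int:
        return self.values.shape[0]

    @property
    def n_days(self) -> int:
        return self.values.shape[1]

    def is_complete(self) -> bool:
        return bool(self.mask.all())

    def copy(self) -> "HeatIndexGrid":
        return HeatIndexGrid(self.values.copy(), self.mask.copy(),
                             self.calendar, self.network)


def grid_cell_count(grid: HeatIndexGrid) -> int:
    """Total number of monitor-day cells (observed or not)."""
    return grid.n_monitors * grid.n_days


# ---------------------------------------------------------------------------
# CSV interfaces
#
# monitors.csv : monitor_id,latitude,longitude,region
# daily.csv    : monitor_id,date,hi_max_f   (missing days simply absent)
# ---------------------------------------------------------------------------

def read_network(metadata_path) -> MonitorNetwork:
    df = pd.read_csv(metadata_path, dtype={"monitor_id": str, "region": str})
    required = {"monitor_id", "latitude", "longitude", "region"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"monitors file lacks columns: {sorted(missing)}")
    return MonitorNetwork(
        monitor_ids=df["monitor_id"].to_numpy(dtype=object),
        latitudes=df["latitude"].to_numpy(dtype=float),
        longitudes=df["longitude"].to_numpy(dtype=float),
        regions=df["region"].to_numpy(dtype=object),
    )


def write_network(network: MonitorNetwork, metadata_path) -> None:
    pd.DataFrame({
        "monitor_id": network.monitor_ids,
        "latitude": np.round(network.latitudes, 4),
        "longitude": np.round(network.longitudes, 4),
        "region": network.regions,
    }).to_csv(metadata_path, index=False)


def read_grid(records_path, metadata_path,
              calendar: WarmSeasonCalendar | None = None,
              start_year: int | None = None,
              end_year: int | None = None) -> HeatIndexGrid:
    """Read daily records into a grid; mask is False exactly where no record
    exists.  Out-of-season records are dropped with a logged count.

    The calendar is taken from ``calendar`` if given, else built from
    ``start_year``/``end_year``, else inferred from the record year range.
    """
    network = read_network(metadata_path)
    df = pd.read_csv(records_path, dtype={"monitor_id": str})
    for col in ("monitor_id", "date", "hi_max_f"):
        if col not in df.columns:
            raise ValueError(f"records file lacks column {col!r}")
    df["date"] = pd.to_datetime(df["date"]).values.astype("datetime64[D]")

    dup = df.duplicated(subset=["monitor_id", "date"], keep=False)
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError("duplicate (monitor, date) record: "
                         f"{row['monitor_id']} {row['date']}")
    unknown = set(df["monitor_id"]) - set(network.monitor_ids.tolist())
    if unknown:
        raise ValueError(f"records reference unknown monitor ids: {sorted(unknown)}")

    if calendar is None:
        if start_year is None:
            if len(df) == 0:
                raise ValueError("cannot infer calendar from an empty records "
                                 "file; pass calendar or start/end year")
            yrs = pd.DatetimeIndex(df["date"]).year
            start_year, end_year = int(yrs.min()), int(yrs.max())
        calendar = build_calendar(start_year, end_year or start_year)

    in_season = np.array([calendar.contains(d) for d in df["date"]], dtype=bool)
    n_dropped = int((~in_season).sum())
    if n_dropped:
        logger.info("dropped %d out-of-season records", n_dropped)
    df = df[in_season]

    values = np.full((network.n_monitors, calendar.n_days), np.nan)
    mask = np.zeros_like(values, dtype=bool)
    mon_index = {m: i for i, m in enumerate(network.monitor_ids)}
    rows = df["monitor_id"].map(mon_index).to_numpy(dtype=int) if len(df) else np.array([], dtype=int)
    cols = np.array([calendar.t_of_date(d) - 1 for d in df["date"]], dtype=int)
    values[rows, cols] = df["hi_max_f"].to_numpy(dtype=float)
    mask[rows, cols] = True
    return HeatIndexGrid(values, mask, calendar, network)


def write_grid(grid: HeatIndexGrid, records_path, metadata_path=None) -> None:
    """Write observed cells as daily.csv rows (4-decimal floats); missing
    cells are simply absent.  Optionally also writes the monitors file."""
    rows, cols = np.nonzero(grid.mask)
    df = pd.DataFrame({
        "monitor_id": grid.network.monitor_ids[rows],
        "date": grid.calendar.dates[cols].astype(str),
        "hi_max_f": np.round(grid.values[rows, cols], 4),
    })
    df.sort_values(["monitor_id", "date"]).to_csv(
        records_path, index=False, float_format="%.4f")
    if metadata_path is not None:
        write_network(grid.network, metadata_path)
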