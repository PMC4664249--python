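"""Regional heat-wave identification under the two-condition definition.

A regional heat wave is a maximal run of consecutive warm-season days on
which (1) every monitor in the region has its daily maximum heat index
strictly above its own 80th warm-season percentile, and (2) every monitor
exceeds a regional upper threshold on at least three days of the run (the
three need not be consecutive).  When missing data are ignored the same
logic applies to the single daily regional-average series, with missing
days breaking runs.

"Above" is strict throughout.  Runs never cross a season boundary: the
grid contains no off-season days, and season starts explicitly break runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from heatwave_id.calendar_io import HeatIndexGrid, WarmSeasonCalendar

__all__ = ["HeatWaveRecord", "find_heatwaves", "find_heatwaves_ignore_missing",
           "regional_benchmark", "restrict_to_years", "NO_BENCHMARK"]

NO_BENCHMARK = None


@dataclass(frozen=True)
class HeatWaveRecord:
    region: str
    method: str
    start_date: np.datetime64
    end_date: np.datetime64
    upper_threshold_f: float
    n_days: int
    hot_days_per_monitor: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if self.start_date > self.end_date:
            raise ValueError("heat wave start after end")


def _maximal_runs(qualifying: np.ndarray, season_break: np.ndarray):
    """Maximal runs of True in ``qualifying`` that do not span a season
    break (break at j means a new season starts at j)."""
    runs = []
    start = None
    for j, ok in enumerate(qualifying):
        if ok and (start is None or season_break[j]):
            if start is not None:
                runs.append((start, j - 1))
            start = j
        elif not ok and start is not None:
            runs.append((start, j - 1))
            start = None
    if start is not None:
        runs.append((start, len(qualifying) - 1))
    return runs


def find_heatwaves(region_grid: HeatIndexGrid, monitor_p80s: dict,
                   upper_threshold: float, min_hot_days: int = 3,
                   region: str | None = None,
                   method: str = "imputed") -> list[HeatWaveRecord]:
    """Heat waves in a completed regional grid.

    ``monitor_p80s`` maps monitor id to its own 80th warm-season
    percentile.  If ``region`` is given, the grid is restricted to that
    region's monitors; otherwise all monitors in the grid form the region
    (the grid is then treated as one region).
    """
    net = region_grid.network
    if region is not None:
        idx = net.monitors_in_region(region)
    else:
        idx = np.arange(net.n_monitors)
        region = region or "+".join(dict.fromkeys(net.regions[idx].tolist()))
    ids = net.monitor_ids[idx]
    unknown = [m for m in ids if m not in monitor_p80s]
    if unknown:
        raise KeyError(f"no 80th percentile provided for monitor(s) {unknown}")
    vals = region_grid.values[idx]
    if not region_grid.mask[idx].all():
        raise ValueError("regional grid has missing cells; impute first")

    p80 = np.array([monitor_p80s[m] for m in ids])
    cond1 = (vals > p80[:, None]).all(axis=0)
    hot = vals > upper_threshold
    season_break = region_grid.calendar.day_of_season == 1

    records = []
    for a, b in _maximal_runs(cond1, season_break):
        if b - a + 1 < min_hot_days:
            continue
        hot_counts = hot[:, a:b + 1].sum(axis=1)
        if np.all(hot_counts >= min_hot_days):
            records.append(HeatWaveRecord(
                region, method,
                region_grid.calendar.dates[a], region_grid.calendar.dates[b],
                float(upper_threshold), b - a + 1,
                {m: int(c) for m, c in zip(ids, hot_counts)}))
    return records


def find_heatwaves_ignore_missing(average_series: np.ndarray,
                                  regional_p80: float,
                                  upper_threshold: float,
                                  calendar: WarmSeasonCalendar,
                                  min_hot_days: int = 3,
                                  region: str = "region") -> list[HeatWaveRecord]:
    """Heat waves from a regional-average series with possible missing
    days (NaN); missing days break candidate runs."""
    s = np.asarray(average_series, dtype=float)
    cond1 = np.isfinite(s) & (s > regional_p80)
    hot = np.isfinite(s) & (s > upper_threshold)
    season_break = calendar.day_of_season == 1
    records = []
    for a, b in _maximal_runs(cond1, season_break):
        if b - a + 1 < min_hot_days:
            continue
        n_hot = int(hot[a:b + 1].sum())
        if n_hot >= min_hot_days:
            records.append(HeatWaveRecord(
                region, "ignore", calendar.dates[a], calendar.dates[b],
                float(upper_threshold), b - a + 1, {"regional_average": n_hot}))
    return records


def restrict_to_years(grid: HeatIndexGrid, start_year: int,
                      end_year: int) -> HeatIndexGrid:
    """Sub-grid covering whole seasons of ``start_year``..``end_year``."""
    from heatwave_id.calendar_io import build_calendar

    keep = (grid.calendar.years >= start_year) & (grid.calendar.years <= end_year)
    if not keep.any():
        raise ValueError("evaluation window outside the grid's calendar")
    cal = build_calendar(max(start_year, grid.calendar.start_year),
                         min(end_year, grid.calendar.end_year))
    return HeatIndexGrid(grid.values[:, keep], grid.mask[:, keep], cal,
                         grid.network)


def regional_benchmark(find_waves, candidate_thresholds) -> float | None:
    """Highest candidate threshold still producing at least one heat wave.

    ``find_waves(u)`` must return the heat-wave list at upper threshold u
    on the evaluation window (the count is non-increasing in u, which the
    linear scan from above relies on).  Returns ``NO_BENCHMARK`` when even
    the smallest candidate yields none.
    """
    for u in sorted(candidate_thresholds, reverse=True):
        if len(find_waves(u)) >= 1:
            return float(u)
    return NO_BENCHMARK
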