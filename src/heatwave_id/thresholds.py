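"""Warm-season percentile thresholds and regional benchmarks.

Percentiles (80/90/95/97.5 by default) of daily maximum heat index are
computed per monitor on a completed grid — imputation first — and per
region on the daily regional-average series when missing data are ignored.
The regional benchmark is the highest upper threshold (integer °F) that
still yields at least one heat wave in the evaluation window; it is an
absolute alternative to a percentile upper threshold.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from heatwave_id.calendar_io import HeatIndexGrid, fahrenheit_to_celsius

DEFAULT_LEVELS = (80.0, 90.0, 95.0, 97.5)
BENCHMARK_CANDIDATES_F = tuple(range(95, 121))  # integer °F


def monitor_percentiles(completed_grid: HeatIndexGrid,
                        levels=DEFAULT_LEVELS) -> pd.DataFrame:
    """Per-monitor empirical percentiles over all warm-season days.

    Linear interpolation between order statistics.  Raises ``ValueError``
    on grids with missing cells: impute first.
    """
    if not completed_grid.is_complete():
        raise ValueError("grid has missing cells; impute before computing "
                         "percentiles")
    qs = np.percentile(completed_grid.values, list(levels), axis=1,
                       method="linear")
    out = pd.DataFrame({"monitor_id": completed_grid.network.monitor_ids,
                        "region": completed_grid.network.regions})
    for lev, row in zip(levels, qs):
        out[f"p{lev:g}_f"] = row
    return out


def regional_average_series(observed_grid: HeatIndexGrid,
                            region: str) -> np.ndarray:
    """Daily mean over the region's observed monitors; NaN on days no
    monitor in the region recorded (the ignore-missing convention)."""
    idx = observed_grid.network.monitors_in_region(region)
    mask = observed_grid.mask[idx]
    vals = np.where(mask, observed_grid.values[idx], 0.0)
    counts = mask.sum(axis=0)
    with np.errstate(invalid="ignore"):
        out = vals.sum(axis=0) / counts
    out[counts == 0] = np.nan
    return out


def series_percentiles(series: np.ndarray, levels=DEFAULT_LEVELS) -> dict[float, float]:
    """Percentiles of a daily series, skipping missing days."""
    vals = series[np.isfinite(series)]
    if len(vals) == 0:
        raise ValueError("series has no observed days")
    qs = np.percentile(vals, list(levels), method="linear")
    return dict(zip(levels, (float(q) for q in qs)))


def threshold_table_to_celsius(table: pd.DataFrame) -> pd.DataFrame:
    """Append °C columns (rounded to 2 decimals) to a °F threshold table."""
    out = table.copy()
    for col in [c for c in table.columns if c.endswith("_f")]:
        out[col[:-2] + "_c"] = np.round(fahrenheit_to_celsius(table[col]), 2)
    return out
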