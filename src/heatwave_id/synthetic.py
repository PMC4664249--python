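"""Synthetic heat-index grids with known ground truth.

Generates a monitor network and a fully observed grid whose structure
matches what the imputation models assume — a seasonal cycle peaking in
mid-July, a slow year trend, monitor-specific offsets, day-to-day AR(1)
anomalies that are spatially correlated with an exponential covariance,
and white nugget noise — then applies month/monitor-stratified MCAR
missingness (heavier in April/May/September than June–August, as monitor
networks typically show).  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from heatwave_id.calendar_io import (
    HeatIndexGrid,
    MonitorNetwork,
    WarmSeasonCalendar,
    build_calendar,
)

__all__ = ["SyntheticConfig", "generate_network", "generate_truth",
           "apply_missingness", "default_config", "load_config"]

PEAK_DAY_OF_YEAR = 196  # mid-July maximum of the seasonal sinusoid
WARM_MONTHS = (6, 7, 8)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic network and grid.

    Defaults mirror a Florida-like 43-monitor, 1973–2012 warm-season
    record: mean daily maximum heat index near 88°F with a ~10°F seasonal
    swing, a modest warming trend, strong day-to-day persistence, and
    spatial correlation decaying over a few hundred km.
    """

    n_monitors: int = 43
    start_year: int = 1973
    end_year: int = 2012
    lat_min: float = 24.5
    lat_max: float = 31.0
    lon_min: float = -87.6
    lon_max: float = -80.0
    n_regions: int = 6
    seasonal_mean: float = 88.0          # °F
    seasonal_amplitude: float = 10.0     # °F, sinusoid peaking mid-July
    year_trend: float = 0.3              # °F per decade
    ar_coefficient: float = 0.65         # day-to-day anomaly persistence
    spatial_range: float = 500.0         # km, synoptic-scale correlation decay
    spatial_sill: float = 9.0            # °F², innovation variance
    nugget: float = 0.5                  # °F², white noise
    monitor_offsets_sd: float = 1.0      # °F
    missing_rate_warm_months: float = 0.05   # June/July/August
    missing_rate_cool_months: float = 0.20   # April/May/September
    monitor_missing_multipliers: tuple | None = None  # default: U(0.5,1.5)
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.missing_rate_warm_months < 1
                and 0 <= self.missing_rate_cool_months < 1):
            raise ValueError("missing rates must lie in [0, 1)")
        if self.spatial_sill < 0 or self.nugget < 0:
            raise ValueError("sill and nugget must be non-negative")
        if self.spatial_range <= 0:
            raise ValueError("spatial range must be positive")
        if not abs(self.ar_coefficient) < 1:
            raise ValueError("|ar_coefficient| must be < 1")

    def calendar(self) -> WarmSeasonCalendar:
        return build_calendar(self.start_year, self.end_year)


def default_config(**overrides) -> SyntheticConfig:
    return SyntheticConfig(**overrides)


def load_config(path) -> SyntheticConfig:
    """Load a SyntheticConfig from a YAML mapping of field overrides."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "monitor_missing_multipliers" in raw and raw["monitor_missing_multipliers"] is not None:
        raw["monitor_missing_multipliers"] = tuple(raw["monitor_missing_multipliers"])
    return SyntheticConfig(**raw)


def _rng(config: SyntheticConfig, stage: int) -> np.random.Generator:
    # fixed per-stage streams so each operation is independently reproducible
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stage]))


def generate_network(config: SyntheticConfig) -> MonitorNetwork:
    """Uniform random monitor locations in the bounding box, assigned to
    contiguous latitude-band regions R1 (south) .. Rk (north)."""
    if config.n_monitors < 1:
        raise ValueError("need at least one monitor")
    if config.lat_min >= config.lat_max or config.lon_min >= config.lon_max:
        raise ValueError("degenerate bounding box")
    rng = _rng(config, stage=1)
    lats = rng.uniform(config.lat_min, config.lat_max, config.n_monitors)
    lons = rng.uniform(config.lon_min, config.lon_max, config.n_monitors)
    n_regions = min(config.n_regions, config.n_monitors)
    edges = np.linspace(config.lat_min, config.lat_max, n_regions + 1)
    band = np.clip(np.searchsorted(edges, lats, side="right") - 1, 0, n_regions - 1)
    ids = np.array([f"M{i + 1:03d}" for i in range(config.n_monitors)], dtype=object)
    regions = np.array([f"R{b + 1}" for b in band], dtype=object)
    return MonitorNetwork(ids, lats, lons, regions)


def _seasonal_cycle(day_of_year: np.ndarray, amplitude: float) -> np.ndarray:
    return amplitude * np.cos(2 * np.pi * (day_of_year - PEAK_DAY_OF_YEAR) / 365.0)


def generate_truth(config: SyntheticConfig, network: MonitorNetwork,
                   calendar: WarmSeasonCalendar) -> HeatIndexGrid:
    """Fully observed ground-truth grid.

    value(i,t) = mean + seasonal(doy) + trend·(year−start)/10 + offset_i
                 + a(i,t) + ε(i,t), where the anomaly field follows
    a(·,t) = φ a(·,t−1) + η(t), η(t) ~ N(0, sill·exp(−d/range)) jointly over
    monitors, restarted at its stationary distribution each season, and ε
    is white nugget noise.
    """
    rng = _rng(config, stage=2)
    n, T = network.n_monitors, calendar.n_days
    phi = config.ar_coefficient

    mean = (config.seasonal_mean
            + _seasonal_cycle(calendar.day_of_year, config.seasonal_amplitude)
            + config.year_trend * (calendar.years - calendar.start_year) / 10.0)

    offsets = (rng.normal(0.0, config.monitor_offsets_sd, n)
               if config.monitor_offsets_sd > 0 else np.zeros(n))

    anomalies = np.zeros((n, T))
    if config.spatial_sill > 0:
        corr = np.exp(-network.pairwise_distance() / config.spatial_range)
        # tiny jitter guards the factorization when monitors nearly coincide
        L = np.linalg.cholesky(config.spatial_sill * corr + 1e-10 * np.eye(n))
        stat_scale = 1.0 / np.sqrt(1.0 - phi * phi)
        z = rng.standard_normal((T, n))
        season_start = calendar.day_of_season == 1
        prev = np.zeros(n)
        for j in range(T):
            innov = L @ z[j]
            prev = stat_scale * innov if season_start[j] else phi * prev + innov
            anomalies[:, j] = prev

    noise = (rng.normal(0.0, np.sqrt(config.nugget), (n, T))
             if config.nugget > 0 else 0.0)

    values = mean[None, :] + offsets[:, None] + anomalies + noise
    return HeatIndexGrid(values, np.ones((n, T), dtype=bool), calendar, network)


def missingness_probabilities(config: SyntheticConfig,
                              network: MonitorNetwork,
                              calendar: WarmSeasonCalendar) -> np.ndarray:
    """Per-cell missingness probability: month rate × monitor multiplier,
    capped at 0.95 (MCAR within month × monitor strata)."""
    months = calendar.dates.astype("datetime64[M]").astype(int) % 12 + 1
    month_rate = np.where(np.isin(months, WARM_MONTHS),
                          config.missing_rate_warm_months,
                          config.missing_rate_cool_months)
    if config.monitor_missing_multipliers is not None:
        mult = np.asarray(config.monitor_missing_multipliers, dtype=float)
        if len(mult) != network.n_monitors:
            raise ValueError("one multiplier per monitor required")
    else:
        mult = _rng(config, stage=3).uniform(0.5, 1.5, network.n_monitors)
    return np.clip(mult[:, None] * month_rate[None, :], 0.0, 0.95)


def apply_missingness(truth: HeatIndexGrid, config: SyntheticConfig
                      ) -> tuple[HeatIndexGrid, pd.DataFrame]:
    """Mask cells independently and return (observed grid, held-out truth).

    The held-out table (monitor_id, date, true_hi_f) contains exactly the
    masked cells, so the truth is recoverable without loss.
    """
    if not truth.is_complete():
        raise ValueError("truth grid must be fully observed")
    p = missingness_probabilities(config, truth.network, truth.calendar)
    rng = _rng(config, stage=4)
    drop = rng.random(truth.values.shape) < p
    observed = truth.copy()
    observed.mask[drop] = False
    observed.values[drop] = np.nan
    rows, cols = np.nonzero(drop)
    heldout = pd.DataFrame({
        "monitor_id": truth.network.monitor_ids[rows],
        "date": truth.calendar.dates[cols].astype(str),
        "true_hi_f": truth.values[rows, cols],
    })
    return observed, heldout
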