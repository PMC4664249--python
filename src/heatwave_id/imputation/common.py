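"""Shared pieces of the imputation models."""

from __future__ import annotations

import numpy as np

from heatwave_id.calendar_io import HeatIndexGrid


class FitError(RuntimeError):
    """A model could not be fit on the data provided."""


class FallbackRequired(FitError):
    """Too little data for the primary model; the caller must use the
    documented fallback (e.g. monthly means on a <2-monitor day)."""


def exponential_covariance(distances_km: np.ndarray, sill: float,
                           range_km: float, nugget: float = 0.0) -> np.ndarray:
    """sill·exp(−d/range) plus nugget on the diagonal (isotropic,
    second-order stationary)."""
    if range_km <= 0:
        raise ValueError("range must be positive")
    cov = sill * np.exp(-np.asarray(distances_km, dtype=float) / range_km)
    if nugget:
        cov = cov + nugget * np.eye(cov.shape[0])
    return cov


def grid_months(grid: HeatIndexGrid) -> np.ndarray:
    """Calendar month (1–12) of each day column."""
    return grid.calendar.dates.astype("datetime64[M]").astype(int) % 12 + 1


def monthly_mean_table(grid: HeatIndexGrid) -> np.ndarray:
    """Monitor × month (April..September → columns 0..5) mean of observed
    values across all years; NaN where a monitor has no observation in a
    month."""
    months = grid_months(grid)
    out = np.full((grid.n_monitors, 6), np.nan)
    for k, month in enumerate(range(4, 10)):
        cols = months == month
        m = grid.mask[:, cols]
        sums = np.where(m, grid.values[:, cols], 0.0).sum(axis=1)
        counts = m.sum(axis=1)
        nz = counts > 0
        out[nz, k] = sums[nz] / counts[nz]
    return out


def completed_like(grid: HeatIndexGrid) -> HeatIndexGrid:
    """Copy of the grid whose mask is all-True; values still to be filled
    at originally missing cells."""
    out = grid.copy()
    out.mask = np.ones_like(grid.mask)
    return out
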