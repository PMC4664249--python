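"""Lag-1 spatio-temporal model: y_it = β0 + β1·y_{i,t−1} + e_it.

Within-day errors e_·t carry an exponential spatial covariance shared
across days; days are independent given the lag term.  β0, β1 and the
covariance parameters are estimated by profiled REML: for a candidate
range, β is the GLS solution and the sill profiles out in closed form,
leaving a one-dimensional search.

Imputation runs forward in time within each season: missing cells get
β0 + β1·lag plus a simple-kriging interpolation of the day's observed
residuals (residuals are mean-zero by construction, hence simple rather
than ordinary kriging); lag values use observed data when present and the
previous day's imputed value otherwise.  The first day of a season has no
lag and falls back to the per-day spatial predictor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize

from heatwave_id.calendar_io import HeatIndexGrid
from heatwave_id.imputation.common import (
    FallbackRequired,
    FitError,
    completed_like,
    exponential_covariance,
    grid_months,
    monthly_mean_table,
)
from heatwave_id.imputation.spatial import (
    RANGE_BOUNDS_KM,
    fit_spatial_day,
    ok_weights,
)

logger = logging.getLogger(__name__)

_SILL_FLOOR = 1e-10


@dataclass
class SpatioTemporalFit:
    beta0: float          # intercept, °F
    beta1: float          # lag coefficient, unitless
    sill: float           # °F²
    range_km: float
    nugget: float         # °F²
    n_pairs: int          # (i,t) pairs used in the fit
    se_beta0: float = np.nan
    se_beta1: float = np.nan


def _lag_pairs(grid: HeatIndexGrid) -> list[tuple[int, np.ndarray]]:
    """Per day t (not season-first), monitor indices with y_t and y_{t−1}
    both observed."""
    season_first = grid.calendar.day_of_season == 1
    pairs = []
    both = grid.mask[:, 1:] & grid.mask[:, :-1]
    for j in range(1, grid.n_days):
        if season_first[j]:
            continue
        idx = np.flatnonzero(both[:, j - 1])
        if len(idx):
            pairs.append((j, idx))
    return pairs


def _profiled_criterion(range_km, pairs, grid, distances, nugget_frac):
    """Profiled REML criterion over β and sill for a candidate range.

    Returns (criterion, beta, sill, XtCiX_inv) — days independent given
    the lag, so everything accumulates over days.
    """
    xtx = np.zeros((2, 2))
    xty = np.zeros(2)
    yty = 0.0
    logdet = 0.0
    n_total = 0
    for j, idx in pairs:
        R = np.exp(-distances[np.ix_(idx, idx)] / range_km)
        if nugget_frac:
            R = R + nugget_frac * np.eye(len(idx))
        y = grid.values[idx, j]
        X = np.column_stack([np.ones(len(idx)), grid.values[idx, j - 1]])
        cho = linalg.cho_factor(R, lower=True)
        Ri_X = linalg.cho_solve(cho, X)
        Ri_y = linalg.cho_solve(cho, y)
        xtx += X.T @ Ri_X
        xty += X.T @ Ri_y
        yty += y @ Ri_y
        logdet += 2.0 * np.sum(np.log(np.diag(cho[0])))
        n_total += len(idx)
    beta = linalg.solve(xtx, xty, assume_a="pos")
    rss = max(yty - beta @ xty, 0.0)
    sill = max(rss / max(n_total - 2, 1), _SILL_FLOOR)
    crit = ((n_total - 2) * np.log(sill) + logdet
            + np.log(max(linalg.det(xtx), 1e-300)))
    return crit, beta, sill, linalg.inv(xtx)


def fit_spatiotemporal(grid: HeatIndexGrid, nugget: float = 0.0) -> SpatioTemporalFit:
    """Profiled-REML fit of the lag model with exponential within-day
    error covariance.

    Pairs with both y_t and y_{t−1} observed enter the fit.  Raises
    :class:`FitError` when no usable lag pairs exist.
    """
    pairs = _lag_pairs(grid)
    if not pairs:
        raise FitError("no (i,t) pairs with observed value and observed lag")
    n_seasons = grid.calendar.n_years
    if n_seasons < 1:
        raise FitError("empty calendar")
    distances = grid.network.pairwise_distance()

    obs = grid.values[grid.mask]
    var_y = float(np.var(obs)) if len(obs) > 1 else 1.0
    nugget_frac = nugget / var_y if nugget else 0.0

    res = optimize.minimize_scalar(
        lambda lr: _profiled_criterion(np.exp(lr), pairs, grid, distances,
                                       nugget_frac)[0],
        bounds=np.log(RANGE_BOUNDS_KM), method="bounded",
        options={"xatol": 1e-2})
    range_km = float(np.exp(res.x))
    _, beta, sill, xtx_inv = _profiled_criterion(range_km, pairs, grid,
                                                 distances, nugget_frac)
    se = np.sqrt(np.clip(sill * np.diag(xtx_inv), 0.0, None))
    n_pairs = sum(len(idx) for _, idx in pairs)
    return SpatioTemporalFit(float(beta[0]), float(beta[1]),
                             float(sill), range_km,
                             float(sill * nugget_frac), n_pairs,
                             float(se[0]), float(se[1]))


def impute_spatiotemporal(grid: HeatIndexGrid,
                          fit: SpatioTemporalFit) -> HeatIndexGrid:
    """Complete the grid with the fitted lag model, forward in time."""
    out = completed_like(grid)
    if grid.is_complete():
        return out
    distances = grid.network.pairwise_distance()
    months = grid_months(grid)
    season_first = grid.calendar.day_of_season == 1
    monthly = monthly_mean_table(grid)

    C_full = exponential_covariance(distances, fit.sill, fit.range_km,
                                    fit.nugget) if fit.sill > _SILL_FLOOR else None

    for j in range(grid.n_days):
        missing = np.flatnonzero(~grid.mask[:, j])
        if len(missing) == 0:
            continue
        if season_first[j]:
            _impute_first_day(grid, out, j, missing, distances, monthly, months)
            continue
        lag = out.values[:, j - 1]  # complete: forward pass
        pred = fit.beta0 + fit.beta1 * lag[missing]
        obs = np.flatnonzero(grid.mask[:, j])
        if len(obs) and C_full is not None:
            resid = grid.values[obs, j] - fit.beta0 - fit.beta1 * lag[obs]
            # simple kriging of the mean-zero residual field
            C_oo = C_full[np.ix_(obs, obs)]
            c_om = C_full[np.ix_(obs, missing)]
            pred = pred + c_om.T @ linalg.solve(C_oo, resid, assume_a="pos")
        out.values[missing, j] = pred
    return out


def _impute_first_day(grid, out, j, missing, distances, monthly, months):
    """Season-opening day: no lag exists, use the spatial-day predictor
    (or monthly means when fewer than two monitors observed)."""
    try:
        fit = fit_spatial_day(grid, j + 1, distances=distances)
        obs = fit.observed_idx
        if fit.sill <= _SILL_FLOOR:
            out.values[missing, j] = fit.mean
        else:
            w = ok_weights(fit, distances[np.ix_(obs, obs)],
                           distances[np.ix_(obs, missing)])
            out.values[missing, j] = w.T @ grid.values[obs, j]
    except (FallbackRequired, FitError):
        vals = monthly[missing, months[j] - 4]
        if np.isnan(vals).any():
            raise FitError("monthly-mean fallback undefined for the first "
                           "day of a season")
        out.values[missing, j] = vals
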