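"""Per-day ordinary kriging with exponential covariance, REML-fitted.

Each day's observations are modeled as y_i = μ + e_i with unknown constant
mean μ and Cov(e_i, e_j) = sill·exp(−d_ij/range).  The sill profiles out of
the restricted likelihood, leaving a one-dimensional search over the range.
Days observed by fewer than two monitors cannot be kriged and fall back to
monitor-specific monthly means; days where the optimizer fails borrow the
median parameters of successfully fitted days in the same calendar month.
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

logger = logging.getLogger(__name__)

RANGE_BOUNDS_KM = (1.0, 5000.0)
_CONSTANT_TOL = 1e-10


@dataclass
class SpatialDayFit:
    """Fitted exponential-covariance parameters for one day."""

    day_t: int                 # 1-based day index
    sill: float                # °F²
    range_km: float
    nugget: float              # °F²
    mean: float                # REML/GLS estimate of the day mean μ_t
    observed_idx: np.ndarray   # monitor row indices observed that day
    pooled: bool = False       # True when parameters were borrowed


def _profiled_reml(range_km: float, dist: np.ndarray, y: np.ndarray,
                   nugget_frac: float) -> tuple[float, float, float]:
    """Profiled REML for (y − 1μ) ~ N(0, sill·(R + nugget_frac·I)).

    Returns (negative restricted log-likelihood, sill_hat, mu_hat).
    """
    n = len(y)
    R = np.exp(-dist / range_km)
    if nugget_frac:
        R = R + nugget_frac * np.eye(n)
    cho = linalg.cho_factor(R, lower=True)
    ones = np.ones(n)
    Ri_1 = linalg.cho_solve(cho, ones)
    Ri_y = linalg.cho_solve(cho, y)
    denom = ones @ Ri_1
    mu = (ones @ Ri_y) / denom
    r = y - mu
    quad = r @ linalg.cho_solve(cho, r)
    sill = max(quad / (n - 1), 0.0)
    logdet_R = 2.0 * np.sum(np.log(np.diag(cho[0])))
    if sill <= _CONSTANT_TOL:
        # degenerate (constant) day: likelihood unbounded; report a flat
        # criterion so the optimizer is inert and the caller sees sill≈0
        return 0.0, sill, mu
    nll = 0.5 * ((n - 1) * np.log(sill) + logdet_R + np.log(denom))
    return nll, sill, mu


def fit_spatial_day(grid: HeatIndexGrid, day_t: int,
                    nugget: float = 0.0,
                    distances: np.ndarray | None = None) -> SpatialDayFit:
    """REML fit of the exponential model to one day's observations.

    Raises :class:`FallbackRequired` when fewer than two monitors observed
    the day, and :class:`FitError` when the optimizer fails.
    """
    obs = np.flatnonzero(grid.mask[:, day_t - 1])
    if len(obs) < 2:
        raise FallbackRequired(
            f"day t={day_t}: {len(obs)} observed monitor(s); ordinary "
            "kriging needs at least two")
    y = grid.values[obs, day_t - 1]
    if distances is None:
        distances = grid.network.pairwise_distance()
    dist = distances[np.ix_(obs, obs)]

    if np.ptp(y) <= _CONSTANT_TOL:
        return SpatialDayFit(day_t, 0.0, RANGE_BOUNDS_KM[0], 0.0,
                             float(y[0]), obs)

    var_y = float(np.var(y, ddof=1))
    nugget_frac = nugget / var_y if nugget else 0.0
    try:
        res = optimize.minimize_scalar(
            lambda lr: _profiled_reml(np.exp(lr), dist, y, nugget_frac)[0],
            bounds=np.log(RANGE_BOUNDS_KM), method="bounded",
            options={"xatol": 1e-2})
        if not np.isfinite(res.fun):
            raise FitError(f"day t={day_t}: non-finite REML criterion")
        range_km = float(np.exp(res.x))
        _, sill, mu = _profiled_reml(range_km, dist, y, nugget_frac)
    except linalg.LinAlgError as exc:
        raise FitError(f"day t={day_t}: covariance factorization failed "
                       f"({exc})") from exc
    return SpatialDayFit(day_t, float(sill), range_km,
                         float(sill * nugget_frac), float(mu), obs)


def krige_day(fit: SpatialDayFit, observations: np.ndarray,
              obs_latlon: np.ndarray, target_latlon: np.ndarray) -> np.ndarray:
    """Ordinary-kriging predictions at target locations.

    Weights solve the standard system with the unbiasedness constraint
    (they sum to one); with zero nugget the predictor honors the data
    exactly at observed sites.  ``obs_latlon``/``target_latlon`` are
    (n, 2) arrays of decimal degrees.
    """
    from heatwave_id.calendar_io import haversine_km

    obs_latlon = np.atleast_2d(obs_latlon)
    target_latlon = np.atleast_2d(target_latlon)
    y = np.asarray(observations, dtype=float)
    n = len(y)
    if n < 2:
        raise FallbackRequired("ordinary kriging needs at least two observations")

    d_oo = haversine_km(obs_latlon[:, 0:1], obs_latlon[:, 1:2],
                        obs_latlon[None, :, 0], obs_latlon[None, :, 1]
                        ).reshape(n, n)
    off_diag = ~np.eye(n, dtype=bool)
    if np.any(d_oo[off_diag] <= 1e-9):
        i, j = np.argwhere((d_oo <= 1e-9) & off_diag)[0]
        raise ValueError(
            "singular kriging system: duplicated coordinates "
            f"{tuple(obs_latlon[i])} and {tuple(obs_latlon[j])}")

    if fit.sill <= _CONSTANT_TOL:
        return np.full(len(target_latlon), fit.mean)

    C = exponential_covariance(d_oo, fit.sill, fit.range_km, fit.nugget)
    d_ot = haversine_km(obs_latlon[:, 0:1], obs_latlon[:, 1:2],
                        target_latlon[None, :, 0], target_latlon[None, :, 1]
                        ).reshape(n, -1)
    c0 = fit.sill * np.exp(-d_ot / fit.range_km)

    # ordinary-kriging system with Lagrange multiplier
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = C
    A[n, :n] = 1.0
    A[:n, n] = 1.0
    rhs = np.vstack([c0, np.ones((1, c0.shape[1]))])
    sol = linalg.solve(A, rhs)
    weights = sol[:n]
    return weights.T @ y


def ok_weights(fit: SpatialDayFit, d_oo: np.ndarray, d_ot: np.ndarray) -> np.ndarray:
    """Ordinary-kriging weight matrix (n_obs × n_targets) from precomputed
    distances; used by the grid-level imputer."""
    n = d_oo.shape[0]
    C = exponential_covariance(d_oo, fit.sill, fit.range_km, fit.nugget)
    c0 = fit.sill * np.exp(-d_ot / fit.range_km)
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = C
    A[n, :n] = 1.0
    A[:n, n] = 1.0
    rhs = np.vstack([c0, np.ones((1, c0.shape[1]))])
    return linalg.solve(A, rhs)[:n]


def fit_all_days(grid: HeatIndexGrid, nugget: float = 0.0
                 ) -> tuple[dict[int, SpatialDayFit], list[int], int]:
    """Fit every day; pool parameters (median over fitted days of the same
    calendar month) where the optimizer failed.

    Returns (fits by day_t, days needing the monthly-mean fallback,
    number of pooled days).
    """
    distances = grid.network.pairwise_distance()
    months = grid_months(grid)
    fits: dict[int, SpatialDayFit] = {}
    fallback_days: list[int] = []
    failed: list[int] = []
    for t in range(1, grid.n_days + 1):
        try:
            fits[t] = fit_spatial_day(grid, t, nugget=nugget, distances=distances)
        except FallbackRequired:
            fallback_days.append(t)
        except FitError:
            failed.append(t)
    for t in failed:
        same_month = [fits[s] for s in fits if months[s - 1] == months[t - 1]]
        if not same_month:
            fallback_days.append(t)
            continue
        obs = np.flatnonzero(grid.mask[:, t - 1])
        y = grid.values[obs, t - 1]
        fits[t] = SpatialDayFit(
            t,
            float(np.median([f.sill for f in same_month])),
            float(np.median([f.range_km for f in same_month])),
            float(np.median([f.nugget for f in same_month])),
            float(np.mean(y)), obs, pooled=True)
    if failed:
        logger.info("spatial: pooled parameters on %d day(s)", len(failed))
    if fallback_days:
        logger.info("spatial: monthly-mean fallback on %d day(s) with <2 "
                    "observed monitors", len(fallback_days))
    return fits, sorted(fallback_days), len(failed)


def impute_spatial(grid: HeatIndexGrid, nugget: float = 0.0) -> HeatIndexGrid:
    """Complete the grid by per-day ordinary kriging.

    Days with fewer than two observed monitors anywhere are filled with
    each missing monitor's own all-years monthly mean of observed values.
    Observed cells are never altered.
    """
    out = completed_like(grid)
    if grid.is_complete():
        return out
    fits, fallback_days, _ = fit_all_days(grid, nugget=nugget)

    monthly = None
    if fallback_days:
        monthly = monthly_mean_table(grid)
        if np.isnan(monthly).any():
            bad = grid.network.monitor_ids[np.isnan(monthly).any(axis=1)]
            raise FitError(
                "monthly-mean fallback undefined: monitor(s) "
                f"{list(bad)} lack observations in some calendar month")
    months = grid_months(grid)
    distances = grid.network.pairwise_distance()

    for t in range(1, grid.n_days + 1):
        j = t - 1
        missing = np.flatnonzero(~grid.mask[:, j])
        if len(missing) == 0:
            continue
        if t in fallback_days or t not in fits:
            out.values[missing, j] = monthly[missing, months[j] - 4]
            continue
        fit = fits[t]
        obs = fit.observed_idx
        if fit.sill <= _CONSTANT_TOL:
            out.values[missing, j] = fit.mean
            continue
        w = ok_weights(fit, distances[np.ix_(obs, obs)],
                       distances[np.ix_(obs, missing)])
        out.values[missing, j] = w.T @ grid.values[obs, j]
    return out
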