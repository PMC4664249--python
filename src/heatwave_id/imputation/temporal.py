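"""Per-monitor temporal model of daily maximum heat index.

The series of one monitor is modeled additively,

    y_t = f1(t) + f2(year_t) + f3(dayofseason_t) + e_t,  e_t ~ N(0, σ²),

with f1 an AR(1) process over the warm-season day index (long-term,
day-to-day changes), f2 a second-order random walk over year (slow yearly
trend) and f3 a second-order random walk over day of season 1..183 (the
within-season cycle, shared across years).  The random walks are improper;
their null spaces (level and linear trend) are moved into explicit fixed
effects, leaving proper full-rank priors for the curvature parts.

Hyperparameters — the AR coefficient and the component precisions relative
to σ² — are estimated by maximizing the marginal likelihood with σ²
profiled out in closed form; components are then read off the posterior
(penalized) mean.  All solves exploit the tridiagonal AR(1) block (banded
Cholesky) with a dense Schur complement for the small smooth-component
block, so one likelihood evaluation is O(T·p + p²·T) with p ≈ 220.

Mirroring behaviour seen on real networks, the year effect is dropped and
the model refit when the year-component variance collapses to the boundary
(no year contrast in the data, or fewer than three years observed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

from heatwave_id.calendar_io import HeatIndexGrid
from heatwave_id.imputation.common import FitError, completed_like

logger = logging.getLogger(__name__)

MIN_OBSERVED_DAYS = 30
_LOG_PREC_BOUND = 16.0
_FIXED_EFFECT_PREC = 1e-8
_BOUNDARY_VAR_FRACTION = 1e-8


@dataclass
class TemporalFit:
    """Fitted components and hyperparameters for one monitor."""

    monitor_id: str
    fitted: np.ndarray            # length-T mean predictions, °F
    f1: np.ndarray                # AR(1) component per day index
    f2_year: np.ndarray           # year effect per year (zeros when dropped)
    f3_season: np.ndarray         # day-of-season effect, length 183
    intercept: float
    sigma2: float                 # noise variance, °F²
    year_effect_dropped: bool
    hyperparameters: dict = field(default_factory=dict)


def _rw2_structure(m: int) -> np.ndarray:
    """Second-difference penalty matrix D2ᵀD2 for m equispaced knots."""
    D = np.zeros((m - 2, m))
    for k in range(m - 2):
        D[k, k:k + 3] = (1.0, -2.0, 1.0)
    return D.T @ D


def _null_free_basis(m: int) -> tuple[np.ndarray, np.ndarray]:
    """(N, Λ): orthonormal basis N of the complement of {constant, linear}
    and the full-rank penalty Λ = Nᵀ(D2ᵀD2)N."""
    x = np.arange(m, dtype=float)
    nullsp = np.column_stack([np.ones(m), x - x.mean()])
    q, _ = np.linalg.qr(np.column_stack([nullsp, np.eye(m)]))
    N = q[:, 2:m]
    K = _rw2_structure(m)
    return N, N.T @ K @ N


class _Design:
    """Shared design for all monitors on one calendar: the T×p matrix of
    smooth-component covariates and the block penalty structure."""

    def __init__(self, grid: HeatIndexGrid, include_year: bool):
        cal = grid.calendar
        self.T = cal.n_days
        self.include_year = include_year
        year_idx = cal.years - cal.start_year
        dos_idx = cal.day_of_season - 1
        ny = cal.n_years

        self.N3, self.L3 = _null_free_basis(183)
        dos_c = (dos_idx - dos_idx.mean()) / 183.0
        blocks = []
        if include_year:
            self.N2, self.L2 = _null_free_basis(ny)
            year_c = (year_idx - year_idx.mean()) / max(ny, 1)
            blocks.append(self.N2[year_idx, :])
            fixed = np.column_stack([np.ones(self.T), year_c, dos_c])
        else:
            self.N2, self.L2 = None, None
            fixed = np.column_stack([np.ones(self.T), dos_c])
        blocks.append(self.N3[dos_idx, :])
        blocks.append(fixed)
        self.U = np.concatenate(blocks, axis=1)       # T × p
        self.p = self.U.shape[1]
        self.n_z2 = ny - 2 if include_year else 0
        self.n_z3 = 181
        self.n_fixed = fixed.shape[1]
        self.year_idx = year_idx
        self.dos_idx = dos_idx
        self.ny = ny

    def prior_u(self, kappa2: float, kappa3: float) -> np.ndarray:
        Q = np.zeros((self.p, self.p))
        k = 0
        if self.include_year:
            Q[:self.n_z2, :self.n_z2] = kappa2 * self.L2
            k = self.n_z2
        Q[k:k + self.n_z3, k:k + self.n_z3] = kappa3 * self.L3
        k += self.n_z3
        Q[k:, k:] = _FIXED_EFFECT_PREC * np.eye(self.n_fixed)
        return Q


def _ar1_banded(T: int, tau: float, phi: float, extra_diag: np.ndarray
                ) -> np.ndarray:
    """Lower-banded (2×T) form of the AR(1) precision with marginal
    precision tau plus a diagonal addition."""
    kappa = tau / (1.0 - phi * phi)
    ab = np.zeros((2, T))
    ab[0, :] = kappa * (1.0 + phi * phi) + extra_diag
    ab[0, 0] = kappa + extra_diag[0]
    ab[0, -1] = kappa + extra_diag[-1]
    ab[1, :-1] = -kappa * phi
    return ab


class _Objective:
    """Profiled negative log marginal likelihood for one monitor."""

    def __init__(self, design: _Design, obs_mask: np.ndarray, y: np.ndarray):
        self.design = design
        self.obsw = obs_mask.astype(float)
        yv = np.where(obs_mask, y, 0.0)
        self.y = yv
        self.n_obs = int(obs_mask.sum())
        self.C = design.U * self.obsw[:, None]          # T × p coupling
        self.U22 = self.C.T @ design.U                  # Σ_obs u uᵀ
        self.b1 = yv * self.obsw
        self.bu = self.C.T @ yv
        self.yty = float(yv @ yv)

    def _solve(self, params):
        phi = np.tanh(params[0])
        tau1, kappa2, kappa3 = np.exp(np.clip(params[1:], -_LOG_PREC_BOUND,
                                              _LOG_PREC_BOUND))
        d = self.design
        ab = _ar1_banded(d.T, tau1, phi, self.obsw)
        cb = linalg.cholesky_banded(ab, lower=True)
        logdet_Q11 = 2.0 * float(np.sum(np.log(cb[0])))
        W = linalg.cho_solve_banded((cb, True), self.C)
        S = d.prior_u(kappa2, kappa3) + self.U22 - self.C.T @ W
        cS = linalg.cho_factor(S, lower=True)
        logdet_S = 2.0 * float(np.sum(np.log(np.diag(cS[0]))))

        q1 = linalg.cho_solve_banded((cb, True), self.b1)
        x_u = linalg.cho_solve(cS, self.bu - self.C.T @ q1)
        x_f1 = linalg.cho_solve_banded((cb, True), self.b1 - self.C @ x_u)

        quad = float(self.b1 @ x_f1 + self.bu @ x_u)
        sigma2 = max((self.yty - quad) / self.n_obs, 1e-12)

        logdet_prior = (d.T * np.log(tau1) - (d.T - 1) * np.log1p(-phi * phi)
                        + d.n_z2 * np.log(kappa2) + d.n_z3 * np.log(kappa3))
        nll = -0.5 * (logdet_prior - logdet_Q11 - logdet_S) \
            + 0.5 * self.n_obs * np.log(sigma2)
        return nll, (x_f1, x_u, sigma2, phi, tau1, kappa2, kappa3)

    def __call__(self, params) -> float:
        try:
            nll, _ = self._solve(params)
        except (linalg.LinAlgError, FloatingPointError, ValueError):
            return np.inf
        return nll if np.isfinite(nll) else np.inf


def _fit_one(design: _Design, obs_mask: np.ndarray, y: np.ndarray,
             maxfev: int = 110, x0: np.ndarray | None = None):
    obj = _Objective(design, obs_mask, y)
    if x0 is None:
        x0 = np.array([np.arctanh(0.6), -1.0, 3.0, 3.0])
    res = optimize.minimize(obj, x0, method="Nelder-Mead",
                            options={"maxfev": maxfev, "xatol": 5e-2,
                                     "fatol": 5e-1, "adaptive": True})
    nll, parts = obj._solve(res.x)
    return obj, res.x, parts


def fit_temporal(grid: HeatIndexGrid, monitor_id: str,
                 _design_cache: dict | None = None) -> TemporalFit:
    """Fit the additive temporal model to one monitor's series.

    Raises :class:`FitError` for monitors with fewer than 30 observed
    days.  The year effect is dropped (and the model refit) when fewer
    than three seasons carry data or the year-component variance estimate
    collapses to its boundary.
    """
    i = grid.network.index_of(monitor_id)
    obs_mask = grid.mask[i]
    y = grid.values[i]
    n_obs = int(obs_mask.sum())
    if n_obs < MIN_OBSERVED_DAYS:
        raise FitError(f"monitor {monitor_id}: only {n_obs} observed days "
                       f"(need ≥ {MIN_OBSERVED_DAYS})")

    cal = grid.calendar
    seasons_with_data = len(np.unique(cal.years[obs_mask]))
    var_y = float(np.var(y[obs_mask])) if n_obs > 1 else 0.0

    cache = _design_cache if _design_cache is not None else {}
    dropped = cal.n_years < 3 or seasons_with_data < 2

    if not dropped:
        if "year" not in cache:
            cache["year"] = _Design(grid, include_year=True)
        design = cache["year"]
        try:
            obj, xopt, parts = _fit_one(design, obs_mask, y,
                                        x0=cache.get("warm_start"))
            f2 = _year_component(design, parts)
            at_boundary = (xopt[2] >= _LOG_PREC_BOUND - 0.5
                           or float(np.var(f2)) <= _BOUNDARY_VAR_FRACTION * max(var_y, 1e-12))
            dropped = bool(at_boundary)
        except (linalg.LinAlgError, FitError):
            dropped = True

    if dropped:
        if "noyear" not in cache:
            cache["noyear"] = _Design(grid, include_year=False)
        design = cache["noyear"]
        obj, xopt, parts = _fit_one(design, obs_mask, y,
                                    x0=cache.get("warm_start"))
    cache["warm_start"] = xopt

    return _assemble_fit(monitor_id, grid, design, parts, dropped, xopt)


def _year_component(design: _Design, parts) -> np.ndarray:
    x_f1, x_u, *_ = parts
    z2 = x_u[:design.n_z2]
    delta_year = x_u[design.n_z2 + design.n_z3 + 1]  # fixed: [1, year_c, dos_c]
    yr = np.arange(design.ny, dtype=float)
    year_c = (yr - yr.mean()) / max(design.ny, 1)
    return design.N2 @ z2 + delta_year * year_c


def _assemble_fit(monitor_id, grid, design, parts, dropped, xopt) -> TemporalFit:
    x_f1, x_u, sigma2, phi, tau1, kappa2, kappa3 = parts
    k = design.n_z2
    z3 = x_u[k:k + design.n_z3]
    fixed = x_u[k + design.n_z3:]
    if design.include_year:
        intercept, delta_year, delta_dos = fixed
        f2_year = _year_component(design, parts)
    else:
        intercept, delta_dos = fixed
        f2_year = np.zeros(design.ny)
    dos = np.arange(183, dtype=float)
    dos_c = (dos - dos.mean()) / 183.0
    f3_season = design.N3 @ z3 + delta_dos * dos_c

    fitted = (intercept + x_f1 + f2_year[design.year_idx]
              + f3_season[design.dos_idx])
    hyper = {"phi": float(phi), "tau_ar_rel": float(tau1),
             "kappa_year_rel": float(kappa2) if design.include_year else None,
             "kappa_season_rel": float(kappa3)}
    return TemporalFit(monitor_id, fitted, x_f1, f2_year, f3_season,
                       float(intercept), float(sigma2), dropped, hyper)


def impute_temporal(grid: HeatIndexGrid) -> HeatIndexGrid:
    """Complete the grid monitor by monitor with each monitor's own
    temporal-model predictions; observed cells are never altered."""
    out = completed_like(grid)
    if grid.is_complete():
        return out
    cache: dict = {}
    n_dropped = 0
    for i, monitor_id in enumerate(grid.network.monitor_ids):
        missing = ~grid.mask[i]
        if not missing.any():
            continue
        fit = fit_temporal(grid, monitor_id, _design_cache=cache)
        n_dropped += fit.year_effect_dropped
        out.values[i, missing] = fit.fitted[missing]
    if n_dropped:
        logger.info("temporal: year effect dropped for %d monitor(s)", n_dropped)
    return out
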