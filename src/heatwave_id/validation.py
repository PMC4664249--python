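"""Stratified hold-out validation of the imputation methods.

A 10% sample of observed cells, stratified by day (round-half-to-even of
fraction × observed monitors per day, sampled without replacement), is
removed; each imputer runs on the reduced grid and is scored by root mean
squared prediction error (RMSPE) at the held-out cells — overall, on
extreme cells (true value above 100°F), and per monitor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from heatwave_id.calendar_io import HeatIndexGrid
from heatwave_id.imputation import IMPUTERS

EXTREME_CUTOFF_F = 100.0


@dataclass
class HoldoutSample:
    rows: np.ndarray          # monitor indices of held-out cells
    cols: np.ndarray          # day indices (0-based)
    true_values: np.ndarray
    fraction: float
    seed: int

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class RmspeReport:
    overall: dict = field(default_factory=dict)        # method -> °F
    extreme: dict = field(default_factory=dict)        # method -> °F or None
    extreme_bias: dict = field(default_factory=dict)   # mean signed error >100°F
    per_monitor: pd.DataFrame | None = None            # monitor × method
    winners: pd.Series | None = None                   # per-monitor best
    losers: pd.Series | None = None                    # per-monitor worst
    n_cells: int = 0
    n_extreme: int = 0


def draw_holdout(grid: HeatIndexGrid, fraction: float = 0.10,
                 seed: int = 0) -> HoldoutSample:
    """Stratified-by-day sample of observed cells.

    Within each day the number held out is round-half-to-even of
    fraction × (observed monitors that day); deterministic given seed.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    rows, cols = [], []
    for j in range(grid.n_days):
        obs = np.flatnonzero(grid.mask[:, j])
        k = int(np.round(fraction * len(obs)))  # numpy rounds half to even
        if k == 0:
            continue
        pick = rng.choice(obs, size=k, replace=False)
        rows.append(pick)
        cols.append(np.full(k, j))
    rows = np.concatenate(rows) if rows else np.array([], dtype=int)
    cols = np.concatenate(cols) if cols else np.array([], dtype=int)
    return HoldoutSample(rows, cols, grid.values[rows, cols], fraction, seed)


def remove_holdout(grid: HeatIndexGrid, sample: HoldoutSample) -> HeatIndexGrid:
    out = grid.copy()
    out.mask[sample.rows, sample.cols] = False
    out.values[sample.rows, sample.cols] = np.nan
    return out


def rmspe(predictions, truths, subset_threshold_f: float | None = None
          ) -> float | None:
    """Root mean squared prediction error; with ``subset_threshold_f`` the
    pairs are restricted to truths strictly above the threshold, and
    ``None`` is returned when no pair qualifies."""
    p = np.asarray(predictions, dtype=float)
    t = np.asarray(truths, dtype=float)
    if p.shape != t.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {t.shape}")
    if subset_threshold_f is not None:
        keep = t > subset_threshold_f
        if not keep.any():
            return None
        p, t = p[keep], t[keep]
    if len(p) == 0:
        return None
    return float(np.sqrt(np.mean((p - t) ** 2)))


def compare_methods(grid: HeatIndexGrid, methods=("temporal", "spatial",
                                                  "spatiotemporal"),
                    fraction: float = 0.10, seed: int = 0,
                    imputers: dict | None = None) -> RmspeReport:
    """Hold out, impute with each method, and score.

    ``imputers`` may override the method table (e.g. with an oracle for
    testing); by default the package's three imputation models are used.
    All methods are scored on the same single hold-out draw (a paired
    comparison).
    """
    if not methods:
        raise ValueError("need at least one method")
    table = imputers or IMPUTERS
    sample = draw_holdout(grid, fraction, seed)
    reduced = remove_holdout(grid, sample)
    truths = sample.true_values
    extreme = truths > EXTREME_CUTOFF_F

    report = RmspeReport(n_cells=len(sample), n_extreme=int(extreme.sum()))
    per_monitor = {}
    for method in methods:
        completed = table[method](reduced)
        preds = completed.values[sample.rows, sample.cols]
        report.overall[method] = rmspe(preds, truths)
        report.extreme[method] = rmspe(preds, truths, EXTREME_CUTOFF_F)
        report.extreme_bias[method] = (
            float(np.mean((preds - truths)[extreme])) if extreme.any() else None)
        sq = (preds - truths) ** 2
        per_monitor[method] = pd.Series(sq).groupby(sample.rows).mean().pow(0.5)
    pm = pd.DataFrame(per_monitor)
    pm.index = grid.network.monitor_ids[pm.index.to_numpy()]
    pm.index.name = "monitor_id"
    report.per_monitor = pm
    if len(methods) > 1 and len(pm):
        report.winners = pm.idxmin(axis=1)
        report.losers = pm.idxmax(axis=1)
    return report


def signed_error(grid: HeatIndexGrid, method: str, fraction: float = 0.10,
                 seed: int = 0, subset_threshold_f: float | None = None
                 ) -> float | None:
    """Mean signed imputation error (prediction − truth) on a hold-out,
    optionally restricted to truths above a threshold.  Negative values on
    the extreme subset indicate regression toward the mean."""
    sample = draw_holdout(grid, fraction, seed)
    reduced = remove_holdout(grid, sample)
    completed = IMPUTERS[method](reduced)
    preds = completed.values[sample.rows, sample.cols]
    truths = sample.true_values
    if subset_threshold_f is not None:
        keep = truths > subset_threshold_f
        if not keep.any():
            return None
        preds, truths = preds[keep], truths[keep]
    return float(np.mean(preds - truths))
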