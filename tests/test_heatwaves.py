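import numpy as np
import pytest

from heatwave_id.heatwaves import (
    NO_BENCHMARK,
    find_heatwaves,
    find_heatwaves_ignore_missing,
    regional_benchmark,
    restrict_to_years,
)
from tests.conftest import toy_grid, toy_network


def brute_force_waves(vals, p80s, upper, min_hot_days=3):
    """Exhaustive enumeration over all O(T²) candidate periods of one
    season: keep periods where condition (1) holds on every day for every
    monitor and condition (2) holds for every monitor, then keep only
    periods maximal under condition (1)."""
    n, T = vals.shape
    cond1 = (vals > np.asarray(p80s)[:, None]).all(axis=0)
    out = []
    for a in range(T):
        for b in range(a + min_hot_days - 1, T):
            if not cond1[a:b + 1].all():
                continue
            if a > 0 and cond1[a - 1]:
                continue          # extensible left
            if b < T - 1 and cond1[b + 1]:
                continue          # extensible right
            hot = (vals[:, a:b + 1] > upper).sum(axis=1)
            if (hot >= min_hot_days).all():
                out.append((a, b))
    return out


def _records_to_offsets(grid, records):
    t0 = grid.calendar.dates[0]
    return [(int((w.start_date - t0).astype(int)),
             int((w.end_date - t0).astype(int))) for w in records]


class TestFindHeatwaves:
    def test_all_cold_gives_nothing(self):
        grid = toy_grid(np.full((2, 183), 80.0))
        waves = find_heatwaves(grid, {"M1": 90.0, "M2": 90.0}, 100.0)
        assert waves == []

    def test_constructed_ten_day_toy(self):
        # days 3–8 (1-based) satisfy condition 1; each monitor has exactly
        # 3 days above the upper threshold of 100
        m1 = [85, 85, 96, 101, 102, 97, 96, 103, 85, 85]
        m2 = [85, 85, 97, 102, 96, 101, 96, 102, 85, 85]
        vals = np.array([m1 + [85] * 173, m2 + [85] * 173], dtype=float)
        grid = toy_grid(vals)
        p80s = {"M1": 95.0, "M2": 95.0}
        waves = find_heatwaves(grid, p80s, 100.0)
        assert _records_to_offsets(grid, waves) == [(2, 7)]
        assert waves[0].hot_days_per_monitor == {"M1": 3, "M2": 3}
        assert brute_force_waves(vals, [95.0, 95.0], 100.0) == [(2, 7)]

    def test_condition_two_failure(self):
        # monitor 2 exceeds the upper threshold on only 2 days
        m1 = [85, 96, 101, 102, 101, 96, 85]
        m2 = [85, 97, 102, 96, 101, 96, 85]
        vals = np.array([m1 + [85] * 176, m2 + [85] * 176], dtype=float)
        grid = toy_grid(vals)
        assert find_heatwaves(grid, {"M1": 95.0, "M2": 95.0}, 100.5) == []

    def test_matches_brute_force_on_random_toys(self):
        rng = np.random.default_rng(12)
        for _ in range(40):
            n = rng.integers(1, 4)
            T = int(rng.integers(10, 21))
            vals = rng.uniform(90, 106, (n, T))
            full = np.concatenate([vals, np.full((n, 183 - T), 80.0)], axis=1)
            grid = toy_grid(full, network=toy_network(n))
            p80 = rng.uniform(92, 98, n)
            upper = float(rng.uniform(98, 104))
            waves = find_heatwaves(grid, {f"M{i+1}": p80[i] for i in range(n)},
                                   upper)
            got = _records_to_offsets(grid, waves)
            want = brute_force_waves(np.concatenate(
                [vals, np.full((n, 1), 80.0)], axis=1), p80, upper)
            assert got == want

    def test_monitor_order_invariance(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(90, 106, (3, 183))
        grid = toy_grid(vals, network=toy_network(3))
        p80s = {"M1": 95.0, "M2": 96.0, "M3": 94.0}
        a = find_heatwaves(grid, p80s, 100.0)
        perm = [2, 0, 1]
        net2 = toy_network(3)
        grid2 = toy_grid(vals[perm], network=net2)
        p80s2 = {f"M{k+1}": p80s[f"M{perm[k]+1}"] for k in range(3)}
        b = find_heatwaves(grid2, p80s2, 100.0)
        assert _records_to_offsets(grid, a) == _records_to_offsets(grid2, b)

    def test_runs_never_cross_seasons(self):
        vals = np.full((1, 366), 105.0)
        grid = toy_grid(vals, network=toy_network(1), pad=105.0)
        waves = find_heatwaves(grid, {"M1": 95.0}, 100.0)
        assert len(waves) == 2  # one full-season wave per year
        for w in waves:
            assert w.n_days == 183

    def test_periods_disjoint_and_maximal(self):
        rng = np.random.default_rng(77)
        vals = rng.uniform(92, 104, (2, 183))
        grid = toy_grid(vals, network=toy_network(2))
        p80s = {"M1": 95.0, "M2": 95.0}
        waves = find_heatwaves(grid, p80s, 99.0)
        spans = _records_to_offsets(grid, waves)
        for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
            assert b1 < a2
        cond1 = (vals > 95.0).all(axis=0)
        for a, b in spans:
            assert cond1[a:b + 1].all()
            assert a == 0 or not cond1[a - 1]
            assert b == 182 or not cond1[b + 1]

    def test_missing_thresholds_rejected(self):
        grid = toy_grid(np.full((2, 183), 90.0))
        with pytest.raises(KeyError, match="M2"):
            find_heatwaves(grid, {"M1": 95.0}, 100.0)


class TestIgnoreMissing:
    def test_full_season_wave(self):
        grid = toy_grid(np.full((1, 183), 105.0), network=toy_network(1))
        waves = find_heatwaves_ignore_missing(
            np.full(183, 105.0), 95.0, 100.0, grid.calendar)
        assert len(waves) == 1
        assert waves[0].n_days == 183

    def test_missing_day_breaks_runs(self):
        s = np.full(183, 80.0)
        s[10:20] = 105.0
        s[14] = np.nan
        cal = toy_grid(np.zeros((1, 183)), network=toy_network(1)).calendar
        waves = find_heatwaves_ignore_missing(s, 95.0, 100.0, cal)
        got = [(int((w.start_date - cal.dates[0]).astype(int)),
                int((w.end_date - cal.dates[0]).astype(int))) for w in waves]
        assert got == [(10, 13), (15, 19)]

    def test_twelve_value_toy_matches_brute_force(self):
        series = np.array([96, 101, 102, 97, 96, 103, 85, 99, 101, 102,
                           103, 85], dtype=float)
        s = np.concatenate([series, np.full(171, 80.0)])
        cal = toy_grid(np.zeros((1, 183)), network=toy_network(1)).calendar
        waves = find_heatwaves_ignore_missing(s, 95.0, 100.0, cal)
        got = [(int((w.start_date - cal.dates[0]).astype(int)),
                int((w.end_date - cal.dates[0]).astype(int))) for w in waves]
        # oracle: treat the average series as a 1-monitor region
        want = brute_force_waves(s[None, :], [95.0], 100.0)
        assert got == want == [(0, 5), (7, 10)]


class TestRegionalBenchmark:
    def _toy(self):
        m1 = [85, 96, 104.5, 105.5, 104.2, 96, 85]
        m2 = [85, 97, 104.3, 104.8, 105.2, 96, 85]
        vals = np.array([m1 + [85] * 176, m2 + [85] * 176], dtype=float)
        grid = toy_grid(vals)
        p80s = {"M1": 95.0, "M2": 95.0}
        return grid, p80s

    def test_highest_threshold_yielding_a_wave(self):
        grid, p80s = self._toy()
        finder = lambda u: find_heatwaves(grid, p80s, u)
        bench = regional_benchmark(finder, range(95, 121))
        # at 104 every monitor has 3 days above; at 105 it does not
        assert bench == 104.0
        assert finder(105.0) == []
        assert len(finder(104.0)) == 1

    def test_all_cold_returns_no_benchmark(self):
        grid = toy_grid(np.full((2, 183), 80.0))
        finder = lambda u: find_heatwaves(grid, {"M1": 90.0, "M2": 90.0}, u)
        assert regional_benchmark(finder, range(95, 121)) is NO_BENCHMARK

    def test_wave_count_monotone_and_scan_equals_search(self):
        rng = np.random.default_rng(21)
        vals = rng.uniform(92, 108, (2, 183))
        grid = toy_grid(vals, network=toy_network(2))
        p80s = {"M1": 94.0, "M2": 94.0}
        finder = lambda u: find_heatwaves(grid, p80s, u)
        counts = [len(finder(u)) for u in range(95, 121)]
        assert all(c1 >= c2 for c1, c2 in zip(counts, counts[1:]))
        # exhaustive scan agrees with the package's top-down search
        exhaustive = max((u for u in range(95, 121) if counts[u - 95] > 0),
                         default=None)
        got = regional_benchmark(finder, range(95, 121))
        assert got == (float(exhaustive) if exhaustive is not None else None)


class TestRestrictToYears:
    def test_whole_seasons_kept(self, small_truth):
        sub = restrict_to_years(small_truth, 2006, 2007)
        assert sub.calendar.n_days == 2 * 183
        assert sub.values.shape == (small_truth.n_monitors, 366)
        j0 = small_truth.calendar.t_of_date("2006-04-01") - 1
        assert np.array_equal(sub.values, small_truth.values[:, j0:j0 + 366])

    def test_window_outside_calendar_rejected(self, small_truth):
        with pytest.raises(ValueError):
            restrict_to_years(small_truth, 1990, 1991)
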