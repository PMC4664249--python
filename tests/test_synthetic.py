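import numpy as np
import pytest

from heatwave_id.synthetic import (
    apply_missingness,
    default_config,
    generate_network,
    generate_truth,
    missingness_probabilities,
)


def _independent_haversine(lat1, lon1, lat2, lon2):
    # textbook formula, written separately from the package's version
    p = np.pi / 180.0
    a = (np.sin(p * (lat2 - lat1) / 2) ** 2
         + np.cos(p * lat1) * np.cos(p * lat2)
         * np.sin(p * (lon2 - lon1) / 2) ** 2)
    return 2 * 6371.0 * np.arctan2(np.sqrt(a), np.sqrt(1 - a))


class TestGenerateNetwork:
    def test_single_monitor(self):
        cfg = default_config(n_monitors=1, seed=4)
        net = generate_network(cfg)
        assert net.n_monitors == 1
        assert net.regions[0] in net.region_names

    def test_deterministic_given_seed(self):
        cfg = default_config(seed=9)
        a, b = generate_network(cfg), generate_network(cfg)
        assert np.array_equal(a.latitudes, b.latitudes)
        assert np.array_equal(a.longitudes, b.longitudes)
        assert np.array_equal(a.regions, b.regions)

    def test_distances_match_haversine_oracle(self):
        cfg = default_config(seed=9)
        net = generate_network(cfg)
        d = net.pairwise_distance()
        assert np.allclose(d, d.T)
        off = d[~np.eye(43, dtype=bool)]
        assert (off > 0).all()
        for i, j in [(0, 1), (5, 40), (12, 30)]:
            expect = _independent_haversine(net.latitudes[i], net.longitudes[i],
                                            net.latitudes[j], net.longitudes[j])
            assert d[i, j] == pytest.approx(expect, rel=1e-9)

    def test_degenerate_bounding_box_rejected(self):
        with pytest.raises(ValueError, match="bounding box"):
            generate_network(default_config(lat_min=28.0, lat_max=28.0))

    def test_regions_are_latitude_bands(self):
        cfg = default_config(seed=2)
        net = generate_network(cfg)
        # region label increases (weakly) with latitude
        order = np.argsort(net.latitudes)
        bands = [int(r[1:]) for r in net.regions[order]]
        assert all(b2 >= b1 for b1, b2 in zip(bands, bands[1:]))


class TestGenerateTruth:
    def test_all_variation_off_gives_constant_surface(self):
        cfg = default_config(n_monitors=3, start_year=2005, end_year=2005,
                             seasonal_amplitude=0.0, year_trend=0.0,
                             spatial_sill=0.0, nugget=0.0,
                             monitor_offsets_sd=0.0, seed=1)
        net = generate_network(cfg)
        truth = generate_truth(cfg, net, cfg.calendar())
        assert np.allclose(truth.values, cfg.seasonal_mean)

    def test_deterministic_given_seed(self):
        cfg = default_config(n_monitors=5, start_year=2005, end_year=2006,
                             seed=3)
        net = generate_network(cfg)
        a = generate_truth(cfg, net, cfg.calendar())
        b = generate_truth(cfg, net, cfg.calendar())
        assert np.array_equal(a.values, b.values)

    def test_zero_phi_kills_lag1_autocorrelation(self):
        cfg = default_config(n_monitors=4, start_year=1973, end_year=1992,
                             ar_coefficient=0.0, nugget=0.0,
                             seasonal_amplitude=0.0, year_trend=0.0, seed=6)
        net = generate_network(cfg)
        truth = generate_truth(cfg, net, cfg.calendar())
        x = truth.values[0] - truth.values[0].mean()
        r1 = (x[:-1] * x[1:]).mean() / x.var()
        assert abs(r1) < 3.0 / np.sqrt(len(x))

    def test_nonzero_phi_detected(self):
        cfg = default_config(n_monitors=2, start_year=1973, end_year=1992,
                             nugget=0.0, seasonal_amplitude=0.0,
                             year_trend=0.0, seed=6)
        net = generate_network(cfg)
        truth = generate_truth(cfg, net, cfg.calendar())
        x = truth.values[0] - truth.values[0].mean()
        r1 = (x[:-1] * x[1:]).mean() / x.var()
        assert r1 == pytest.approx(cfg.ar_coefficient, abs=0.08)

    def test_spatial_correlation_decays_with_stated_range(self):
        cfg = default_config(n_monitors=20, start_year=1973, end_year=1992,
                             seasonal_amplitude=0.0, year_trend=0.0,
                             monitor_offsets_sd=0.0, nugget=0.0,
                             ar_coefficient=0.0, seed=8)
        net = generate_network(cfg)
        truth = generate_truth(cfg, net, cfg.calendar())
        d = net.pairwise_distance()
        x = truth.values - truth.values.mean(axis=1, keepdims=True)
        c = np.corrcoef(x)
        iu = np.triu_indices(20, k=1)
        # fit log corr ~ -d/range by least squares through the origin
        logc = np.log(np.clip(c[iu], 1e-6, None))
        est_range = -np.sum(d[iu] ** 2) / np.sum(d[iu] * logc)
        assert est_range == pytest.approx(cfg.spatial_range, rel=0.25)


class TestApplyMissingness:
    def test_zero_rates_identity(self):
        cfg = default_config(n_monitors=3, start_year=2005, end_year=2005,
                             missing_rate_warm_months=0.0,
                             missing_rate_cool_months=0.0, seed=1)
        net = generate_network(cfg)
        truth = generate_truth(cfg, net, cfg.calendar())
        obs, heldout = apply_missingness(truth, cfg)
        assert obs.mask.all()
        assert len(heldout) == 0

    def test_warm_months_untouched_when_warm_rate_zero(self):
        cfg = default_config(n_monitors=4, start_year=2005, end_year=2006,
                             missing_rate_warm_months=0.0,
                             missing_rate_cool_months=0.5, seed=1)
        net = generate_network(cfg)
        truth = generate_truth(cfg, net, cfg.calendar())
        obs, _ = apply_missingness(truth, cfg)
        months = obs.calendar.dates.astype("datetime64[M]").astype(int) % 12 + 1
        warm = np.isin(months, (6, 7, 8))
        assert obs.mask[:, warm].all()
        assert not obs.mask[:, ~warm].all()

    def test_empirical_rates_match_binomial_targets(self):
        cfg = default_config(n_monitors=10, start_year=1973, end_year=1992,
                             missing_rate_warm_months=0.05,
                             missing_rate_cool_months=0.20,
                             monitor_missing_multipliers=(1.0,) * 10, seed=2)
        net = generate_network(cfg)
        truth = generate_truth(cfg, net, cfg.calendar())
        obs, _ = apply_missingness(truth, cfg)
        months = obs.calendar.dates.astype("datetime64[M]").astype(int) % 12 + 1
        for rate, sel in [(0.05, np.isin(months, (6, 7, 8))),
                          (0.20, ~np.isin(months, (6, 7, 8)))]:
            n = obs.mask[:, sel].size
            frac = 1.0 - obs.mask[:, sel].mean()
            se = np.sqrt(rate * (1 - rate) / n)
            assert abs(frac - rate) < 3 * se

    def test_heldout_table_recovers_masked_truth(self, small_config,
                                                 small_truth):
        obs, heldout = apply_missingness(small_truth, small_config)
        assert len(heldout) == int((~obs.mask).sum())
        for row in heldout.itertuples(index=False):
            i = obs.network.index_of(row.monitor_id)
            j = obs.calendar.t_of_date(row.date) - 1
            assert not obs.mask[i, j]
            assert small_truth.values[i, j] == row.true_hi_f

    def test_probability_cap(self):
        cfg = default_config(n_monitors=2, missing_rate_cool_months=0.9,
                             monitor_missing_multipliers=(5.0, 1.0), seed=1)
        net = generate_network(cfg)
        p = missingness_probabilities(cfg, net, cfg.calendar())
        assert p.max() <= 0.95
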