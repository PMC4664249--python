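import numpy as np
import pytest

from heatwave_id.calendar_io import HeatIndexGrid, MonitorNetwork, build_calendar
from heatwave_id.synthetic import (
    apply_missingness,
    default_config,
    generate_network,
    generate_truth,
)


@pytest.fixture(scope="session")
def small_config():
    """Six monitors, three seasons — quick but structurally complete."""
    return default_config(n_monitors=6, start_year=2005, end_year=2007, seed=11)


@pytest.fixture(scope="session")
def small_network(small_config):
    return generate_network(small_config)


@pytest.fixture(scope="session")
def small_truth(small_config, small_network):
    return generate_truth(small_config, small_network,
                          small_config.calendar())


@pytest.fixture(scope="session")
def small_observed(small_config, small_truth):
    observed, heldout = apply_missingness(small_truth, small_config)
    return observed


def toy_network(n=2, spacing_deg=0.5, region="R1"):
    """Monitors in a row along one latitude."""
    return MonitorNetwork(
        monitor_ids=np.array([f"M{i+1}" for i in range(n)], dtype=object),
        latitudes=np.full(n, 28.0),
        longitudes=-82.0 + spacing_deg * np.arange(n),
        regions=np.full(n, region, dtype=object),
    )


def toy_grid(values, network=None, start_year=2005, mask=None, pad=np.nan):
    """Grid from an (n_monitors, n_days) array; NaN means missing.  Days
    beyond the supplied columns are padded with ``pad`` (NaN = missing)."""
    values = np.asarray(values, dtype=float)
    n, T = values.shape
    n_years = int(np.ceil(T / 183))
    cal = build_calendar(start_year, start_year + n_years - 1)
    full = np.full((n, cal.n_days), float(pad))
    full[:, :T] = values
    if mask is None:
        m = np.isfinite(full)
    else:
        m = np.zeros((n, cal.n_days), dtype=bool)
        m[:, :T] = mask
        full[~m] = np.nan
    net = network if network is not None else toy_network(n)
    return HeatIndexGrid(full, m, cal, net)
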