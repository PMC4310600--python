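import numpy as np
import pandas as pd
import pytest

import rangeshift as rs


@pytest.fixture
def toy_plots() -> pd.DataFrame:
    """Six forested plots in two strata with simple attributes."""
    return pd.DataFrame(
        {
            "plot_id": [f"p{i}" for i in range(1, 7)],
            "stratum": ["CA-OR", "CA-OR", "CA-OR", "WA", "WA", "WA"],
            "latitude": [33.0, 35.0, 38.0, 45.0, 46.5, 48.0],
            "longitude": [-120.0, -121.0, -122.0, -122.5, -121.5, -120.5],
            "elevation_m": [100.0, 800.0, 1500.0, 300.0, 900.0, 1200.0],
            "mat_c": [16.0, 12.0, 8.0, 9.0, 6.0, 4.0],
            "tmin_c": [8.0, 4.0, 0.0, 1.0, -2.0, -4.0],
            "tmax_c": [24.0, 20.0, 16.0, 17.0, 14.0, 12.0],
            "forested": [True] * 6,
            "weight": [24.0, 24.0, 24.0, 26.6, 26.6, 26.6],
        }
    )


@pytest.fixture
def toy_tally() -> pd.DataFrame:
    """A seedling, a small stem and a large stem of one species."""
    return pd.DataFrame(
        {
            "plot_id": ["p1", "p2", "p3"],
            "species": ["PSME"] * 3,
            "size_class": [None, None, None],
            "diameter_cm": [np.nan, 5.0, 40.0],
            "count": [2, 1, 1],
        }
    )


@pytest.fixture(scope="session")
def small_inventory():
    """A modest synthetic inventory shared by pipeline-level tests."""
    niches = rs.default_niches(n_species=8, delta=0.15)
    plots, tally, truth = rs.simulate_inventory(rs.LandscapeConfig(), niches, 3000, seed=11)
    return plots, tally, truth, niches
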