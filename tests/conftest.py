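import logging

import numpy as np
import pytest

from ambientpop.grid_io import GridRaster, GridSpec
from ambientpop.synthetic import ScenarioConfig, generate_scenario

logging.getLogger("ambientpop").setLevel(logging.ERROR)


@pytest.fixture
def small_spec():
    return GridSpec(origin_lon=110.0, origin_lat=35.0, cell_size=0.01,
                    n_rows=4, n_cols=5)


@pytest.fixture
def small_raster(small_spec):
    values = np.arange(20, dtype=float).reshape(4, 5)
    return GridRaster(small_spec, values, units="counts")


@pytest.fixture(scope="session")
def small_scenario():
    """A quick desk scenario shared by read-only tests."""
    cfg = ScenarioConfig(
        grid=GridSpec(110.0, 35.0, 0.01, 30, 30),
        n_counties=36, n_towns_per_county=2, n_hotspots=5,
        n_days=10, holiday_dates=("2018-03-05",), seed=11,
    )
    return generate_scenario(cfg)


@pytest.fixture(scope="session")
def default_scenario():
    """One full default-size scenario for heavier read-only tests."""
    return generate_scenario(ScenarioConfig(seed=42))
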