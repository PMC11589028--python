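import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fadrift.synth import Grid, make_uniform_flow

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_grid():
    """20°×20° equatorial grid at 1°, two time levels spanning 100 days."""
    return Grid.regular(lon_bounds=(180.0, 200.0), lat_bounds=(-10.0, 10.0),
                        resolution=1.0, time_days=(0.0, 100.0))


@pytest.fixture
def uniform_slab(small_grid):
    return make_uniform_flow(0.1, 0.0, small_grid)


@pytest.fixture
def make_slab():
    """Factory for uniform slabs on arbitrary grids."""
    def _make(u0=0.1, v0=0.0, lon_bounds=(180.0, 200.0), lat_bounds=(-10.0, 10.0),
              resolution=1.0, time_days=(0.0, 100.0)):
        grid = Grid.regular(lon_bounds=lon_bounds, lat_bounds=lat_bounds,
                            resolution=resolution, time_days=time_days)
        return make_uniform_flow(u0, v0, grid)
    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
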