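import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from resiligrid import GridCube, GridSpec

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_grid() -> GridSpec:
    return GridSpec(lon0=100.0, lat0=45.0, dlon=0.5, dlat=0.5, nrows=6, ncols=8)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


def make_cube(values, start_year=2000, grid=None, kind=None) -> GridCube:
    values = np.asarray(values, dtype=float)
    if grid is None:
        grid = GridSpec(100.0, 45.0, 0.5, 0.5, values.shape[1], values.shape[2])
    years = list(range(start_year, start_year + values.shape[0]))
    return GridCube(values, years, grid, kind=kind)


@pytest.fixture
def cube_factory():
    return make_cube
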