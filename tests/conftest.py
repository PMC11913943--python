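import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from encroach import synthetic
from encroach.grids import Grid, LandCoverMap
from encroach.synthetic import bisley_scheme

settings.register_profile(
    "ci", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def scheme():
    return bisley_scheme()


def make_map(codes, scheme, pixel_size=5.0, nodata=None):
    grid = Grid(
        values=np.asarray(codes),
        pixel_size=pixel_size,
        origin=(0.0, np.asarray(codes).shape[0] * pixel_size),
        nodata=nodata,
        kind="categorical",
    )
    return LandCoverMap(grid=grid, scheme=scheme)


@pytest.fixture(scope="session")
def small_series():
    """An 80x80 synthetic landscape with three simulated intervals."""
    params = synthetic.LandscapeParams(shape=(80, 80), seed=11)
    stack = synthetic.generate_covariates(params)
    initial = synthetic.generate_initial_landcover(stack, params)
    return synthetic.simulate_series(initial, stack, synthetic.bisley_like_dynamics(), seed=12)


@pytest.fixture(scope="session")
def full_series():
    """A reserve-scale (374x374, 5 m) series for end-to-end recovery checks."""
    params = synthetic.LandscapeParams(seed=1)
    stack = synthetic.generate_covariates(params)
    initial = synthetic.generate_initial_landcover(stack, params)
    return synthetic.simulate_series(initial, stack, synthetic.bisley_like_dynamics(), seed=2)
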