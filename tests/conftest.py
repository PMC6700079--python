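import numpy as np
import pytest

from swallowtrace import GridSpec, generate_breeding_records, generate_isoscapes
from swallowtrace.synthetic import box_origin_sampler, generate_feather_samples


@pytest.fixture(scope="session")
def small_grid():
    """A 20x20 half-degree grid over a sub-Saharan-like box."""
    return GridSpec(lon_min=10.0, lon_max=20.0, lat_min=-15.0, lat_max=-5.0, resolution=0.5)


@pytest.fixture(scope="session")
def toy_grid():
    """A 3x3 one-degree grid for hand-checkable oracles."""
    return GridSpec(lon_min=0.0, lon_max=3.0, lat_min=0.0, lat_max=3.0, resolution=1.0)


@pytest.fixture(scope="session")
def small_isoscapes(small_grid):
    return generate_isoscapes(small_grid, seed=7)


@pytest.fixture(scope="session")
def residual_cov():
    return np.array([[64.0, 12.0, 2.0], [12.0, 4.0, 0.3], [2.0, 0.3, 1.44]])


@pytest.fixture(scope="session")
def feather_batch(small_isoscapes, residual_cov):
    sampler = box_origin_sampler(-13.0, -7.0, 12.0, 18.0)
    return generate_feather_samples(
        n=40, origin_sampler=sampler, isoscapes=small_isoscapes,
        residual_cov=residual_cov, seed=11,
    )


@pytest.fixture(scope="session")
def breeding_table():
    """One default-parameter breeding table shared by the SEM tests."""
    return generate_breeding_records(seed=42)
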