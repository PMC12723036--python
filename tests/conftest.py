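import numpy as np
import pytest

from shipair import synthetic_world as sw


@pytest.fixture(scope="session")
def grid32():
    return sw.build_grid(32, 32, 36.0, seed=7)


@pytest.fixture(scope="session")
def dataset32():
    """Full 5-year dataset on the 32x32 world (shared, read-only)."""
    grid = sw.build_grid(32, 32, 36.0, seed=7)
    params = sw.WorldParams()
    samples = sw.make_dataset(grid, params, n_years=5, seed=7)
    return samples, grid, params


@pytest.fixture(scope="session")
def tiny_world():
    """Coarse 16x16 world (72-km cells) for fast training-path tests."""
    grid = sw.build_grid(16, 16, 72.0, seed=3)
    params = sw.WorldParams()
    samples = sw.make_dataset(grid, params, n_years=5, seed=3)
    return samples, grid, params


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
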