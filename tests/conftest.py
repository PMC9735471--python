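import numpy as np
import pytest

from skewkrige import SyntheticSiteConfig, simulate_site
from skewkrige.samples import SampleSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_site():
    """One default synthetic contaminated-site sample set (n=60)."""
    return simulate_site(seed=1)


@pytest.fixture
def small_samples(rng):
    """A small irregular sample set with positive values."""
    coords = rng.uniform(0, 500, size=(12, 2))
    values = np.exp(rng.normal(0, 1, 12))
    return SampleSet(tuple(f"s{i}" for i in range(12)), coords, values)


@pytest.fixture
def nugget_free_config():
    """Exponential-variogram site config without nugget (for exactness tests)."""
    return SyntheticSiteConfig(nugget=0.0, sill=1.0, range_=150.0)
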