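import numpy as np
import pytest

from ozmort import ModelSpec
from ozmort.synthetic import ExposureEffect, SyntheticConfig, simulate_city


@pytest.fixture(scope="session")
def null_city():
    """Four-year city with confounders but no ozone effect."""
    return simulate_city(SyntheticConfig(n_days=1461, seed=101), 0)


@pytest.fixture(scope="session")
def hockey_city():
    """Ten-year city with a known 25-ppb hockey-stick ozone effect."""
    cfg = SyntheticConfig(
        n_days=3650, seed=7,
        exposure=ExposureEffect.hockey(25.0, -0.002, 0.003),
    )
    return simulate_city(cfg, 0)


@pytest.fixture(scope="session")
def spec():
    return ModelSpec()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
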