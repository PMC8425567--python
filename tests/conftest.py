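import numpy as np
import pytest

from mahaforest import WorldConfig, generate_world


@pytest.fixture(scope="session")
def small_world():
    """2 countries x 2 survey rounds x 40 EAs, default noise/signal."""
    cfg = WorldConfig(
        n_countries=2,
        years_per_country=(2010, 2014),
        eas_per_survey=40,
        n_markets=2,
        n_commodities=2,
        seed=11,
    )
    return generate_world(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
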