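import numpy as np
import pytest

from edsurrogate import default_flow, grid_configs, simulate_campaign


@pytest.fixture(scope="session")
def campaign():
    """The default study campaign: 108 scenarios x 2 replicate days."""
    daily, patients = simulate_campaign(
        grid_configs(), days_per_config=2, flow=default_flow(), base_seed=1
    )
    return daily, patients


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
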