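import numpy as np
import pytest

from misdiagpower import ScenarioParams

# single test-wide seed so every stochastic check is reproducible
TEST_SEED = 1


@pytest.fixture
def rng():
    return np.random.default_rng(TEST_SEED)


@pytest.fixture
def moderate_scenario():
    """A mid-strength association: OR 3 at 25% control prevalence."""
    return ScenarioParams(theta0=0.25, delta_t=3.0, gamma=0.0, n0=250, n1=250)
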