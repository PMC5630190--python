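import numpy as np
import pytest

from methmr.simdata import SimulationConfig, simulate_scenario


@pytest.fixture(scope="session")
def mediation_study():
    """One medium-size mediation study shared across read-only tests."""
    return simulate_scenario(SimulationConfig(scenario="mediation", seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_iv_data():
    """50-sample single-instrument dataset for exact-identity checks."""
    r = np.random.default_rng(99)
    g = r.binomial(2, 0.4, 50).astype(float)
    covs = np.column_stack([r.normal(size=50), r.integers(0, 2, 50)])
    x = 0.8 * g + 0.1 * covs[:, 0] + r.normal(size=50)
    y = 0.5 * x + 0.05 * covs[:, 1] + r.normal(size=50)
    return g, x, y, covs
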