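import numpy as np
import pytest

from twostep_social import AgentParameters, PriorSpec, TaskConfig, simulate_agent


@pytest.fixture(scope="session")
def config() -> TaskConfig:
    return TaskConfig()


@pytest.fixture(scope="session")
def priors() -> PriorSpec:
    return PriorSpec()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20250922)


@pytest.fixture(scope="session")
def default_params() -> AgentParameters:
    # prior means of the default empirical priors
    return AgentParameters(alpha=0.5, beta=4.2416, lam=0.5, w=0.83, pi=0.15)


@pytest.fixture(scope="session")
def example_session(config, default_params):
    rng = np.random.default_rng(12345)
    return simulate_agent(default_params, config, rng, subject_id="s000")


class FixedNormalRng:
    """rng stub that returns preset 'Gaussian' increments (for walk tests)."""

    def __init__(self, values):
        self.values = np.asarray(values, dtype=float)

    def normal(self, loc, scale, size=None):
        assert size is None or size == len(self.values)
        return self.values.copy()


@pytest.fixture()
def fixed_increments():
    return FixedNormalRng
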