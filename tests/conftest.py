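import numpy as np
import pytest

from hfmsim import (
    AgeClassDistribution,
    GrowthParams,
    ScenarioConfig,
    default_shape_catalog,
)


@pytest.fixture(scope="session")
def growth():
    return GrowthParams()


@pytest.fixture(scope="session")
def catalog():
    return default_shape_catalog()


@pytest.fixture(scope="session")
def default_config():
    return ScenarioConfig()


@pytest.fixture(scope="session")
def default_bundle(default_config):
    """The full shipped experiment, run once per session."""
    from hfmsim import run_experiment

    return run_experiment(default_config)


@pytest.fixture
def uniform_state():
    return AgeClassDistribution.uniform()


def random_states(n, seed=0, total_area=10_000.0):
    """Random valid 24-class states with the given total area."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        raw = rng.dirichlet(np.ones(24) * rng.uniform(0.2, 5.0))
        out.append(AgeClassDistribution(raw * total_area, label="random"))
    return out
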