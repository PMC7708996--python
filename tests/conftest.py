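import numpy as np
import pytest

from moodsim import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_config():
    """A small, fast society for engine-level tests."""
    return SimulationConfig(n_agents=40, n_rounds=60, seed=7)


@pytest.fixture
def small_rational_config():
    """Rational-only society (deterministic traits, neutral moods)."""
    return SimulationConfig(
        n_agents=20,
        n_rounds=50,
        proportions={"rational": 1.0},
        seed=11,
    )
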