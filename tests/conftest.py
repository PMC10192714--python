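import numpy as np
import pytest

from nucleodyn import SceneConfig, SimConfig, make_nucleus, simulate_trace


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def short_sim():
    """A 10 s default-physics simulation shared across tests."""
    return simulate_trace(SimConfig(seed=42, duration_s=10.0))


@pytest.fixture()
def plain_scene():
    return make_nucleus(SceneConfig(), seed=7)


@pytest.fixture(scope="session")
def noisy_cfg():
    return SceneConfig(snr=5.0)
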