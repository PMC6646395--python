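import numpy as np
import pytest

from stngpe import NetworkConfig, ControllerConfig, SimulationConfig


@pytest.fixture(scope="session")
def tiny_net() -> NetworkConfig:
    """A 20+20 ring that integrates in a couple of seconds."""
    return NetworkConfig(N=20, seed=42)


@pytest.fixture(scope="session")
def tiny_cfg(tiny_net) -> SimulationConfig:
    return SimulationConfig(network=tiny_net,
                            controller=ControllerConfig(mode="cDBS", K=0.0),
                            duration_ms=1500.0, stim_onset_ms=500.0,
                            transient_skip_ms=300.0, ic_seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
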