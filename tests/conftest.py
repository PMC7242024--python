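import numpy as np
import pytest

import oscmem as om


@pytest.fixture(scope="session")
def tiny_config() -> om.SimulationConfig:
    """Small but structurally complete study configuration."""
    return om.SimulationConfig(n_subjects=2, n_trials=48, n_blocks=4,
                               n_channels=12, n_sources=27, seed=7)


@pytest.fixture(scope="session")
def tiny_subject(tiny_config):
    sim = om.Simulator(tiny_config)
    epochs, truth = sim.subject(0)
    return sim, epochs, truth


@pytest.fixture(scope="session")
def default_subject():
    """One subject at the full study size (288 trials, 32 channels); shared
    across the tests that need realistic planted-effect SNR."""
    cfg = om.SimulationConfig(n_subjects=1, seed=11)
    sim = om.Simulator(cfg)
    epochs, truth = sim.subject(0)
    return sim, epochs, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
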