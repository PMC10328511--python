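import numpy as np
import pytest

from mismatch2p import synth


@pytest.fixture(scope="session")
def lc_config():
    return synth.SessionConfig(frame_rate=60.0, duration=300.0)


@pytest.fixture(scope="session")
def lc_session(lc_config):
    """One axonal session with default gains, reused across read-only tests."""
    return synth.simulate_lc_session(lc_config, synth.LcAxonModel(), seed=11)


@pytest.fixture(scope="session")
def small_v1_experiment():
    """A small plasticity-arm experiment (2 mice x 2 sites x 9 neurons)."""
    cfg = synth.SessionConfig(frame_rate=15.0, duration=240.0)
    pop = synth.sample_v1_population(n_mice=2, n_sites_per_mouse=2,
                                     n_neurons_per_site=9, seed=5)
    return synth.simulate_v1_experiment(cfg, pop, "closed_loop_opto", "high",
                                        closed_duration=240.0, open_duration=360.0,
                                        seed=21)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
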