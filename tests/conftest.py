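import numpy as np
import pytest

from popsumstats import synth


@pytest.fixture(scope="session")
def small_config():
    return synth.SessionConfig(het_range=180.0, trials_per_direction=3, seed=0)


@pytest.fixture(scope="session")
def quiet_session(small_config):
    """Noiseless, drift-free tuned session: ground truth is exactly readable."""
    rng = np.random.default_rng(0)
    pop = synth.make_population(16, rng, coding_mode="sharpened_mean", width=2.0)
    calcium = synth.CalciumParams(noise_sd=0.0, drift_amplitude=0.0)
    return synth.generate_session(small_config, pop, calcium, seed=1)


@pytest.fixture(scope="session")
def noisy_session():
    """Default-SNR session used for the stochastic recovery checks."""
    cfg = synth.SessionConfig(het_range=180.0, trials_per_direction=5, seed=2)
    rng = np.random.default_rng(2)
    pop = synth.make_population(24, rng, coding_mode="sharpened_mean")
    calcium = synth.CalciumParams(noise_sd=0.3, drift_amplitude=0.05)
    return synth.generate_session(cfg, pop, calcium, seed=3)
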