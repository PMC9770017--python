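import numpy as np
import pytest

from quadgait.io_core import SessionConfig
from quadgait.synthetic import generate_session


@pytest.fixture(scope="session")
def small_clean_session():
    """Zero-noise 1-animal session with a few stimuli of each phase."""
    cfg = SessionConfig(n_animals=1, cycles_per_animal=60, stimuli_per_phase=2,
                        seed=11)
    return generate_session(cfg, noise=False, with_emg=False)


@pytest.fixture(scope="session")
def small_noisy_session():
    """Default-noise 2-animal session without EMG."""
    cfg = SessionConfig(n_animals=2, cycles_per_animal=60, stimuli_per_phase=2,
                        seed=12)
    return generate_session(cfg, noise=True, with_emg=False)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
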