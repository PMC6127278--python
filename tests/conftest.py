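import numpy as np
import pytest

from mrcpipe import SimulationConfig, estimate_all_io, generate_session


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    """Desk-scale paradigm: 6 trials/condition, short rest runs."""
    return SimulationConfig(trials_per_condition=6, rest_run_duration=10.0,
                            invalid_report_rate=0.1)


@pytest.fixture(scope="session")
def session(small_cfg):
    """One simulated session with validity flags and estimated IOs."""
    rec, trials = generate_session(small_cfg, subject_seed=1)
    estimate_all_io(trials)
    return rec, trials


@pytest.fixture(scope="session")
def clean_cfg() -> SimulationConfig:
    """Noise-free, blink-free paradigm for exact template checks."""
    return SimulationConfig(trials_per_condition=5, rest_run_duration=5.0,
                            noise_scale=0.0, blink_rate=0.0,
                            invalid_report_rate=0.0)


@pytest.fixture(scope="session")
def clean_session(clean_cfg):
    rec, trials = generate_session(clean_cfg, subject_seed=2)
    estimate_all_io(trials)
    return rec, trials


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
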