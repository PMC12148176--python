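import numpy as np
import pytest

from ocutremor import (
    ParticipantProfile,
    SimulationConfig,
    fixational_velocity,
    simulate_recording,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def tone(freq_hz: float, duration_s: float = 4.0, amp: float = 1.0, fs: float = 1000.0):
    t = np.arange(int(duration_s * fs)) / fs
    return amp * np.sin(2 * np.pi * freq_hz * t)


@pytest.fixture(scope="session")
def tremor_profile():
    return ParticipantProfile("P000", tremor_freq=150.0)


@pytest.fixture(scope="session")
def tremor_recording(tremor_profile):
    """60 s of default-condition gaze with a 150 Hz circular microtremor."""
    cfg = SimulationConfig(duration=60.0, seed=1)
    return simulate_recording(tremor_profile, cfg)


@pytest.fixture(scope="session")
def tremor_fix_velocity(tremor_recording):
    return fixational_velocity(tremor_recording)


@pytest.fixture
def pure_tremor_recording(tremor_profile):
    """Noise-free, drift-free, fully coherent circular tremor."""
    cfg = SimulationConfig(
        duration=5.0,
        seed=3,
        noise_sd=0.0,
        tremor_phase_jitter=0.0,
        microsaccade_rate=0.0,
    )
    profile = ParticipantProfile(
        "P000", tremor_freq=150.0, tremor_amp=0.01, drift_diffusion=0.0
    )
    return simulate_recording(profile, cfg)
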