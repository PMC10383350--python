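import numpy as np
import pytest

from radarbp.core import RadarConfig
from radarbp.sim import PulseWaveformModel


@pytest.fixture
def small_config() -> RadarConfig:
    """Short record (2 s) for fast unit tests."""
    return RadarConfig(n_frames=4000)


@pytest.fixture
def table1_config() -> RadarConfig:
    """Full 10 s record with the default chirp/frame parameters."""
    return RadarConfig()


@pytest.fixture
def chest_model() -> PulseWaveformModel:
    return PulseWaveformModel(
        heart_rate_hz=1.2,
        pulse_amplitude_mm=0.3,
        pulse_width_s=0.15,
        respiration_amplitude_mm=0.0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
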