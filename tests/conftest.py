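import numpy as np
import pytest

from flightcall.audio import TARGET_SAMPLE_RATE, Waveform
from flightcall.frontend import StftConfig, TimeFreqMatrix, melspectrogram
from flightcall.synth import NightSpec, synthesize_night

SR = TARGET_SAMPLE_RATE


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture(scope="session")
def noise_second(rng):
    """One second of low-level white noise at the nominal sample rate."""
    return Waveform(0.01 * rng.standard_normal(SR), SR, sensor_id="unitA")


@pytest.fixture(scope="session")
def sine_5k():
    t = np.arange(SR) / SR
    return Waveform(0.1 * np.sin(2 * np.pi * 5000.0 * t), SR)


@pytest.fixture(scope="session")
def mel_noise(noise_second):
    return melspectrogram(noise_second)


def make_tfm(values, frame_rate=689.0625):
    """Wrap a raw matrix as a melspec TimeFreqMatrix with synthetic centers."""
    n_bands = values.shape[1]
    centers = np.linspace(2000.0, 11000.0, n_bands)
    return TimeFreqMatrix(values=np.asarray(values, dtype=np.float64),
                          frame_rate=frame_rate, band_centers=centers,
                          representation="melspec")


@pytest.fixture(scope="session")
def quiet_night():
    """A short background-only synthetic night (no events)."""
    spec = NightSpec(duration=20.0, n_sensors=1, seed=7,
                     rate_start=0.0, rate_end=0.0)
    return synthesize_night(spec, "bg00")


@pytest.fixture(scope="session")
def busy_night():
    """A short synthetic night with a realistic event density."""
    spec = NightSpec(duration=30.0, n_sensors=1, seed=11,
                     rate_start=10.0, rate_end=30.0)
    return synthesize_night(spec, "ev00")
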