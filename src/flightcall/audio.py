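"""Waveform container and WAV file I/O.

Audio is held internally as unit-range float64/float32 samples. The detector
pipeline assumes a nominal sample rate of 22,050 Hz; :func:`load_wav`
resamples on read when needed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

#: Nominal sample rate of the detection pipeline, in Hz.
TARGET_SAMPLE_RATE = 22_050

#: Full-scale factor applied before the STFT, so that spectrogram magnitudes
#: live on the scale of int32-decoded audio (range [-2^31, 2^31)).
FULL_SCALE = float(2**31)


@dataclass
class Waveform:
    """A mono audio signal with provenance metadata.

    Parameters
    ----------
    samples : ndarray
        1-D float array, unit range (full scale is ±1).
    sample_rate : float
        Sampling rate in Hz, > 0.
    sensor_id : str
        Identifier of the recording unit.
    split : str
        One of ``train``, ``validation``, ``test`` (or ``""`` if unassigned).
    """

    samples: np.ndarray
    sample_rate: float
    sensor_id: str = ""
    split: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return self.samples.size / self.sample_rate

    def resampled(self, sample_rate: float) -> "Waveform":
        """Return a copy resampled to `sample_rate` (polyphase)."""
        if sample_rate == self.sample_rate:
            return replace(self)
        from fractions import Fraction

        frac = Fraction(sample_rate / self.sample_rate).limit_denominator(1000)
        out = resample_poly(self.samples, frac.numerator, frac.denominator)
        return replace(self, samples=out, sample_rate=sample_rate)


def load_wav(path, sensor_id: str = "", split: str = "",
             target_sr: float | None = TARGET_SAMPLE_RATE) -> Waveform:
    """Read a WAV file into a unit-range mono :class:`Waveform`.

    Stereo input is averaged to mono with a warning. Integer PCM is scaled
    to [-1, 1); the pipeline's nominal sample rate is restored by polyphase
    resampling unless ``target_sr`` is None.
    """
    sr, data = wavfile.read(path)
    if data.ndim == 2:
        warnings.warn("stereo input averaged to mono", stacklevel=2)
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / float(np.iinfo(data.dtype).max + 1)
    else:
        data = data.astype(np.float64)
    w = Waveform(samples=data, sample_rate=float(sr),
                 sensor_id=sensor_id, split=split)
    if target_sr is not None and sr != target_sr:
        w = w.resampled(target_sr)
    return w


def save_wav(path, w: Waveform) -> None:
    """Write a :class:`Waveform` as 16-bit PCM WAV."""
    clipped = np.clip(w.samples, -1.0, 1.0 - 2.0**-15)
    wavfile.write(path, int(w.sample_rate),
                  (clipped * 2**15).astype(np.int16))
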