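"""Training-clip augmentation: geometrical and adaptive audio effects.

Geometrical data augmentation (GDA) perturbs the clip independently of the
rest of the dataset: small pitch shifts (phase-vocoder resampling) and time
stretches. Adaptive data augmentation (ADA) mixes the clip with background
noise drawn from other sensors of the same split. Effects are never applied
in combination; a full plan is 20 variants per clip (4 pitch shifts, 4 time
stretches, 4 noise additions from each of 3 training sensors).

ADA cannot be combined with context adaptation: adding noise to a 150 ms
clip would require recomputing its 30-minute auxiliary statistics for the
mixture, which is intractable at that time scale. Plans therefore refuse
ADA for context-adaptive model configurations.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from fractions import Fraction

import numpy as np
from scipy.signal import istft, resample_poly, stft

from .audio import Waveform

GDA_VARIANTS_PER_KIND = 4
ADA_SOURCES = 3            # noise drawn from each of the training sensors


@dataclass
class AugmentationSpec:
    """One randomized audio effect applied to one clip."""

    kind: str                                  # pitch_shift|time_stretch|add_noise
    clip_index: int
    semitones: float | None = None             # pitch_shift
    rate: float | None = None                  # time_stretch
    noise_sensor: str | None = None            # add_noise
    noise_time: float | None = None            # s, start of noise excerpt
    snr_db: float | None = None

    def to_dict(self):
        return {k: v for k, v in asdict(self).items() if v is not None}


def _phase_vocoder(x: np.ndarray, rate: float, sr: float,
                   n_fft: int = 1024, hop: int = 256) -> np.ndarray:
    """Time-stretch by ``rate`` (rate 2 -> half duration), preserving pitch."""
    if rate == 1.0:
        return x.copy()
    pad = n_fft
    xp = np.pad(x, pad)
    _, _, Z = stft(xp, fs=sr, nperseg=n_fft, noverlap=n_fft - hop,
                   boundary=None, padded=False)
    n_bins, n_frames = Z.shape
    steps = np.arange(0.0, n_frames - 1, rate)
    omega = 2 * np.pi * hop * np.arange(n_bins) / n_fft
    out = np.empty((n_bins, len(steps)), dtype=complex)
    phase = np.angle(Z[:, 0])
    for k, s in enumerate(steps):
        i = int(s)
        frac = s - i
        mag = (1 - frac) * np.abs(Z[:, i]) + frac * np.abs(Z[:, i + 1])
        out[:, k] = mag * np.exp(1j * phase)
        dphi = np.angle(Z[:, i + 1]) - np.angle(Z[:, i]) - omega
        dphi -= 2 * np.pi * np.round(dphi / (2 * np.pi))
        phase = phase + omega + dphi
    with warnings.catch_warnings():
        # the analysis grid is self-padded, so scipy's NOLA edge warning
        # does not apply
        warnings.simplefilter("ignore", UserWarning)
        _, y = istft(out, fs=sr, nperseg=n_fft, noverlap=n_fft - hop,
                     boundary=False)
    start = int(round(pad / rate))
    length = int(round(len(x) / rate))
    y = y[start:start + length]
    if len(y) < length:
        y = np.pad(y, (0, length - len(y)))
    return y


def _fit_length(x: np.ndarray, n: int) -> np.ndarray:
    """Center-crop or symmetrically zero-pad to n samples."""
    if len(x) > n:
        lo = (len(x) - n) // 2
        return x[lo:lo + n]
    pad = n - len(x)
    return np.pad(x, (pad // 2, pad - pad // 2))


def pitch_shift(clip: Waveform, semitones: float) -> Waveform:
    """Shift pitch by a (fractional) number of semitones, keeping duration."""
    if semitones == 0.0:
        return Waveform(clip.samples.copy(), clip.sample_rate,
                        clip.sensor_id, clip.split)
    factor = 2.0 ** (semitones / 12.0)
    frac = Fraction(1.0 / factor).limit_denominator(200)
    fast = resample_poly(clip.samples, frac.numerator, frac.denominator)
    out = _phase_vocoder(fast, 1.0 / factor, clip.sample_rate)
    return Waveform(_fit_length(out, len(clip.samples)), clip.sample_rate,
                    clip.sensor_id, clip.split)


def time_stretch(clip: Waveform, rate: float,
                 keep_duration: bool = True) -> Waveform:
    """Stretch duration by 1/rate at constant pitch; re-fit to 150 ms."""
    if rate <= 0:
        raise ValueError("rate must be positive")
    out = _phase_vocoder(clip.samples, rate, clip.sample_rate)
    if keep_duration:
        out = _fit_length(out, len(clip.samples))
    return Waveform(out, clip.sample_rate, clip.sensor_id, clip.split)


def add_noise(clip: Waveform, noise: Waveform, snr_db: float) -> Waveform:
    """Mix a background excerpt into the clip at a given SNR (dB).

    Clip and noise must belong to the same split (no leakage between
    training and validation augmentations); +inf dB returns the clip
    unchanged.
    """
    if clip.split and noise.split and clip.split != noise.split:
        raise ValueError("augmentation leaks across splits")
    if np.isinf(snr_db) and snr_db > 0:
        return Waveform(clip.samples.copy(), clip.sample_rate,
                        clip.sensor_id, clip.split)
    x = clip.samples
    v = _fit_length(noise.samples, len(x))
    p_clip = np.mean(x**2)
    p_noise = np.mean(v**2)
    if p_noise == 0:
        raise ValueError("noise excerpt is silent")
    gain = np.sqrt(p_clip / p_noise * 10.0 ** (-snr_db / 10.0))
    return Waveform(x + gain * v, clip.sample_rate, clip.sensor_id, clip.split)


def augment(clip: Waveform, spec: AugmentationSpec,
            noise: Waveform | None = None) -> Waveform:
    """Apply the single effect described by an :class:`AugmentationSpec`."""
    if spec.kind == "pitch_shift":
        return pitch_shift(clip, spec.semitones)
    if spec.kind == "time_stretch":
        return time_stretch(clip, spec.rate)
    if spec.kind == "add_noise":
        if noise is None:
            raise ValueError("add_noise requires a noise excerpt")
        return add_noise(clip, noise, spec.snr_db)
    raise ValueError(f"unknown augmentation kind {spec.kind!r}")


def make_augmentation_plan(manifest, mode: str, seed: int = 0,
                           context_adaptive: bool = False,
                           noise_sensors: list | None = None,
                           pitch_range: float = 1.0,
                           stretch_range: tuple[float, float] = (0.9, 1.1),
                           snr_range: tuple[float, float] = (-6.0, 6.0)) -> list:
    """Randomized effect plan: GDA (8/clip) or GDA+ADA (20/clip).

    ``manifest`` is a frame with columns (sensor_id, split, time_s, label).
    Pitch shifts are uniform in +/- ``pitch_range`` semitones, stretch rates
    log-uniform in ``stretch_range``, noise SNR uniform in ``snr_range`` dB;
    noise excerpts are drawn from the background of same-split sensors.
    Deterministic under a fixed seed.
    """
    if mode not in ("GDA", "GDA+ADA"):
        raise ValueError("mode must be 'GDA' or 'GDA+ADA'")
    if mode == "GDA+ADA" and context_adaptive:
        raise ValueError("adaptive data augmentation cannot be combined with "
                         "a context-adaptive model")
    rng = np.random.default_rng(seed)
    plan: list[AugmentationSpec] = []
    for i, row in manifest.reset_index(drop=True).iterrows():
        for _ in range(GDA_VARIANTS_PER_KIND):
            plan.append(AugmentationSpec(
                kind="pitch_shift", clip_index=i,
                semitones=float(rng.uniform(-pitch_range, pitch_range))))
        for _ in range(GDA_VARIANTS_PER_KIND):
            rate = float(np.exp(rng.uniform(np.log(stretch_range[0]),
                                            np.log(stretch_range[1]))))
            plan.append(AugmentationSpec(kind="time_stretch", clip_index=i,
                                         rate=rate))
        if mode == "GDA+ADA":
            sensors = noise_sensors
            if sensors is None:
                sensors = sorted(set(manifest["sensor_id"]))
            same_split = [s for s in sensors]
            for sensor in same_split[:ADA_SOURCES]:
                for _ in range(GDA_VARIANTS_PER_KIND):
                    plan.append(AugmentationSpec(
                        kind="add_noise", clip_index=i, noise_sensor=sensor,
                        noise_time=float(rng.uniform(0.0, 1.0)),
                        snr_db=float(rng.uniform(*snr_range))))
    return plan


def save_plan(plan: list, path) -> None:
    with open(path, "w") as fh:
        json.dump([s.to_dict() for s in plan], fh, indent=1)
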