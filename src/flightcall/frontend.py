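"""Time-frequency frontend: mel spectrogram, log compression, and PCEN.

The central representation is the matrix E(t, f) of mel-frequency magnitudes
(squared-modulus STFT mapped through a mel filterbank). Two loudness mappings
are provided:

* ``logmelspec`` — static dynamic-range compression, log(eps + E);
* ``pcen`` — per-channel energy normalization, which divides each subband by
  a low-passed version of itself raised to the power alpha (adaptive gain
  control) before root compression:

      PCEN(t, f) = (E(t, f) / (eps + M(t, f))**alpha + delta)**r - delta**r

  where M = E * phi_T is a causal first-order IIR smoothing of E with
  support T. AGC makes the representation approximately invariant to slow
  multiplicative loudness changes (insect beds, passing vehicles), which is
  what distinguishes it from the purely pointwise logmelspec mapping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import get_window, lfilter
from scipy.stats import kurtosis, skew

from .audio import FULL_SCALE, TARGET_SAMPLE_RATE, Waveform

#: Floor inside the logarithm for logmelspec.
LOG_EPS = 1e-10


@dataclass
class StftConfig:
    """STFT / mel-filterbank settings for the detection frontend.

    Defaults: 256-sample Hann window (12 ms at 22,050 Hz), hop 32 (1.5 ms),
    1024-point FFT, 128 mel bands spanning 2,000-11,025 Hz. No padding: only
    frames fully inside the signal are emitted, and frame times refer to
    window centers.
    """

    window_size: int = 256
    hop_size: int = 32
    n_fft: int = 1024
    n_mels: int = 128
    fmin: float = 2000.0
    fmax: float = 11025.0
    sample_rate: float = TARGET_SAMPLE_RATE

    @property
    def frame_rate(self) -> float:
        return self.sample_rate / self.hop_size


@dataclass
class TimeFreqMatrix:
    """E(t, f): nonnegative (frames x bands) matrix with axis metadata."""

    values: np.ndarray                 # (n_frames, n_bands)
    frame_rate: float
    band_centers: np.ndarray           # Hz, strictly increasing
    representation: str                # melspec | logmelspec | pcen
    start_time: float = 0.0            # center time of first frame, s

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.band_centers = np.asarray(self.band_centers, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (frames x bands)")
        if self.representation not in ("melspec", "logmelspec", "pcen"):
            raise ValueError(f"unknown representation {self.representation!r}")
        if np.any(np.diff(self.band_centers) <= 0):
            raise ValueError("band_centers must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def frame_times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_frames) / self.frame_rate

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate


@dataclass
class PcenParams:
    """PCEN constants (eps, alpha, delta, r) and smoother support T.

    Two published presets are provided: ``indoor`` (far-field speech:
    alpha=0.98, delta=2, r=1/2, T=400 ms) and ``outdoor`` (bioacoustic event
    detection: alpha=0.8, delta=10, r=1/4, T=60 ms). The outdoor setting
    uses a lower alpha and r and a higher delta to cope with louder, more
    skewed backgrounds and faster foreground modulations.
    """

    eps: float = 1e-6
    alpha: float = 0.8
    delta: float = 10.0
    r: float = 0.25
    T: float = 0.060                 # smoother support, seconds
    preset_name: str = "custom"

    def __post_init__(self) -> None:
        if self.eps <= 0 or self.delta <= 0 or self.T <= 0:
            raise ValueError("eps, delta and T must be positive")
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must lie in (0, 1]")
        if not (0 < self.r <= 1):
            raise ValueError("r must lie in (0, 1]")

    @classmethod
    def indoor(cls) -> "PcenParams":
        return cls(eps=1e-6, alpha=0.98, delta=2.0, r=0.5, T=0.400,
                   preset_name="indoor")

    @classmethod
    def outdoor(cls) -> "PcenParams":
        return cls(eps=1e-6, alpha=0.8, delta=10.0, r=0.25, T=0.060,
                   preset_name="outdoor")

    @classmethod
    def from_preset(cls, name: str) -> "PcenParams":
        try:
            return {"indoor": cls.indoor, "outdoor": cls.outdoor}[name]()
        except KeyError:
            raise ValueError(f"unknown PCEN preset {name!r}") from None


# ---------------------------------------------------------------------------
# Mel filterbank (Slaney-style, area-normalized)

_F_SP = 200.0 / 3                 # linear region slope, Hz per mel
_MIN_LOG_HZ = 1000.0
_MIN_LOG_MEL = _MIN_LOG_HZ / _F_SP
_LOGSTEP = np.log(6.4) / 27.0


def hz_to_mel(f):
    f = np.asarray(f, dtype=np.float64)
    mel = f / _F_SP
    log_region = f >= _MIN_LOG_HZ
    mel = np.where(log_region,
                   _MIN_LOG_MEL + np.log(np.maximum(f, _MIN_LOG_HZ)
                                         / _MIN_LOG_HZ) / _LOGSTEP,
                   mel)
    return mel


def mel_to_hz(m):
    m = np.asarray(m, dtype=np.float64)
    f = m * _F_SP
    log_region = m >= _MIN_LOG_MEL
    f = np.where(log_region,
                 _MIN_LOG_HZ * np.exp(_LOGSTEP * (m - _MIN_LOG_MEL)),
                 f)
    return f


def mel_filterbank(cfg: StftConfig) -> tuple[np.ndarray, np.ndarray]:
    """Triangular Slaney-style filterbank.

    Returns ``(weights, centers)`` where ``weights`` has shape
    (n_mels, n_fft//2 + 1) and rows are normalized to unit triangle area
    (2 / bandwidth), and ``centers`` are the band center frequencies in Hz.
    """
    n_bins = cfg.n_fft // 2 + 1
    fft_freqs = np.linspace(0, cfg.sample_rate / 2, n_bins)
    mel_pts = np.linspace(hz_to_mel(cfg.fmin), hz_to_mel(cfg.fmax),
                          cfg.n_mels + 2)
    hz_pts = mel_to_hz(mel_pts)
    weights = np.zeros((cfg.n_mels, n_bins))
    for i in range(cfg.n_mels):
        lo, ctr, hi = hz_pts[i], hz_pts[i + 1], hz_pts[i + 2]
        up = (fft_freqs - lo) / (ctr - lo)
        down = (hi - fft_freqs) / (hi - ctr)
        tri = np.maximum(0.0, np.minimum(up, down))
        weights[i] = tri * (2.0 / (hi - lo))     # area normalization
    return weights, hz_pts[1:-1]


# ---------------------------------------------------------------------------
# Operations

def melspectrogram(w: Waveform, cfg: StftConfig | None = None) -> TimeFreqMatrix:
    """Mel-frequency power spectrogram of a waveform.

    The unit-range samples are scaled to the int32 full-scale convention
    before the STFT so that the published PCEN constants (eps, delta) apply
    unchanged. No padding: frame count = floor((N - window) / hop) + 1.
    """
    cfg = cfg or StftConfig()
    if w.sample_rate != cfg.sample_rate:
        w = w.resampled(cfg.sample_rate)
    x = w.samples * FULL_SCALE
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite samples")
    if x.size < cfg.window_size:
        raise ValueError("input too short")
    frames = sliding_window_view(x, cfg.window_size)[::cfg.hop_size]
    win = get_window("hann", cfg.window_size, fftbins=True)
    # single precision: melspec values feed float32 models and dB medians,
    # where 1e-7 relative error is immaterial; halves frontend time
    windowed = (frames * win).astype(np.float32)
    spec = np.abs(np.fft.rfft(windowed, n=cfg.n_fft, axis=1)) ** 2
    fb, centers = mel_filterbank(cfg)
    mel = spec @ fb.T.astype(np.float32)
    start = (cfg.window_size / 2) / cfg.sample_rate
    return TimeFreqMatrix(values=mel, frame_rate=cfg.frame_rate,
                          band_centers=centers, representation="melspec",
                          start_time=start)


def logmelspec(m: TimeFreqMatrix, eps: float = LOG_EPS) -> TimeFreqMatrix:
    """Elementwise log(eps + E); static dynamic-range compression."""
    if m.representation != "melspec":
        raise ValueError("logmelspec expects a melspec input")
    if np.any(m.values < 0):
        raise ValueError("negative input values")
    return TimeFreqMatrix(values=np.log(eps + m.values),
                          frame_rate=m.frame_rate,
                          band_centers=m.band_centers,
                          representation="logmelspec",
                          start_time=m.start_time)


def _smoother_coeff(T_frames: float) -> float:
    """IIR coefficient s for a first-order smoother of support T (frames)."""
    return (np.sqrt(1.0 + 4.0 * T_frames**2) - 1.0) / (2.0 * T_frames**2)


def pcen(m: TimeFreqMatrix, params: PcenParams | None = None) -> TimeFreqMatrix:
    """Per-channel energy normalization of a mel spectrogram.

    The per-band smoother is the causal first-order IIR
    M(t) = (1 - s) M(t-1) + s E(t), initialized at M(0) = E(0) to suppress
    the onset transient; s is chosen so the filter's support matches
    ``params.T`` expressed in frames.
    """
    params = params or PcenParams.outdoor()
    if m.representation != "melspec":
        raise ValueError("pcen expects a melspec input")
    E = np.asarray(m.values, dtype=np.float64)
    s = _smoother_coeff(params.T * m.frame_rate)
    # lfilter with state chosen so that M[0] = E[0] per band
    zi = (1.0 - s) * E[0:1, :]
    M, _ = lfilter([s], [1.0, -(1.0 - s)], E, axis=0, zi=zi)
    out = (E / (params.eps + M) ** params.alpha + params.delta) ** params.r \
        - params.delta ** params.r
    return TimeFreqMatrix(values=out, frame_rate=m.frame_rate,
                          band_centers=m.band_centers,
                          representation="pcen",
                          start_time=m.start_time)


def apply_frontend(w: Waveform, representation: str,
                   cfg: StftConfig | None = None,
                   pcen_params: PcenParams | None = None) -> TimeFreqMatrix:
    """Waveform -> logmelspec or pcen matrix, in one call."""
    mel = melspectrogram(w, cfg)
    if representation == "logmelspec":
        return logmelspec(mel)
    if representation == "pcen":
        return pcen(mel, pcen_params)
    if representation == "melspec":
        return mel
    raise ValueError(f"unknown representation {representation!r}")


def magnitude_distribution(m: TimeFreqMatrix, n_bins: int = 100,
                           hist_range: tuple[float, float] = (-5.0, 5.0)):
    """Moments and histogram of globally standardized magnitudes.

    Standardizes all time-frequency values to zero mean and unit variance,
    then returns ``{"skewness", "kurtosis", "bin_edges", "histogram"}``.
    Used to diagnose how close a loudness mapping brings the background
    distribution to a Gaussian (PCEN Gaussianizes; logmelspec does not).
    """
    v = np.asarray(m.values, dtype=np.float64).ravel()
    if v.size == 0:
        raise ValueError("empty matrix")
    sd = v.std()
    if sd == 0:
        raise ValueError("degenerate distribution")
    z = (v - v.mean()) / sd
    hist, edges = np.histogram(z, bins=n_bins, range=hist_range, density=True)
    return {"skewness": float(skew(z)),
            "kurtosis": float(kurtosis(z)),
            "bin_edges": edges,
            "histogram": hist}
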