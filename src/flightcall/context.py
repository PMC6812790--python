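"""Long-term context features: quantile summary statistics and SPL trends.

The auxiliary features mu(t, q, f) summarize the background of a recording
with nine order statistics (permille, percentile, decile, quartile, median
and their upper counterparts) of the time-frequency magnitudes over trailing
windows of T_CA = 30 minutes, on a reduced 32-band frequency axis. They vary
slowly (default one frame every 450 s) and are, by construction, nearly
invariant to the presence of any single 150 ms transient in the window,
which is what makes them usable as a noise descriptor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .frontend import TimeFreqMatrix

#: The nine percentile levels: permille/percentile/decile/quartile pairs
#: around the median.
QUANTILE_LEVELS = np.array([0.1, 1.0, 10.0, 25.0, 50.0, 75.0, 90.0, 99.0, 99.9])

#: Number of reduced frequency bands in the auxiliary features.
N_CONTEXT_BANDS = 32


@dataclass
class ContextTensor:
    """mu(t, q, f): (context frames x 9 quantiles x 32 bands)."""

    values: np.ndarray
    frame_times: np.ndarray          # s, center of each context frame
    band_centers: np.ndarray         # Hz, 32 values
    quantile_levels: np.ndarray = None
    window_span: float = 1800.0
    frame_period: float = 450.0

    def __post_init__(self) -> None:
        if self.quantile_levels is None:
            self.quantile_levels = QUANTILE_LEVELS.copy()
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3 or self.values.shape[1] != len(self.quantile_levels):
            raise ValueError("values must be (frames x quantiles x bands)")
        if self.frame_period <= 0:
            raise ValueError("frame_period must be positive")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    def slice_at(self, t: float) -> np.ndarray:
        """Most recent context slice (9 x 32) at or before time t."""
        idx = int(np.searchsorted(self.frame_times, t, side="right")) - 1
        return self.values[max(idx, 0)]


def reduce_bands(values: np.ndarray, factor: int = 4) -> np.ndarray:
    """Average-pool adjacent bands (128 -> 32 with the default factor)."""
    n = values.shape[1] - values.shape[1] % factor
    return values[:, :n].reshape(values.shape[0], n // factor, factor).mean(axis=2)


def summary_statistics(m: TimeFreqMatrix, window_span: float = 1800.0,
                       frame_period: float = 450.0) -> ContextTensor:
    """Long-term quantile statistics of E(t, f) over trailing windows.

    Per context frame (every ``frame_period`` seconds) and per reduced band,
    computes the nine order statistics of all time-frequency magnitudes in
    the trailing ``window_span`` seconds (linear-interpolation quantiles).
    Windows are causal so the features are computable in streaming mode; the
    first frames use whatever audio is available, and a window longer than
    the recording is truncated with a warning.
    """
    if frame_period <= 0:
        raise ValueError("frame_period must be positive")
    if m.n_frames < 1:
        raise ValueError("empty time-frequency matrix")
    if window_span > m.duration:
        warnings.warn("window span exceeds recording; truncating to "
                      "available data", stacklevel=2)
    reduced = reduce_bands(np.asarray(m.values, dtype=np.float64))
    centers = reduce_bands(m.band_centers[None, :]).ravel()
    duration = m.duration
    n_ctx = max(int(duration // frame_period), 1)
    times = (np.arange(n_ctx) + 1) * frame_period
    times = np.minimum(times, duration)
    out = np.empty((n_ctx, len(QUANTILE_LEVELS), reduced.shape[1]))
    rel = m.frame_times - m.start_time
    for i, t in enumerate(times):
        lo = np.searchsorted(rel, max(t - window_span, 0.0), side="left")
        hi = np.searchsorted(rel, t, side="right")
        chunk = reduced[lo:max(hi, lo + 1)]
        out[i] = np.percentile(chunk, QUANTILE_LEVELS, axis=0)
    return ContextTensor(values=out, frame_times=times, band_centers=centers,
                         window_span=float(window_span),
                         frame_period=float(frame_period))


def band_spl_trend(m: TimeFreqMatrix, band_lo: float, band_hi: float,
                   segment: float = 1800.0) -> tuple[np.ndarray, np.ndarray]:
    """Median in-band SPL (dB re full scale) per temporal segment.

    Selects the mel bands whose centers fall in [band_lo, band_hi], sums
    their energies per frame, and reports 10*log10 of the per-segment median
    of that in-band energy. Returns ``(segment_centers_s, spl_db)``.

    The full-scale reference is the squared int32 full-scale amplitude, so a
    full-scale sine would sit near 0 dB before window/filterbank gains.
    """
    if m.representation != "melspec":
        raise ValueError("band_spl_trend expects a melspec input")
    if band_lo >= band_hi:
        raise ValueError("band_lo must be below band_hi")
    sel = (m.band_centers >= band_lo) & (m.band_centers <= band_hi)
    if not np.any(sel):
        raise ValueError("empty band selection")
    from .audio import FULL_SCALE

    energy = np.asarray(m.values, dtype=np.float64)[:, sel].sum(axis=1)
    duration = m.duration
    n_seg = max(int(duration // segment), 1)
    rel = m.frame_times - m.start_time
    centers = np.empty(n_seg)
    spl = np.empty(n_seg)
    for i in range(n_seg):
        t0, t1 = i * segment, (i + 1) * segment
        lo = np.searchsorted(rel, t0, side="left")
        hi = np.searchsorted(rel, t1, side="right")
        med = np.median(energy[lo:max(hi, lo + 1)])
        centers[i] = (t0 + min(t1, duration)) / 2
        spl[i] = 10.0 * np.log10(max(med, 1e-300) / FULL_SCALE**2)
    return centers, spl


def fitted_decay_db(segment_centers: np.ndarray, spl_db: np.ndarray,
                    duration: float) -> float:
    """Total SPL change over ``duration`` from a least-squares linear trend.

    Segment medians sample the ramp at segment centers, so the first-to-last
    difference underestimates a programmed full-duration decay; fitting a
    slope and extrapolating over the full duration recovers it.
    """
    slope = np.polyfit(segment_centers, spl_db, 1)[0]
    return float(slope * duration)
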