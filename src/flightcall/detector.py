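"""Sliding-window detection in continuous audio.

A trained clip classifier is slid over the recording with a 150 ms window
and a 50 ms hop, producing an event detection function (EDF) y(t) sampled at
20 frames per second; thresholding and peak picking turn the EDF into a list
of predicted event timestamps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .audio import Waveform
from .canet import CLIP_FRAMES, ContextAdaptiveDetector
from .context import ContextTensor, summary_statistics
from .frontend import TimeFreqMatrix, apply_frontend

#: Sliding-window geometry: 150 ms window, 50 ms hop -> 20 frames/s.
WINDOW_S = 0.150
HOP_S = 0.050


@dataclass
class EventDetectionFunction:
    """y(t) in (0,1) at 20 frames/s; times refer to window centers."""

    values: np.ndarray
    start_time: float = WINDOW_S / 2
    frame_hop: float = HOP_S

    @property
    def frame_times(self) -> np.ndarray:
        return self.start_time + np.arange(len(self.values)) * self.frame_hop


@dataclass
class EventList:
    """Detected or reference events: center timestamps, scores, band labels."""

    timestamps: np.ndarray
    scores: np.ndarray | None = None
    band_labels: list | None = None        # "low" (<5 kHz) or "high"

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=np.float64)
        if np.any(np.diff(self.timestamps) < 0):
            raise ValueError("timestamps must be sorted")
        if self.scores is not None:
            self.scores = np.asarray(self.scores, dtype=np.float64)

    def __len__(self):
        return len(self.timestamps)

    def to_frame(self) -> pd.DataFrame:
        d = {"time_s": self.timestamps}
        if self.scores is not None:
            d["score"] = self.scores
        if self.band_labels is not None:
            d["band_label"] = self.band_labels
        return pd.DataFrame(d)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "EventList":
        df = pd.read_csv(path)
        order = np.argsort(df["time_s"].to_numpy(), kind="stable")
        df = df.iloc[order]
        return cls(timestamps=df["time_s"].to_numpy(),
                   scores=df["score"].to_numpy() if "score" in df else None,
                   band_labels=list(df["band_label"]) if "band_label" in df else None)


def extract_clip_frames(tfm: TimeFreqMatrix, center_times,
                        n_frames: int = CLIP_FRAMES) -> np.ndarray:
    """Slice fixed-length clips (n_frames x bands) around center times.

    Frames beyond either edge of the matrix are zero-padded, keeping the
    event center aligned with the clip center.
    """
    centers = np.atleast_1d(np.asarray(center_times, dtype=np.float64))
    vals = tfm.values
    half = n_frames // 2
    out = np.zeros((len(centers), n_frames, vals.shape[1]), dtype=vals.dtype)
    idx = np.round((centers - tfm.start_time) * tfm.frame_rate).astype(int)
    for i, c in enumerate(idx):
        lo, hi = c - half, c - half + n_frames
        src_lo, src_hi = max(lo, 0), min(hi, vals.shape[0])
        if src_hi > src_lo:
            out[i, src_lo - lo:src_hi - lo] = vals[src_lo:src_hi]
    return out


def compute_edf(recording: Waveform, model: ContextAdaptiveDetector,
                context: ContextTensor | None = None,
                features: TimeFreqMatrix | None = None,
                batch_size: int = 256) -> EventDetectionFunction:
    """Slide the classifier over a continuous recording.

    The frontend configuration stored in the model checkpoint is applied to
    the whole recording at once (so the PCEN smoother sees true long-term
    context), then each 150 ms window centered on an EDF frame is classified
    together with the context slice active at that time. Baseline models
    ignore ``context``; context-adaptive models compute it from the
    recording when not supplied. ``features`` may carry a precomputed
    matrix in the model's own representation.
    """
    if recording.duration < WINDOW_S:
        raise ValueError("recording shorter than one 150 ms window")
    tfm = features
    if tfm is None:
        tfm = apply_frontend(recording, model.representation,
                             model.stft_config, model.pcen_params)
    elif tfm.representation != model.representation:
        raise ValueError("features representation does not match the model")
    if model.uses_context and context is None:
        context = summary_statistics(tfm)
    n_win = int(np.floor((recording.duration - WINDOW_S) / HOP_S + 1e-9)) + 1
    times = WINDOW_S / 2 + HOP_S * np.arange(n_win)
    values = np.empty(n_win)
    for i in range(0, n_win, batch_size):
        ts = times[i:i + batch_size]
        clips = extract_clip_frames(tfm, ts)
        ctx = None
        if model.uses_context:
            ctx = np.stack([context.slice_at(t) for t in ts])
        values[i:i + batch_size] = model.predict(clips, ctx,
                                                 batch_size=batch_size)
    return EventDetectionFunction(values=values)


def pick_peaks(edf: EventDetectionFunction, tau: float,
               min_spacing: float = 0.150) -> EventList:
    """Thresholded local maxima of the EDF.

    Peaks are strict-left / weak-right local maxima (y[t-1] < y[t] >= y[t+1])
    exceeding ``tau``; flat stretches and edge frames yield no peak. With
    ``min_spacing`` > 0 (seconds), peaks are greedily suppressed in
    descending score order (ties broken by earlier time) so that no two
    survivors are closer than the spacing. With spacing 0, adjacent peaks
    can be as close as two hops (100 ms).
    """
    if not (0.0 < tau < 1.0):
        raise ValueError("tau must lie in (0, 1)")
    y = edf.values
    if len(y) < 3:
        return EventList(np.empty(0), np.empty(0))
    interior = np.arange(1, len(y) - 1)
    is_peak = (y[interior] > y[interior - 1]) & (y[interior] >= y[interior + 1]) \
        & (y[interior] > tau)
    peaks = interior[is_peak]
    if min_spacing > 0 and len(peaks) > 1:
        order = sorted(range(len(peaks)), key=lambda i: (-y[peaks[i]], peaks[i]))
        kept: list[int] = []
        for i in order:
            if all(abs(peaks[i] - peaks[j]) * edf.frame_hop >= min_spacing
                   for j in kept):
                kept.append(i)
        peaks = np.sort(peaks[kept])
    t = edf.start_time + peaks * edf.frame_hop
    return EventList(timestamps=t, scores=y[peaks])


def export_event_clips(recording: Waveform, events: EventList, out_dir,
                       clip_duration: float = WINDOW_S) -> list:
    """Write one 150 ms WAV per detected event; returns the file paths."""
    import pathlib

    from .audio import save_wav

    out_dir = pathlib.Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sr = recording.sample_rate
    half = int(clip_duration * sr / 2)
    paths = []
    for t in events.timestamps:
        c = int(round(t * sr))
        lo, hi = max(c - half, 0), min(c + half, len(recording.samples))
        clip = Waveform(recording.samples[lo:hi], sr,
                        sensor_id=recording.sensor_id, split=recording.split)
        path = out_dir / f"event_{t:010.3f}s.wav"
        save_wav(path, clip)
        paths.append(path)
    return paths
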