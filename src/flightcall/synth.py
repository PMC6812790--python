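"""Seeded generator of synthetic nocturnal soundscapes with ground truth.

The generator emulates the statistical structure of full-night recordings
from a network of autonomous recording units during fall bird migration:

* a sensor-specific background made of pink (1/f) noise plus amplitude-
  modulated "insect" tone clusters near 2-2.5, 4-5 and 5.5-8 kHz whose
  level decays ~10 dB over the night (stridulation fades after dusk), with
  per-sensor gain offsets, per-cluster level factors, spectral jitter and
  modulation-rate jitter (spatial nonuniformity), and optional sensor-
  specific impulsive confounds;
* sparse transient flight calls drawn from an inhomogeneous Poisson process
  whose rate increases toward the end of the night: "low"-band thrush-like
  downsweeps (2-5 kHz, ~100 ms) and "high"-band warbler/sparrow-like chirps
  (5-10 kHz, ~50 ms), with raised-cosine envelopes and log-normal peak
  amplitudes.

Everything is reproducible from (spec, seed, sensor_id). The generator aims
at the statistics the detector and its diagnostics react to — noise
nonstationarity/nonuniformity and event sparsity — not at species-accurate
call synthesis.
"""

from __future__ import annotations

import json
import warnings
import zlib
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .audio import TARGET_SAMPLE_RATE, Waveform
from .detector import EventList


@dataclass
class NightSpec:
    """Parameters of one synthetic night (desk scale by default).

    Defaults produce a compressed night: the relative structure of a real
    ten-hour recording (10 dB background decay, event rate rising several-
    fold, per-sensor nonuniformity) at a duration that desktop experiments
    can iterate on.
    """

    duration: float = 480.0            # s
    n_sensors: int = 4
    seed: int = 0
    # background
    pink_rms: float = 0.010            # broadband noise RMS (full scale 1)
    insect_rms: float = 0.040          # nominal AM tone-cluster RMS at dusk
    decay_db: float = 10.0             # insect-bed level decay over the night
    sensor_level_spread_db: float = 4.0  # max +/- per-sensor gain offset
    cluster_level_spread: float = 3.5  # per-sensor, per-cluster RMS factor
    # events
    rate_start: float = 3.0            # events/min at t=0, nondecreasing
    rate_end: float = 12.0             # events/min at t=duration
    event_amp_median: float = 0.010    # log-normal median peak amplitude
    event_amp_sigma: float = 0.5      # log-normal sigma (natural log)
    p_high_band: float = 0.5
    # impulsive confounds (clicks, electronic beeps), NOT flight calls;
    # their rate differs per sensor. Off by default: the baseline night
    # model is insect AM beds + pink noise; enable for harder regimes.
    confound_rate_max: float = 0.0     # per-sensor rate ~ U(0, max)/min
    confound_amp_median: float = 0.02
    sample_rate: float = TARGET_SAMPLE_RATE

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.rate_start < 0 or self.rate_end < self.rate_start:
            raise ValueError("event rate must be nonnegative and nondecreasing")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "NightSpec":
        with open(path) as fh:
            return cls(**json.load(fh))


def _sensor_rng(spec: NightSpec, sensor_id: str) -> np.random.Generator:
    tag = zlib.crc32(str(sensor_id).encode())
    return np.random.default_rng(np.random.SeedSequence([spec.seed, tag]))


def _pink_noise(rng, n: int) -> np.ndarray:
    """Unit-RMS 1/f noise via spectral shaping (flat below 20 Hz)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    shape = 1.0 / np.sqrt(np.maximum(f, 20.0 / n))
    x = np.fft.irfft(spec * shape, n)
    return x / x.std()


def _chirp(t: np.ndarray, f0: float, f1: float) -> np.ndarray:
    """Linear chirp with a raised-cosine (Hann) amplitude envelope."""
    dur = t[-1] - t[0] if len(t) > 1 else 1.0
    tt = t - t[0]
    phase = 2 * np.pi * (f0 * tt + (f1 - f0) / (2 * dur) * tt**2)
    env = 0.5 * (1 - np.cos(2 * np.pi * tt / dur))
    return env * np.sin(phase)


def synthesize_night(spec: NightSpec, sensor_id: str = "unit01",
                     split: str = "") -> tuple[Waveform, EventList]:
    """Render one sensor-night: background + Poisson flight calls.

    Returns the audio and the exact ground-truth event list (center times,
    peak-picking scores unset, band labels "low"/"high"). Deterministic
    given (spec, spec.seed, sensor_id).
    """
    rng = _sensor_rng(spec, sensor_id)
    sr, dur = spec.sample_rate, spec.duration
    n = int(round(dur * sr))
    t = np.arange(n) / sr

    # --- background -------------------------------------------------------
    audio = spec.pink_rms * _pink_noise(rng, n)
    level_db = rng.uniform(-spec.sensor_level_spread_db,
                           spec.sensor_level_spread_db)
    sensor_gain = 10.0 ** (level_db / 20.0)
    decay = 10.0 ** (-spec.decay_db * (t / dur) / 20.0)
    # three stridulation clusters: fundamental, second harmonic, and a
    # high-band (cricket/katydid-like) chorus; per-sensor random levels
    # give the network its spatial nonuniformity
    for lo, hi in ((2000.0, 2500.0), (4000.0, 5000.0), (5500.0, 8000.0)):
        f_carrier = rng.uniform(lo, hi)
        f_am = rng.uniform(15.0, 35.0)
        phase = rng.uniform(0, 2 * np.pi, size=3)
        lvl = spec.cluster_level_spread ** rng.uniform(-1.0, 1.0)
        am = 1.0 + 0.8 * np.sin(2 * np.pi * f_am * t + phase[0])
        tone = np.sin(2 * np.pi * f_carrier * t + phase[1]) \
            + 0.4 * np.sin(2 * np.pi * (1.013 * f_carrier) * t + phase[2])
        cluster = lvl * spec.insect_rms * am * tone / np.sqrt(0.5 * (1 + 0.16))
        audio += decay * cluster
    audio *= sensor_gain

    # --- impulsive confounds: sensor-specific clicks and beeps -------------
    conf_rate = rng.uniform(0.0, spec.confound_rate_max) / 60.0   # per s
    n_conf = rng.poisson(conf_rate * dur)
    for tc in np.sort(rng.uniform(0.2, dur - 0.2, size=n_conf)):
        amp = spec.confound_amp_median * np.exp(rng.normal(0.0, 0.5))
        if rng.uniform() < 0.5:                       # broadband click
            c_dur = 0.008
            i0 = int(round(tc * sr))
            i1 = min(i0 + int(round(c_dur * sr)), n)
            env = np.hanning(i1 - i0)
            audio[i0:i1] += amp * env * rng.standard_normal(i1 - i0)
        else:                                         # tonal beep
            c_dur = 0.150
            i0 = int(round(tc * sr))
            i1 = min(i0 + int(round(c_dur * sr)), n)
            seg = np.arange(i1 - i0) / sr
            env = np.hanning(i1 - i0)
            f_beep = rng.uniform(2500.0, 9000.0)
            audio[i0:i1] += amp * env * np.sin(2 * np.pi * f_beep * seg)

    # --- events: inhomogeneous Poisson by thinning -------------------------
    lam_max = spec.rate_end / 60.0                     # events/s
    times: list[float] = []
    if lam_max > 0:
        n_cand = rng.poisson(lam_max * dur)
        cand = np.sort(rng.uniform(0.0, dur, size=n_cand))
        lam = (spec.rate_start
               + (spec.rate_end - spec.rate_start) * cand / dur) / 60.0
        keep = rng.uniform(0, 1, size=n_cand) < lam / lam_max
        margin = 0.1
        times = [float(c) for c in cand[keep] if margin < c < dur - margin]
    if len(times) > 1 and np.median(np.diff(times)) < 0.15:
        warnings.warn("event rate high enough that calls routinely overlap",
                      stacklevel=2)

    bands: list[str] = []
    for tc in times:
        high = rng.uniform() < spec.p_high_band
        if high:
            ev_dur = 0.050
            f_start = rng.uniform(6000.0, 9500.0)
            f_end = np.clip(f_start + rng.uniform(-2000.0, 2000.0),
                            5200.0, 10000.0)
        else:
            ev_dur = 0.100
            f_start = rng.uniform(3200.0, 4800.0)
            f_end = rng.uniform(2100.0, f_start - 800.0)   # downsweep
        amp = spec.event_amp_median * np.exp(
            rng.normal(0.0, spec.event_amp_sigma))
        i0 = int(round((tc - ev_dur / 2) * sr))
        i1 = min(i0 + int(round(ev_dur * sr)), n)
        seg = np.arange(i0, i1) / sr
        audio[i0:i1] += amp * _chirp(seg, f_start, f_end)
        bands.append("high" if high else "low")

    w = Waveform(np.clip(audio, -1.0, 1.0), sr, sensor_id=sensor_id,
                 split=split)
    events = EventList(timestamps=np.array(times),
                       scores=np.ones(len(times)),
                       band_labels=bands)
    return w, events


def synthesize_network(spec: NightSpec, split: str = "",
                       prefix: str = "unit") -> dict:
    """All sensor-nights of the network: {sensor_id: (Waveform, EventList)}."""
    return {f"{prefix}{k:02d}": synthesize_night(spec, f"{prefix}{k:02d}", split)
            for k in range(spec.n_sensors)}


def make_clip_dataset(nights: dict, n_pos_per_sensor: int,
                      n_neg_per_sensor: int, seed: int = 0,
                      clip_len: float = 0.150,
                      guard: float = 0.5) -> pd.DataFrame:
    """Sample a balanced clip manifest from ground-truthed nights.

    Positives are centered on true events; negatives are uniform draws at
    least ``guard`` seconds away from every event (and half a clip from the
    edges). Returns a manifest frame with columns
    (sensor_id, split, time_s, label).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for sensor_id, (w, events) in nights.items():
        ev = events.timestamps
        if n_pos_per_sensor > len(ev):
            raise ValueError(f"sensor {sensor_id}: only {len(ev)} events "
                             f"available for {n_pos_per_sensor} positives")
        pos = rng.choice(ev, size=n_pos_per_sensor, replace=False)
        half = clip_len / 2
        lo, hi = half, w.duration - half
        neg: list[float] = []
        attempts = 0
        while len(neg) < n_neg_per_sensor:
            attempts += 1
            if attempts > 200 * n_neg_per_sensor:
                raise ValueError("not enough event-free background for the "
                                 "requested number of negatives")
            c = rng.uniform(lo, hi)
            if len(ev) == 0 or np.min(np.abs(ev - c)) >= guard:
                neg.append(c)
        for c in np.sort(pos):
            rows.append({"sensor_id": sensor_id, "split": w.split,
                         "time_s": float(c), "label": 1})
        for c in np.sort(np.array(neg)):
            rows.append({"sensor_id": sensor_id, "split": w.split,
                         "time_s": float(c), "label": 0})
    return pd.DataFrame(rows)
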