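# flightcall

Robust detection of avian nocturnal flight calls in continuous, noisy
field recordings.

Autonomous recording units (ARUs) capture full nights of migration audio in
which thrush, warbler and sparrow flight calls — 50–150 ms chirps between
2 and 10 kHz — sit on top of background noise that changes both through the
night (insect stridulation fading by ~10 dB after dusk) and across sensor
locations. Ordinary spectrogram CNN detectors degrade badly under these
shifts. `flightcall` implements a detection stack built around two noise-
adaptation ideas:

* **Per-channel energy normalization (PCEN).** Instead of `log(ε + E)`, each
  mel band of the spectrogram `E(t, f)` is divided by a low-passed version
  of itself before root compression:

      PCEN(t, f) = ( E(t, f) / (ε + (E ∗ φ_T)(t, f))^α + δ )^r − δ^r

  The division is a per-band automatic gain control with time constant
  `T` (60 ms for the outdoor preset: ε = 10⁻⁶, α = 0.8, δ = 10, r = ¼),
  which suppresses slowly varying background while keeping transients, and
  approximately Gaussianizes background magnitudes.

* **Context adaptation (CA).** An auxiliary network summarizes the acoustic
  environment with long-term order statistics μ(t, q, f) — nine quantiles ×
  32 mel bands over trailing 30-minute windows — and conditions the
  detector's output layer on them. Four merge formulations are provided for
  the final layer `y(t) = σ(b + Σₙ w(n) z(t, n))`: the static baseline,
  adaptive weights (`w(n)` replaced by the context embedding), adaptive
  threshold (a context-dependent bias, equivalently a slowly varying
  detection threshold), and a softmax-gated mixture of K = 4 experts.

Detection in continuous audio slides the 150 ms classifier at a 50 ms hop
(an event detection function at 20 frames/s), extracts thresholded local
peaks, and scores them against reference timestamps by maximum bipartite
matching within a tolerance, sweeping the threshold to get a
precision–recall curve and its area (AUPRC).

A seeded generator of synthetic full-night soundscapes (decaying AM insect
beds, pink noise, per-sensor nonuniformity, inhomogeneous-Poisson chirps
with exact ground truth) makes the whole pipeline testable end to end
without any data download.

## Worked example

```python
from flightcall import (NightSpec, synthesize_night, melspectrogram,
                        logmelspec, pcen, PcenParams,
                        magnitude_distribution)

# one synthetic sensor-night: insect bed decaying 10 dB, rising call rate
spec = NightSpec(duration=60.0, seed=1, rate_start=10.0, rate_end=40.0)
audio, truth = synthesize_night(spec, sensor_id="unit00")
print(len(truth), truth.band_labels[:4])

mel = melspectrogram(audio)
print(mel.values.shape, round(mel.frame_rate, 4))

for name, tfm in [("logmelspec", logmelspec(mel)),
                  ("pcen", pcen(mel, PcenParams.outdoor()))]:
    print(name, round(magnitude_distribution(tfm)["skewness"], 2))
```

prints (seed 1):

```
17 ['low', 'high', 'high', 'low']
(41336, 128) 689.0625
logmelspec 1.6
pcen 0.73
```

17 calls were planted with exact center times and band labels; the mel
matrix holds 41,336 frames × 128 bands at 689.06 frames/s; and the
standardized PCEN magnitudes are markedly less skewed than logmelspec
(|0.73| vs |1.6|) — the Gaussianization that underpins PCEN's robustness.

The CLI ties the stages together:

```sh
flightcall synth --out-dir nights --duration 60 --n-sensors 4 --seed 1
flightcall train --nights-dir nights --out detector.fcmodel --preset outdoor --formulation at
flightcall detect nights/unit03.wav --model detector.fcmodel --out-dir out --threshold 0.5
flightcall evaluate nights/unit03.wav --model detector.fcmodel \
    --reference nights/unit03_events.csv --out-dir out
```

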