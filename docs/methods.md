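# Methods

This note documents the models, conventions and numerical choices behind
`flightcall`, and what the synthetic experiments do and do not show.

## Time-frequency frontend

Audio is decoded to unit-range floats, resampled to 22,050 Hz, multiplied
by 2³¹ (the int32 full-scale convention) and analyzed with a 256-sample
Hann window, hop 32, FFT length 1024. Only frames fully inside the signal
are emitted (no padding), and frame times refer to window centers; this
avoids synthetic edge energy that PCEN's gain control would amplify. The
squared-modulus STFT is mapped through a Slaney-style, area-normalized
triangular mel filterbank with 128 bands from 2,000 Hz to 11,025 Hz
(Nyquist). 2 kHz is the lower edge of the thrush vocal range; everything
below is dominated by wind and vehicle rumble. The frame rate is
22,050 / 32 = 689.0625 frames/s. Filterbank weights and spectra are
computed in single precision; the values feed float32 models and dB-scale
medians, where 10⁻⁷ relative error is immaterial.

Two loudness mappings:

* `logmelspec`: `log(ε_log + E)` with ε_log = 10⁻¹⁰ (a floor, only to avoid
  −∞ on silent bands).
* `pcen`: `(E / (ε + M)^α + δ)^r − δ^r`, with the smoother `M` the causal
  first-order IIR `M(t) = (1 − s) M(t−1) + s E(t)`. The mapping between
  the smoother support `T` (in frames) and the coefficient follows
  `s = (√(1 + 4T²) − 1) / (2T²)`, and `M(0) = E(0)` suppresses the onset
  transient. A symmetric FIR low-pass would also fit the definition; the
  causal IIR was chosen so the frontend is streamable and needs no
  lookahead. Presets: indoor (ε = 10⁻⁶, α = 0.98, δ = 2, r = ½, T = 400 ms)
  and outdoor (ε = 10⁻⁶, α = 0.8, δ = 10, r = ¼, T = 60 ms). The outdoor
  preset is the package default: lower α and r and higher δ suit loud,
  right-skewed outdoor backgrounds and fast foreground modulations.

With α = 1 and ε → 0 a constant input of any level produces the same
steady state `(1 + δ)^r − δ^r` — the pure gain-control limit, asserted in
tests at 10⁻⁶ relative tolerance after letting the IIR converge (600
frames ≈ 0.9 s for T = 60 ms).

## Context features

The auxiliary descriptor μ(t, q, f) holds nine order statistics — the
0.1, 1, 10, 25, 50, 75, 90, 99, 99.9 percentiles (permille, percentile,
decile, quartile pairs around the median; the unique symmetric reading
that yields exactly nine levels) — of all time-frequency magnitudes in a
trailing window of T_CA = 30 minutes, pooled per reduced band. The 128 mel
bands are reduced to 32 by non-overlapping averaging of 4 neighbors.
Quantiles use linear interpolation between order statistics. Windows are
trailing (causal) so the features are computable in a streaming deployment;
the default sampling period is 450 s (8 frames/hour), configurable.
Pooling is over all bins in the window rather than per-frame energies:
order statistics of the raw bins are what make the descriptor insensitive
to any single 150 ms transient (a property tested directly: one inserted
transient moves the window median far less than the 99.9th percentile).

`band_spl_trend` reports 10·log₁₀ of the per-segment median in-band energy
referenced to full scale. Because segment medians sample a ramp at segment
centers, a programmed full-duration decay is recovered by fitting a line
to the segment medians and extrapolating the slope over the full duration,
not from the first-to-last difference.

## Detector

The main branch is the standard flight-call CNN: three valid (unpadded)
convolutions of 24, 24 and 48 kernels (5×5) with ReLU, the first two
followed by non-overlapping 4×2 max pooling (so the time axis is
downsampled 16× — 16 frames ≈ 24 ms per position), then a dense layer of
64 ReLU units with an L2 penalty of 10⁻³, giving the embedding z(t, n),
n < 64. Input clips are 104 frames × 128 bands: 150 ms of audio at hop 32
spans 104 frame centers; clips cut near recording edges are zero-padded
symmetrically. The auxiliary branch applies 8 kernels of size 1×32 to the
9×32 context slice — full-band spectral templates shared across quantile
rows, yielding 9 × 8 = 72 activations — followed by a dense 72 → 64 ReLU
layer, giving z_aux(t, n).

Merge formulations (σ the logistic function):

* baseline: `y = σ(b + w·z)`
* adaptive weights (AW): `y = σ(b + z_aux·z)`
* adaptive threshold (AT): `y = σ(w_aux·z_aux + w·z)` (no scalar bias);
  equivalently, thresholding `y` at τ compares the static detection
  function `σ(w·z)` with the slowly varying threshold
  `σ(σ⁻¹(τ) − w_aux·z_aux(t))`
* mixture of experts (MoE): nodes reshaped by n = K·m + k into M = 16
  mixture indices × K = 4 experts; a softmax over
  `α(k) = b_aux(k) + Σ_m w̃_aux(m, k) z̃_aux(m, k)` gates the per-expert
  inner products `Σ_m w̃(m, k) z̃(m, k)`. The gate weights w̃_aux are
  static learned parameters; only z̃_aux varies in time (the only reading
  under which they are trainable).

Each formulation contains the baseline as a particular parameter setting;
the tests construct these settings explicitly and verify equality to 10⁻⁶
on 1,000 random embeddings.

Training minimizes standard binary cross-entropy
`−[y_true log y + (1 − y_true) log(1 − y)]` with Adam (lr 10⁻³, β = 0.9 /
0.999, batch 32), Glorot-uniform initialization from a user seed, and
optional early stopping on validation accuracy (patience 20) under a
leave-one-sensor-out split whose train/validation sensor disjointness is
enforced. Classification accuracy is the fraction of clips with
|y − y_true| strictly below 0.5. Inputs are standardized by scalar
training-set mean/std (per representation), stored in the checkpoint;
scalar rather than per-band statistics so that band structure — what the
frontends differ in — is preserved.

The network is implemented directly in numpy with explicit backward
passes; convolution and pooling inner loops are numba-compiled (NHWC
layout). Gradients are validated against central finite differences in
float64 (directional derivatives, ε = 10⁻⁷, 10⁻⁴ relative agreement);
ReLU/max-pool kink crossings limit how small the FD error can be made, so
the per-layer backward passes are additionally checked with smooth
surrogate losses.

## Detection and evaluation

The event detection function slides the 150 ms window at a 50 ms hop
(20 frames/s); values are window-centered, and only windows fully inside
the recording are evaluated. PCEN and context statistics are computed once
on the whole recording, so the smoother and the quantiles see true
long-term context; each window is paired with the most recent context
frame at or before its center.

Peaks are strict-left/weak-right local maxima above τ; plateaus and edge
frames yield no peak. With a minimum spacing (150 ms by default, matching
the evaluation convention for the baseline; 0 disables it), peaks are
suppressed greedily in descending score order, ties broken by earlier
time — deterministic and oracle-checkable.

Matching between detected and reference timestamps is a maximum-
cardinality bipartite matching on pairs within 500 ms, via
augmenting-path matching (scipy); TP/FP/FN depend only on the matching
cardinality. Precision is defined as 1 when nothing is detected; an empty
reference list is an error (undefined recall). The PR curve sweeps 100
thresholds in (0, 1); AUPRC integrates trapezoidally over the recall axis
after sorting by recall, extending the curve to recall 0 while holding the
lowest-recall precision. Recall diagnostics (per 30-minute segment and per
band, split at 5 kHz) reuse one global matching per threshold rather than
per-segment matchings.

## Augmentation

Geometrical augmentation draws pitch shifts uniformly in ±1 semitone and
time-stretch rates log-uniformly in [0.9, 1.1] — small perturbations
consistent with vocal-range constraints; adaptive augmentation mixes 150 ms
background excerpts from same-split sensors at SNRs uniform in ±6 dB.
Exactly one effect per augmented clip; a full plan is 4 + 4 + 4×3 = 20
variants. Pitch shift and stretch use a phase vocoder (1024-point STFT,
hop 256) plus polyphase resampling. Plans refuse adaptive augmentation for
context-adaptive models: mixing noise into a clip would invalidate its
30-minute auxiliary statistics, which cannot be recomputed per mixture at
that time scale.

## Synthetic nights

Per sensor-night the generator renders pink (1/f) noise plus three
amplitude-modulated tone clusters (2–2.5, 4–5, 5.5–8 kHz; AM at 15–35 Hz)
whose level decays linearly in dB (default 10 dB) over the night —
emulating insect stridulation fading after dusk. Spatial nonuniformity
comes from a per-sensor broadband gain offset (±4 dB), per-cluster level
factors (log-uniform over a 3.5² range), and carrier/AM-frequency jitter;
the per-cluster spread is wide enough that across-sensor detection
difficulty genuinely varies, which is the regime in which context
adaptation has something to adapt to. Events are an inhomogeneous Poisson
process (thinning) with a nondecreasing rate ramp; low-band events are
100 ms downsweeps (start 3.2–4.8 kHz), high-band events 50 ms chirps
(5.2–10 kHz), with raised-cosine envelopes and log-normal peak amplitudes
(median 0.01 full scale — near or below the early-night insect bed, so
dusk detection is genuinely noise-limited, as in real deployments).
Everything derives from `(seed, sensor_id)` via a SeedSequence, so nights
are bitwise reproducible.

The generator reproduces the statistical structure the methods react to —
nonstationary and nonuniform backgrounds, sparse transients, rising event
rates — not acoustic realism: no species-specific call morphology, no
reverberation, no weather, no overlapping choruses. Passing tests
demonstrate the algorithms behave as designed under these statistics; they
are not field validation.

## Desk-scale experiment sizes

The robustness experiment compresses a ten-hour night into tens of
seconds while preserving relative structure: training nights of 60 s and
held-out test nights of 45 s with 15 s segments standing in for 30-minute
blocks; event rates ramping 20 → 60 per minute; matching tolerance and
minimum peak spacing of 150 ms (scaled in proportion — calls last
50–100 ms, so the tolerance stays generous); context windows of 15 s
sampled every 3.75 s so several context frames fit in a night. Three
training sensors and four test sensors per seed; 24 positive and 24
negative clips per training sensor; 7 epochs at batch 32. Per seed, three
detectors are trained (logmelspec baseline, PCEN baseline, PCEN + AT) and
run over all test sensors at one global operating point per model — the
threshold maximizing F1 on TP/FP/FN pooled over the whole test network.
A per-sensor threshold choice would amount to an oracle form of the very
context adaptation under study, so it is deliberately avoided. Reported
quantities: pooled recall in the earliest (noisiest) segment, and the
across-sensor recall median and interquartile range. With four sensors the
IQR is a genuine interquartile but still a small-sample statistic; the
directional comparisons are therefore evaluated over five seeds.

What these desk-scale runs do and do not show: the PCEN-vs-logmelspec
early-segment comparison reproduces reliably, because the mechanism (AGC
suppressing a loud, slowly varying insect bed) acts directly on the
synthetic background. The adaptive-threshold-narrows-sensor-spread
comparison does not reproduce reliably at this scale: the generator's
nonuniformity is multiplicative (gains, cluster levels, spectral jitter),
which per-band gain control removes almost entirely, leaving the
non-adaptive PCEN model's across-sensor recall IQR at the binomial noise
floor of a few dozen events per sensor-night — there is no spread left to
narrow, and the auxiliary branch has only three training sensors from
which to learn a noise-to-threshold mapping. Real sensor networks differ
in ways gain control cannot normalize (species mixes, hardware,
vegetation, impulsive interference), which is the regime where context
adaptation pays off; emulating that regime faithfully is beyond this
generator's scope.

## Known limitations

* The AT + MoE hybrid is deliberately not implemented.
* PCEN parameters are global constants, not trainable or
  frequency-dependent.
* Audio I/O is WAV only.
* The numpy/numba network is single-threaded and sized for desk-scale
  experiments, not for training on real multi-hour corpora.
* IQR over four sensors remains noisy; single-seed comparisons of the
  spread statistic should not be over-interpreted, and the desk-scale
  experiments do not demonstrate the across-sensor-spread benefit of
  context adaptation (see above).
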