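# Methods

This note records the models, parameter choices, and numerical conventions
behind `ppgwave`, and what its synthetic benchmarks can and cannot show.

## Signal model and assumptions

A PPG record is treated as an additive mixture

    x(t) = pulse(t) + drift(t) + artifacts(t) + noise(t)

where the pulse train's energy lies in roughly 1–10 Hz (fundamental at the
heart rate, 0.8–3.3 Hz for 50–200 bpm, plus harmonics from the systolic
upstroke), the drift and the low-frequency component of motion artifacts lie
below 1 Hz, and high-frequency noise is assumed small (front-end hardware
filtering is presumed, and the detector is insensitive to it by
construction, since it reads levels 4–5 of a dyadic decomposition).
Amplitudes are arbitrary: every stage is invariant to positive rescaling,
and the detector also to DC offsets, so no normalization is required.

## Baseline suppression

- **Wavelet**: sym8 (order-8 symlet, 16 taps) — compactly supported,
  orthogonal, least-asymmetric; its scaling function resembles the pulse
  waveform. Configurable (`suppression.wavelet`).
- **Level rule**: `L_max = fix(log2(N/(l_w − 1)))` with N the window length
  and l_w the filter length. Of the two readings the typography of this rule
  admits, `fix(log2(N/l_w − 1))` gives 5 for N = 1024, l_w = 16, while
  `fix(log2(N/(l_w−1)))` gives 6 and an approximation band (0–0.78 Hz at
  100 Hz) that matches the sub-1-Hz drift model; the latter is implemented.
  Requesting a deeper level than the window supports is an error.
- **Baseline estimate**: inverse transform with all detail coefficients
  zeroed — the standard multiresolution approximation reconstruction. The
  corrected signal is the pointwise difference. The whole raw → baseline →
  subtract map is linear.
- **Boundary handling**: half-point symmetric extension, the common choice
  for biosignals. Boundary effects are unavoidable within roughly one filter
  support of the record's ends; tests therefore assert on the interior 80%
  of samples.
- **Blocking**: records longer than 1024 samples are processed in
  non-overlapping 1024-sample core blocks. Each core is *decomposed* with up
  to half a block of context on either side, and only the core's baseline
  samples are kept: without the context, the symmetric reflection at
  interior block joints leaks pulse energy into the approximation and the
  assembled baseline acquires steps of a substantial fraction of the pulse
  amplitude at every joint, which the detector then misreads. The
  decomposition level is always taken from the *nominal* block length
  (1024 → level 6), never from the context-extended or merged length, so
  the baseline band stays pinned to the sub-1-Hz drift model. A trailing
  remainder shorter than a block is merged into the preceding block rather
  than processed alone: a short block's own deepest level is smaller, and
  its wider approximation band (e.g. 0–1.56 Hz at level 5) would swallow
  the pulse fundamental, while a merged block's deeper level would narrow
  the band (0–0.39 Hz at level 7) and under-remove the drift. A whole
  record too short to support one level falls back to mean subtraction.
- **Limitation**: correction also removes the pulse train's *own* sub-band
  content (notably its DC offset). This is immaterial for peak detection
  and for the ratio-of-ratios (scale- and offset-invariant per channel),
  but means the corrected signal is a band-limited version of the clean
  pulse train, not the clean train itself.

## Quadratic spline wavelet transform

- **Filters**: the quadratic-spline pair h = (0.125, 0.375, 0.375, 0.125),
  g = (2, −2). g sums to zero (constants are annihilated exactly); h is
  symmetric and sums to one. The absolute normalization of the pair is
  irrelevant here: the detection threshold is proportional to the
  coefficients' own magnitudes, so any per-level rescaling cancels — a
  property the tests assert directly.
- **À trous scheme**: at level *i* the taps are spread by 2^(i−1) samples;
  no decimation, so every level keeps the input's length and alignment.
  Five levels at 100 Hz; at that rate the pulse band maps to levels 4–5
  (verified spectrally in the tests). For other sampling rates the level
  count is a configuration knob.
- **Alignment**: filters are applied causally and each output is advanced
  by its accumulated group delay (1.5·spacing per smoothing stage,
  0.5·spacing for the derivative filter), rounded to the nearest sample.
  The derivative filter has even length, so a symmetric pulse's level-1
  response is antisymmetric about the apex minus half a sample; the
  residual half-sample bias (growing to a few samples at level 5 through
  rounding) is absorbed by the ±100 ms raw-signal refinement.
- **Boundaries**: half-point symmetric extension, as in the suppression
  stage.

## Detector

- **Threshold**: per level, ε = 0.5 × mean of per-segment maxima of |W|,
  with t = 256-sample segments (at least one heartbeat at 100 Hz for any
  rate above 24 bpm) and N = int(L/t) segments; a trailing remainder
  shorter than one segment is ignored. Each of levels 4 and 5 gets its own
  ε computed from its own coefficient magnitudes — coefficient scales
  differ per level, so a shared threshold would be meaningless.
- **Maxima**: strict local maxima of |W| above ε, signed. Cross-level
  persistence: a level-4 maximum is kept only if a same-sign level-5
  maximum lies within ±16 samples (the level-4 filter's support scale);
  matching is nearest-first with each partner consumed once.
- **Pairing**: adjacent opposite-sign maxima within 300 ms form a pair
  (the window must exceed the systolic upstroke–downstroke span but stay
  under one beat at 200 bpm); either polarity order is accepted, since
  reflective-probe polarity is device-dependent. Isolated maxima are
  dropped as artifact signatures. The pair's zero-crossing is the rounded
  root of the chord joining the two signed extrema — the pair itself
  carries enough information, and the subsequent raw-signal refinement
  makes the locus non-critical. Two pairs whose zero-crossings fall within
  the 200 ms refractory cannot both be beats; the larger-amplitude pair
  survives.
- **Localization**: peak = argmax of the signal within ±100 ms of the
  zero-crossing (covers the à trous alignment slack at level 5); duplicate
  refinements collapse to one peak.
- **Blocking**: 1024-sample cores with a 256-sample decomposition context
  on each side, so a beat straddling a block edge keeps both of its
  extrema; peaks are reported only from each core, and a final global
  refractory pass deduplicates edge peaks keeping the taller one. A
  trailing remainder shorter than one threshold segment merges into the
  preceding block.
- **Determinism**: the full path is deterministic for fixed input and
  configuration; tests assert byte-identical CLI outputs.

## Evaluation

Detections and references are matched one-to-one within ±150 ms — below
half a beat at 200 bpm and generous for PPG apex jitter. The matcher
maximizes the number of matches (ties broken by smaller total offset) via a
dynamic program over the two sorted sequences; the optimal matching of
sorted point sets on a line is non-crossing, so this equals exhaustive
assignment, and swapping the two sets exactly swaps FP and FN. The error
percentage 100·(FP+FN)/RB is reported to two decimals, rounded half-up to
match conventional table formatting. Pooled counts over repeated
experiments reproduce the pooled error exactly.

## SpO₂

Per matched beat, each channel contributes s = ΔI/I with ΔI the
peak-to-trough excursion (trough = minimum between the previous and current
peak) and I the peak value. R = s_red / s_ir, following the pulse-oximetry
convention of red in the numerator; SpO₂ = A·R + B. The exact logarithmic
form lg(1−s_red)/lg(1−s_ir) is available behind `spo2.form = "log"`; the
linear form is the default first-order approximation. A and B are
device-calibration coefficients and deliberately have no defaults. Beats
with zero IR pulsatility are skipped with a warning (all-skipped is an
error); in the log form, beats with s ≥ 1 are rejected rather than clamped,
since the logarithm's domain excludes them. Across beats the median is
reported alongside the per-beat values — robust to single-beat artifacts.

## Synthetic generator

The generator emulates fingertip PPG under three acquisition conditions and
returns every additive component plus the true beat positions:

- **Pulse template**: systolic Gaussian (σ = 60 ms, height 1) plus a
  dicrotic Gaussian 300 ms later at 35% height (σ = 90 ms) — a standard
  two-bump morphology surrogate. Only complete templates are stamped, so
  the ground truth never contains a beat the record cuts off.
- **Beat intervals**: Gaussian around 60/HR with the beat-to-beat SD
  implied by `hr_sd` (in bpm), truncated at 300 ms; defaults 75 ± 3 bpm.
  Configurations with `hr_sd ≥ hr_mean/2` are rejected as degenerate.
- **Drift**: sub-1-Hz sinusoids with random phases plus a smooth random
  walk (cubic spline through Gaussian knots every 5 s, normalized to unit
  RMS); all its energy lies below 1 Hz (asserted spectrally).
- **Artifacts**: Poisson-distributed transient Gaussian bumps
  (0.5–2 s duration, signed amplitude 0.3–0.8).
- **Regimes**: sitting (drift 5% of pulse, no artifacts, noise SD 0.01);
  raising hand (drift ≈ 1× pulse at 0.1–0.3 Hz, noise 0.015); walking
  (drift ≈ 2× pulse plus 4 artifact events/min, noise 0.02). These are
  chosen so detector difficulty orders sitting < raising hand < walking;
  the absolute error percentages on synthetic records are *not* claims
  about any particular device or cohort.
- **Dual channel**: both channels share beat times; each channel is
  DC + a·pulse(t) with the AC gain a solved so the nominal per-beat
  ratio-of-ratios equals the configured value (the per-beat excursion
  cancels in the ratio, so beat-shape variation enters only through the
  peak sample value — a sub-percent effect).
- **Reproducibility**: one seeded generator per record; a fixed seed
  reproduces the record bit-for-bit, and the seed is embedded in written
  artifacts.

What passing on synthetic data does **not** show: real PPG has
beat-morphology variability, amplitude modulation by respiration,
device-specific transfer functions, and artifact shapes far richer than
smooth bumps. The synthetic benchmarks validate the mechanics
(band separation, pairing logic, scoring, ratio recovery), the qualitative
claim that baseline correction improves drift-contaminated detection, and
nothing stronger.

## Problem sizes

The test suite and examples use 30–60 s records at 100 Hz (20-seed
ensembles for the clean-detection and corrected-vs-raw properties, one
300 s record for interval statistics), which gives stable ensemble means
while keeping the whole suite in the seconds range. Transform-vs-oracle
equivalence uses length ≤ 128 signals where the brute-force oracle is
exact and cheap.

## Known limitations

- Boundary effects at the first and last filter support of a record are
  inherent to both transforms; assertions and downstream use should prefer
  interior samples.
- The detector assumes the 100 Hz band mapping (levels 4–5); other
  sampling rates need the level pair and count adjusted via configuration.
- No trough-based or foot-based fiducial detection beyond the per-beat
  minimum used for SpO₂; no adaptive motion-artifact cancellation with
  auxiliary sensors; no high-frequency denoising (assumed handled upstream).
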