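# Methods

## Scope and model

The package classifies 20-second multimodal windows into normal (N),
preictal (P) and ictal (I) states. The discriminative signal comes from
three physiological effects, each carried by a different modality:

* **Autonomic shift before seizures.** The preictal state is modeled as a
  sympathovagal shift: shorter base R–R intervals and a larger LF/HF
  modulation ratio of the tachogram (LF 0.04–0.15 Hz, HF 0.15–0.4 Hz).
* **Hemodynamic change.** Pulse transit time (R peak → next PPG pulse
  peak) shortens with rising arterial pressure; state means step from
  250 ms (N) through 235 ms (P) to 215 ms (I).
* **Ictal EEG desynchronization.** Seizure EEG adds broadband power and a
  3 Hz transient train to the 1/f background, raising the normalized
  spectral entropy of 1 s sub-segments.

## Synthetic study conditions

No clinical recordings of this kind are public, so the generator defines
the study conditions and every stage is validated against its ground
truth. Defaults:

| parameter | N | P | I | unit |
|---|---|---|---|---|
| base RR | 800 | 740 | 650 | ms |
| LF modulation depth | 0.03 | 0.06 | 0.07 | fraction of RR |
| HF modulation depth | 0.04 | 0.02 | 0.015 | fraction of RR |
| PTT mean | 250 | 235 | 215 | ms |

PTT noise sd 3 ms (clipped at ±6 sd to keep the documented envelope);
multiplicative RR jitter sd 0.005; EEG background 1/f (exponent 1.0)
band-limited below 40 Hz; ictal broadband gain 1.2 × background sd and
3 Hz transient amplitude 2.0. The 40-minute protocol timeline (eyes
open/close 2 min, strobe 6 min, hyperventilation 1.5 min, rest 2 min,
hyperventilation 1.5 min, rest 2 min, sleep 20 min, waking 5 min) totals
2400 s; each seizure interval is preceded by a 60 s preictal interval,
truncated at time zero or a previous seizure.

Design choices inside the generator:

* Beats are placed iteratively (next beat = previous + RR(t)) rather than
  by integral pulse-frequency modulation: simpler, and ground-truth RR is
  exact by construction.
* RR modulation sits exactly at the LF/HF band centres (0.10 / 0.25 Hz) so
  band-power assertions are unambiguous.
* Base RR ramps linearly over 5 s at state transitions to avoid step
  artifacts in peak detection; ground truth records the ramped values.
  PTT means step at the boundary (the recovery check compares state
  means, which a ramp would only blur).
* The ECG template is a single Gaussian R wave (FWHM ≈ 19 ms); the PPG
  pulse a 300 ms raised cosine peaking at beat time + PTT. One integer
  seed drives deterministic per-channel sub-streams.

What the generator deliberately does **not** emulate: realistic
ECG morphology (P/T waves), respiration–HRV coupling, motion and
electrode artifacts, strobe-evoked EEG responses, inter-patient
variability beyond seed noise. Passing tests therefore demonstrate that
the pipeline recovers the states *it encodes*, with effect sizes that are
plausible but not estimates of clinical effect sizes; they say nothing
about performance on real patients.

## Signal processing

Filters are 4th-order Butterworth band-passes applied forward–backward
(zero phase). The ECG "smoothing" step is a 12 ms moving average
(3 samples at 250 Hz). Zero-phase filtering was chosen because PTT is a
timing measurement — causal filtering would bias the R-peak/pulse-peak
latency difference.

R peaks: differentiate → square → 150 ms moving-window integration →
adaptive signal/noise threshold (running peak estimates, threshold =
noise + 0.25·(signal − noise)) with a 250 ms refractory period, refined
to the local ECG maximum within ±50 ms. PPG peaks: local maxima above a
rolling 75th-percentile (5 s) threshold, 300 ms refractory. Physiological
gates discard RR outside 250–2500 ms and PTT outside 50–600 ms; an R peak
whose "next PPG peak" falls after the following R peak is skipped so a
pulse is never paired with the wrong beat.

## Features

A window is 25 HRV intervals; the hop is 12 intervals (50% of 25 is not
integral, so consecutive windows share 13 intervals and no interval is
ever split). PTT features use the gated PTT values whose R times fall
inside the window; windows with fewer than 5 such values are dropped.

Numerical conventions, fixed and mirrored by the brute-force test
oracles:

* std/variance use the N−1 (sample) denominator, matching the z-score
  definition; kurtosis is non-excess (normal → 3) and skewness is the
  biased Fisher moment ratio; both are defined as 0 for a zero-variance
  sample, where the moment ratios are 0/0.
* mode of continuous values: round to the 4 ms sampling quantum first
  (EEG amplitudes: 0.01 units), ties resolved to the smallest value.
* "median interval difference" is the median of |Δ| (absolute successive
  differences).
* HRV spectra: cubic-spline resampling to 4 Hz (standard tachogram
  practice), mean removal, boxcar FFT periodogram, rectangle-rule band
  integration. Zero HF power would make LF/HF +inf; it is reported as an
  inf sentinel and logged.
* EEG spectra: Welch (1 s Hann segments, 50% overlap) over 0.5–40 Hz;
  spectral entropy is the Shannon entropy (natural log) of each
  non-overlapping 1 s sub-segment's normalized periodogram (DC excluded),
  divided by log of the bin count so it lies in [0, 1]; the harmonic mean
  is computed on |x| + 1e-12 because EEG is signed.
* The EEG statistic list omits the geometric mean (12 statistics), which
  is what makes the total 16 + 16 + 7 + 18×3 = 93.

Normalization is per recording before pooling (each recording's windows
are z-scored with that recording's own statistics) — this mirrors
per-subject spreadsheets and removes inter-recording offsets; a `global`
mode instead fits the scaler on training rows only and applies it to
validation rows.

## Datasets and models

Window state = state at the window midpoint. Preictal relabeling assigns
at most 5 windows per ictal run and stops at any earlier ictal window.
RUS downsamples only the single majority class to the second-largest
count (a tie is a logged no-op); the stratified split rounds half-rows
toward training. The training pool is balanced after the split; the
validation set keeps the original imbalance, so reported accuracy and
sensitivities refer to naturally imbalanced data.

Boosted trees are sklearn's `GradientBoostingClassifier`; hyperparameter
search is randomized (learning rate 10^[−2,−0.3], 50–300 trees, depth
1–6) with the default configuration always among the candidates, so the
selected configuration is never worse than the default on the same
folds. The NCA feature weighting is a per-feature-weight variant:
distance d(x_i, x_j) = Σ_r w_r² |x_ir − x_jr|, stochastic-neighbor
leave-one-out objective with an L2 penalty on w, maximized by projected
gradient ascent with backtracking (rows subsampled to 400 for the O(n²)
objective). sklearn's NCA learns a full linear transform and is therefore
not a substitute for per-feature weights. PCA keeps the fewest components
reaching the explained-variance target.

## Problem sizes

The default end-to-end experiment simulates 10 recordings × 40 min with
2 seizures each (~250 windows per recording, ~2500 pooled; training pool
~300 rows after balancing, validation ~760 rows). Unit tests use shorter
series and smaller matrices; the determinism check reruns a 2-recording
configuration.

## Known limitations

* Pooling shuffles windows of the same recording into both splits, as the
  procedure prescribes; for honest generalization across subjects a
  grouped (leave-one-recording-out) split should be used instead.
* The synthetic preictal effect size is a modeling choice, not a clinical
  estimate; classifier performance on this data is an upper bound tied to
  the generator's separability.
* PTT uses the PPG peak, not the waveform foot; NN50 of PTT is constant
  (zero) under default noise and is flagged by the scaler.
* EDF export is not provided; recordings round-trip through CSV.
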