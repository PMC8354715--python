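# Methods

This note documents the analysis chain, the statistical machinery, the
synthetic-session generator, and the numerical choices made where the
procedures admit more than one reasonable reading.

## Signal model and preprocessing

The package assumes multichannel epidural EEG recorded around repeated
brief intracortical current pulses. Continuous signal is re-referenced
(common average for evoked analyses; a frontal–occipital bipolar derivation
for spontaneous activity), band-passed 0.5–80 Hz with a 3rd-order
Butterworth filter, and downsampled to 500 samples/s. Filtering is
zero-phase (forward–backward), so evoked latencies are not shifted; the
effective attenuation is the squared magnitude response. Downsampling uses
polyphase anti-aliased resampling.

Epochs span −5 to +5 s around each stimulus on a half-open `[a, b)` sample
grid with t = 0 the first post-stimulus sample. Each trial/channel is
offset-corrected by its −1–0 s baseline mean. The stimulus artifact (0–5 ms)
is replaced by a cubic spline anchored on 10 samples on each side. Trials
whose pooled-channel baseline rms exceeds the across-trial mean + 3 sample
standard deviations are rejected (strict `>`, so a zero-variance set rejects
nothing; the pooled-channel rms gives a single per-trial criterion). Noisy
channels are removed by a caller-supplied drop list, not an automatic
detector; sessions missing more than two channels are excluded from
connectivity.

## Spectral analysis

Spontaneous activity is characterized by the trial-averaged periodogram of
the −5…−1 s baseline: per-epoch FFT normalized by the sample count N,
squared modulus, averaged over epochs. Spectra are stored two-sided and read
one-sided without doubling (`|FFT/N|²`), so an on-grid sinusoid of amplitude
A peaks at A²/4 and the two-sided sum equals the mean squared signal. The
spectral exponent is the least-squares slope of log10 power against log10
frequency over 20–40 Hz.

Time–frequency analysis uses complex Morlet wavelets, 40 integer center
frequencies 1–40 Hz, 3 cycles at every frequency, Gaussian envelope
truncated at ±4 SD, each wavelet normalized to unit peak spectral gain.
Convolution always runs on the full epoch; the retained time range may be
cropped (the pipeline keeps −0.55…0.85 s, which covers every statistic's
window with margin) and coefficients are stored single-precision. Power is
normalized per channel and frequency by the trial-averaged −0.5…−0.2 s
baseline power and expressed as trial-averaged dB; dB maps are therefore
invariant to rescaling the input.

## Bootstrap significance

All significance masks are built from the pre-stimulus baseline. Per
permutation, each of the n trial slots receives a resampled
(trial, baseline-time) pair drawn with replacement, and the statistic (dB
power, ITPC, or baseline-corrected ISPC) is recomputed; draws are shared
across channels and frequencies so the null preserves their correlation.
Resampling time alone would be wrong here: at frequencies whose wavelet
correlation length exceeds the 0.3 s baseline window each trial contributes
essentially one effective baseline value, and without trial resampling the
null variance collapses. Map entries outside the percentile thresholds (two
one-sided tails at α/2 for power and ISPC, one-sided 1−α for ITPC, 500
permutations) are kept; all others are set to exactly 0. Power and ISPC
masks use α = 0.05, ITPC masks α = 0.01.

Scalar detections — OFF period, late HF increments, LF peak, ITPC drop —
operate on band-averaged series, not on single map bins, because a
"first/last significant sample" statistic scanned over thousands of
pointwise tests is dominated by isolated false positives. For each
registered band the bootstrap also records band-mean null draws (2000, a
larger sample than the 500 map permutations because a far smaller tail
probability must be resolved) and an autocorrelation length of the baseline
band series. The band-level threshold is the Šidák-adjusted quantile for
the effective number of independent samples in the search window
(m_eff = window length / autocorrelation length); quantiles beyond the
empirical resolution are extrapolated with a generalized Pareto fit to the
exceedances over the 90th percentile, which a few thousand draws estimate
far more stably than a raw order statistic.

## Evoked features

- **Early response**: rms of the trial-averaged ERP in 6–50 ms, per channel
  and channel-averaged.
- **Slow component (SC)**: responses low-passed below 4 Hz (Butterworth,
  3rd order, zero-phase); spontaneous (−2–0 s) and evoked (0–0.3 s) rms per
  trial, then trial- and channel-averaged; SC max amplitude and latency from
  the maximal absolute peak of the per-channel ensemble average in 0–0.6 s.
- **OFF period**: the 20–40 Hz band-mean dB series must fall below its
  band-level threshold somewhere in 0–0.3 s (detection); the episode is then
  timed at the half-depth crossings around its minimum, with depth taken as
  the median of the suppressed run. Half-depth is used because, on a
  smoothed edge, the zero crossing of a noisy series drifts outward with
  adjacent sub-zero noise runs while a significance-threshold crossing
  drifts inward; the half-depth point is unbiased under symmetric smearing.
  A series already suppressed at a window edge yields that edge. The mean
  HF dB in the fixed 0.08–0.18 s window is reported from the pointwise
  masked map. Channel aggregation reports statistics over detected channels
  plus the detected fraction.
- **Late HF / LF features**: earliest band-level-significant positive HF
  value in 0.08–0.8 s per channel (probability = detected channels /
  channels); mean masked LF (1–4 Hz) dB over 0–0.5 s and the maximal
  positive LF peak latency in 0–0.6 s.

## Phase statistics

ITPC is the modulus of the trial-mean unit phasor; ISPC the same statistic
applied to phase differences of channel pairs. The ITPC drop per channel is
the time of the last 8–40 Hz band-mean sample above the band-level threshold
in 0–0.8 s (strict "last", no gap tolerance), 0 with a flag when nothing is
significant, and censored when significance persists to the window end — so
group averages remain defined.

ISPC values are baseline-corrected by subtracting the pair/frequency mean
over −0.5…−0.2 s. Volume conduction is rejected per pair × frequency with
Gaussian v tests on the per-trial mean phase differences pooled over the
analysis window: V = n·R̄·cos(θ̄ − μ) for μ ∈ {0, π},
u = V·√(2/n) referred to the standard normal, one-sided at α = 0.05 each;
flagged entries are set to 0. A pair is "connected" in a window
(0.08–0.18 s or 0.18–0.3 s) when its 5–14 Hz band- and window-mean of the
masked, corrected ISPC is strictly positive; the connectivity degree divides
each channel's connected-partner count by (channels − 1). Regional profiles
average channels by electrode-label prefix (frontal: M2, M1; parietal: S1,
RS, PA; occipital: V2, V1).

## PCIst

The response window is 0–0.6 s, the baseline −0.5…−0.005 s. The SVD runs on
the response segment of the trial-averaged response; the smallest leading
component set reaching 99 % cumulative variance is kept, each component's
full time course is the projection onto its left singular vector (sign fixed
so the largest-magnitude loading is positive), and components with
SNR = rms(response)/rms(baseline) below SNR_min are dropped. Per component,
recurrence (pairwise absolute-difference) matrices of the baseline and
response segments are thresholded on 100 distances spanning (0, max pooled
distance]; NST(ε) counts the changes of the recurrence structure along time
per squared segment length, and

ΔNST = max_ε [NST_resp(ε) − k·NST_base(ε)] × n_resp,  k = 1.2,

clipped at 0 (a config flag) so the index is nonnegative and the surrogate
median-zero calibration is attainable. PCIst = Σ ΔNST over survivors; 0
when none survives. The index is exactly invariant to global positive
scaling (the ε grid and SNR are scale-relative) and to channel
permutations. Embedding dimension is 1.

SNR_min is calibrated on 16 surrogates per signal: two random,
non-overlapping 0.5 s non-response segments (t < 0 or t > 1.5 s) serve as
baseline and response; the smallest grid candidate with median surrogate
PCIst equal to 0 is adopted (1.8 on the default grid for the noise
sessions generated here). Sliding-window time courses (0.1 s width, 0.02 s
shift, ending by 1.1 s → 51 windows) re-derive components per window, which
keeps each window's value consistent with the fixed-window definition.

## Group statistics

All tests are two-tailed. The Wilcoxon signed-rank test drops zero
differences, mid-ranks ties, and computes the exact sign-flip permutation
distribution by generating-function convolution for n ≤ 25 (doubled ranks
are integers even with mid-ranks); larger samples use the tie-corrected
normal approximation. Effect sizes are mean paired differences with BCa
95 % intervals over 5000 seeded resamples (scipy's BCa machinery).
Weighted least-squares fits (statsmodels WLS) report slope, intercept, R²
and the t-test p value for slope = 0; weights follow the inverse-variance
convention. Mann–Whitney and Friedman tests wrap scipy, with the degenerate
all-identical Friedman case defined as statistic 0.

## The synthetic generator

The generator produces the conditions the analyses are validated under;
its defaults are the study design itself: 90 trials, 16 grid electrodes,
500 samples/s, epochs −5…+5 s, 50 µA events at 0.1 Hz in continuous mode.

- **Background**: inverse-FFT amplitude shaping to `max(f, knee)^(β/2)`
  with random phases, exact per-trial rms (25 µV). The knee (8 Hz) models
  the low-frequency plateau of aperiodic EEG spectra; without it a β = −3
  spectrum holds almost no 8–40 Hz power and arbitrarily small evoked
  leakage dominates every band statistic. The fit band 20–40 Hz lies above
  the knee, so the measured exponent equals β. The epoch is generated in
  two independently shaped blocks split at −1 s so the −5…−1 s spontaneous
  window coincides with a generation grid and its rectangular-window FFT is
  leakage-exact — a windowed segment of a single shaped realization reads a
  β = −3 slope as ≈ −2.2 purely through sidelobe leakage.
- **Evoked, phase-locked**: an early biphasic deflection (derivative of a
  Gaussian, peak 25 ms, σ 12 ms) and a two-oscillator locked bank with
  session-level frequencies and phases, ramped envelope, mild damping, and
  a hard end at the template's locked duration — the ground-truth ITPC
  drop. The bank is spatially coherent (zero lag across channels, the
  signature of a shared/volume-conducted source) so the v tests legitimately
  exclude its pairs from connectivity; its two oscillators carry distinct
  spatial profiles (stimulation-centered and posterior-weighted), giving
  the ERP more than one principal component. Evoked amplitudes decay
  exponentially with grid distance from the stimulation site (scale 12 mm).
- **Slow component**: a negative Gaussian half-wave (width = peak/3) whose
  latency travels away from the stimulation site (8 ms/mm) and jitters
  uniformly (±120 ms) per trial and channel. The Gaussian shape is
  spectrally compact: a jittered pulse with onset/offset corners would
  leave partial phase alignment at its jitter-range extremes and
  contaminate the ITPC drop. Under the steep-background states the matched
  spontaneous slow wave (65 µV at 1 Hz, random phase) keeps the wavelet-side
  leakage of slow activity comparable between baseline and response, as in
  real anesthesia recordings.
- **OFF period**: multiplicative attenuation of the >15 Hz content (exact
  FFT split) inside the template window with 10 ms ramps; depth in dB
  applies to amplitude (g = 10^(dB/20)), so the slow component co-occurs
  with HF suppression.
- **Late HF bursts**: 25–35 Hz, per-trial random phase (power without phase
  locking), present per channel with the template probability; onsets drawn
  per channel.
- **Coupling**: a 6 Hz common source with per-trial random global phase and
  fixed per-channel offsets in multiples of π/2: phase differences are
  trial-consistent (ISPC) while trial phases are uniform (no ITPC). Odd
  π/2 multiples survive the v tests, even multiples are excluded by
  design — the generator thus exercises both arms of the volume-conduction
  filter. Regional gains (frontal 0.6, parietal 1.0, occipital 1.6) produce
  the occipitally weighted connectivity profile.
- **Pairing**: condition pairs share per-channel gains (stable per-animal
  anatomy, log-normal σ = 0.1) with independent noise; all per-pair seeds
  derive from the master seed, and identical seeds give bit-identical
  sessions.

State defaults: wake (β = −1.4, locked 0.30 s, no OFF, late HF everywhere,
strong coupling), propofol (β = −3.0, locked 0.08 s at 12–18 Hz, OFF −4 dB,
large slow component, no late HF, weak coupling), sevoflurane (slightly
milder propofol), ketamine (β = −1.0, locked 0.28 s at 6–12 Hz, OFF −3 dB,
late HF in 90 % of channels, intermediate coupling), and a background-only
"noise" template for surrogate and null calibrations.

What the generator does **not** emulate: non-stationarity across trials,
movement or electrode artifacts beyond the stimulus transient, volume
conduction as a forward model (only the duplicated zero-lag construction),
spatially correlated background noise, and state drift within a session.
Passing tests therefore demonstrate correctness of the analysis chain under
the stated statistical structure, not robustness to every pathology of real
recordings.

## Problem sizes and runtime choices

Tests and example analyses run the full study geometry (90 trials × 16
channels × 40 frequencies) per session; the direction-fidelity study uses
nine synthetic pairs (the study's sample-size geometry, which makes the
all-same-sign exact Wilcoxon p equal 2/512), ketamine at three seeds, and
parameter-recovery checks at two to four seeds per quantity. Morlet
coefficients are retained on −0.55…0.85 s at single precision; ISPC is
computed on the 5–14 Hz rows over −0.5…0.35 s, the only region the
connectivity statistics read.

## Known limitations

- The band-level detection thresholds control the family-wise error over the
  search window approximately (Šidák with an estimated autocorrelation
  length, tail-extrapolated quantiles); occasional single-channel false
  detections remain and are visible as outlier drop times.
- Under the steep-background states, wavelet-side leakage of strong slow
  activity into the 20–40 Hz bins can register as spurious late-HF
  "increments"; the late-HF probability is only meaningful where HF bursts
  are physiologically plausible (wake- and ketamine-like states).
- OFF-period timing is unbiased for shallow suppressions on half-depth
  crossings; very deep suppressions with slow edges are still smeared by
  the wavelet envelope (±1 sample tolerance does not apply there).
- The exact Wilcoxon enumeration covers n ≤ 25; above that the normal
  approximation is used.
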