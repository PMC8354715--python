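# percort

Perturbational complexity and phase-clustering analysis of stimulus-evoked
cortical EEG.

`percort` is a Python toolkit for quantifying how richly a cortex responds
to a brief, direct electrical perturbation — the kind of measurement used to
separate brain states that sustain complex dynamics (wakefulness, ketamine
anesthesia) from states that do not (propofol or sevoflurane anesthesia,
deep sleep). It targets multichannel epidural EEG recorded around repeated
intracortical current pulses (16-electrode grids, hundreds of trials,
signals analyzed at 500 samples/s) and implements the full chain from raw
continuous recordings to group statistics, together with a synthetic-session
generator with complete ground truth so every stage can be validated without
animal data.

## What it computes

- **Preprocessing** (`percort.io_preprocess`): common-average or bipolar
  re-referencing, zero-phase 0.5–80 Hz Butterworth filtering, anti-aliased
  downsampling to 500 Hz, −5…+5 s epoching with baseline (−1–0 s) offset
  correction, cubic-spline interpolation of the stimulus artifact (0–5 ms),
  and rejection of trials whose baseline rms exceeds the across-trial mean
  by 3 SD. Sessions live in a documented HDF5 layout; EDF import is
  supported.
- **Time–frequency analysis** (`percort.timefreq`): trial-averaged FFT
  periodograms and the 1/f spectral exponent (log–log slope, 20–40 Hz);
  complex Morlet decomposition (40 wavelets, 1–40 Hz, 3 cycles); power
  normalized to the −0.5…−0.2 s baseline in dB with bootstrap significance
  masks (500 permutations, α = 0.05, non-significant values set to 0 dB).
- **Evoked features** (`percort.evoked_features`): early response amplitude
  (rms of the mean ERP, 6–50 ms), the slow (<4 Hz) component, detection of
  high-frequency (20–40 Hz) power suppression after the stimulus — the EEG
  signature of a cortical OFF period — and of later HF power increments.
- **Phase locking** (`percort.phase_locking`): intertrial phase clustering

  ITPC(t, f) = | n⁻¹ Σᵣ exp(i kₜ,f,ᵣ) |,

  its bootstrap significance (α = 0.01), and the **ITPC drop** — the time of
  the last significant band-mean (8–40 Hz) ITPC value, i.e. the duration of
  the deterministic part of the response.
- **Connectivity** (`percort.connectivity`): intersite phase clustering
  ISPC(t, f) = | n⁻¹ Σᵣ exp(i (kₓ − k_y)ₜ,f,ᵣ) | per channel pair,
  baseline-corrected and bootstrap-thresholded, with circular v tests that
  exclude pairs whose phase differences cluster at 0 or π (volume
  conduction); the **connectivity degree** (CD) of a channel is its fraction
  of significantly connected partners.
- **PCIst** (`percort.pcist`): the state-transition perturbational
  complexity index. The trial-averaged response (0–0.6 s) is reduced by SVD
  to the principal components carrying ≥99 % of the variance; components
  whose SNR (response rms / baseline rms) falls below a surrogate-calibrated
  gate (SNR_min = 1.8) are dropped, and each survivor contributes its number
  of significant state transitions ΔNST from recurrence-matrix
  thresholding:

  PCIst = N_C × mean(ΔNST)  (= Σ ΔNST).

  Sliding-window time courses (0.1 s windows, 0.02 s shift) are included.
- **Group statistics** (`percort.group_stats`): exact Wilcoxon signed-rank
  tests (full sign-flip distribution at small n), Mann–Whitney and Friedman
  tests, BCa bootstrap confidence intervals for mean differences (5000
  resamples), and weighted least-squares fits.
- **Synthetic sessions** (`percort.synthetic`): state templates (wake,
  propofol, sevoflurane, ketamine) that emulate the statistical structure
  the analyses assume — 1/f background with a state-dependent exponent,
  phase-locked evoked components with a known locked duration, OFF-period
  attenuation, late HF bursts, lagged functional coupling — with every draw
  recorded as ground truth.

## Worked example

Simulate one paired wake-like / propofol-like session (90 trials, 16
channels, shared per-animal channel gains) and run the full analysis:

```python
from percort import pipeline, synthetic as syn

pairs = syn.paired_conditions(syn.template("wake"), syn.template("propofol"),
                              n_pairs=1, seed=1)
(wake_epochs, _), (prop_epochs, _) = pairs[0]
wake = pipeline.session_metrics(wake_epochs, seed=1000)
prop = pipeline.session_metrics(prop_epochs, seed=2000)
for key in ("pcist_08_06", "itpc_drop_s", "hf_db", "cd_late"):
    print(f"{key:>12}:  wake {wake[key]:7.3f}   propofol {prop[key]:7.3f}")
```

prints

```
 pcist_08_06:  wake  42.777   propofol   6.650
 itpc_drop_s:  wake   0.326   propofol   0.200
       hf_db:  wake   2.061   propofol  -1.869
     cd_late:  wake   0.633   propofol   0.100
```

The four numbers carry the study's contrasts: complexity (PCIst over
0.08–0.6 s) collapses under the propofol-like regime, the phase-locked
response ends earlier (ITPC drop 0.33 → 0.20 s, tracking the planted locked
durations of 0.30 and 0.08 s), the 20–40 Hz power in 0.08–0.18 s flips from
an increase (+2.1 dB) to a suppression (−1.9 dB, the OFF period), and the
late-window (0.18–0.3 s) connectivity degree falls from 0.63 to 0.10 —
the wavelet time smearing at 8–16 Hz accounts for the drop reading ~0.1 s
above the short propofol locked duration.
Across nine such pairs every contrast holds in every pair, so the exact
two-tailed Wilcoxon signed-rank p is 2/512 ≈ 0.004.

A command-line interface mirrors the library:

```bash
percort simulate --state propofol --pairs 9 --seed 7 --out sessions/
percort preprocess --in session.h5 --out epochs.h5 --reference common_average
percort pcist --epochs epochs.h5 --out results.h5 --calibrate --seed 7
```

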