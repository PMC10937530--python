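# Methods

## The pipeline in one paragraph

`cogload` quantifies cognitive load from wearable multi-modal recordings of a
two-condition n-back session (zero-back parity control vs. three-back working
memory, 6 min each, 200 trials at 3-s intervals). Frontal EEG (6 channels at
256 Hz) is reduced to a per-second time series of normalized alpha power; the
rhythmic infra-slow content of that series — the fraction of its fluctuation
power at periods of 64–128 s relative to 5–128 s — is the central index.
Around it sit autonomic indices (RMSSD from PPG, SCR counts from EDA),
behavioral indices (accuracy, RT mean/IQR, RT very-low-frequency fluctuation),
an SVM arousal-state classifier over 24 EEG-fluctuation features, and a
statistics layer (paired t with KS screen, effect size r = |z|/√N,
difference-score Pearson correlations, Benjamini–Hochberg correction).

## EEG feature extraction

1. **Windowing.** The first 60 s of each task are discarded (instability after
   task onset); the amount is a parameter (`trim_s`) because some protocols
   may apply a different rule to resting baselines.
2. **Conditioning.** Per-channel mean subtraction, then a linear-phase
   windowed-sinc (Hamming) FIR band-pass, 4–30 Hz, order 424, designed at
   256 Hz. Filtering is single-pass with the constant 212-sample group delay
   compensated by shifting, so features stay aligned with the task clock.
   Edge transients span 212 samples (~0.83 s) at each end, which the windowing
   tolerates. A zero-phase (forward–backward) variant exists behind
   `zero_phase=True`; it squares the magnitude response and is off by default.
3. **First-order series.** Welch PSD on 20-s windows advanced by 1 s, each
   window split into 1-s non-overlapping Hann segments (frequency resolution
   1 Hz). Since the shift equals the segment length, per-second periodograms
   are computed once and rolling-averaged — algebraically identical to
   running Welch per window, and ~20× faster. Alpha (8–13 Hz) and theta
   (4–7 Hz) power are each normalized by total 4–30 Hz power per window and
   channel. Window values are stamped at the *window start*.
4. **Band integration rule.** Band power is the trapezoidal integral of the
   PSD between the band edges, with the PSD linearly interpolated at the
   edges. This makes a spectrally flat signal yield exactly the bandwidth
   ratio ((13−8)/(30−4) = 0.1923 for alpha) regardless of frequency
   resolution, and behaves continuously when band edges fall between bins.
   Windows with zero total power yield NaN, never a silent 0/0.

## The infra-slow fluctuation index

Per channel, the fluctuation PSD of the alpha-power series (1 sample/s) is
estimated by Welch with a single 256-sample Hann segment, linearly detrended,
zero-padded to 512 points (resolution ≈ 0.002 Hz). A ~300-s usable task
window leaves no room for segment averaging at a 128-s analysis period; for
longer recordings the segment length is a parameter. The index is

    index = ∫ PSD over [1/128, 1/64] Hz / ∫ PSD over [1/128, 1/5] Hz,

averaged over the six channels (ratio first, then channel mean). Both
integrals exclude 0 Hz, and detrending removes the mean and slow drift, so the
index measures *fluctuation*, is invariant to adding a constant to the power
series, and lies in [0, 1] because the numerator band nests in the
denominator. The module warns when fewer than two full cycles of the longest
analyzed period fit the series — with the study's 300-s windows and the
128-s period this is exactly at the margin, which is an inherent limitation of
the index at this recording length: single-segment estimation leaves the band
integrals with few effective degrees of freedom, giving the per-session index
a standard deviation of roughly 0.05–0.07 under the synthetic conditions
below. Any application of this index should expect that noise floor.

The **second-order series** applies the same idea in sliding form: each 130-s
window of a first-order series yields the integrated fluctuation power at
periods 40–90 s (periodogram of the detrended, Hann-tapered window,
zero-padded to 256). Values are stored on a linear scale; the downstream
z-normalization absorbs scale. Output length is `len − 130 + 1`, stamped at
window starts.

## Autonomic indices

**Pulse detection.** The PPG is band-limited to 0.5–8 Hz (3rd-order
Butterworth, zero-phase). A beat-period prior comes from the autocorrelation
of the band-limited signal (lags 300–2000 ms); if the autocorrelation peak is
below 0.2 the signal is declared aperiodic and an error is raised. Local
maxima are then gated against a running period estimate (EWMA, weight 0.2):
candidates closer than 0.5× the running period are rejected; a gap beyond
1.5× re-anchors without folding the gap into the estimate. N-N intervals are
screened to [300, 2000] ms and ±25% of an 11-beat running median before
RMSSD = √mean(ΔNN²). RMSSD is computed over the full analyzed window.

**SCR counting.** The conductance trace is low-passed, decimated to 32 Hz and
smoothed over 250 ms. Each local maximum is paired with the preceding local
minimum; a deflection counts as an SCR when the trough-to-peak rise completes
within 1–5 s and the amplitude is ≥ 0.05 μS (the common minimum-amplitude
convention; configurable). The index is events per minute. This is a simple
trough-to-peak counter: overlapping responses riding a single rise are counted
once, and no tonic/phasic decomposition is attempted.

## Behavior

Three-back trials 0–2 have no defined truth and are excluded from the
accuracy denominator by default (an all-trials denominator is selectable).
RT mean and IQR use all *responded* trials, correct and incorrect alike;
omissions are excluded and counted. Quartiles use linear interpolation
(type-7), stated explicitly because IQR values depend on the rule. The RT
fluctuation index is the mean Welch PSD of the trial-indexed RT series
(sampled at 1/3 Hz; missing RTs linearly interpolated, rejected above 20%
missing) over 0 < f < 0.05 Hz — the very-low-frequency band in which task
load expresses itself as slow waxing and waning of responsiveness.

## Arousal-state estimation

Features per second: {first-order, second-order} × {alpha, theta} × 6
channels = 24 dimensions, assembled on the overlapping time support of the
four series (the second-order series is shorter by the 130-s window
formation). Vectors are z-normalized per participant and task (a global
option exists), zero-variance dimensions flagged and zeroed. The classifier
is a Gaussian-kernel SVM (C = 1, kernel width by the 1/(d·var) heuristic;
both configurable) validated with leave-one-person-out CV — each fold holds
out every vector of one participant, which is the partitioning that prevents
person-identity leakage. The published model's weights and training data are
not available, so the package ships the architecture and training harness and
trains on labeled (synthetic) sessions; the run-level output is the
high-arousal portion, the fraction of seconds classified high.

## Statistics

Paired t-test after a Kolmogorov–Smirnov normality screen of the pair
differences (estimated parameters; the screen's outcome is attached to the
result, and a Lilliefors-corrected variant is noted as an option). The effect
size convention is r = |z|/√N; since z is not defined for a t statistic, z is
taken as the signed inverse-normal transform of the two-sided p — documented
because the source convention stems from rank tests. N is the number of
pairs. Identical pairs return t = 0, p = 1; a constant non-zero shift with
zero-variance differences is an error. Correlations are Pearson on
difference scores (three-back − zero-back), which standardizes away
between-participant level differences; Spearman is a switch. BH correction
is applied within a user-declared family (the pipeline's default family is
its correlation battery).

## Synthetic data: what it emulates, what it does not

`synthdata` generates the study conditions with known ground truth:

* **EEG** = 1/f background (exponent 1) + narrowband theta + narrowband
  alpha whose envelope is `(1 + depth·sin(2πt/period)) · spontaneous`, with
  the rhythmic phase shared across channels (a global arousal-like drive) and
  the spontaneous component a per-channel log-normal infra-slow process
  (sd 0.25 in log units, band 0–0.25 Hz). Default amplitudes (alpha 6 μV sd,
  theta 5, background 10) put the normalized alpha fraction near 0.5 of the
  band-limited 4–30 Hz total — clearly dominant yet below the saturation
  regime of the bounded fraction; at much higher alpha amplitudes the
  fraction saturates and deep modulations distort harmonically, flattening
  the index's response to modulation depth.
* **PPG** = pulse-template train with IBI = 800 ms + 40 ms·sin(2π·0.25 Hz·t)
  (respiratory sinus arrhythmia) + jitter, plus white noise at a set SNR.
* **EDA** = slowly drifting tonic level (2 μS) with biexponential SCR
  transients (rise ~1.3 s, decay 3 s) at 4/min.
* **Behavior** = uniform digits, Bernoulli correctness at the target
  accuracy, RT = 600 ms + low-frequency drift + 80 ms noise, floored at
  150 ms.
* **Cohorts** couple a latent trait to the high-minus-low-load modulation-
  depth difference (mean 0.15, sd 0.24, split symmetrically around a 0.30
  midpoint so both conditions stay on the responsive part of the index's
  depth-response curve) and to three-back accuracy (0.78 ± 0.12) through a
  bivariate Gaussian copula with correlation `trait_rho`; an infeasible
  `trait_rho` given the binomial accuracy noise raises instead of clipping.
  Within a participant, the noise realizations of a modality are shared
  across the two conditions (common random numbers): the participant's
  intrinsic signal processes are the same in both tasks and only the imposed
  parameters differ, mirroring the paired-measurement structure of a
  within-subject design.

What passing tests on this data do **not** show: the generator has no eye
blinks, EMG, electrode drift or line-noise residue, no biophysical source
geometry, no heavy-tailed RT distributions, no motion artifacts in PPG/EDA,
and the arousal labels of synthetic training sessions are induced by
construction rather than psychologically manipulated. Results demonstrate
the pipeline's correctness and sensitivity under the stated signal model,
not field robustness on raw wearable data.

## Problem sizes and numerical choices

Simulation-based checks use sizes chosen to be statistically meaningful while
keeping a full run tractable on one CPU: 50 paired seeded sessions for the
discriminability and depth-monotonicity properties; 200 seeds for the
white-noise index calibration (flat-spectrum expectation
(1/64−1/128)/(1/5−1/128) ≈ 0.0407); 1,000 random digit sequences against the
brute-force three-back oracle; 100 label permutations for the SVM chance
floor; 10,000 null replicates (n = 12) for correlation-p uniformity; and 40
synthetic cohorts of n = 40 for the end-to-end recovery of `trait_rho` = 0.7.
On the recovery check: the Pearson sampling sd at n = 40 and r ≈ 0.65 is
≈ 0.08, so even a perfectly recovered correlation of 0.7 lands in
[0.5, 0.85] only about 95% of the time per cohort; the observed recovery
(mean r ≈ 0.66) reflects mild attenuation from index estimation noise and
the bounded index's compressive response.

Ties and degenerate inputs: zero-total-power spectra give NaN fractions;
zero-variance feature dimensions z-normalize to 0 with a warning; identical
pairs give p = 1; constant variables make correlations error rather than
return NaN silently; an aperiodic PPG raises instead of returning an empty
beat list.
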