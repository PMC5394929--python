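# Methods

This note documents the models, estimators and numerical choices behind
`fxs-oscillo`, and what its synthetic cohorts do and do not establish
about real recordings.

## Scientific setting

*Fmr1* knockout (KO) mice — the standard mouse model of fragile X
syndrome — show elevated baseline and auditory-evoked gamma-band
(30–80 Hz) EEG power, consistent with reduced GABAergic inhibitory
control, alongside working-memory, sociability and anxiety-related
behavioral differences.  The GABA-B agonist baclofen partially
normalizes the electrophysiology and some behaviors, and the drop in a
mouse's evoked gamma power under drug tracks its working-memory
improvement.  The package implements the full analysis chain needed to
quantify those phenomena: ERP component extraction, baseline and
stimulus-related gamma power, mixed repeated-measures statistics over a
genotype × sex × dose cohort design, and within-subject responder
analysis — exercised end to end on a synthetic-cohort generator whose
ground truth is retained for recovery testing.

## Recording model and preprocessing

A session is a single-channel voltage trace (µV) at a constant sampling
rate (default 2 kHz, so the 1–500 Hz analysis band sits comfortably
below Nyquist), with a silent baseline (default 60 s) followed by
`n_stim` white-noise stimulus onsets at a fixed inter-stimulus interval.
Preprocessing is:

1. **Band-pass 1–500 Hz**, 4th-order Butterworth applied
   forward-backward (`sosfiltfilt`).  Zero-phase filtering matters
   because the ERP peak-search windows are only 15 ms wide; a causal
   filter would shift latencies.
2. **Epoching** into half-open windows `[-0.25, 0.5)` s around each
   onset (0-based sample indexing; events with incomplete windows are
   skipped and counted).  The window covers the pre-stimulus baseline,
   the 0–200 ms event-related span and the 30–100 ms N40 search window.
3. **Artifact rejection**: a sweep is rejected when its RMS exceeds
   2 × the RMS of that animal's whole filtered recording.  The
   criterion is per-mouse and scale invariant.  The amplitude statistic
   is per-sweep RMS rather than peak amplitude: under Gaussian
   background a peak-based 2×RMS rule would reject nearly every sweep,
   while sweep RMS concentrates near the recording RMS and only
   genuinely energetic sweeps cross 2×.

## ERP features

Sweeps are baseline-corrected by subtracting each sweep's pre-stimulus
mean, then averaged over kept sweeps.  P20 is the maximum of the
average in the closed 15–30 ms window, N40 the (signed) minimum in
30–100 ms; ties resolve to the earliest sample, so a flat waveform
deterministically reports (0 µV, window start).  Amplitudes are
baseline-referenced µV; latencies never leave their defining windows by
construction.

## Spectral measures

**Baseline power.**  Welch periodogram of the pre-stimulus span (1 s
Hann segments, 50% overlap, constant detrend, density scaling).  Band
power is the trapezoidal integral of the PSD with interpolated band
edges, which makes band powers exactly additive over a partition and
satisfies Parseval within a few percent on band-limited signals.
Absolute gamma is the 30–80 Hz integral (µV²); relative gamma divides
by the 1–120 Hz total.  The nominal total band "0–120 Hz" is
implemented as 1–120 Hz because the recording is high-passed at 1 Hz —
power below 1 Hz is unmeasurable by design.

**Time-frequency decomposition.**  Complex Morlet wavelets on a linear
2–120 Hz grid (1 Hz steps) with cycle counts ramping linearly 3 → 8
from the lowest to the highest frequency, unit-energy normalized,
applied by FFT convolution with center-crop alignment.  Wavelet support
is ±4σ; frequencies whose wavelet outgrows the epoch (below ~8 Hz for
the default window) are excluded from the event-related analysis, which
only consumes the gamma band.

**Evoked vs induced gamma.**  Evoked power is the wavelet power of the
across-sweep average waveform (phase-locked activity survives
averaging).  Induced power is the mean across sweeps of the wavelet
power of each sweep's residual after subtracting that average
(ERP-subtraction form).  The subtraction form is preferred over
total-minus-evoked because it is non-negative per sweep and directly
instantiates "not time-locked".  Both are reported two ways:

* raw µV²-scale power averaged over gamma × the 0–200 ms event window
  (used for energy-accounting checks), and
* dB relative to baseline: per frequency, power is averaged over the
  event window and over a −200…−50 ms baseline window, and the dB of
  the ratio is averaged across the gamma band.  Averaging power
  *before* the log matters: the evoked map is the transform of a single
  waveform, so a pixel-wise log (ERSP-style) carries an irreducible
  chi-square log bias near −2.5 dB regardless of sweep count, which
  would make even pure stationary noise report a spurious "decrease".
  The window-mean form is unbiased to ~0.1 dB under stationary noise.
  The baseline window stops 50 ms before the stimulus to keep wavelet
  bleed of the evoked response out of the reference.

## Statistics

The battery mirrors a two-stage design: factorial genotype × sex ANOVA
in the vehicle condition, then a mixed-design ANOVA with genotype and
sex between subjects and dose (vehicle, 1, 2.5, 5 mg/kg) within
subjects.

* Sums of squares are Type II, computed by least-squares model
  comparisons, so mildly unbalanced cells are handled; for balanced
  data they reduce to the classical partition (verified against a
  brute-force marginal-means oracle and R's `aov` during development).
* Between effects are tested against the subject-within-group mean
  square (df = N − cells); within effects against the dose × subject
  residual (df = (N − cells)(k − 1)).  No sphericity correction is
  applied and LSD post hocs use the raw error term with unadjusted p —
  deliberately matching the reporting conventions of the literature
  this pipeline serves rather than modern corrected practice.
* Subjects missing any dose session are listed and dropped
  (complete-case), mirroring how such exclusions are reported.
* Markedly skewed measures (adjusted Fisher–Pearson skewness outside
  (−1, 1)) are log10-transformed; open-field center time and water-maze
  latency are always transformed.
* Pearson correlations report the exact t-based two-tailed p; group
  contrasts use the pooled-variance t (df = n₁ + n₂ − 2).

Degenerate inputs are handled explicitly: identically constant data
report F = 0, p = 1; a zero-variance correlation raises an
undefined-value error rather than returning NaN.

## Responder analysis

For each subject with both vehicle and 2.5 mg/kg sessions, Δ = value at
dose − value at vehicle.  A subject is an *evoked-gamma responder* when
Δ evoked gamma < 0, strictly; Δ = 0 counts as nonresponder (exact zeros
have measure zero in practice, and "decrease, yes/no" implies a strict
binary).  The contrast machinery — pooled t between responders and
nonresponders on Δ T-maze %alternation, plus the Pearson correlation of
the two Δs, overall and within genotype strata — is generic over any
(Δ measure, outcome) pair, so null checks (baseline relative gamma,
induced power, center time, sociability) are one-liners.  A stratum
with a degenerate group is reported not-estimable instead of aborting
the others.

## Synthetic cohorts

Each recording is the sum of:

* **1/f background** (exponent α = 1, default SD 20 µV) — the broadband
  EEG floor;
* **ongoing gamma**: 30–80 Hz band-passed noise whose *power* carries
  the genotype × sex baseline-gamma gains (defaults: KO males 1.5,
  females 1.4 in both genotypes, WT males 1.0 — elevated baseline gamma
  in KO males, higher female power in WT, no KO effect in females);
* **ERP kernel** per stimulus: Gaussian atoms at +20 µV (20 ms, σ 4 ms)
  and −30 µV (40 ms, σ 6 ms), scaled per dose (largest at 2.5 mg/kg);
* **phase-locked gamma burst**: 45 Hz Gabor, σ 20 ms, centered 80 ms
  post-stimulus, identical phase every sweep — its power multiplier per
  dose (1, 0.9, 0.85, 0.6) makes 2.5 mg/kg a *marginal* mean decrease,
  so cohorts split into responders and nonresponders there while
  5 mg/kg suppresses clearly;
* **phase-random gamma burst**: same atom with per-sweep uniform phase,
  power rising with dose (1, 1.8, 2.0, 2.2);
* **movement artifacts**: with probability 0.05 per sweep, a 10 Hz
  Gabor transient (σ 0.1 s, 12 × background RMS) lands 100 ms
  post-stimulus.

Subject-level (σ = 0.15) and session-level (σ = 0.3) lognormal jitters
multiply the component powers.  The subject value is calibrated so that
a 72-mouse cohort reproduces the reported strength of the KO
baseline-gamma elevation (genotype F ≈ 11 on (1, 68) df); the session
value reflects the low test-retest repeatability of evoked power in
awake rodents and is what makes within-subject Δs informative.

Behavior couples to electrophysiology through the generative rule

    %alternation = base + genotype/dose offsets
                   + coupling · (−z(Δ evoked energy)) + N(0, σ_b),

clipped to [0, 100], where z standardizes each subject's true
evoked-energy change from vehicle within the cohort.  The implied
population correlation between Δ evoked and Δ %alternation is
ρ = −c/√(c² + 2σ_b²); `coupling_for_rho` inverts this so a target ρ
(e.g. −0.4) can be dialed in exactly.  Center time, social preference
and water-maze latency are generated with genotype/dose offsets only
(KO: higher center time, lower sociability) — they are deliberately
*uncoupled* from gamma, providing the null side of the responder
analysis.

Default protocol is desk-scale (60 sweeps at 1.5 s ISI) so the full
pipeline runs in seconds; the in-vivo protocol (120 sweeps, 8 s ISI)
is a config change.  Recovery and power studies in the test suite use
60 s baselines with stimulus sweeps scaled down, and 18 mice per
genotype × sex cell for cohort-level power — within the 15–23 range the
design targets.

**What the generator does not emulate**: real spectra's theta
prominence and non-stationarity, sedation or locomotor confounds at
high dose, electrode drift, line noise, and realistic relative-gamma
fractions (the synthetic gamma component is deliberately strong
relative to the 1/f floor so that band-power recovery is identifiable,
which pushes relative gamma well above in-vivo values).  Passing
recovery tests therefore demonstrates correctness of the estimators
under the stated generative model, not field validity on any particular
recording system.

## Numerical choices and degenerate inputs

* Events are seconds (float), stored sorted; epoch windows half-open so
  sweep lengths are exact sample counts.
* All writers round-trip: CSV uses `%.17g` floats with round-trip
  parsing; the EDF writer quantizes to 16 bits over the physical range
  (the reader, via MNE, is an independent code path).
* Ties in peak search go to the earliest sample; responder Δ = 0 goes
  to nonresponder; both for determinism.
* Cohort generation derives every stream from
  (`rng_seed`, subject index, session index) via `SeedSequence`, so
  identical configs give byte-identical cohorts and any session can be
  regenerated in isolation.

## Known limitations

* The mixed ANOVA is the classical univariate decomposition; no
  Greenhouse–Geisser correction or REML mixed models (out of scope by
  design).
* Unbalanced designs use Type II SS; the exact-partition property of
  sums of squares holds for (near-)balanced data only.
* Evoked/induced dB values depend on the baseline-window placement;
  with very short pre-stimulus spans the low-gamma wavelets bleed
  stimulus energy into the reference.
* EDF output requires an integer sampling rate.
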