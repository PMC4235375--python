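# Methods

`hybridbci` implements a hybrid fNIRS-EEG analysis pipeline for decoding
auditory vs. visual perceptual processing, together with a synthetic
multimodal session generator that stands in for real recordings.  This note
documents the models, the numerical choices, and what the synthetic data do
and do not establish.

## The decoding problem

A subject is presented with audiobook clips (AUD), silent movies (VIS),
movies with sound (MIX), or nothing (IDLE), in five blocks: one block of
three fixed 60 s continuous clips and four blocks of randomized
stimulus-locked trials (30 per label; stimulus durations uniform on
12.5 ± 2.5 s, rests on 20 ± 5 s, no two consecutive stimuli of the same
modality, no rest after IDLE).  Two signals are recorded simultaneously:

- **fNIRS**: two-wavelength (690/830 nm) AC light intensities from three
  multi-distance probes — 60 channels over the occipital cortex and 55 over
  each temporal lobe (170 total) at 19.5 Hz, source-detector distances
  1.7-2.5 cm.
- **EEG**: 10 analysis electrodes (Fz, Cz, Pz, Oz, O1, O2, FT7, FT8, TP7,
  TP8; mastoid-referenced) at 256 Hz.

Five binary conditions are evaluated: AUD vs VIS, AUD vs IDLE, VIS vs IDLE,
allAUD = {AUD, MIX} vs nonAUD = {VIS, IDLE}, and allVIS vs nonVIS.

## Preprocessing

**Optical chain** (order fixed): per-channel mean-normalization → cardiac
pulse correction → 8 s median filter with decimation to 1 Hz → optical
density (−log10 of the normalized intensity) → modified Beer-Lambert
conversion to ΔHbO/ΔHbR → common average referencing (CAR) across all
channels jointly.

- *Pulse correction*: the dominant spectral peak of the channel-mean signal
  in 0.7-2.0 Hz is located by Welch PSD (peak must rise 3-fold above the
  band median, else the stage is a logged no-op); every channel is then
  notch-filtered at that frequency (second-order band-stop, ±0.15 Hz,
  applied forward and backward).
- *Median filter*: 8 s = 157 samples at 19.5 Hz (rounded to odd).  The
  median is evaluated at the input sample nearest each integer second with
  edge replication, which equals filtering the full series and decimating.
- *Beer-Lambert*: ΔOD_λ = (ε_HbO,λ ΔHbO + ε_HbR,λ ΔHbR)·d·DPF_λ, solved per
  channel by the inverse of the 2×2 extinction matrix.  Extinction
  coefficients are the Prahl compilation values at 690/830 nm; the
  differential path-length factor defaults to 6.0 at both wavelengths and
  is configurable — results should be quoted together with the DPF used,
  since it rescales concentrations linearly.

**EEG chain**: zero-phase FIR band-pass 0.5-48 Hz (length 3·(fs/low cutoff)
= 1536 taps, rounded to odd; the filter is applied forward and backward) →
ICA blink rejection → stimulus-locked epoching → subtraction of the 100 ms
prestimulus mean.  Blink rejection decomposes the 10 channels into 10
independent components (FastICA, fixed seed, unmixing estimated on 4-fold
decimated data and applied at full rate), removes exactly the one whose
time course correlates most (|r| ≥ 0.3) with a blink proxy — the
low-frequency (<5 Hz) Fz envelope thresholded at 4 robust SDs, so that
blink-free data correlate with no component and pass through unchanged —
and reconstructs from the remaining components.  Filtering is applied to
the continuous record before epoching.

## Features

Per stimulus-locked trial (10 s epochs; ERP epochs are the first second):

- **HbO/HbR slope** (per channel, 1 Hz): f_c = (2/w)·(Σ_{t_opt}^{t_opt+w/2} x_c(t)
  − Σ_{t_opt−w/2}^{t_opt} x_c(t)), sums over integer-second samples, both
  endpoints inclusive.  (t_opt, w) are selected per training fold from the
  grids t_opt ∈ {2..8} s, w ∈ {2,4,6,8} s (windows clipped to the epoch),
  independently for HbO and HbR — each species picks the grid point
  maximizing its own inner-CV accuracy; ties break toward smaller t_opt,
  then smaller w.
- **POW** (per electrode): Welch PSD of the 10 s epoch (2 s Hann segments,
  50 % overlap → 0.5 Hz grid); every other component in 3-40 Hz inclusive →
  38 linear-power values.  Band-ablation runs reconfigure the band (e.g.
  13-40 Hz → 28 values).
- **ERP** (per electrode): median filter (5 samples) → moving average (13
  samples, edges replicated so constants are preserved) → every 13th sample
  → 20 values.
- **Continuous-mode fNIRS** (windowed decoding of block-1 clips): window
  mean minus the mean of all already-elapsed samples of the segment; the
  first window of a segment is 0 by convention.  Continuous windows overlap
  50 % (count = ceil(T/(w_len/2)), final windows truncated); POW on short
  windows zero-pads the Welch segments so the integer-Hz selection always
  exists.  ERP features are refused in continuous mode (they require an
  onset).

All features are z-normalized with statistics estimated on training trials
only; zero-variance features are centered, given unit scale, and flagged.

## Classifiers and fusion

HbO, HbR and POW use a shrinkage-regularized LDA with pooled covariance
S_reg = (1−γ)S + γ(tr S/d)I and γ = 0.5 (closed form, implemented
in-package; γ = 0 reproduces classical LDA, γ = 1 nearest class mean).  ERP
uses a soft-margin linear SVM (libsvm, C = 1) whose margin is mapped to
probabilities by a Platt sigmoid fitted on the training margins; the slope
is clamped non-negative so calibration is monotone.

The META classifier fuses the four per-classifier posteriors:
p_meta = Σ_m w_m p_m.  Weights come from evaluation-data accuracies:
acc > 0.5 is mapped affinely (0.5 → 0, 1.0 → 1), sub-chance classifiers get
0, the vector is 1-norm-normalized, and an all-zero vector falls back to
uniform.  The class with larger fused probability wins; exact ties go to
the first class (deterministic).

## Cross-validation

- **Subject-dependent**: leave-one-trial-out (60 folds for 60 condition
  trials).  Each outer training set runs an inner 10-fold CV
  (class-stratified by round-robin dealing; 59 trials → nine 6-trial
  evaluation folds with 53 training trials and one 5-trial fold) that both
  selects (t_opt, w) and supplies the per-classifier accuracies for the
  fusion weights; normalizers and models are then refit on the full outer
  training set.
- **Subject-independent**: leave-one-subject-out (12 subjects × 60 trials →
  660 training / 60 test per fold).  One training subject, drawn
  deterministically per fold, serves as held-out evaluation data for
  parameter selection and fusion weights; the final model is refit on all
  training subjects.  With only one training subject (2-subject cohorts)
  there is nothing to hold out and the driver falls back to inner k-fold
  splits on that subject's trials.
- No quantity fitted in a fold ever sees the fold's test trials or test
  subject (verified by a marker-poisoning test).

Chance levels use the two-sided normal-approximation binomial interval
around 50 %: upper limit 0.5 + z_{1−α/2}·√(0.25/n), e.g. 52.4 % at
α = 0.01 and n = 2880 (2 classes × 120 one-second windows × 12 subjects)
and 53.4 % at n = 1440; an adjusted-Wald variant (effective n + z²) is
available as a switch.  META-vs-best comparisons use one-sided paired
t-tests with Holm step-down correction; all-zero difference vectors yield
p = 1.

## Reporting

Grand averages: baseline-subtracted (2 s prestimulus) per-label HRF means,
first-second ERP means, and log-scale Welch PSDs.  Feature rankings: per
subject, each item (electrode, frequency component, time window, or fNIRS
probe) is scored by the maximum |Pearson r| between its features and the
0/1 labels (constant features score 0 and rank last); ordinal ranks
(1 = best, deterministic tie-break) are averaged across subjects, and a
Friedman chi-square on the rank rows (k−1 df, mid-rank tie correction via
scipy) tests whether the ordering is consistent; identical rankings give
the maximum statistic n(k−1).

## Synthetic sessions

The generator is a pure function of (config, models, seed); per-subject
seeds derive from the master seed via `numpy` seed sequences.

**Haemodynamics.** Label-gated boxcars convolved with a double-gamma
impulse response (peak 5.5 s, undershoot peak 15 s, undershoot ratio 1/6,
kernel normalized to unit integral so a sustained stimulus plateaus at the
configured amplitude).  VIS drives the occipital probe, AUD both temporal
probes, MIX superposes the two additively, IDLE drives nothing.  Defaults:
ΔHbO plateau 1 µM, ΔHbR = −0.3·ΔHbO; per-channel sensitivity uniform on
[0.15, 1] (overlapping multi-distance channels sample the activated cortex
unevenly — this heterogeneity is what makes probe-level localization
meaningful after CAR); slow sinusoidal drift (amplitude 1 µM, period
60-180 s, random phase per channel); white optical-density noise
σ = 0.04/sample at 19.5 Hz (chosen so single-trial haemoglobin decoding
lands around 80-95 % rather than saturating); multiplicative cardiac
pulsation (1.0-1.5 Hz per subject, amplitude 1 %, near-coherent phase
across channels); per-subject log-normal amplitude scaling (σ = 0.3).
Concentrations map to AC intensities through the forward Beer-Lambert law,
I = I₀·10^(−ΔOD).

**EEG.** 1/f background (7 µV RMS) built from a few shared latent sources
mixed across the scalp plus a small independent sensor floor (volume
conduction; this also keeps the 10-channel ICA problem well-posed); alpha
(9.5 Hz, 6 µV occipitally weighted) and beta (18.5 Hz, 2 µV) narrowband
generators whose gain is switched during stimuli — occipital alpha gain
ordering AUD (1.3) ≥ IDLE (1.05) > VIS (0.35) is enforced by construction
(MIX 0.45); ERP templates over the first second (negative deflection near
110 ms, positive P300-like deflection near 330 ms, 12 µV, latency jitter
σ = 20 ms, log-normal amplitude jitter σ = 0.2) with an occipitally
dominant VIS topography and a centro-parietal (Pz/Cz) AUD topography;
Poisson blinks (0.15/s, 100 µV, 350 ms raised cosine) with a steeply
frontal topography clearly distinct from the AUD ERP.

**Special model sets.** `CohortModels.null()` removes every
label-dependent effect (for chance calibration);
`CohortModels.general_activity_only()` gives AUD, VIS and MIX *identical*
responses (same probes, same generic ERP, no oscillatory label
information) to probe whether a detector trained on AUD vs IDLE is
modality-specific.  Under that construction the detector necessarily
treats VIS trials exactly like AUD trials, so its false-detection rate on
VIS equals its true-positive rate (~0.9 here) — the confound (detection
without auditory content) appears in full strength rather than at the
~50 % level a partially-shared-effect scenario would produce.

**What the synthetic data do not show.** Effects are stationary, Gaussian
around known templates, and spatially simplistic (rank-one topographies,
uniform probe drive up to a scalar gain); there is no motion artifact, no
habituation, no inter-trial dependence, and stimulus "content" carries no
structure.  Passing tests therefore establish correctness and internal
consistency of the pipeline — the advertised accuracies characterize the
planted effect sizes, not expected performance on real recordings.

## Problem sizes used in tests and the acceptance script

The study-scale checks run 12 subjects × 30 trials per label at a reduced
montage of 6 channels per probe (the probe structure, not the channel
count, is what the analyses exercise); the tiny test fixture uses 2
subjects × 8 trials per label with effects planted at twice the default
amplitude.  The acceptance script regenerates its cohort from the provided
seed and recomputes every reported number at run time.

## Known limitations

- ICA blink rejection removes a full component; a small fraction of
  frontal ERP energy goes with it (the template-recovery checks bound this
  at the cohort-grand-average level).
- The per-species (t_opt, w) selection doubles the inner grid search; the
  paper's wording would also admit a single shared grid point.
- The SNIRF reader covers the subset of the format needed for channel
  import (dataTimeSeries/time/measurementList); full optode geometry is
  ignored because the montage is configured by counts and probe
  membership.
- Chance bounds use the normal approximation; at small window counts
  (≥4 s windows) it is a couple of tenths of a percentage point tighter
  than adjusted-Wald-style bounds.
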