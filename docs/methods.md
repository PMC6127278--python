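# Methods

This note records the models, parameter choices and numerical conventions
behind `mrcpipe`, and what the synthetic data can and cannot establish.

## Paradigm and simulator

A session is a sequence of trials: 2 s baseline → condition cue (ID,
IDII or EC, pseudo-randomly interleaved with equal counts) together with
a scroller showing a fresh 3-digit number every 750 ms → self-paced
imagination onset (IO) → reporting at trial end → 1.5 s break.  The
post-cue period is fixed at 13.5 s (the real paradigm leaves it
unspecified; 13.5 s is the smallest round value that fits the 12 s
evaluation period starting 1 s after the cue and the [4, 5] s REST
window for mid-range IOs).  Three 60 s rest runs are appended.

**IO distribution.** Truncated lognormal over seconds-after-cue,
median 4 s, log-sd 0.5, support [2, 9] s.  The family is a modelling
choice (only per-subject IO spread is known for the real task); the
support keeps every MI labeling window and REST window inside the trial.
The *report* is the scroller number whose 750 ms display interval
contains the true IO, so the estimated IO (the number's display onset)
precedes the true IO by up to one scroller period — deliberately
reproducing the paradigm's alignment error.  With probability
`invalid_report_rate` (default 0.05, matching ~9 incorrect of ~195
trials) the report is replaced by a never-shown number or a
condition-inconsistent target.

**Signal templates.**  Morphology landmarks, not biophysics:

* ERP (per condition): Gaussian P200 (3 µV, 200 ms, σ=40 ms) and P300
  (5 µV, 500 ms, σ=90 ms) plus a raised-cosine late slow wave supported
  exactly on 0.6–0.8 s with amplitude 3 µV (ID, IDII) vs 1 µV (EC) — a
  2 µV internally-driven vs externally-cued difference.  Component
  topographies are Gaussian gain maps (σ≈0.45 rad in an azimuthal
  projection) centred on POz, CPz and Pz respectively.
* MRCP: zero before −1 s (relative to the true IO), half-cosine descent
  to −6 µV at +0.5 s, half-cosine return to zero at +2 s; gain map
  centred on Cz (σ=0.5), peaking over FCz/Cz.

**Noise.**  Background EEG is spatially low-rank 1/f noise: 20 shared
pink (exponent 1) sources mixed through random smooth gain maps, plus a
10 % white sensor floor, normalized to `noise_scale` RMS per channel;
EOG channels get independent pink noise.  Blinks are squared-Hann 300 ms
transients (150 µV on EOG, frontally decaying on EEG) at 4/min Poisson
times, recorded as ground-truth events.

**Noise calibration (fixed once).**  `noise_scale = 2.5 µV` broadband
RMS was chosen so the synthetic regime reproduces the study regime the
pipeline is meant to operate in: the per-subject late ERP effect is
detectable by the tmax test in ≈95 % of subjects at ~60 trials/condition,
asynchronous percent-correct sits in the 50–80 % range against a ~20–35 %
structured-permutation chance, and time-locked accuracy is high but
imperfect.  It is a single abstract scale, not a fit to any recording.

**Epoch-level generators.**  `simulate_condition_epochs` and
`simulate_io_locked_epochs` produce template-plus-noise epoch sets
directly for calibration studies that need hundreds of datasets.  Noise
is drawn *independently per trial* (trials in a real session are ~17 s
apart, so their 0.1 Hz-band noise is essentially uncorrelated; slicing
consecutive short segments from one stream was measured to make the
trial-level permutation test conservative).  Band-pass filtering is
applied on a ±4–6 s padded grid so filter edge transients stay outside
the analysis window, mirroring the continuous filtering of the session
pipeline.

## Preprocessing

Order: bad channels → notch (50 Hz, Q=30, zero-phase) → copy A
(1–70 Hz, 4th-order zero-phase Butterworth) for trial-based artifact
rejection and PCA+ICA fitting → back-projection of non-artifact
components onto copy B (notch-only), rest runs included.

* **Bad channels**: per-channel MAD amplitude scale over the rest runs;
  flagged when > 5 robust SDs *and* a 2× ratio from the median EEG
  channel scale, plus a manual override list.  MAD (not variance) so the
  ~2 % blink duty cycle — which belongs to the ICA stage — cannot
  condemn frontal channels.
* **Trial rejection** on trial-locked 1–70 Hz epochs: (1) any sample
  outside ±200 µV; (2) joint probability — per channel, the mean negative
  log-likelihood of the trial's samples under the pooled 100-bin
  empirical histogram, flagged beyond 5 across-trial SDs on any channel
  or the all-channel mean (a documented stand-in for the toolbox
  statistic the field uses, which has no published formula); (3) sample
  kurtosis with the same outlier rule.
* **PCA** keeps the fewest components reaching 99 % variance;
  **extended Infomax ICA** is fit on the concatenated artifact-free
  epochs decimated to ≤12 000 observations, `max_iter=50`,
  `ext_blocks=50`, fixed recorded seed.  Full-resolution default-iteration
  fitting costs ~3 minutes per subject and was measured to improve
  blink-component recovery not at all on synthetic sessions (~99 %
  blink-locked frontal amplitude reduction either way).  ICA is fit on
  epochs (not continuous data), following the processing-diagram order.
* **Component marking** (visual in practice) is automated: components
  whose activations correlate with any EOG channel above |r| = 0.7,
  union a manual list.

## ERP statistics

Averages and tests run on 0.1–15 Hz cleaned data.  Confidence bands are
t-percentile bootstrap: resample trials, studentize (mean* − mean)/se*,
invert the α/2 and 1−α/2 quantiles.  Condition contrasts use the paired
two-tailed tmax permutation test on [0, 2] s after the cue across all
channels jointly: whole-trial sign flips of paired differences (the
standard paired construction), signed extreme statistic, critical values
at the 0.025/0.975 quantiles.  Defaults: 10 000 permutations for the
operation (the pipeline uses 1 000–2 000, recorded per run); when
2^n_pairs ≤ 4096 the full enumeration replaces sampling and results are
exactly reproducible.  The observed labeling is always part of the
reference distribution, so Monte-Carlo p ≥ 1/n_perm.  A zero-variance
nonzero-mean cell gets t = ±∞ (infinitely extreme); an all-zero
difference family is reported as entirely non-significant.

## MRCP analysis

0.1–1 Hz band; IO-locked averages with the same bootstrap machinery; no
channel-space baseline subtraction by default (the 0.1 Hz high-pass
detrends; a baseline window is available as an option).  Peak negativity
is the argmin over the closed interval [−2, 2] s, ties to the earliest
latency; each peak carries a CI-contains-zero flag rather than an
MRCP-present verdict (how absence was adjudicated in practice is
unknown).  Two systematic effects of the pipeline itself, quantified on
noise-free templates: the 0.1–1 Hz filter attenuates the −6 µV template
peak to ≈ −3.8 µV, and estimated-IO locking adds ≈ +0.38 s mean latency
bias (half the scroller period).  Parameter-recovery studies therefore
lock to the retained true IO and compare against the *filtered-template
oracle*.

## Detection

0.1–1 Hz cleaned EEG → zero-phase 4 Hz low-pass → decimation to 10 Hz.
The 26-channel sensorimotor set (`CLASSIFIER_26`: F1/Fz/F2, FC5–FC6,
C5–C6, CP5–CP6, P1/Pz) approximates a montage that is only shown
graphically in the field.  The MI-window rule (training-fold average
MRCP at Cz, peak in [−2, 2] s; strictly-before-0.5 s → window [−1, 0],
else [0, 1]) and REST rule ([4, 5] s after the IO while it fits the
trial, else [−5, −4] s) are re-evaluated inside every training split;
shrinkage estimation likewise — no leakage.  Folds are trial-level,
stratified by condition (stratification is this package's choice).  The
classifier is LDA with the pooled class-centered covariance shrunk
toward (trace Σ̂/d)·I at the analytic Ledoit–Wolf intensity, verified
against scikit-learn's covariance estimators (note scikit-learn's own
`lsqr+auto` LDA shrinks per class *before* pooling, so it is a different
estimator).  P(MI) is a logistic link on the decision value — a
calibration convenience; only p > 0.5 ⟺ w·x + b > 0 matters downstream.
Chance is the adjusted Wald interval at p₀ = 0.5 for n = 2 × n_trials
(each trial contributes one MI and one REST test observation per
repeat).

## Asynchronous evaluation

Traces cover [1, 13] s after the cue at 10 Hz with both edges included
(121 samples — the documented boundary convention); the feature window
for sample s_i is [s_i − 1, s_i], so data from the cue onward is needed.
The MI period is 3 s from the subject's MI-window start; the
true-positive window is shifted +0.5 s (trailing-edge attribution), and
detections in the first half-window count as false positives — the
strict reading of the evaluation scheme.  A detection at s_i requires
s_{i−x} … s_i all strictly above 0.5; detections are stamped at the
trailing edge.  x ∈ {5…15} maximizes validation percent-correct, ties to
the smallest x (earliest detections).  Cross-validation is 10×5-fold
with 3 training / 1 validation / 1 test folds per rotation.  Chance:
observed IOs shuffled across trials without replacement (preserving the
IO marginal — the "structured" permutation), tp windows recomputed,
fixed detections re-scored; assignments that would push a tp window
outside the evaluation period are redrawn and counted.  PLR is
TPR/FPR over sliding samples (∞ when no false positive occurs).

## Problem sizes

Defaults mirror the study conditions: 65 trials/condition (~195/session),
61+3 channels, 250 Hz simulation rate (all analysis bands are ≤ 70 Hz,
so the recorded 1 kHz would only cost time; everything is
rate-agnostic).  The test and acceptance studies use: tmax oracle at 6
pairs × 5 cells; FWER on 200 null datasets (40 pairs, 16 channels, 500
permutations); effect recovery on 50 subjects (65 pairs, 32 channels,
800 permutations); MRCP recovery on 50 subjects × 60 trials over 5
central channels; chance calibration on 20 signal-free runs of 30
trials; end-to-end cohorts of 3 subjects × 180 trials × 32 EEG channels
with 1 000 permutations and 200 bootstrap resamples.

## What passing tests do and do not show

The simulator reproduces event structure, template morphology, 1/f
spatial noise, blinks and reporting errors — not real EEG's artifact
diversity (EMG, electrode drift, saccades), non-stationarity across a
session, inter-subject morphology variability, or volume-conduction
physics (gain maps are abstract).  Synthetic separability is higher than
real data's: time-locked accuracies here sit in the 90s rather than the
80s.  Passing therefore certifies that the statistics are calibrated
(FWER, chance levels), that every rule of the procedure is implemented
as stated (window logic, consecutive-detection arithmetic, permutation
schemes), and that injected ground truth is recovered at realistic
SNR — not that any particular accuracy would be attained on recordings.

## Known limitations

* The joint-probability rejection statistic is a documented
  reimplementation, not bit-compatible with any toolbox.
* ICA on mostly-Gaussian synthetic backgrounds identifies only the
  artifact components reliably; source recovery beyond that is not
  claimed (and not needed for back-projection cleaning).
* The logistic probability link is uncalibrated (monotone only).
* `downsample_10hz` requires the sampling rate to be an integer multiple
  of 10 Hz.
* Wilcoxon variant for the IO comparison: the unpaired rank-sum is the
  default (conditions have unequal trial counts after rejection); a
  signed-rank variant on trimmed samples is provided as an option since
  the field's reports are ambiguous between the two.
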