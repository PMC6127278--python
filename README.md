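# mrcpipe

Analysis pipeline for EEG experiments on **self-paced reach-and-grasp
movement imagination (MI)**, with a synthetic-session generator that makes
every stage testable without access to recorded data.

## The problem

In a self-paced MI paradigm the participant first defines a movement
target — either freely (internally driven, *ID* / *IDII*) or dictated by
the cue (externally cued, *EC*) — and then starts a single kinesthetic
reach-and-grasp imagination whenever they want.  A scroller of 3-digit
numbers (new number every 750 ms) lets them report, Libet-style, the
moment they felt the urge to move: the display onset of the reported
number is the estimated **imagination onset (IO)**.  Two neural correlates
are analyzed:

* **Cue-locked ERPs** (0.1–15 Hz): P200, P300/P3b and a late slow wave
  over 0.6–0.8 s whose amplitude separates internally driven from
  externally cued target selection.  Conditions are compared with a paired
  two-tailed **tmax permutation test** over all channel × time cells in
  [0, 2] s after the cue: for each of N permutations the paired trial
  differences are sign-flipped, a t-statistic is computed at every cell,
  and the most extreme value t_max enters the reference distribution; a
  cell is significant when its observed t falls outside the 0.025/0.975
  quantiles of that distribution, which controls the family-wise error
  rate.
* **IO-locked MRCPs** (0.1–1 Hz): the Bereitschaftspotential-like slow
  negativity starting ~1 s before the IO, peaking near +0.5 s over
  midline central electrodes and returning to baseline by ~2 s.

MRCP amplitudes then drive single-trial **MI-vs-REST detection** with a
shrinkage-regularized LDA: w = Σ̃⁻¹(μ_MI − μ_REST), where
Σ̃ = (1−γ)Σ̂ + γν I is the pooled covariance shrunk toward a scaled
identity with the analytic (Ledoit–Wolf) intensity γ.  Features are the
10 amplitude samples of a 1 s window at 10 Hz over 26 sensorimotor
channels (260 features).  Evaluation is 10×5-fold cross-validation:

* **time-locked**: one MI window ([−1, 0] or [0, 1] s relative to the IO,
  chosen from the training folds' average MRCP peak latency at Cz) against
  one REST window ([4, 5] or [−5, −4] s); chance level is the adjusted
  Wald binomial interval;
* **asynchronous**: a 1 s window slides over a 12 s evaluation period
  (from 1 s after the cue) producing a P(MI) trace at every 10 Hz sample;
  a detection requires x+1 consecutive samples above 0.5 (x ∈ [5, 15] is
  optimized on a validation fold); a trial is *correct* iff at least one
  detection falls in the MI period (shifted +0.5 s for the trailing-edge
  window convention) and none falls outside.  Chance level comes from a
  structured permutation: the observed IOs are shuffled across trials and
  the fixed detections re-scored.

Because no public recordings exist for this paradigm, the package ships a
first-class simulator: 61-channel (configurable) sessions with the full
event structure, condition-dependent ERP templates, an MRCP template
locked to the true IO, spatially correlated 1/f background noise, blink
artifacts and invalid reports — with all ground truth retained.

## Worked example

```python
import mrcpipe as m
from mrcpipe.pipeline import run_subject, AnalysisConfig

cfg = m.SimulationConfig(trials_per_condition=15, rest_run_duration=30)
res = run_subject(cfg, subject_seed=7, cfg=AnalysisConfig(n_perm=500, n_boot=200))
for k, v in res.summary().items():
    print(k, v)
```

prints (exact values; everything is seeded):

```
subject_seed 7
n_valid_trials 43
n_removed_artifact 1
mrcp_peak_latency_s 0.8799999999999999
mrcp_peak_amplitude_uv -2.7553490906169946
timelocked_accuracy_pct 96.27976190476191
timelocked_chance_upper_pct 60.456066231458635
async_percent_correct 59.16666666666666
async_chance_pct 21.916666666666668
async_plr 20.478120588828393
erp_any_significant {'ID_vs_EC': False, 'IDII_vs_EC': False, 'ID_vs_IDII': False}
```

Reading this: of 45 simulated trials, 43 had consistent reports and 42
survived artifact rejection.  The IO-locked grand average at Cz peaks at
−2.8 µV, 0.88 s after the *estimated* IO — the template peaks at +0.5 s,
and the extra ~0.4 s is the reporting quantization (the scroller number
is shown up to 750 ms before the true urge), exactly the alignment bias
self-paced paradigms suffer.  Time-locked detection reaches 96 % against
a 60 % chance bound (small n); asynchronously 59 % of trials are detected
with no false positive, against a ~22 % structured-permutation chance.
The per-subject ERP contrast is not significant here because 14 trials
per condition give little power; at full trial counts (~60/condition) the
late-component ID-vs-EC difference is detected in >90 % of simulated
subjects.

The same chain is scriptable from the shell:

```
mrcpipe simulate --subjects 3 --seed 0 --out raw/
mrcpipe preprocess --in raw/ --out work/
mrcpipe erp --in work/ --out work/
mrcpipe mrcp --in work/ --out work/
mrcpipe classify-timelocked --in work/ --out work/
mrcpipe classify-async --in work/ --out work/
mrcpipe report --in work/
```

## Scope

Channel-space analysis only: source imaging (sLORETA, boundary-element
head models) is out of scope, as are saccade/EMG simulation and true
online (causal) processing — like the analysis it implements, the
asynchronous evaluation is an offline simulation with zero-phase filters.
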