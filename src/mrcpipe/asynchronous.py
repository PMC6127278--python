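"""Simulated-online asynchronous detection of movement imagination.

The classifier trained on 3 MI + 3 REST windows per trial is evaluated on
a 12 s period starting 1 s after the cue: a 1 s sliding window at every
10 Hz sample yields a P(MI) trace; a sample is a *detection* when it and
the previous ``x`` samples all exceed the probability threshold (``x`` is
optimized on a validation fold); a trial is *correct* when at least one
detection falls inside the true-positive window (the 3 s MI period shifted
by +0.5 s, because a window is attributed to its trailing edge) and none
falls outside it.  Chance level comes from a structured permutation: the
observed imagination onsets are shuffled across trials, the windows are
recomputed, and the unchanged detections are re-scored.

All trace times are cue-relative seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import ContinuousRecording, TrialRecord
from .detection import (
    CLASSIFIER_26,
    ShrinkageLDA,
    _fold_window_rule,
    _window_vector,
    extract_features,
    fit_slda,
    stratified_folds,
)

MI_LABEL_DURATION = 3.0  # s of each trial labeled as MI
TP_SHIFT = 0.5           # s; trailing-edge window attribution


@dataclass
class AsyncConfig:
    eval_start: float = 1.0       # s after cue
    eval_duration: float = 12.0   # s
    window_length: float = 1.0    # s sliding feature window
    prob_threshold: float = 0.5
    x_range: tuple[int, int] = (5, 15)  # inclusive
    n_perm: int = 500
    mi_label_duration: float = MI_LABEL_DURATION

    def __post_init__(self):
        if self.eval_duration <= self.mi_label_duration:
            raise ValueError("evaluation period must exceed the MI period")
        if self.x_range[0] > self.x_range[1] or self.x_range[0] < 1:
            raise ValueError("x_range must be a non-empty range of ints >= 1")

    @property
    def xs(self) -> np.ndarray:
        return np.arange(self.x_range[0], self.x_range[1] + 1)


@dataclass
class ProbabilityTrace:
    """P(MI) at every 10 Hz sample of one trial's evaluation period.

    ``times`` has ``eval_duration * 10 + 1`` entries (both period edges
    included — the documented boundary convention).
    """

    times: np.ndarray        # s relative to cue
    probs: np.ndarray
    trial_id: int
    io_rel: float            # estimated IO, s relative to cue
    mi_period: tuple[float, float]
    tp_window: tuple[float, float]

    def __post_init__(self):
        if np.any((self.probs < 0) | (self.probs > 1)):
            raise ValueError("probabilities must lie in [0, 1]")


def mi_period_for(io_rel: float, mi_start: float,
                  cfg: AsyncConfig) -> tuple[float, float]:
    return (io_rel + mi_start, io_rel + mi_start + cfg.mi_label_duration)


def sliding_probability_trace(
    model: ShrinkageLDA,
    rec10: ContinuousRecording,
    trial: TrialRecord,
    mi_start: float,
    cfg: AsyncConfig | None = None,
    channel_set: tuple[str, ...] = CLASSIFIER_26,
) -> ProbabilityTrace:
    """Sliding-window P(MI) over the trial's evaluation period.

    At each sample ``s_i`` the features come from the window
    ``[s_i - 1, s_i]``, so data from ``eval_start - window_length`` after
    the cue must exist.
    """
    if cfg is None:
        cfg = AsyncConfig()
    fs = rec10.fs
    n = int(round(cfg.eval_duration * fs)) + 1
    rel_times = cfg.eval_start + np.arange(n) / fs
    ch_idx = np.array([rec10.channel_index(l) for l in channel_set])
    feats = []
    for t in rel_times:
        vec = _window_vector(rec10, ch_idx,
                             trial.cue_time + t - cfg.window_length)
        if vec is None:
            raise ValueError("trial segment shorter than the evaluation period")
        feats.append(vec)
    probs = model.predict_proba(np.asarray(feats))
    io_rel = trial.io_time - trial.cue_time
    mi = mi_period_for(io_rel, mi_start, cfg)
    return ProbabilityTrace(
        times=rel_times, probs=probs, trial_id=trial.index, io_rel=io_rel,
        mi_period=mi, tp_window=(mi[0] + TP_SHIFT, mi[1] + TP_SHIFT),
    )


def build_async_training_set(
    rec10: ContinuousRecording,
    trials: list[TrialRecord],
    mi_start: float,
    channel_set: tuple[str, ...] = CLASSIFIER_26,
):
    """Three consecutive MI and REST windows per trial (6 observations)."""
    return extract_features(rec10, trials, mi_start, channel_set, n_windows=3)


def apply_consecutive_rule(
    probs: np.ndarray, x: int, threshold: float = 0.5
) -> np.ndarray:
    """Indices i where samples i-x .. i are all strictly above threshold."""
    if x < 1:
        raise ValueError("x must be >= 1")
    above = np.asarray(probs) > threshold
    run = x + 1  # the sample itself plus the previous x
    if above.size < run:
        return np.array([], dtype=int)
    csum = np.concatenate(([0], np.cumsum(above)))
    window_sums = csum[run:] - csum[:-run]
    return np.flatnonzero(window_sums == run) + x


@dataclass
class TrialVerdict:
    trial_id: int
    n_tp: int
    n_fp: int

    @property
    def correct(self) -> bool:
        return self.n_tp >= 1 and self.n_fp == 0


def evaluate_trial(
    detection_times: np.ndarray, tp_window: tuple[float, float],
    trial_id: int = -1,
) -> TrialVerdict:
    """TP = detection inside the (closed) tp window, FP = outside."""
    detection_times = np.asarray(detection_times, dtype=float)
    inside = (detection_times >= tp_window[0] - 1e-9) & (
        detection_times <= tp_window[1] + 1e-9)
    return TrialVerdict(trial_id=trial_id, n_tp=int(inside.sum()),
                        n_fp=int((~inside).sum()))


def _percent_correct(traces: list[ProbabilityTrace], x: int,
                     threshold: float) -> float:
    ok = 0
    for tr in traces:
        det = tr.times[apply_consecutive_rule(tr.probs, x, threshold)]
        if evaluate_trial(det, tr.tp_window, tr.trial_id).correct:
            ok += 1
    return 100.0 * ok / len(traces)


def optimize_consecutive(
    traces: list[ProbabilityTrace], cfg: AsyncConfig | None = None
) -> int:
    """x* maximizing validation percent-correct; ties go to the smallest x
    (faster detections)."""
    if cfg is None:
        cfg = AsyncConfig()
    if not traces:
        raise ValueError("empty validation set")
    best_x, best = None, -1.0
    for x in cfg.xs:
        pc = _percent_correct(traces, int(x), cfg.prob_threshold)
        if pc > best:
            best, best_x = pc, int(x)
    return best_x


@dataclass
class _Evaluation:
    """One test-trial evaluation kept for chance permutation re-scoring."""

    trial_id: int
    io_rel: float
    mi_start: float
    detections: np.ndarray  # cue-relative times


@dataclass
class AsyncResult:
    percent_correct: float
    percent_correct_sd: float
    chosen_x: list[int]
    plr: float
    chance_level: float | None
    verdicts: list[TrialVerdict]
    n_trials: int
    fold_percent_correct: np.ndarray
    evaluations: list[_Evaluation] = field(default_factory=list)
    infeasible_redraws: int = 0


def chance_by_permutation(
    evaluations: list[_Evaluation],
    cfg: AsyncConfig | None = None,
    n_perm: int = 500,
    seed: int = 0,
) -> tuple[float, int]:
    """Structured-permutation chance: shuffle the observed IOs across
    trials (without replacement), recompute the tp windows, and re-score
    the fixed detections.  Returns (chance percent, infeasible redraws).

    A permutation is redrawn (and counted) when an assigned IO would push
    a trial's tp window outside the evaluation period.
    """
    if cfg is None:
        cfg = AsyncConfig()
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    ios = np.array([e.io_rel for e in evaluations])
    lo = cfg.eval_start
    hi = cfg.eval_start + cfg.eval_duration
    redraws = 0
    pcs = np.empty(n_perm)
    for p in range(n_perm):
        for _attempt in range(100):
            perm = rng.permutation(ios)
            feas = True
            for e, io in zip(evaluations, perm):
                a, b = mi_period_for(io, e.mi_start, cfg)
                if a + TP_SHIFT < lo - 1e-9 or b + TP_SHIFT > hi + 1e-9:
                    feas = False
                    break
            if feas:
                break
            redraws += 1
        ok = 0
        for e, io in zip(evaluations, perm):
            a, b = mi_period_for(io, e.mi_start, cfg)
            v = evaluate_trial(e.detections, (a + TP_SHIFT, b + TP_SHIFT))
            if v.correct:
                ok += 1
        pcs[p] = 100.0 * ok / len(evaluations)
    return float(pcs.mean()), redraws


def async_crossvalidate(
    rec10: ContinuousRecording,
    trials: list[TrialRecord],
    channel_set: tuple[str, ...] = CLASSIFIER_26,
    repeats: int = 10,
    folds: int = 5,
    seed: int = 0,
    cfg: AsyncConfig | None = None,
    cz: str = "Cz",
    compute_chance: bool = True,
) -> AsyncResult:
    """10 x 5-fold asynchronous evaluation: per repeat and fold, 3 folds
    train the classifier, 1 validation fold picks the consecutive-detection
    parameter x, and 1 fold is scored trial-by-trial."""
    if cfg is None:
        cfg = AsyncConfig()
    usable = [tr for tr in trials if tr.valid and tr.io_time is not None]
    if len(usable) < folds:
        raise ValueError("too few trials")
    rng = np.random.default_rng(seed)
    cond = np.array([tr.condition for tr in usable])

    fold_pc, chosen, verdicts, evaluations = [], [], [], []
    tp_hits = tp_total = fp_hits = fp_total = 0
    for _ in range(repeats):
        fold_idx = stratified_folds(cond, folds, rng)
        for f in range(folds):
            test_pos = fold_idx[f]
            val_pos = fold_idx[(f + 1) % folds]
            train_pos = np.concatenate(
                [fold_idx[g] for g in range(folds)
                 if g != f and g != (f + 1) % folds])
            train = [usable[i] for i in train_pos]
            val = [usable[i] for i in val_pos]
            test = [usable[i] for i in test_pos]

            mi_start = _fold_window_rule(rec10, train, cz)
            feats = build_async_training_set(rec10, train, mi_start, channel_set)
            model = fit_slda(feats.X, feats.y)

            val_traces = [sliding_probability_trace(model, rec10, tr, mi_start,
                                                    cfg, channel_set)
                          for tr in val]
            x_star = optimize_consecutive(val_traces, cfg)
            chosen.append(x_star)

            ok = 0
            for tr in test:
                trace = sliding_probability_trace(model, rec10, tr, mi_start,
                                                  cfg, channel_set)
                det = trace.times[apply_consecutive_rule(
                    trace.probs, x_star, cfg.prob_threshold)]
                v = evaluate_trial(det, trace.tp_window, tr.index)
                verdicts.append(v)
                ok += v.correct
                evaluations.append(_Evaluation(
                    trial_id=tr.index, io_rel=trace.io_rel,
                    mi_start=mi_start, detections=det))
                in_tp = (trace.times >= trace.tp_window[0] - 1e-9) & (
                    trace.times <= trace.tp_window[1] + 1e-9)
                det_mask = np.zeros(trace.times.size, dtype=bool)
                det_mask[apply_consecutive_rule(trace.probs, x_star,
                                                cfg.prob_threshold)] = True
                tp_hits += int(np.sum(det_mask & in_tp))
                tp_total += int(np.sum(in_tp))
                fp_hits += int(np.sum(det_mask & ~in_tp))
                fp_total += int(np.sum(~in_tp))
            fold_pc.append(100.0 * ok / len(test))

    fold_pc = np.asarray(fold_pc)
    tpr = tp_hits / tp_total if tp_total else np.nan
    fpr = fp_hits / fp_total if fp_total else np.nan
    plr = tpr / fpr if fpr and fpr > 0 else np.inf

    chance = None
    redraws = 0
    if compute_chance:
        chance, redraws = chance_by_permutation(
            evaluations, cfg, cfg.n_perm, seed=seed + 1)
    return AsyncResult(
        percent_correct=float(fold_pc.mean()),
        percent_correct_sd=float(fold_pc.std(ddof=1)),
        chosen_x=chosen,
        plr=float(plr),
        chance_level=chance,
        verdicts=verdicts,
        n_trials=len(usable),
        fold_percent_correct=fold_pc,
        evaluations=evaluations,
        infeasible_redraws=redraws,
    )
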