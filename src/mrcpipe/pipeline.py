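"""End-to-end per-subject analysis: simulate → clean → ERP → MRCP → detect.

This is the glue the CLI and the acceptance script drive; every stage is a
thin call into the corresponding module, with the intermediate products
kept on the result object for inspection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import asynchronous as async_mod
from . import detection, erp, events, mrcp, preprocess
from .containers import ContinuousRecording, EpochSet, TrialRecord
from .montage import CLASSIFIER_26
from .simulate import SimulationConfig, generate_session


@dataclass
class AnalysisConfig:
    erp_window: tuple[float, float] = (-0.5, 2.0)   # s around cue
    erp_test_window: tuple[float, float] = (0.0, 2.0)
    mrcp_window: tuple[float, float] = (-3.0, 3.0)  # s around IO
    n_perm: int = 2000
    n_boot: int = 300
    cv_repeats: int = 10
    cv_folds: int = 5
    channel_set: tuple[str, ...] = CLASSIFIER_26
    mrcp_channel: str = "Cz"
    async_cfg: async_mod.AsyncConfig = field(default_factory=async_mod.AsyncConfig)
    seed: int = 0


@dataclass
class SubjectResult:
    subject_seed: int
    trials: list[TrialRecord]
    cleaned: preprocess.CleanedSession
    erp_tests: dict[tuple[str, str], erp.PermTestResult]
    io_comparison: pd.DataFrame
    mrcp_avg: erp.BootstrapCI
    mrcp_epochs: EpochSet
    mrcp_peak: mrcp.PeakNegativity
    timelocked: detection.TimeLockedResult
    asynchronous: async_mod.AsyncResult

    def summary(self) -> dict:
        return {
            "subject_seed": self.subject_seed,
            "n_valid_trials": sum(bool(t.valid) for t in self.trials),
            "n_removed_artifact": int(self.cleaned.artifact_report.removed_mask.sum()),
            "mrcp_peak_latency_s": self.mrcp_peak.latency,
            "mrcp_peak_amplitude_uv": self.mrcp_peak.amplitude,
            "timelocked_accuracy_pct": self.timelocked.accuracy,
            "timelocked_chance_upper_pct": self.timelocked.chance_interval[1],
            "async_percent_correct": self.asynchronous.percent_correct,
            "async_chance_pct": self.asynchronous.chance_level,
            "async_plr": self.asynchronous.plr,
            "erp_any_significant": {
                f"{a}_vs_{b}": bool(t.significance_mask.any())
                for (a, b), t in self.erp_tests.items()
            },
        }


def run_subject(
    sim_cfg: SimulationConfig,
    subject_seed: int,
    pre_cfg: preprocess.PreprocessConfig | None = None,
    cfg: AnalysisConfig | None = None,
) -> SubjectResult:
    if cfg is None:
        cfg = AnalysisConfig()
    rec, trials = generate_session(sim_cfg, subject_seed)
    return analyze_session(rec, trials, subject_seed, pre_cfg, cfg)


def analyze_session(
    rec: ContinuousRecording,
    trials: list[TrialRecord],
    subject_seed: int = 0,
    pre_cfg: preprocess.PreprocessConfig | None = None,
    cfg: AnalysisConfig | None = None,
) -> SubjectResult:
    if cfg is None:
        cfg = AnalysisConfig()

    # behavior: validity, IO estimation, condition comparison
    events.estimate_all_io(trials)
    valid = [t for t in trials if t.valid]
    io_cmp = events.compare_io_conditions(trials)

    # cleaning
    windows = np.array([[t.index, t.trial_start, t.trial_end] for t in valid])
    cleaned = preprocess.preprocess_session(rec, windows, pre_cfg)
    kept = set(cleaned.kept_trial_indices.tolist())
    analysis_trials = [t for t in valid if t.index in kept]

    base = cleaned.recording
    seed = cfg.seed + subject_seed

    # cue-locked ERP statistics (0.1-15 Hz)
    erp_rec = base.copy_with(
        preprocess.bandpass_array(base.data, base.fs, *erp.ERP_BAND, axis=0))
    eeg_labels = [l for l, t in zip(base.channel_labels, base.channel_types)
                  if t == "EEG"]
    by_cond: dict[str, EpochSet] = {}
    for cond in TrialRecord.CONDITIONS:
        cues = np.array([t.cue_time for t in analysis_trials
                         if t.condition == cond])
        idx = np.array([t.index for t in analysis_trials
                        if t.condition == cond])
        by_cond[cond] = events.epoch(erp_rec, cues, cfg.erp_window,
                                     lock="cue", trial_indices=idx,
                                     channel_labels=eeg_labels)
    erp_tests = {}
    for a, b in (("ID", "EC"), ("IDII", "EC"), ("ID", "IDII")):
        n = min(by_cond[a].n_trials, by_cond[b].n_trials)
        erp_tests[(a, b)] = erp.tmax_permutation_test(
            by_cond[a].select_trials(np.arange(n)),
            by_cond[b].select_trials(np.arange(n)),
            n_perm=cfg.n_perm, seed=seed,
            window=cfg.erp_test_window,
        )

    # IO-locked MRCP (0.1-1 Hz)
    mrcp_rec = base.copy_with(
        preprocess.bandpass_array(base.data, base.fs, *mrcp.MRCP_BAND, axis=0))
    ios = np.array([t.io_time for t in analysis_trials])
    io_idx = np.array([t.index for t in analysis_trials])
    mrcp_epochs = events.epoch(mrcp_rec, ios, cfg.mrcp_window, lock="IO",
                               trial_indices=io_idx,
                               channel_labels=eeg_labels)
    mrcp_avg = mrcp.mrcp_average(mrcp_epochs, n_boot=cfg.n_boot, seed=seed)
    cz = mrcp_epochs.channel_index(cfg.mrcp_channel)
    peak = mrcp.find_peak_negativity(
        mrcp_avg.mean[cz], mrcp_epochs.times, channel=cfg.mrcp_channel,
        ci=(mrcp_avg.lower[cz], mrcp_avg.upper[cz]))

    # detection (0.1-1 Hz, 10 Hz feature rate)
    rec10 = detection.prepare_detection_recording(base)
    timelocked = detection.crossvalidate_timelocked(
        rec10, analysis_trials, cfg.channel_set,
        repeats=cfg.cv_repeats, folds=cfg.cv_folds, seed=seed,
        cz=cfg.mrcp_channel)
    asy = async_mod.async_crossvalidate(
        rec10, analysis_trials, cfg.channel_set,
        repeats=cfg.cv_repeats, folds=cfg.cv_folds, seed=seed,
        cfg=cfg.async_cfg, cz=cfg.mrcp_channel)

    return SubjectResult(
        subject_seed=subject_seed,
        trials=trials,
        cleaned=cleaned,
        erp_tests=erp_tests,
        io_comparison=io_cmp,
        mrcp_avg=mrcp_avg,
        mrcp_epochs=mrcp_epochs,
        mrcp_peak=peak,
        timelocked=timelocked,
        asynchronous=asy,
    )


def cohort_report(results: list[SubjectResult]) -> pd.DataFrame:
    """One row per subject with the headline metrics."""
    rows = []
    for r in results:
        s = r.summary()
        s.pop("erp_any_significant")
        rows.append(s)
    return pd.DataFrame(rows)
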