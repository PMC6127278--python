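"""Time-locked single-trial detection of movement imagination (MI vs REST).

Features are MRCP amplitudes: the cleaned EEG is band-passed 0.1-1 Hz,
anti-alias filtered and downsampled to 10 Hz, and each observation is the
concatenation of the 10 samples of a 1 s window over 26 sensorimotor
channels (260 features).  Windows are chosen per subject from the training
folds only:

* MI window: the training-average MRCP at Cz is searched for its peak
  negativity in [-2, 2] s; a peak before 0.5 s puts the MI window at
  [-1, 0] s, otherwise at [0, 1] s,
* REST window: [4, 5] s after the IO when it fits inside the trial,
  otherwise [-5, -4] s.

The classifier is a shrinkage-regularized LDA (pooled covariance shrunk
toward a scaled identity with an analytically estimated intensity), the
standard approach when features outnumber observations.  Chance level is
the adjusted Wald binomial interval at p0 = 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats

from .containers import ContinuousRecording, TrialRecord
from .events import epoch
from .montage import CLASSIFIER_26
from .mrcp import MRCP_BAND, find_peak_negativity
from .preprocess import bandpass_array

FEATURE_FS = 10.0        # Hz after downsampling
ANTI_ALIAS_HZ = 4.0      # corner of the zero-phase anti-aliasing low-pass
MI_LATENCY_CUT = 0.5     # s; peak before this => MI window starts at -1 s
WINDOW_LEN = 1.0         # s per feature window


# ---------------------------------------------------------------------------
# rate reduction


def downsample_10hz(rec: ContinuousRecording) -> ContinuousRecording:
    """Zero-phase anti-alias low-pass (4 Hz) followed by decimation to 10 Hz."""
    factor = rec.fs / FEATURE_FS
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError("sampling rate must be an integer multiple of 10 Hz")
    factor = int(round(factor))
    sos = signal.butter(4, ANTI_ALIAS_HZ, btype="low", fs=rec.fs, output="sos")
    low = signal.sosfiltfilt(sos, rec.data, axis=0)
    out = rec.copy_with(low[::factor].copy())
    out.fs = FEATURE_FS
    return out


def prepare_detection_recording(
    cleaned: ContinuousRecording, band: tuple[float, float] = MRCP_BAND
) -> ContinuousRecording:
    """0.1-1 Hz band-pass at the native rate, then downsample to 10 Hz."""
    filt = cleaned.copy_with(bandpass_array(cleaned.data, cleaned.fs,
                                            *band, axis=0))
    return downsample_10hz(filt)


# ---------------------------------------------------------------------------
# window rules


def select_mi_window(avg_cz: np.ndarray, times: np.ndarray) -> float:
    """MI-window start (-1.0 or 0.0 s) from the training-average Cz MRCP.

    The rule is strict: only a peak-negativity latency strictly before
    0.5 s selects the early [-1, 0] s window.
    """
    pk = find_peak_negativity(avg_cz, times, window=(-2.0, 2.0))
    return -1.0 if pk.latency < MI_LATENCY_CUT else 0.0


def select_rest_window(io_time: float, trial_end: float) -> tuple[float, float]:
    """REST window (s relative to IO): [4, 5] while it fits, else [-5, -4]."""
    if io_time + 5.0 <= trial_end + 1e-9:
        return (4.0, 5.0)
    return (-5.0, -4.0)


# ---------------------------------------------------------------------------
# features


@dataclass
class FeatureSet:
    X: np.ndarray             # observations x (n_channels * 10)
    y: np.ndarray             # 1 = MI, 0 = REST
    trial_id: np.ndarray
    window_start: np.ndarray  # s relative to IO
    channel_labels: list[str]
    skipped: list[tuple[int, float]] = field(default_factory=list)


def _window_vector(rec10: ContinuousRecording, ch_idx: np.ndarray,
                   t_start: float) -> np.ndarray | None:
    """260-feature vector of the 1 s window starting at absolute ``t_start``."""
    n = int(round(WINDOW_LEN * rec10.fs))
    i0 = int(round(t_start * rec10.fs))
    if i0 < 0 or i0 + n > rec10.n_samples:
        return None
    return rec10.data[i0 : i0 + n, ch_idx].T.ravel()  # channel-major


def extract_features(
    rec10: ContinuousRecording,
    trials: list[TrialRecord],
    mi_start: float,
    channel_set: tuple[str, ...] = CLASSIFIER_26,
    n_windows: int = 1,
) -> FeatureSet:
    """MI and REST observations for ``trials``.

    ``n_windows`` consecutive 1 s windows are taken per class and trial
    (1 for time-locked, 3 for the asynchronous training set); the first MI
    window starts at ``mi_start`` and the first REST window at the
    trial-dependent REST rule.  Out-of-bounds windows are skipped and
    recorded in ``skipped``.
    """
    ch_idx = np.array([rec10.channel_index(l) for l in channel_set])
    rows, ys, tid, wst, skipped = [], [], [], [], []
    for tr in trials:
        if tr.io_time is None:
            continue
        rest_start = select_rest_window(tr.io_time, tr.trial_end)[0]
        for k in range(n_windows):
            for label, start in ((1, mi_start + k), (0, rest_start + k)):
                t0 = tr.io_time + start
                vec = _window_vector(rec10, ch_idx, t0)
                inside_trial = (t0 >= tr.trial_start - 1e-9
                                and t0 + WINDOW_LEN <= tr.trial_end + 1e-9)
                if vec is None or not inside_trial:
                    skipped.append((tr.index, start))
                    continue
                rows.append(vec)
                ys.append(label)
                tid.append(tr.index)
                wst.append(start)
    if not rows:
        raise ValueError("no feature windows could be extracted")
    return FeatureSet(
        X=np.asarray(rows), y=np.asarray(ys, dtype=int),
        trial_id=np.asarray(tid, dtype=int), window_start=np.asarray(wst),
        channel_labels=list(channel_set), skipped=skipped,
    )


# ---------------------------------------------------------------------------
# shrinkage LDA


def ledoit_wolf_gamma(xc: np.ndarray) -> float:
    """Analytic shrinkage intensity toward nu*I for centered data ``xc``."""
    n, d = xc.shape
    s = xc.T @ xc / n
    nu = np.trace(s) / d
    target_dist = np.sum((s - nu * np.eye(d)) ** 2)
    if target_dist <= 0:
        return 0.0
    sq_norms = np.einsum("ij,ij->i", xc, xc)
    xsx = np.einsum("ij,ij->i", xc @ s, xc)
    num = (np.sum(sq_norms**2) - 2.0 * np.sum(xsx) + n * np.sum(s**2)) / n**2
    return float(np.clip(num / target_dist, 0.0, 1.0))


@dataclass
class ShrinkageLDA:
    """Binary LDA with the pooled covariance shrunk toward a scaled identity.

    ``shrinkage=None`` estimates the intensity gamma analytically
    (Ledoit-Wolf) from the training data; a float in [0, 1] forces it.
    The decision value is ``w . x + b`` with the bias at the class-mean
    midpoint; ``predict_proba`` applies a logistic link, so p > 0.5 iff the
    decision value is positive.
    """

    shrinkage: float | None = None
    weights: np.ndarray | None = None
    bias: float | None = None
    gamma_: float | None = None
    class_means_: np.ndarray | None = None
    pooled_covariance_: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ShrinkageLDA":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError("ShrinkageLDA requires exactly two classes")
        m0 = X[y == classes[0]].mean(axis=0)
        m1 = X[y == classes[1]].mean(axis=0)
        xc = X.copy()
        xc[y == classes[0]] -= m0
        xc[y == classes[1]] -= m1
        n, d = xc.shape
        gamma = (ledoit_wolf_gamma(xc) if self.shrinkage is None
                 else float(self.shrinkage))
        if not 0 <= gamma <= 1:
            raise ValueError("shrinkage must lie in [0, 1]")
        s = xc.T @ xc / n
        nu = np.trace(s) / d
        sigma = (1.0 - gamma) * s + gamma * nu * np.eye(d)
        diff = m1 - m0
        if gamma == 1.0:
            w = diff / nu if nu > 0 else diff
        else:
            w = np.linalg.solve(sigma, diff)
        self.weights = w
        self.bias = float(-w @ (m0 + m1) / 2.0)
        self.gamma_ = float(gamma)
        self.class_means_ = np.vstack([m0, m1])
        self.pooled_covariance_ = sigma
        return self

    def decision_value(self, X: np.ndarray) -> np.ndarray:
        if self.weights is None:
            raise ValueError("model is not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.weights.size:
            raise ValueError("feature dimension mismatch")
        return X @ self.weights + self.bias

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """P(MI) via a logistic link on the decision value."""
        z = self.decision_value(X)
        return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.decision_value(X) > 0).astype(int)


def fit_slda(X: np.ndarray, y: np.ndarray,
             shrinkage: float | None = None) -> ShrinkageLDA:
    return ShrinkageLDA(shrinkage=shrinkage).fit(X, y)


# ---------------------------------------------------------------------------
# chance level and cross-validation


def adjusted_wald_interval(
    n: int, alpha: float = 0.05, p0: float = 0.5
) -> tuple[float, float]:
    """Adjusted Wald binomial interval around ``p0`` for ``n`` observations."""
    if n < 1:
        raise ValueError("n must be >= 1")
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    p_tilde = (n * p0 + z**2 / 2.0) / (n + z**2)
    half = z * np.sqrt(p_tilde * (1.0 - p_tilde) / (n + z**2))
    return (max(0.0, p_tilde - half), min(1.0, p_tilde + half))


def stratified_folds(
    labels: np.ndarray, n_folds: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Random fold assignment balanced within each stratum; returns
    per-fold arrays of trial positions."""
    labels = np.asarray(labels)
    assignment = np.empty(labels.size, dtype=int)
    for stratum in np.unique(labels):
        idx = np.flatnonzero(labels == stratum)
        idx = rng.permutation(idx)
        assignment[idx] = np.arange(idx.size) % n_folds
    return [np.flatnonzero(assignment == f) for f in range(n_folds)]


@dataclass
class TimeLockedResult:
    accuracy: float      # percent, mean over folds
    accuracy_sd: float
    tpr: float
    tpr_sd: float
    fpr: float
    fpr_sd: float
    tnr: float
    tnr_sd: float
    fnr: float
    fnr_sd: float
    chance_interval: tuple[float, float]  # percent
    n_trials: int
    mi_window_start_per_fold: list[float]
    fold_accuracies: np.ndarray


def _fold_window_rule(rec10: ContinuousRecording, train_trials, cz: str) -> float:
    ios = np.array([tr.io_time for tr in train_trials])
    ep = epoch(rec10, ios, (-2.0, 2.0 + 1.0 / rec10.fs), lock="IO",
               channel_labels=[cz])
    avg = ep.data[:, 0, :].mean(axis=0)
    return select_mi_window(avg, ep.times)


def crossvalidate_timelocked(
    rec10: ContinuousRecording,
    trials: list[TrialRecord],
    channel_set: tuple[str, ...] = CLASSIFIER_26,
    repeats: int = 10,
    folds: int = 5,
    seed: int = 0,
    cz: str = "Cz",
) -> TimeLockedResult:
    """10 x 5-fold cross-validated MI-vs-REST classification.

    Folds are trial-level and stratified by condition; the MI-window rule
    and the classifier are re-fit inside every training split (no leakage).
    Rates are averaged over all repeat x fold evaluations; the chance
    interval is the adjusted Wald interval for the per-repeat number of
    test observations (2 per trial).
    """
    usable = [tr for tr in trials if tr.valid and tr.io_time is not None]
    counts = {c: sum(tr.condition == c for tr in usable)
              for c in TrialRecord.CONDITIONS}
    if min(counts.values(), default=0) < folds:
        raise ValueError("need at least `folds` trials per condition")
    rng = np.random.default_rng(seed)
    cond = np.array([tr.condition for tr in usable])

    acc, tprs, fprs, starts = [], [], [], []
    for _ in range(repeats):
        fold_idx = stratified_folds(cond, folds, rng)
        for f in range(folds):
            test_pos = fold_idx[f]
            train_pos = np.concatenate([fold_idx[g] for g in range(folds)
                                        if g != f])
            train = [usable[i] for i in train_pos]
            test = [usable[i] for i in test_pos]
            mi_start = _fold_window_rule(rec10, train, cz)
            starts.append(mi_start)
            ftr = extract_features(rec10, train, mi_start, channel_set)
            fte = extract_features(rec10, test, mi_start, channel_set)
            model = fit_slda(ftr.X, ftr.y)
            pred = model.predict(fte.X)
            mi, rest = fte.y == 1, fte.y == 0
            acc.append(np.mean(pred == fte.y))
            tprs.append(np.mean(pred[mi] == 1) if mi.any() else np.nan)
            fprs.append(np.mean(pred[rest] == 1) if rest.any() else np.nan)

    acc = np.asarray(acc) * 100.0
    tprs = np.asarray(tprs) * 100.0
    fprs = np.asarray(fprs) * 100.0
    lo, hi = adjusted_wald_interval(2 * len(usable))
    return TimeLockedResult(
        accuracy=float(np.mean(acc)), accuracy_sd=float(np.std(acc, ddof=1)),
        tpr=float(np.nanmean(tprs)), tpr_sd=float(np.nanstd(tprs, ddof=1)),
        fpr=float(np.nanmean(fprs)), fpr_sd=float(np.nanstd(fprs, ddof=1)),
        tnr=float(100.0 - np.nanmean(fprs)), tnr_sd=float(np.nanstd(fprs, ddof=1)),
        fnr=float(100.0 - np.nanmean(tprs)), fnr_sd=float(np.nanstd(tprs, ddof=1)),
        chance_interval=(lo * 100.0, hi * 100.0),
        n_trials=len(usable),
        mi_window_start_per_fold=starts,
        fold_accuracies=acc,
    )
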