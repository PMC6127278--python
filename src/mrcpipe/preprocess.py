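"""Cleaning of continuous recordings.

Processing order mirrors the offline pipeline of the study design:

1. remove bad channels (robust amplitude-scale criterion plus overrides),
2. notch filter (50 Hz),
3. copy A: 1-70 Hz zero-phase band-pass, epoched per trial, trial-based
   artifact rejection (amplitude, joint probability, kurtosis) and
   PCA (99 % variance) + extended-Infomax ICA fit on the surviving epochs,
4. copy B: the notch-only data, from which the non-artifact independent
   components are back-projected into channel space ("cleaned EEG"),
   rest runs included.

Component marking, done visually in practice, is automated here by
correlating component activations with the EOG channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal

from .containers import ContinuousRecording, EpochSet

N_JP_BINS = 100  # histogram bins of the joint-probability statistic


# ---------------------------------------------------------------------------
# filters


def _apply_sos_zero_phase(data: np.ndarray, sos: np.ndarray) -> np.ndarray:
    return signal.sosfiltfilt(sos, data, axis=0)


def notch_filter(rec: ContinuousRecording, f0: float = 50.0,
                 quality: float = 30.0) -> ContinuousRecording:
    """Zero-phase IIR notch at ``f0`` (power-line removal)."""
    if f0 >= rec.fs / 2:
        raise ValueError("notch frequency must be below Nyquist")
    b, a = signal.iirnotch(f0, quality, fs=rec.fs)
    out = signal.filtfilt(b, a, rec.data, axis=0)
    return rec.copy_with(out)


def butter_bandpass_zero_phase(
    rec: ContinuousRecording, low: float, high: float, order: int = 4
) -> ContinuousRecording:
    """Forward-backward Butterworth band-pass of the stated per-pass order."""
    if not 0 < low < high < rec.fs / 2:
        raise ValueError("need 0 < low < high < Nyquist")
    sos = signal.butter(order, [low, high], btype="bandpass",
                        fs=rec.fs, output="sos")
    return rec.copy_with(_apply_sos_zero_phase(rec.data, sos))


def bandpass_array(x: np.ndarray, fs: float, low: float, high: float,
                   order: int = 4, axis: int = -1) -> np.ndarray:
    """Zero-phase Butterworth band-pass on a bare array."""
    sos = signal.butter(order, [low, high], btype="bandpass",
                        fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x, axis=axis)


# ---------------------------------------------------------------------------
# bad channels


def detect_bad_channels(
    rec: ContinuousRecording,
    n_robust_sd: float = 5.0,
    manual: Sequence[str] = (),
) -> list[str]:
    """Channels whose amplitude scale is a robust outlier, plus overrides.

    Each channel's scale is the median absolute deviation of its samples
    (so sparse transients such as blinks barely move it), computed over the
    rest runs when present, otherwise over the whole recording.  A channel
    is bad when its scale deviates more than ``n_robust_sd`` robust SDs
    (1.4826 * MAD) from the median EEG-channel scale.
    """
    rest = rec.events.of_label("rest_run_start")
    if len(rest):
        segments = []
        for _, row in rest.iterrows():
            i0 = int(round(row["onset_s"] * rec.fs))
            i1 = int(round((row["onset_s"] + row["duration_s"]) * rec.fs))
            segments.append(rec.data[i0 : min(i1, rec.n_samples)])
        x = np.vstack(segments)
    else:
        x = rec.data
    scales = np.median(np.abs(x - np.median(x, axis=0)), axis=0)
    eeg = rec.eeg_indices
    v = scales[eeg]
    med = np.median(v)
    mad = np.median(np.abs(v - med)) * 1.4826
    bad = set(manual)
    # the MAD flag alone is too eager when channel scales are homogeneous
    # (tiny MAD); additionally require a 2x scale ratio, so that moderate
    # wide-spread physiological activity is left to the ICA stage
    if mad > 0:
        for i, vi in zip(eeg, v):
            if (abs(vi - med) > n_robust_sd * mad
                    and (vi > 2.0 * med or vi < med / 2.0)):
                bad.add(rec.channel_labels[i])
    return sorted(bad & set(rec.channel_labels))


# ---------------------------------------------------------------------------
# trial-based artifact rejection


@dataclass
class ArtifactReport:
    amplitude_exceeded: np.ndarray        # bool per trial
    abnormal_joint_probability: np.ndarray
    abnormal_kurtosis: np.ndarray
    amp_limit: float
    sd_thresh: float
    trial_indices: np.ndarray

    @property
    def removed_mask(self) -> np.ndarray:
        return (self.amplitude_exceeded
                | self.abnormal_joint_probability
                | self.abnormal_kurtosis)

    @property
    def removed_trial_indices(self) -> np.ndarray:
        return self.trial_indices[self.removed_mask]


def _flag_outliers(stat: np.ndarray, sd_thresh: float) -> np.ndarray:
    """Two-sided >sd_thresh-SD outliers per column; zero-SD columns never flag.

    ``stat`` is trials x channels (or trials x 1 for an aggregate).
    """
    mu = stat.mean(axis=0)
    sd = stat.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (stat - mu) / sd, 0.0)
    return np.any(np.abs(z) > sd_thresh, axis=1)


def detect_artifact_trials(
    epochs: EpochSet, amp_limit: float = 200.0, sd_thresh: float = 5.0
) -> ArtifactReport:
    """Trial-based artifact flags on 1-70 Hz band-passed, trial-locked epochs.

    * amplitude: any sample outside +-``amp_limit`` microvolts;
    * joint probability: per channel, the mean negative log-likelihood of
      the trial's samples under the empirical (100-bin histogram)
      distribution pooled over trials; flagged if the statistic deviates
      more than ``sd_thresh`` across-trial SDs on any channel or on the
      all-channel mean;
    * kurtosis: same outlier rule applied to the per-trial, per-channel
      sample kurtosis.
    """
    x = epochs.data  # trials x channels x samples
    n_trials, n_ch, _ = x.shape
    if n_trials < 3:
        raise ValueError("artifact statistics need at least 3 trials")

    amp = np.any(np.abs(x) > amp_limit, axis=(1, 2))

    jp = np.empty((n_trials, n_ch))
    for c in range(n_ch):
        pooled = x[:, c, :].ravel()
        counts, edges = np.histogram(pooled, bins=N_JP_BINS)
        p = counts / counts.sum()
        p = np.clip(p, 1e-12, None)
        idx = np.clip(np.searchsorted(edges, x[:, c, :], side="right") - 1,
                      0, N_JP_BINS - 1)
        jp[:, c] = -np.log(p[idx]).mean(axis=1)
    jp_stat = np.hstack([jp, jp.mean(axis=1, keepdims=True)])
    jp_flag = _flag_outliers(jp_stat, sd_thresh)

    # manual moment computation (scipy.stats.kurtosis is ~30x slower here)
    mean = x.mean(axis=2, keepdims=True)
    xc = x - mean
    x2 = xc * xc
    m2 = x2.mean(axis=2)
    m4 = (x2 * x2).mean(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        kur = np.where(m2 > 0, m4 / np.where(m2 > 0, m2, 1.0) ** 2 - 3.0, 0.0)
    kur_stat = np.hstack([kur, kur.mean(axis=1, keepdims=True)])
    kur_flag = _flag_outliers(kur_stat, sd_thresh)

    return ArtifactReport(
        amplitude_exceeded=amp,
        abnormal_joint_probability=jp_flag,
        abnormal_kurtosis=kur_flag,
        amp_limit=amp_limit,
        sd_thresh=sd_thresh,
        trial_indices=epochs.trial_indices.copy(),
    )


# ---------------------------------------------------------------------------
# PCA + ICA


@dataclass
class PCAReduction:
    mean: np.ndarray                 # per-channel mean of the fit data
    basis: np.ndarray                # channels x components, orthonormal
    explained_variance_ratio: np.ndarray

    @property
    def n_components(self) -> int:
        return self.basis.shape[1]

    def project(self, x: np.ndarray) -> np.ndarray:
        return (x - self.mean) @ self.basis


def pca_reduce(x: np.ndarray, var_frac: float = 0.99) -> tuple[PCAReduction, np.ndarray]:
    """Project observations x channels onto the fewest principal axes
    whose cumulative explained variance reaches ``var_frac``."""
    if not 0 < var_frac <= 1:
        raise ValueError("var_frac must be in (0, 1]")
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("x must be observations x channels with >= 2 channels")
    mean = x.mean(axis=0)
    xc = x - mean
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    var = s**2
    total = var.sum()
    if total == 0:
        raise ValueError("zero-variance data")
    ratio = var / total
    k = int(np.searchsorted(np.cumsum(ratio), var_frac - 1e-12) + 1)
    k = min(k, ratio.size)
    red = PCAReduction(mean=mean, basis=vt[:k].T.copy(),
                       explained_variance_ratio=ratio[:k])
    return red, xc @ red.basis


@dataclass
class ICADecomposition:
    """PCA + ICA decomposition fit on epoched band-passed data."""

    pca: PCAReduction
    unmixing: np.ndarray             # components x components (PCA space)
    mixing: np.ndarray               # inverse of unmixing
    method: str = "extended-infomax"
    seed: int = 0
    artifact_component_indices: frozenset[int] = field(default_factory=frozenset)

    @property
    def n_components(self) -> int:
        return self.unmixing.shape[0]

    def sources(self, x_channels: np.ndarray) -> np.ndarray:
        """Component activations for observations x channels input."""
        return self.pca.project(x_channels) @ self.unmixing.T

    def reconstruct(self, x_channels: np.ndarray,
                    drop: Sequence[int] = ()) -> np.ndarray:
        """Back-project to channel space, zeroing components in ``drop``.

        The input's own channel means are removed before projection and
        restored afterwards, so DC offsets survive the rank reduction.
        """
        drop = sorted(set(int(i) for i in drop))
        if drop and (min(drop) < 0 or max(drop) >= self.n_components):
            raise ValueError("artifact component index out of range")
        mean = x_channels.mean(axis=0)
        # compose the channel->channel operator once; a single GEMM beats
        # chaining four tall-matrix products
        keep = np.ones(self.n_components)
        keep[drop] = 0.0
        op = (self.pca.basis @ self.unmixing.T) @ (keep[:, None] * self.mixing.T) \
            @ self.pca.basis.T
        return (x_channels - mean) @ op + mean


def ica_decompose(
    x_reduced: np.ndarray,
    method: str = "extended-infomax",
    seed: int = 0,
    pca: PCAReduction | None = None,
    max_iter: int = 200,
) -> ICADecomposition:
    """Fit ICA on PCA-space observations x components data.

    ``extended-infomax`` (the default) handles both sub- and super-Gaussian
    sources; ``fastica`` is accepted as an alternative meeting the same
    decomposition contract.  Deterministic for a fixed seed.
    """
    if x_reduced.ndim != 2:
        raise ValueError("x_reduced must be observations x components")
    n_obs, k = x_reduced.shape
    if n_obs < 10 * k:
        raise ValueError("need many more observations than components")
    if method in ("extended-infomax", "infomax"):
        from mne.preprocessing import infomax

        unmixing = infomax(
            x_reduced,
            extended=(method == "extended-infomax"),
            max_iter=max_iter,
            ext_blocks=50,  # re-estimate sub/super-Gaussian signs sparingly
            random_state=seed,
            verbose="error",
        )
    elif method == "fastica":
        from sklearn.decomposition import FastICA

        fica = FastICA(n_components=k, whiten="unit-variance",
                       random_state=seed, max_iter=max_iter)
        fica.fit(x_reduced)
        unmixing = fica.components_
    else:
        raise ValueError(f"unknown ICA method {method!r}")
    mixing = np.linalg.inv(unmixing)
    if pca is None:
        pca = PCAReduction(
            mean=np.zeros(k), basis=np.eye(k),
            explained_variance_ratio=np.full(k, 1.0 / k),
        )
    return ICADecomposition(pca=pca, unmixing=unmixing, mixing=mixing,
                            method=method, seed=seed)


def mark_artifact_components(
    ica: ICADecomposition,
    x_channels: np.ndarray,
    eog: np.ndarray,
    corr_thresh: float = 0.7,
    manual: Sequence[int] = (),
) -> frozenset[int]:
    """Components whose activation correlates with any EOG channel.

    ``x_channels`` are the observations x channels the decomposition was
    fit on; ``eog`` the time-aligned observations x n_eog series.  A
    component is marked when |r| exceeds ``corr_thresh`` for any EOG
    channel; the manual override list is unioned in.
    """
    if eog.ndim == 1:
        eog = eog[:, None]
    if eog.shape[0] != x_channels.shape[0]:
        raise ValueError("EOG not time-aligned with the fitted data")
    s = ica.sources(x_channels)
    marked = set(int(i) for i in manual)
    s_sd = s.std(axis=0)
    e_sd = eog.std(axis=0)
    sc = s - s.mean(axis=0)
    ec = eog - eog.mean(axis=0)
    denom = np.outer(s_sd, e_sd) * s.shape[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (sc.T @ ec) / denom, 0.0)
    marked |= set(np.flatnonzero(np.any(np.abs(r) > corr_thresh, axis=1)).tolist())
    return frozenset(marked)


def clean_backproject(
    rec_notch_only: ContinuousRecording,
    ica: ICADecomposition,
    artifact_idx: Sequence[int] | frozenset[int],
) -> ContinuousRecording:
    """Back-project only the non-artifact components onto notch-only data.

    The ICA weights were fit on 1-70 Hz epoched data; here they are applied
    to the notch-only continuous recording (rest runs included).  Channel
    count and event stream are preserved.
    """
    cleaned = ica.reconstruct(rec_notch_only.data, drop=artifact_idx)
    return rec_notch_only.copy_with(cleaned)


# ---------------------------------------------------------------------------
# session-level orchestration


@dataclass
class PreprocessConfig:
    notch_hz: float = 50.0
    reject_band: tuple[float, float] = (1.0, 70.0)
    amp_limit: float = 200.0
    sd_thresh: float = 5.0
    var_frac: float = 0.99
    eog_corr_thresh: float = 0.7
    ica_method: str = "extended-infomax"
    ica_seed: int = 0
    ica_max_obs: int = 12000  # fit-time decimation cap (see methods note)
    ica_max_iter: int = 50
    bad_channel_sd: float = 5.0
    manual_bad_channels: tuple[str, ...] = ()
    manual_artifact_components: tuple[int, ...] = ()


@dataclass
class CleanedSession:
    recording: ContinuousRecording   # cleaned, notch-only base
    artifact_report: ArtifactReport
    ica: ICADecomposition
    bad_channels: list[str]
    kept_trial_indices: np.ndarray
    config: PreprocessConfig


def preprocess_session(
    rec: ContinuousRecording,
    trial_windows: np.ndarray,
    cfg: PreprocessConfig | None = None,
) -> CleanedSession:
    """Run the full cleaning chain on one session.

    ``trial_windows`` is (n_trials, 3): trial index, start time, end time
    (absolute seconds) of the trials to consider (invalid trials should
    already have been dropped by the caller).
    """
    if cfg is None:
        cfg = PreprocessConfig()
    trial_windows = np.asarray(trial_windows, dtype=float)

    bad = detect_bad_channels(rec, cfg.bad_channel_sd, cfg.manual_bad_channels)
    keep = [l for l in rec.channel_labels if l not in bad]
    rec = rec.pick(keep)

    rec_notch = notch_filter(rec, cfg.notch_hz)
    rec_band = butter_bandpass_zero_phase(rec_notch, *cfg.reject_band)

    starts = trial_windows[:, 1]
    win_len = float(np.median(trial_windows[:, 2] - trial_windows[:, 1]))
    from .events import epoch  # local import to avoid a cycle

    trial_epochs = epoch(
        rec_band, starts, (0.0, win_len), lock="trial_start",
        trial_indices=trial_windows[:, 0].astype(int),
    )
    report = detect_artifact_trials(trial_epochs, cfg.amp_limit, cfg.sd_thresh)
    kept = ~report.removed_mask
    kept_epochs = trial_epochs.select_trials(kept)

    # concatenate artifact-free epochs: observations x channels
    x = kept_epochs.data.transpose(0, 2, 1).reshape(-1, len(keep))
    stride = max(1, int(np.ceil(x.shape[0] / cfg.ica_max_obs)))
    x_fit = x[::stride]
    pca, x_red = pca_reduce(x_fit, cfg.var_frac)
    ica = ica_decompose(x_red, cfg.ica_method, cfg.ica_seed, pca=pca,
                        max_iter=cfg.ica_max_iter)

    eog_cols = [i for i, t in enumerate(rec.channel_types) if t == "EOG"]
    artifact_idx = mark_artifact_components(
        ica, x_fit, x_fit[:, eog_cols], cfg.eog_corr_thresh,
        manual=cfg.manual_artifact_components,
    )
    ica.artifact_component_indices = artifact_idx

    cleaned = clean_backproject(rec_notch, ica, artifact_idx)
    return CleanedSession(
        recording=cleaned,
        artifact_report=report,
        ica=ica,
        bad_channels=bad,
        kept_trial_indices=kept_epochs.trial_indices.copy(),
        config=cfg,
    )
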