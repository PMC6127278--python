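"""Synthetic sessions of the self-paced reach-and-grasp imagination paradigm.

Each trial starts with a 2 s baseline, then a condition cue (ID: freely
choose one of five empty glasses; IDII: choose one of two water glasses;
EC: the single water glass is the target) together with a scroller showing
a new 3-digit number every 750 ms.  The participant starts a single
kinesthetic movement imagination (MI) at a self-chosen moment, memorises
the scroller number displayed at that moment, and reports number and target
after the trial.  The simulator reproduces this event structure together
with the signal content needed to exercise every downstream stage:

* condition-dependent cue-locked ERP templates (P200, P300/P3b, and a late
  slow-wave component over 0.6-0.8 s whose amplitude separates the
  internally-driven conditions from the externally-cued one),
* a movement-related cortical potential (Bereitschaftspotential-like)
  template locked to the true imagination onset (IO): negativity from 1 s
  before the IO, peak at +0.5 s, return to baseline by +2 s,
* 1/f ("pink") background noise and optional blink artifacts,
* three 60 s rest runs appended after the trials.

Ground truth (true IO per trial, blink times, the condition templates) is
retained so recovery tests can assert against it.  Topographies are abstract
gain maps — there is no biophysical forward model, and no saccade or EMG
simulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .containers import ContinuousRecording, EventStream, TrialRecord
from .montage import EEG_61, EOG_3, FRONTAL, gaussian_gains

CONDITIONS = ("ID", "IDII", "EC")

BLINK_DURATION = 0.3  # seconds; stereotypical blink transient width


@dataclass(frozen=True)
class ScalpTopography:
    """Abstract per-channel gain map in [0, 1]."""

    weights: Mapping[str, float]

    def __post_init__(self):
        if not any(w > 0 for w in self.weights.values()):
            raise ValueError("topography needs at least one positive weight")
        if any(w < 0 or w > 1 for w in self.weights.values()):
            raise ValueError("topography gains must lie in [0, 1]")

    def gains(self, channel_labels) -> np.ndarray:
        return np.array([self.weights.get(l, 0.0) for l in channel_labels])


@dataclass(frozen=True)
class ErpTemplateParams:
    """Cue-locked ERP template: two Gaussian peaks plus a late slow wave.

    The late component is a raised-cosine bump supported exactly on
    ``late_window``; its amplitude is the condition-dependent knob that
    separates internally-driven from externally-cued trials.
    """

    p200_amplitude: float = 3.0
    p200_latency: float = 0.2
    p300_amplitude: float = 5.0
    p300_latency: float = 0.5
    late_amplitude: float = 3.0
    late_window: tuple[float, float] = (0.6, 0.8)
    component_widths: tuple[float, float] = (0.04, 0.09)  # Gaussian sigmas
    topography: Mapping[str, ScalpTopography] | None = None

    def __post_init__(self):
        if not self.p200_latency < self.p300_latency < self.late_window[0]:
            raise ValueError("component latencies must be strictly increasing")
        if any(w <= 0 for w in self.component_widths):
            raise ValueError("component widths must be positive")
        if not self.late_window[0] < self.late_window[1]:
            raise ValueError("late_window must be increasing")


@dataclass(frozen=True)
class MrcpTemplateParams:
    """Self-paced MRCP template relative to the imagination onset."""

    onset_lead: float = 1.0      # negativity starts onset_lead s before IO
    peak_latency: float = 0.5    # s after IO
    peak_amplitude: float = -6.0  # microvolts, negative
    return_time: float = 2.0     # s after IO, back at baseline
    topography: ScalpTopography | None = None

    def __post_init__(self):
        if self.onset_lead <= 0:
            raise ValueError("onset_lead must be positive")
        if self.peak_amplitude >= 0:
            raise ValueError("peak_amplitude must be negative")
        if self.return_time <= self.peak_latency:
            raise ValueError("return_time must exceed peak_latency")


@dataclass(frozen=True)
class IODistribution:
    """Truncated lognormal over imagination-onset times (s after cue)."""

    median: float = 4.0
    sigma: float = 0.5
    lo: float = 2.0
    hi: float = 9.0

    def __post_init__(self):
        if not 0 < self.lo < self.hi:
            raise ValueError("need 0 < lo < hi")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        out = np.empty(n)
        mu = math.log(self.median)
        filled = 0
        while filled < n:
            draw = rng.lognormal(mu, self.sigma, size=2 * (n - filled) + 8)
            draw = draw[(draw >= self.lo) & (draw <= self.hi)]
            take = min(draw.size, n - filled)
            out[filled : filled + take] = draw[:take]
            filled += take
        return out


def default_erp_params() -> dict[str, ErpTemplateParams]:
    """Per-condition templates: late slow wave ID = IDII > EC (2 uV apart)."""
    return {
        "ID": ErpTemplateParams(late_amplitude=3.0),
        "IDII": ErpTemplateParams(late_amplitude=3.0),
        "EC": ErpTemplateParams(late_amplitude=1.0),
    }


@dataclass
class SimulationConfig:
    """Study-level configuration of the synthetic paradigm."""

    n_subjects: int = 1
    trials_per_condition: int = 65
    fs: float = 250.0
    channel_names: tuple[str, ...] = EEG_61 + EOG_3
    post_cue_duration: float = 13.5
    baseline_duration: float = 2.0
    scroller_period: float = 0.75
    break_duration: float = 1.5
    io_distribution: IODistribution = field(default_factory=IODistribution)
    erp_params: dict[str, ErpTemplateParams] = field(default_factory=default_erp_params)
    mrcp_params: MrcpTemplateParams = field(default_factory=MrcpTemplateParams)
    noise_exponent: float = 1.0
    noise_scale: float = 2.5       # microvolts RMS per channel, broadband
    noise_spatial_rank: int | None = 20  # shared scalp noise sources
    sensor_noise_frac: float = 0.1  # white sensor noise, fraction of scale
    blink_rate: float = 4.0        # events / minute
    blink_amplitude: float = 150.0  # microvolts at the EOG channels
    invalid_report_rate: float = 0.05
    n_rest_runs: int = 3
    rest_run_duration: float = 60.0
    seed: int = 0

    def __post_init__(self):
        if self.scroller_period <= 0:
            raise ValueError("scroller_period must be positive")
        if self.post_cue_duration < 13.0:
            raise ValueError(
                "post_cue_duration must be >= 13 s so the 12 s evaluation "
                "period starting 1 s after the cue fits inside every trial"
            )
        if self.io_distribution.hi > self.post_cue_duration - 3.5:
            raise ValueError(
                "IO distribution support must stay within "
                "(0, post_cue_duration - 3.5] so MI and REST windows fit"
            )
        if self.trials_per_condition < 5:
            raise ValueError("need >= 5 trials per condition for 5-fold CV")
        if self.noise_exponent < 0:
            raise ValueError("noise_exponent must be >= 0")
        if set(self.erp_params) != set(CONDITIONS):
            raise ValueError(f"erp_params must cover conditions {CONDITIONS}")

    @property
    def eeg_labels(self) -> list[str]:
        return [c for c in self.channel_names if not c.upper().startswith("EOG")]

    @property
    def channel_types(self) -> list[str]:
        return ["EOG" if c.upper().startswith("EOG") else "EEG"
                for c in self.channel_names]


# ---------------------------------------------------------------------------
# waveform primitives


def mrcp_waveform(t_grid: np.ndarray, params: MrcpTemplateParams) -> np.ndarray:
    """MRCP template evaluated on ``t_grid`` (s relative to the IO).

    Zero before ``-onset_lead``; half-cosine descent to ``peak_amplitude``
    at ``peak_latency``; half-cosine return to zero at ``return_time``;
    zero afterwards.  Piecewise smooth and monotone on each branch.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or (t.size > 1 and np.any(np.diff(t) <= 0)):
        raise ValueError("t_grid must be 1-D and strictly increasing")
    L, P, R, A = (params.onset_lead, params.peak_latency,
                  params.return_time, params.peak_amplitude)
    out = np.zeros_like(t)
    rise = (t >= -L) & (t <= P)
    out[rise] = A * 0.5 * (1.0 - np.cos(np.pi * (t[rise] + L) / (L + P)))
    fall = (t > P) & (t <= R)
    out[fall] = A * 0.5 * (1.0 + np.cos(np.pi * (t[fall] - P) / (R - P)))
    return out


def erp_component_waveforms(
    t_grid: np.ndarray, params: ErpTemplateParams
) -> dict[str, np.ndarray]:
    """The three template components evaluated separately on ``t_grid``."""
    t = np.asarray(t_grid, dtype=float)
    w200, w300 = params.component_widths
    comps = {
        "p200": params.p200_amplitude
        * np.exp(-0.5 * ((t - params.p200_latency) / w200) ** 2),
        "p300": params.p300_amplitude
        * np.exp(-0.5 * ((t - params.p300_latency) / w300) ** 2),
    }
    a, b = params.late_window
    late = np.zeros_like(t)
    inside = (t > a) & (t < b)
    late[inside] = params.late_amplitude * 0.5 * (
        1.0 - np.cos(2.0 * np.pi * (t[inside] - a) / (b - a))
    )
    comps["late"] = late
    return comps


def erp_waveform(
    t_grid: np.ndarray,
    condition: str,
    params: Mapping[str, ErpTemplateParams] | ErpTemplateParams,
) -> np.ndarray:
    """Summed ERP template for ``condition`` on ``t_grid`` (s after cue)."""
    if isinstance(params, Mapping):
        if condition not in params:
            raise ValueError(f"unknown condition {condition!r}")
        params = params[condition]
    elif condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    comps = erp_component_waveforms(t_grid, params)
    return comps["p200"] + comps["p300"] + comps["late"]


def pink_noise(
    n_samples: int,
    n_channels: int,
    exponent: float = 1.0,
    scale: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """1/f^exponent Gaussian noise, per-channel RMS equal to ``scale``.

    Generated by shaping the spectrum of white noise; the DC bin is zeroed,
    so every channel is exactly zero-mean.
    """
    if n_samples <= 1:
        raise ValueError("n_samples must be > 1")
    if exponent < 0:
        raise ValueError("exponent must be >= 0")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    if scale == 0:
        return np.zeros((n_samples, n_channels))
    from scipy import fft as sfft

    n_fft = sfft.next_fast_len(n_samples)  # pad: awkward lengths are slow
    white = rng.standard_normal((n_channels, n_fft))  # contiguous FFT axis
    spec = sfft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_fft)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-exponent / 2.0)
    x = sfft.irfft(spec * shaping[None, :], n=n_fft, axis=-1)[:, :n_samples]
    rms = np.sqrt(np.mean(x**2, axis=1))
    rms[rms == 0] = 1.0
    return (x.T * (scale / rms)).copy()


def blink_kernel(fs: float, amplitude: float) -> np.ndarray:
    """Stereotyped ~300 ms blink transient (squared-Hann positive pulse)."""
    n = max(int(round(BLINK_DURATION * fs)), 3)
    return amplitude * np.hanning(n) ** 2


def inject_blinks(
    recording: ContinuousRecording,
    rate: float,
    amplitude: float,
    seed: int | np.random.Generator = 0,
) -> ContinuousRecording:
    """Add Poisson-timed blink transients; returns a new recording.

    Blinks go on the EOG channels at full amplitude and on frontal EEG
    channels with gains decreasing away from the eyes.  Blink times are
    appended to the event stream as ground truth.
    """
    if rate < 0:
        raise ValueError("blink rate must be >= 0")
    if len(recording.eog_indices) == 0:
        raise ValueError("recording has no EOG channels")
    if rate == 0:
        return recording
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    duration = recording.duration
    n_blinks = rng.poisson(rate * duration / 60.0)
    data = recording.data.copy()
    kern = blink_kernel(recording.fs, amplitude)
    frontal_gain = gaussian_gains(recording.channel_labels, "Fpz", sigma=0.6)
    gains = np.zeros(data.shape[1])
    for i, lbl in enumerate(recording.channel_labels):
        if i in recording.eog_indices:
            gains[i] = 1.0
        elif lbl in FRONTAL:
            gains[i] = frontal_gain.get(lbl, 0.0)
    onsets = np.sort(rng.uniform(0, duration - BLINK_DURATION, size=n_blinks))
    for t in onsets:
        i0 = int(round(t * recording.fs))
        i1 = min(i0 + kern.size, data.shape[0])
        data[i0:i1] += np.outer(kern[: i1 - i0], gains)
    frame = recording.events.frame
    import pandas as pd

    blink_frame = pd.DataFrame(
        {"onset_s": onsets, "duration_s": BLINK_DURATION,
         "label": "blink", "payload": ""}
    )
    events = EventStream(pd.concat([frame, blink_frame], ignore_index=True))
    out = recording.copy_with(data)
    out.events = events
    return out


# ---------------------------------------------------------------------------
# session generation


def default_component_topographies(
    labels, sigma: float = 0.45
) -> dict[str, ScalpTopography]:
    """Parieto-occipital P200, centro-parietal P300, parietal late wave."""
    return {
        "p200": ScalpTopography(gaussian_gains(labels, "POz", sigma)),
        "p300": ScalpTopography(gaussian_gains(labels, "CPz", sigma)),
        "late": ScalpTopography(gaussian_gains(labels, "Pz", sigma)),
    }


def default_mrcp_topography(labels, sigma: float = 0.5) -> ScalpTopography:
    """Midline central gain map (max at Cz, strong at FCz)."""
    return ScalpTopography(gaussian_gains(labels, "Cz", sigma))


def _background_noise(
    cfg: SimulationConfig,
    labels: list[str],
    eog_mask: np.ndarray,
    n_samples: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Scalp background noise for one session.

    EEG channels receive spatially correlated pink noise — ``rank`` shared
    1/f sources mixed through random smooth gain maps (a cheap stand-in
    for volume conduction) plus a small white sensor-noise floor — with
    every channel normalised to ``noise_scale`` RMS.  EOG channels get
    independent pink noise.  With ``noise_spatial_rank=None`` all channels
    are independent pink noise.
    """
    from .montage import channel_positions

    n_ch = len(labels)
    if cfg.noise_scale == 0:
        return np.zeros((n_samples, n_ch))
    rank = cfg.noise_spatial_rank
    if rank is None:
        return pink_noise(n_samples, n_ch, cfg.noise_exponent,
                          cfg.noise_scale, rng)
    data = np.empty((n_samples, n_ch))
    eeg_idx = np.flatnonzero(~eog_mask)
    eeg_labels = [labels[i] for i in eeg_idx]
    xy = channel_positions(eeg_labels)
    sources = pink_noise(n_samples, rank, cfg.noise_exponent, 1.0, rng)
    centers = xy[rng.integers(0, len(eeg_idx), size=rank)]
    sigmas = rng.uniform(0.35, 0.9, size=rank)
    signs = rng.choice([-1.0, 1.0], size=rank)
    amps = rng.uniform(0.5, 1.0, size=rank)
    d2 = np.sum((xy[:, None, :] - centers[None, :, :]) ** 2, axis=2)
    gains = signs * amps * np.exp(-d2 / (2.0 * sigmas**2))  # ch x src
    eeg = sources @ gains.T
    if cfg.sensor_noise_frac > 0:
        eeg += cfg.sensor_noise_frac * rng.standard_normal(eeg.shape)
    rms = np.sqrt(np.mean(eeg**2, axis=0))
    rms[rms == 0] = 1.0
    data[:, eeg_idx] = eeg * (cfg.noise_scale / rms)
    eog_idx = np.flatnonzero(eog_mask)
    if eog_idx.size:
        data[:, eog_idx] = pink_noise(
            n_samples, eog_idx.size, cfg.noise_exponent, cfg.noise_scale, rng)
    return data


def _sample_distinct_numbers(rng: np.random.Generator, k: int) -> np.ndarray:
    return rng.choice(np.arange(100, 1000), size=k, replace=False)


def _add_template(
    data: np.ndarray,
    fs: float,
    lock_time: float,
    waveform: np.ndarray,
    wave_t0: float,
    gains: np.ndarray,
) -> None:
    """Add outer(waveform, gains) into data at the lock sample (in place)."""
    i0 = int(round((lock_time + wave_t0) * fs))
    j0 = max(i0, 0)
    j1 = min(i0 + waveform.size, data.shape[0])
    if j1 <= j0:
        return
    data[j0:j1] += np.outer(waveform[j0 - i0 : j1 - i0], gains)


def _trialwise_background_noise(
    cfg: SimulationConfig,
    labels: list[str],
    n_trials: int,
    n_samp: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """(n_trials, n_ch, n_samp) background noise, independent across trials.

    Trials in a real session are ~17 s apart, so their low-frequency noise
    is essentially independent; slicing consecutive segments from one
    stream would correlate neighbouring epochs and bias trial-level
    statistics.  The spatial gain maps are drawn once (a subject's noise
    topography is fixed); the source time courses are fresh per trial.
    """
    from .montage import channel_positions

    n_ch = len(labels)
    if cfg.noise_scale == 0:
        return np.zeros((n_trials, n_ch, n_samp))
    rank = cfg.noise_spatial_rank
    if rank is None:
        x = pink_noise(n_samp, n_trials * n_ch, cfg.noise_exponent,
                       cfg.noise_scale, rng)
        return x.T.reshape(n_trials, n_ch, n_samp)
    xy = channel_positions(labels)
    centers = xy[rng.integers(0, n_ch, size=rank)]
    sigmas = rng.uniform(0.35, 0.9, size=rank)
    signs = rng.choice([-1.0, 1.0], size=rank)
    amps = rng.uniform(0.5, 1.0, size=rank)
    d2 = np.sum((xy[:, None, :] - centers[None, :, :]) ** 2, axis=2)
    gains = signs * amps * np.exp(-d2 / (2.0 * sigmas**2))  # ch x src
    src = pink_noise(n_samp, n_trials * rank, cfg.noise_exponent, 1.0, rng)
    src = src.T.reshape(n_trials, rank, n_samp)
    eeg = np.einsum("cr,trs->tcs", gains, src)
    if cfg.sensor_noise_frac > 0:
        eeg += cfg.sensor_noise_frac * rng.standard_normal(eeg.shape)
    rms = np.sqrt(np.mean(eeg**2, axis=(0, 2)))
    rms[rms == 0] = 1.0
    return eeg * (cfg.noise_scale / rms)[None, :, None]


def simulate_condition_epochs(
    cfg: SimulationConfig,
    n_trials: int,
    conditions: tuple[str, ...] = CONDITIONS,
    window: tuple[float, float] = (-0.5, 2.0),
    channels: tuple[str, ...] | None = None,
    band: tuple[float, float] | None = (0.1, 15.0),
    seed: int = 0,
):
    """Cue-locked epoch sets per condition, generated directly.

    A light-weight path for calibration studies that need many datasets:
    each trial is the condition's ERP template plus background noise drawn
    with the session generator's spatial model, optionally band-passed.
    Far cheaper than simulating, cleaning and epoching a full session;
    contains no MRCP, blinks or trial bookkeeping.
    """
    from .containers import EpochSet
    from .preprocess import bandpass_array

    rng = np.random.default_rng(seed)
    labels = list(channels if channels is not None else cfg.eeg_labels)
    fs = cfg.fs
    n_samp = int(round((window[1] - window[0]) * fs))
    # pad so band-pass edge transients stay outside the analysis window
    pad = int(round(4.0 * fs))
    t_pad = (window[0] - pad / fs) + np.arange(n_samp + 2 * pad) / fs

    out = {}
    for cond in conditions:
        params = cfg.erp_params[cond]
        topo = (params.topography if params.topography is not None
                else default_component_topographies(labels))
        comps = erp_component_waveforms(t_pad, params)
        template = np.zeros((len(labels), t_pad.size))
        for name, wave in comps.items():
            template += np.outer(topo[name].gains(labels), wave)
        data = _trialwise_background_noise(cfg, labels, n_trials,
                                           n_samp + 2 * pad, rng)
        data += template[None]
        if band is not None:
            data = bandpass_array(data, fs, *band, axis=2)
        data = data[:, :, pad : pad + n_samp]
        out[cond] = EpochSet(
            data=data, fs=fs, t0_offset=window[0], lock="cue",
            channel_labels=labels, trial_indices=np.arange(n_trials),
        )
    return out


def simulate_io_locked_epochs(
    cfg: SimulationConfig,
    n_trials: int,
    window: tuple[float, float] = (-3.0, 3.0),
    channels: tuple[str, ...] | None = None,
    band: tuple[float, float] | None = (0.1, 1.0),
    seed: int = 0,
):
    """IO-locked epochs (MRCP template + noise), generated directly.

    Same shortcut as :func:`simulate_condition_epochs` but locked to the
    (perfectly known) imagination onset — the path used for template
    parameter-recovery studies.
    """
    from .containers import EpochSet
    from .preprocess import bandpass_array

    rng = np.random.default_rng(seed)
    labels = list(channels if channels is not None else cfg.eeg_labels)
    fs = cfg.fs
    n_samp = int(round((window[1] - window[0]) * fs))
    topo = (cfg.mrcp_params.topography
            if cfg.mrcp_params.topography is not None
            else default_mrcp_topography(labels))
    pad = int(round(6.0 * fs))
    t_pad = (window[0] - pad / fs) + np.arange(n_samp + 2 * pad) / fs
    template = np.outer(topo.gains(labels),
                        mrcp_waveform(t_pad, cfg.mrcp_params))
    data = _trialwise_background_noise(cfg, labels, n_trials,
                                       n_samp + 2 * pad, rng)
    data += template[None]
    if band is not None:
        data = bandpass_array(data, fs, *band, axis=2)
    data = data[:, :, pad : pad + n_samp]
    return EpochSet(
        data=data, fs=fs, t0_offset=window[0], lock="IO",
        channel_labels=labels, trial_indices=np.arange(n_trials),
    )


def generate_session(
    cfg: SimulationConfig, subject_seed: int
) -> tuple[ContinuousRecording, list[TrialRecord]]:
    """Simulate one subject's session.

    Returns the continuous recording (EEG + EOG, microvolts) with its event
    stream, and the list of trial records carrying conditions, scroller
    schedules, reports and the ground-truth IO.  Identical
    ``(cfg, subject_seed)`` give bitwise-identical output.
    """
    import pandas as pd

    rng = np.random.default_rng(subject_seed)
    labels = list(cfg.channel_names)
    ch_types = cfg.channel_types
    fs = cfg.fs

    n_trials = 3 * cfg.trials_per_condition
    conditions = rng.permutation(np.repeat(CONDITIONS, cfg.trials_per_condition))

    trial_len = cfg.baseline_duration + cfg.post_cue_duration + cfg.break_duration
    rest_total = cfg.n_rest_runs * cfg.rest_run_duration
    total_dur = n_trials * trial_len + rest_total + 1.0
    n_samples = int(round(total_dur * fs))

    n_scroller = int(math.floor(cfg.post_cue_duration / cfg.scroller_period))
    io_offsets = cfg.io_distribution.sample(rng, n_trials)

    erp_topo = {
        cond: (p.topography if p.topography is not None
               else default_component_topographies(labels))
        for cond, p in cfg.erp_params.items()
    }
    mrcp_topo = (cfg.mrcp_params.topography
                 if cfg.mrcp_params.topography is not None
                 else default_mrcp_topography(labels))
    eog_mask = np.array([t == "EOG" for t in ch_types])

    data = _background_noise(cfg, labels, eog_mask, n_samples, rng)

    # ERP template grid covers every component; MRCP grid covers its support
    erp_t = np.arange(0.0, 1.5 + 1.0 / fs, 1.0 / fs)
    mrcp_t = np.arange(
        -cfg.mrcp_params.onset_lead,
        cfg.mrcp_params.return_time + 1.0 / fs,
        1.0 / fs,
    )
    mrcp_wave = mrcp_waveform(mrcp_t, cfg.mrcp_params)
    mrcp_gains = mrcp_topo.gains(labels) * ~eog_mask

    events: list[tuple] = []
    trials: list[TrialRecord] = []
    t_cursor = 0.5  # settle-in pad before the first trial

    for i in range(n_trials):
        cond = str(conditions[i])
        trial_start = t_cursor
        cue_time = trial_start + cfg.baseline_duration
        trial_end = cue_time + cfg.post_cue_duration
        t_cursor = trial_end + cfg.break_duration

        numbers = _sample_distinct_numbers(rng, n_scroller)
        scroller = [
            (int(numbers[k]), cue_time + k * cfg.scroller_period)
            for k in range(n_scroller)
        ]

        # glass layout / targets
        if cond == "EC":
            water = rng.choice(5, size=1, replace=False) + 1
        elif cond == "IDII":
            water = rng.choice(5, size=2, replace=False) + 1
        else:
            water = np.arange(1, 6)
        expected = frozenset(int(w) for w in water)

        true_io = cue_time + io_offsets[i]
        shown_idx = min(int((true_io - cue_time) // cfg.scroller_period),
                        n_scroller - 1)
        reported_number = int(numbers[shown_idx])
        reported_target = int(rng.choice(sorted(expected)))

        if rng.random() < cfg.invalid_report_rate:
            wrong_number_possible = True
            wrong_target_possible = cond != "ID"
            if wrong_target_possible and (not wrong_number_possible
                                          or rng.random() < 0.5):
                others = sorted(set(range(1, 6)) - expected)
                reported_target = int(rng.choice(others))
            else:
                while True:
                    cand = int(rng.integers(100, 1000))
                    if cand not in numbers:
                        reported_number = cand
                        break

        events.append((trial_start, 0.0, "trial_start", i))
        events.append((cue_time, 0.0, "cue", cond))
        for num, onset in scroller:
            events.append((onset, cfg.scroller_period, "scroller", num))
        events.append((true_io, 0.0, "true_io", i))
        events.append((trial_end, 0.0, "report", reported_number))
        events.append((trial_end, 0.0, "trial_end", i))

        params = cfg.erp_params[cond]
        comps = erp_component_waveforms(erp_t, params)
        for name, wave in comps.items():
            gains = erp_topo[cond][name].gains(labels) * ~eog_mask
            _add_template(data, fs, cue_time, wave, 0.0, gains)
        _add_template(data, fs, true_io, mrcp_wave, float(mrcp_t[0]), mrcp_gains)

        trials.append(
            TrialRecord(
                index=i,
                condition=cond,
                trial_start=trial_start,
                cue_time=cue_time,
                trial_end=trial_end,
                scroller=scroller,
                reported_number=reported_number,
                reported_target=reported_target,
                expected_target_set=expected,
                true_io_time=true_io,
            )
        )

    for r in range(cfg.n_rest_runs):
        onset = t_cursor + r * cfg.rest_run_duration
        events.append((onset, cfg.rest_run_duration, "rest_run_start", r))

    frame = pd.DataFrame(events, columns=["onset_s", "duration_s", "label", "payload"])
    rec = ContinuousRecording(
        data=data,
        fs=fs,
        channel_labels=labels,
        channel_types=ch_types,
        events=EventStream(frame),
    )
    if cfg.blink_rate > 0:
        rec = inject_blinks(rec, cfg.blink_rate, cfg.blink_amplitude, rng)
    return rec, trials
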