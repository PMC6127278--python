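"""Cue-locked ERP statistics.

Condition averages are computed on 0.1-15 Hz band-passed cleaned data with
nonparametric t-percentile bootstrap confidence intervals, and conditions
are compared with a paired two-tailed tmax permutation test over all
channel x time cells: per permutation the paired trial differences are
randomly sign-flipped, a paired t-statistic is computed at every cell, and
the signed most-extreme value (tmax) across the whole family enters the
reference distribution.  The per-cell adjusted p-values derived from that
distribution control the family-wise error rate by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import EpochSet

ERP_BAND = (0.1, 15.0)   # Hz, band used before averaging cue-locked trials
TEST_WINDOW = (0.0, 2.0)  # s after cue, default tmax test window
EXHAUSTIVE_LIMIT = 4096   # use full sign-flip enumeration when 2^n <= this


@dataclass
class BootstrapCI:
    mean: np.ndarray   # channels x samples
    lower: np.ndarray
    upper: np.ndarray
    alpha: float
    n_boot: int


def condition_average_ci(
    epochs: EpochSet,
    alpha: float = 0.05,
    n_boot: int = 1000,
    seed: int = 0,
) -> BootstrapCI:
    """Trial average with a t-percentile bootstrap CI per channel/sample.

    Trials are resampled with replacement; each resample is studentized as
    ``(mean* - mean) / se*`` and the empirical alpha/2 and 1-alpha/2
    quantiles of the studentized statistic are inverted around the observed
    mean and standard error.
    """
    x = epochs.data
    n = x.shape[0]
    if n < 2:
        raise ValueError("bootstrap CI needs at least 2 trials")
    if n_boot < 100:
        import warnings

        warnings.warn("n_boot < 100 gives unstable bootstrap quantiles")
    rng = np.random.default_rng(seed)
    mean = x.mean(axis=0)
    se = x.std(axis=0, ddof=1) / np.sqrt(n)

    tstats = np.empty((n_boot,) + mean.shape)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        xb = x[idx]
        mb = xb.mean(axis=0)
        seb = xb.std(axis=0, ddof=1) / np.sqrt(n)
        with np.errstate(invalid="ignore", divide="ignore"):
            tstats[b] = np.where(seb > 0, (mb - mean) / seb, 0.0)
    q_lo, q_hi = np.quantile(tstats, [alpha / 2, 1 - alpha / 2], axis=0)
    lower = mean - q_hi * se
    upper = mean - q_lo * se
    lower = np.minimum(lower, mean)
    upper = np.maximum(upper, mean)
    return BootstrapCI(mean=mean, lower=lower, upper=upper,
                       alpha=alpha, n_boot=n_boot)


@dataclass
class PermTestResult:
    t_map: np.ndarray               # channels x samples
    tmax_distribution: np.ndarray   # n_perm signed extreme values
    critical_low: float
    critical_high: float
    significance_mask: np.ndarray   # bool, channels x samples
    adjusted_p: np.ndarray          # channels x samples
    n_perm: int
    alpha: float
    exhaustive: bool
    times: np.ndarray
    channel_labels: list[str]

    def cluster_table(self) -> pd.DataFrame:
        """Significant runs per channel as (channel, t_start, t_end) rows."""
        rows = []
        dt = float(np.median(np.diff(self.times))) if self.times.size > 1 else 0.0
        for c, label in enumerate(self.channel_labels):
            m = self.significance_mask[c]
            if not m.any():
                continue
            edges = np.flatnonzero(np.diff(np.concatenate(([0], m.view(np.int8), [0]))))
            for a, b in zip(edges[::2], edges[1::2]):
                rows.append((label, self.times[a], self.times[b - 1] + dt))
        return pd.DataFrame(rows, columns=["channel", "t_start", "t_end"])


def _sign_matrix(n: int, n_perm: int, rng: np.random.Generator,
                 allow_exhaustive: bool = True) -> tuple[np.ndarray, bool]:
    """Sign-flip design: exhaustive when feasible, else MC incl. observed."""
    if allow_exhaustive and 2**n <= EXHAUSTIVE_LIMIT:
        bits = (np.arange(2**n)[:, None] >> np.arange(n)[None, :]) & 1
        return bits * 2.0 - 1.0, True
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    signs[0] = 1.0  # observed labeling is part of the reference distribution
    return signs, False


def _safe_t(mean: np.ndarray, var: np.ndarray, n: int) -> np.ndarray:
    """Paired t; a zero-variance nonzero-mean cell is infinitely extreme."""
    var = np.maximum(var, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(var > 0, mean / np.sqrt(var / n), 0.0)
    degenerate = (var == 0) & (mean != 0)
    if np.any(degenerate):
        with np.errstate(invalid="ignore"):
            t = np.where(degenerate, np.sign(mean) * np.inf, t)
    return t


def tmax_permutation_test(
    a: EpochSet,
    b: EpochSet,
    alpha: float = 0.05,
    n_perm: int = 10000,
    seed: int = 0,
    window: tuple[float, float] | None = TEST_WINDOW,
    allow_exhaustive: bool = True,
    _chunk: int = 4096,
) -> PermTestResult:
    """Paired two-tailed tmax permutation test between EpochSets ``a``, ``b``.

    Trials must be paired (same count and axes).  When ``2**n_pairs`` does
    not exceed 4096 the full sign-flip enumeration replaces Monte-Carlo
    sampling and the result is exactly reproducible.
    """
    if a.data.shape != b.data.shape:
        raise ValueError("paired test needs identically shaped EpochSets")
    if a.fs != b.fs or abs(a.t0_offset - b.t0_offset) > 1e-9:
        raise ValueError("paired test needs identical time axes")
    ea, eb = a, b
    if window is not None:
        ea, eb = a.crop(*window), b.crop(*window)
    d = ea.data - eb.data
    n, n_ch, n_t = d.shape
    if n < 2:
        raise ValueError("need at least 2 trial pairs")

    rng = np.random.default_rng(seed)
    signs, exhaustive = _sign_matrix(n, n_perm, rng, allow_exhaustive)
    n_perm_eff = signs.shape[0]

    df = d.reshape(n, -1)
    msq = np.einsum("ij,ij->j", df, df) / n  # fixed under sign flips

    m = df.shape[1]
    t_obs = np.empty(m)
    tmax = np.zeros(n_perm_eff)
    tmax_abs = np.zeros(n_perm_eff)
    for j0 in range(0, m, _chunk):
        sl = slice(j0, min(j0 + _chunk, m))
        mean = signs @ df[:, sl] / n
        var = (msq[sl] - mean**2) * (n / (n - 1))
        t = _safe_t(mean, var, n)
        obs = df[:, sl].mean(axis=0)
        vobs = (msq[sl] - obs**2) * (n / (n - 1))
        t_obs[sl] = _safe_t(obs, vobs, n)
        idx = np.argmax(np.abs(t), axis=1)
        cand = t[np.arange(n_perm_eff), idx]
        better = np.abs(cand) > tmax_abs
        tmax[better] = cand[better]
        tmax_abs[better] = np.abs(cand[better])

    critical_low, critical_high = np.quantile(tmax, [alpha / 2, 1 - alpha / 2])
    sorted_abs = np.sort(tmax_abs)
    counts = n_perm_eff - np.searchsorted(sorted_abs, np.abs(t_obs), side="left")
    adjusted_p = counts / n_perm_eff
    mask = (t_obs >= critical_high) | (t_obs <= critical_low)
    # a zero-difference family has a degenerate reference distribution
    if np.all(tmax == 0):
        mask[:] = False
        adjusted_p[:] = 1.0

    return PermTestResult(
        t_map=t_obs.reshape(n_ch, n_t),
        tmax_distribution=tmax,
        critical_low=float(critical_low),
        critical_high=float(critical_high),
        significance_mask=mask.reshape(n_ch, n_t),
        adjusted_p=adjusted_p.reshape(n_ch, n_t),
        n_perm=n_perm_eff,
        alpha=alpha,
        exhaustive=exhaustive,
        times=ea.times.copy(),
        channel_labels=list(ea.channel_labels),
    )
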