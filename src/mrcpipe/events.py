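"""Trial validation, imagination-onset estimation, epoching, behavior stats.

The imagination onset (IO) of a valid trial is the display onset of the
scroller number the participant reported (Libet-style reporting): the
number's 750 ms display interval contains the true onset, so the estimate
is accurate to within one scroller period.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ContinuousRecording, EpochSet, TrialRecord


def validate_trials(trials: list[TrialRecord]) -> list[TrialRecord]:
    """Set the ``valid`` flag on every trial (in place; returns the list).

    A trial is valid iff the reported number was actually shown on the
    scroller during that trial AND the reported target is consistent with
    the condition (EC: the single water glass; IDII: one of the two water
    glasses; ID: any of the five).  A missing report makes the trial
    invalid, not an error.
    """
    for tr in trials:
        if tr.reported_number is None or tr.reported_target is None:
            tr.valid = False
            continue
        number_ok = tr.reported_number in tr.scroller_numbers()
        target_ok = tr.reported_target in tr.expected_target_set
        tr.valid = bool(number_ok and target_ok)
        if not tr.valid:
            tr.io_time = None
    return trials


def estimate_io(trial: TrialRecord) -> float:
    """Estimated IO: onset of the scroller event carrying the reported number."""
    if not trial.valid:
        raise ValueError("IO is undefined for invalid trials")
    numbers = trial.scroller_numbers()
    if len(numbers) != len(set(numbers)):
        raise ValueError("duplicate scroller payloads within one trial")
    for num, onset in trial.scroller:
        if num == trial.reported_number:
            trial.io_time = float(onset)
            return trial.io_time
    raise ValueError("reported number not found on the scroller")


def estimate_all_io(trials: list[TrialRecord]) -> list[TrialRecord]:
    """Validate and fill ``io_time`` for every valid trial."""
    validate_trials(trials)
    for tr in trials:
        if tr.valid:
            estimate_io(tr)
    return trials


def epoch(
    rec: ContinuousRecording,
    lock_events: np.ndarray | list[float],
    window: tuple[float, float],
    lock: str = "cue",
    trial_indices: np.ndarray | list[int] | None = None,
    channel_labels: list[str] | None = None,
) -> EpochSet:
    """Cut epochs around ``lock_events`` over the half-open window [start, end).

    The sample at relative time ``t`` is the recording sample at
    ``round((event + t) * fs)``.  Events whose window leaves the recording
    are dropped with a warning listing their indices.
    """
    lock_events = np.asarray(lock_events, dtype=float)
    if lock_events.size == 0:
        raise ValueError("no lock events given")
    start, end = window
    if end <= start:
        raise ValueError("window end must exceed start")
    if trial_indices is None:
        trial_indices = np.arange(lock_events.size)
    trial_indices = np.asarray(trial_indices, dtype=int)

    fs = rec.fs
    n_win = int(round((end - start) * fs))
    first = np.round((lock_events + start) * fs).astype(int)
    ok = (first >= 0) & (first + n_win <= rec.n_samples)
    if not ok.all():
        dropped = trial_indices[~ok].tolist()
        warnings.warn(f"dropping {len(dropped)} out-of-bounds trials: {dropped}")
    first = first[ok]

    if channel_labels is None:
        ch_idx = np.arange(rec.data.shape[1])
        channel_labels = list(rec.channel_labels)
    else:
        ch_idx = np.array([rec.channel_index(l) for l in channel_labels])

    data = np.empty((first.size, ch_idx.size, n_win))
    for k, i0 in enumerate(first):
        data[k] = rec.data[i0 : i0 + n_win, ch_idx].T
    return EpochSet(
        data=data,
        fs=fs,
        t0_offset=start,
        lock=lock,
        channel_labels=list(channel_labels),
        trial_indices=trial_indices[ok],
    )


def compare_io_conditions(
    trials: list[TrialRecord],
    test: str = "ranksum",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pairwise comparison of cue-relative IO times across conditions.

    Runs a nonparametric Wilcoxon-family test on each of the three condition
    pairs and Benjamini-Hochberg-adjusts the three p-values.  ``test`` is
    ``"ranksum"`` (unpaired rank-sum / Mann-Whitney, the default) or
    ``"signed_rank"`` (paired Wilcoxon on trimmed-to-equal-length samples).
    Pairs with fewer than 2 valid trials in a condition are skipped and
    reported with NaN p-values.
    """
    if test not in ("ranksum", "signed_rank"):
        raise ValueError("test must be 'ranksum' or 'signed_rank'")
    by_cond: dict[str, np.ndarray] = {}
    for cond in TrialRecord.CONDITIONS:
        vals = [tr.io_relative_to_cue() for tr in trials
                if tr.condition == cond and tr.valid and tr.io_time is not None]
        by_cond[cond] = np.asarray(vals, dtype=float)

    pairs = [("ID", "IDII"), ("ID", "EC"), ("IDII", "EC")]
    rows = []
    for a, b in pairs:
        xa, xb = by_cond[a], by_cond[b]
        if xa.size < 2 or xb.size < 2:
            rows.append((a, b, xa.size, xb.size, np.nan))
            continue
        if test == "ranksum":
            p = stats.ranksums(xa, xb).pvalue
        else:
            n = min(xa.size, xb.size)
            da = xa[:n] - xb[:n]
            if np.allclose(da, 0):
                p = 1.0
            else:
                p = stats.wilcoxon(xa[:n], xb[:n]).pvalue
        rows.append((a, b, xa.size, xb.size, float(p)))

    df = pd.DataFrame(rows, columns=["cond_a", "cond_b", "n_a", "n_b", "p_value"])
    tested = df["p_value"].notna()
    adj = np.full(len(df), np.nan)
    if tested.any():
        adj[tested.to_numpy()] = multipletests(
            df.loc[tested, "p_value"], alpha=alpha, method="fdr_bh"
        )[1]
    df["p_adjusted"] = adj
    df["significant"] = df["p_adjusted"] < alpha
    return df
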