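"""Core data containers: event streams, continuous recordings, trials, epochs.

Conventions used throughout the package (documented once, here):

* times are seconds; relative times are signed,
* epoch windows are half-open ``[start, end)``,
* sample indices are 0-based and the sample locked to an event at time ``t``
  is ``round(t * fs)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

EVENT_COLUMNS = ("onset_s", "duration_s", "label", "payload")

#: documented event vocabulary of the simulated paradigm
EVENT_LABELS = (
    "trial_start", "cue", "scroller", "true_io", "report",
    "trial_end", "rest_run_start", "blink",
)


class EventStream:
    """Ordered stream of (onset, duration, label, payload) records."""

    def __init__(self, frame: pd.DataFrame | None = None):
        if frame is None:
            frame = pd.DataFrame({c: [] for c in EVENT_COLUMNS})
        missing = set(EVENT_COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"event frame missing columns {sorted(missing)}")
        frame = frame.loc[:, list(EVENT_COLUMNS)].reset_index(drop=True)
        onsets = frame["onset_s"].to_numpy(dtype=float)
        if onsets.size and np.any(np.diff(onsets) < 0):
            frame = frame.sort_values("onset_s", kind="stable").reset_index(drop=True)
        self.frame = frame

    def __len__(self) -> int:
        return len(self.frame)

    def of_label(self, label: str) -> pd.DataFrame:
        return self.frame[self.frame["label"] == label].reset_index(drop=True)

    def onsets(self, label: str) -> np.ndarray:
        return self.of_label(label)["onset_s"].to_numpy(dtype=float)

    def shifted(self, delta: float) -> "EventStream":
        f = self.frame.copy()
        f["onset_s"] = f["onset_s"] + delta
        return EventStream(f)

    @classmethod
    def from_records(cls, records: Iterable[tuple]) -> "EventStream":
        return cls(pd.DataFrame(list(records), columns=list(EVENT_COLUMNS)))

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "EventStream":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class ContinuousRecording:
    """Multichannel time series (samples x channels, microvolts)."""

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    channel_types: list[str]  # "EEG" | "EOG" per channel
    events: EventStream = field(default_factory=EventStream)
    reference_label: str = "right mastoid"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be samples x channels")
        if self.data.shape[1] != len(self.channel_labels):
            raise ValueError("channel count mismatch")
        if len(self.channel_labels) != len(set(self.channel_labels)):
            raise ValueError("duplicate channel labels")
        if len(self.channel_types) != len(self.channel_labels):
            raise ValueError("channel_types length mismatch")
        if "EEG" not in self.channel_types:
            raise ValueError("at least one EEG channel required")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def eeg_indices(self) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.channel_types) == "EEG")

    @property
    def eog_indices(self) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.channel_types) == "EOG")

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None

    def pick(self, labels: Sequence[str]) -> "ContinuousRecording":
        idx = [self.channel_index(l) for l in labels]
        return replace(
            self,
            data=self.data[:, idx].copy(),
            channel_labels=[self.channel_labels[i] for i in idx],
            channel_types=[self.channel_types[i] for i in idx],
        )

    def copy_with(self, data: np.ndarray) -> "ContinuousRecording":
        return replace(self, data=data)


@dataclass
class TrialRecord:
    """One trial of the paradigm.

    ``io_time`` is the *estimated* imagination onset (absolute seconds),
    defined only for valid trials; ``true_io_time`` is the simulator's
    ground truth, unavailable for real data.
    """

    index: int
    condition: str  # "ID" | "IDII" | "EC"
    trial_start: float
    cue_time: float
    trial_end: float
    scroller: list[tuple[int, float]]  # (3-digit number, onset seconds)
    reported_number: int | None
    reported_target: int | None
    expected_target_set: frozenset[int]
    valid: bool | None = None
    io_time: float | None = None
    true_io_time: float | None = None

    CONDITIONS = ("ID", "IDII", "EC")

    def scroller_numbers(self) -> list[int]:
        return [n for n, _ in self.scroller]

    def io_relative_to_cue(self) -> float | None:
        if self.io_time is None:
            return None
        return self.io_time - self.cue_time


@dataclass
class EpochSet:
    """trials x channels x samples array locked to an event.

    ``t0_offset`` is the relative time of the first sample with respect to
    the lock event; the time axis is ``t0_offset + arange(n_samples)/fs``.
    """

    data: np.ndarray
    fs: float
    t0_offset: float
    lock: str  # "cue" | "IO" | "trial_start"
    channel_labels: list[str]
    trial_indices: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        self.trial_indices = np.asarray(self.trial_indices, dtype=int)
        if self.data.shape[0] != self.trial_indices.size:
            raise ValueError("trial_indices length mismatch")
        if self.data.shape[1] != len(self.channel_labels):
            raise ValueError("channel label count mismatch")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.t0_offset + np.arange(self.data.shape[2]) / self.fs

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in epochs") from None

    def select_trials(self, mask_or_idx) -> "EpochSet":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return replace(
            self, data=self.data[idx], trial_indices=self.trial_indices[idx]
        )

    def pick(self, labels: Sequence[str]) -> "EpochSet":
        idx = [self.channel_index(l) for l in labels]
        return replace(
            self,
            data=self.data[:, idx, :],
            channel_labels=[self.channel_labels[i] for i in idx],
        )

    def crop(self, start: float, end: float) -> "EpochSet":
        """Restrict the time axis to the half-open window [start, end)."""
        t = self.times
        m = (t >= start - 1e-9) & (t < end - 1e-9)
        if not m.any():
            raise ValueError("crop window outside epoch time axis")
        return replace(
            self, data=self.data[:, :, m], t0_offset=float(t[m][0])
        )
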