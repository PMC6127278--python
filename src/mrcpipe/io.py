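"""Persistence: HDF5 recordings/epochs, TSV events, JSON trials, YAML configs.

Continuous EEG can also be *read* from EDF(+) or BrainVision files through
mne; the package's own container format is HDF5 (data + channel metadata)
with the event stream as a sidecar TSV.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .containers import ContinuousRecording, EpochSet, EventStream, TrialRecord


# ---------------------------------------------------------------------------
# recordings


def save_recording(rec: ContinuousRecording, path) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data, compression="gzip", shuffle=True)
        f.attrs["fs"] = rec.fs
        f.attrs["reference_label"] = rec.reference_label
        f.create_dataset("channel_labels",
                         data=np.array(rec.channel_labels, dtype="S"))
        f.create_dataset("channel_types",
                         data=np.array(rec.channel_types, dtype="S"))
    rec.events.to_tsv(path.with_suffix(".events.tsv"))


def load_recording(path) -> ContinuousRecording:
    path = Path(path)
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        fs = float(f.attrs["fs"])
        ref = str(f.attrs["reference_label"])
        labels = [s.decode() for s in f["channel_labels"][()]]
        types = [s.decode() for s in f["channel_types"][()]]
    ev_path = path.with_suffix(".events.tsv")
    events = EventStream.from_tsv(ev_path) if ev_path.exists() else EventStream()
    return ContinuousRecording(data=data, fs=fs, channel_labels=labels,
                               channel_types=types, events=events,
                               reference_label=ref)


def read_raw(path) -> ContinuousRecording:
    """Read an EDF(+)/BrainVision/FIF file via mne into the package container.

    Signal units are converted to microvolts; events are taken from an
    ``<stem>.events.tsv`` sidecar when present, else from the file's own
    annotations.
    """
    import mne

    path = Path(path)
    raw = mne.io.read_raw(path, preload=True, verbose="error")
    data = raw.get_data().T * 1e6
    labels = list(raw.ch_names)
    types = ["EOG" if t == "eog" or "EOG" in n.upper() else "EEG"
             for n, t in zip(labels, raw.get_channel_types())]
    sidecar = path.with_suffix(".events.tsv")
    if sidecar.exists():
        events = EventStream.from_tsv(sidecar)
    else:
        ann = raw.annotations
        events = EventStream(pd.DataFrame({
            "onset_s": ann.onset, "duration_s": ann.duration,
            "label": ann.description, "payload": "",
        }))
    return ContinuousRecording(data=data, fs=float(raw.info["sfreq"]),
                               channel_labels=labels, channel_types=types,
                               events=events)


# ---------------------------------------------------------------------------
# epochs


def save_epochs(epochs: EpochSet, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data, compression="gzip")
        f.attrs["fs"] = epochs.fs
        f.attrs["t0_offset"] = epochs.t0_offset
        f.attrs["lock"] = epochs.lock
        f.create_dataset("channel_labels",
                         data=np.array(epochs.channel_labels, dtype="S"))
        f.create_dataset("trial_indices", data=epochs.trial_indices)


def load_epochs(path) -> EpochSet:
    with h5py.File(path, "r") as f:
        return EpochSet(
            data=f["data"][()],
            fs=float(f.attrs["fs"]),
            t0_offset=float(f.attrs["t0_offset"]),
            lock=str(f.attrs["lock"]),
            channel_labels=[s.decode() for s in f["channel_labels"][()]],
            trial_indices=f["trial_indices"][()],
        )


# ---------------------------------------------------------------------------
# trials


def trials_to_json(trials: list[TrialRecord], path) -> None:
    payload = []
    for tr in trials:
        d = dataclasses.asdict(tr)
        d["expected_target_set"] = sorted(tr.expected_target_set)
        d["scroller"] = [[int(n), float(t)] for n, t in tr.scroller]
        payload.append(d)
    Path(path).write_text(json.dumps(payload, indent=1))


def trials_from_json(path) -> list[TrialRecord]:
    out = []
    for d in json.loads(Path(path).read_text()):
        d["expected_target_set"] = frozenset(d["expected_target_set"])
        d["scroller"] = [(int(n), float(t)) for n, t in d["scroller"]]
        out.append(TrialRecord(**d))
    return out


# ---------------------------------------------------------------------------
# configs


def config_to_yaml(cfg, path) -> None:
    def encode(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {"__class__": type(obj).__name__,
                    **{f.name: encode(getattr(obj, f.name))
                       for f in dataclasses.fields(obj)}}
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, (tuple, list)):
            return [encode(v) for v in obj]
        if isinstance(obj, dict):
            return {k: encode(v) for k, v in obj.items()}
        if isinstance(obj, frozenset):
            return sorted(obj)
        return obj

    Path(path).write_text(yaml.safe_dump(encode(cfg), sort_keys=False))


def simulation_config_from_yaml(path):
    """Rebuild a SimulationConfig from YAML written by ``config_to_yaml``."""
    from .simulate import (ErpTemplateParams, IODistribution,
                           MrcpTemplateParams, ScalpTopography,
                           SimulationConfig)

    classes = {c.__name__: c for c in (
        SimulationConfig, ErpTemplateParams, MrcpTemplateParams,
        IODistribution, ScalpTopography)}

    def decode(obj):
        if isinstance(obj, dict):
            name = obj.pop("__class__", None)
            decoded = {k: decode(v) for k, v in obj.items()}
            if name is not None:
                cls = classes[name]
                fields = {f.name for f in dataclasses.fields(cls)}
                kwargs = {}
                for k, v in decoded.items():
                    if k in fields:
                        if isinstance(v, list):
                            v = tuple(tuple(e) if isinstance(e, list) else e
                                      for e in v)
                        kwargs[k] = v
                return cls(**kwargs)
            return decoded
        if isinstance(obj, list):
            return [decode(v) for v in obj]
        return obj

    return decode(yaml.safe_load(Path(path).read_text()))
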