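"""Electrode montage helpers.

The simulated sessions use a 61-channel 10-10 EEG layout covering frontal,
central, parietal, temporal and occipital areas, plus three EOG channels
(one above the nasion, two below the outer canthi).  Scalp topographies for
the synthetic sources are abstract gain maps computed from the 2-D projected
standard electrode positions — no biophysical forward model is involved.
"""

from __future__ import annotations

import functools
import warnings

import numpy as np

#: 61 EEG labels of the simulated cap (10-10 system).
EEG_61: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2",
    "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2",
)

#: EOG channel labels (above nasion, below left/right outer canthus).
EOG_3: tuple[str, ...] = ("EOG1", "EOG2", "EOG3")

#: Default 26-channel set over sensorimotor / parietal cortex used for
#: MI-vs-REST feature extraction (fronto-central to centro-parietal strip).
CLASSIFIER_26: tuple[str, ...] = (
    "F1", "Fz", "F2",
    "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6",
    "C5", "C3", "C1", "Cz", "C2", "C4", "C6",
    "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6",
    "P1", "Pz",
)

#: Frontal EEG channels that pick up ocular activity in the simulator.
FRONTAL: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2", "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
)


@functools.lru_cache(maxsize=1)
def _standard_positions() -> dict[str, np.ndarray]:
    """2-D (azimuthal) electrode positions from the standard 10-05 montage."""
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            mon = mne.channels.make_standard_montage("standard_1005")
        except ValueError:  # montage renamed in newer mne
            mon = mne.channels.make_standard_montage("colin27_1005")
    pos3 = mon.get_positions()["ch_pos"]
    out: dict[str, np.ndarray] = {}
    for label, xyz in pos3.items():
        xyz = np.asarray(xyz, dtype=float)
        r = np.linalg.norm(xyz)
        if r == 0 or not np.isfinite(r):
            continue
        # azimuthal equidistant projection: angle from vertex scales radius
        x, y, z = xyz / r
        theta = np.arccos(np.clip(z, -1.0, 1.0))
        rho = np.hypot(x, y)
        if rho < 1e-12:
            out[label] = np.zeros(2)
        else:
            out[label] = theta * np.array([x, y]) / rho
    return out


def channel_positions(labels: tuple[str, ...] | list[str]) -> np.ndarray:
    """Return an (n, 2) array of projected positions for *labels*.

    Unknown labels (e.g. EOG) are placed far frontally so distance-based
    gains fall to ~0 for scalp sources.
    """
    pos = _standard_positions()
    fallback = np.array([2.2, 0.0])
    return np.array([pos.get(lbl, fallback) for lbl in labels])


def gaussian_gains(
    labels: tuple[str, ...] | list[str], center: str, sigma: float = 0.45
) -> dict[str, float]:
    """Gaussian scalp gain map centred on electrode *center*.

    sigma is in projected-radians (~0.45 spans roughly two electrode rings).
    The centre channel has gain 1; gains below 0.05 are dropped.
    """
    pos = _standard_positions()
    if center not in pos:
        raise ValueError(f"unknown centre electrode {center!r}")
    c = pos[center]
    xy = channel_positions(labels)
    d2 = np.sum((xy - c) ** 2, axis=1)
    g = np.exp(-d2 / (2.0 * sigma**2))
    return {lbl: float(w) for lbl, w in zip(labels, g) if w >= 0.05}
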