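"""Shared test fixtures built programmatically (no stored data)."""

import numpy as np

from mrcpipe import ContinuousRecording, TrialRecord
from mrcpipe.montage import CLASSIFIER_26


def make_detection_fixture(n_trials=30, amp=-6.0, noise=0.0, seed=0,
                           peak_latency=0.3, fs=10.0):
    """10 Hz recording with an MRCP-like bump at each trial's IO.

    Returns a 26-channel recording (already at the feature rate) and valid
    trial records, for classifier tests that do not need the full session
    simulation and preprocessing chain.
    """
    rng = np.random.default_rng(seed)
    labels = list(CLASSIFIER_26)
    trial_len = 17.0
    n = int((n_trials * trial_len + 5) * fs)
    data = noise * rng.standard_normal((n, len(labels)))
    trials = []
    conds = ["ID", "IDII", "EC"]
    t_bump = np.arange(-1.0, 2.0, 1 / fs)
    bump = amp * np.exp(-0.5 * ((t_bump - peak_latency) / 0.5) ** 2)
    for i in range(n_trials):
        start = 0.5 + i * trial_len
        cue = start + 2.0
        io = cue + 3.0 + rng.uniform(0, 2.0)
        i0 = int(round((io - 1.0) * fs))
        data[i0 : i0 + bump.size] += bump[:, None]
        trials.append(TrialRecord(
            index=i, condition=conds[i % 3], trial_start=start, cue_time=cue,
            trial_end=cue + 13.5, scroller=[(100 + i, cue)],
            reported_number=100 + i, reported_target=1,
            expected_target_set=frozenset({1}), valid=True, io_time=io,
        ))
    rec = ContinuousRecording(data, fs, labels, ["EEG"] * len(labels))
    return rec, trials
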