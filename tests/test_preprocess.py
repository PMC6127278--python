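"""Filters, artifact rejection, PCA+ICA, back-projection."""

import numpy as np
import pytest

from mrcpipe import (
    ContinuousRecording,
    EpochSet,
    butter_bandpass_zero_phase,
    clean_backproject,
    detect_artifact_trials,
    ica_decompose,
    mark_artifact_components,
    notch_filter,
    pca_reduce,
)
from mrcpipe.preprocess import PCAReduction


def _sine_rec(freq, fs=250.0, dur=10.0, amp=1.0):
    t = np.arange(int(dur * fs)) / fs
    x = amp * np.sin(2 * np.pi * freq * t)
    return ContinuousRecording(x[:, None], fs, ["Cz"], ["EEG"]), x


class TestNotchFilter:
    def test_50hz_attenuated(self):
        rec, x = _sine_rec(50.0)
        out = notch_filter(rec, 50.0)
        assert np.std(out.data) < 0.1 * np.std(x)

    def test_passband_preserved(self):
        rec, x = _sine_rec(10.0)
        out = notch_filter(rec, 50.0)
        core = slice(250, -250)  # ignore edge transients
        assert np.std(out.data[core]) == pytest.approx(np.std(x[core]),
                                                       rel=0.01)

    def test_dc_unchanged(self):
        rec = ContinuousRecording(np.full((1000, 1), 5.0), 250.0,
                                  ["Cz"], ["EEG"])
        out = notch_filter(rec, 50.0)
        assert np.allclose(out.data, 5.0, atol=1e-6)

    def test_above_nyquist_rejected(self):
        rec, _ = _sine_rec(10.0)
        with pytest.raises(ValueError):
            notch_filter(rec, 130.0)


class TestBandpass:
    def test_inband_preserved(self):
        rec, x = _sine_rec(10.0)
        out = butter_bandpass_zero_phase(rec, 1.0, 70.0)
        core = slice(500, -500)
        assert np.std(out.data[core, 0]) == pytest.approx(
            np.std(x[core]), rel=0.02)

    def test_stopband_attenuated(self):
        rec, x = _sine_rec(0.05, dur=60.0)
        out = butter_bandpass_zero_phase(rec, 0.1, 1.0)
        assert np.std(out.data) < 0.5 * np.std(x)

    def test_zero_phase_pulse_peak_unmoved(self):
        n = 2000
        x = np.zeros((n, 1))
        x[:, 0] = np.exp(-0.5 * ((np.arange(n) - 900) / 12.0) ** 2)
        rec = ContinuousRecording(x, 250.0, ["Cz"], ["EEG"])
        out = butter_bandpass_zero_phase(rec, 1.0, 70.0)
        assert abs(int(np.argmax(out.data[:, 0])) - 900) <= 1

    def test_invalid_band_rejected(self):
        rec, _ = _sine_rec(10.0)
        with pytest.raises(ValueError):
            butter_bandpass_zero_phase(rec, 0.0, 70.0)
        with pytest.raises(ValueError):
            butter_bandpass_zero_phase(rec, 1.0, 200.0)


def _epochs(data):
    n_tr, n_ch, n_s = data.shape
    return EpochSet(data=data, fs=250.0, t0_offset=0.0, lock="trial_start",
                    channel_labels=[f"c{i}" for i in range(n_ch)],
                    trial_indices=np.arange(n_tr))


class TestArtifactRejection:
    def test_amplitude_spike_flagged(self, rng):
        data = rng.standard_normal((10, 2, 500)) * 10
        data[3, 1, 100] = 300.0
        rep = detect_artifact_trials(_epochs(data))
        assert rep.amplitude_exceeded[3]
        assert 3 in rep.removed_trial_indices

    def test_identical_trials_no_statistical_flags(self):
        one = np.random.default_rng(0).standard_normal((1, 2, 500))
        data = np.repeat(one, 8, axis=0)
        rep = detect_artifact_trials(_epochs(data))
        assert not rep.abnormal_joint_probability.any()
        assert not rep.abnormal_kurtosis.any()

    def test_high_variance_trial_flagged(self, rng):
        """One trial with 10x noise SD is a joint-probability/kurtosis
        outlier; verified against a direct z-score computation."""
        data = rng.standard_normal((100, 1, 400)) * 5
        data[42] *= 10
        rep = detect_artifact_trials(_epochs(data), amp_limit=1e9)
        flagged = rep.abnormal_joint_probability | rep.abnormal_kurtosis
        assert flagged[42]
        assert flagged.sum() <= 3  # no mass false flagging

    def test_too_few_trials_rejected(self, rng):
        with pytest.raises(ValueError):
            detect_artifact_trials(_epochs(rng.standard_normal((2, 1, 100))))

    def test_rejection_monotonic_in_amp_limit(self, rng):
        data = rng.standard_normal((30, 3, 300)) * 60
        strict = detect_artifact_trials(_epochs(data), amp_limit=100)
        loose = detect_artifact_trials(_epochs(data), amp_limit=200)
        assert set(loose.removed_trial_indices) <= set(
            strict.removed_trial_indices)

    def test_ground_truth_recovery(self, rng):
        """>=90% of trials with injected +-300 uV artifacts are removed,
        <10% of clean trials are removed (200-trial fixture)."""
        data = rng.standard_normal((200, 4, 500)) * 15
        bad = rng.choice(200, size=30, replace=False)
        for i in bad:
            j = rng.integers(0, 4)
            k = rng.integers(50, 450)
            data[i, j, k : k + 25] += 300.0 * np.sign(rng.standard_normal())
        rep = detect_artifact_trials(_epochs(data))
        removed = set(rep.removed_trial_indices.tolist())
        hit = len(removed & set(bad.tolist())) / len(bad)
        false = len(removed - set(bad.tolist())) / (200 - len(bad))
        assert hit >= 0.9
        assert false < 0.1


class TestPCA:
    def test_full_rank_var1(self, rng):
        x = rng.standard_normal((200, 5))
        red, proj = pca_reduce(x, var_frac=1.0)
        assert red.n_components == 5
        assert proj.shape == (200, 5)

    def test_rank2_data(self, rng):
        basis = rng.standard_normal((2, 6))
        x = rng.standard_normal((300, 2)) @ basis
        red, _ = pca_reduce(x, var_frac=0.99)
        assert red.n_components == 2

    def test_cumulative_sum_path(self, rng):
        """Eigenvalues 8,1,1: cumulative fractions 0.8, 0.9, 1.0 so
        var_frac=0.99 needs all three components."""
        n = 20000
        x = rng.standard_normal((n, 3)) * np.sqrt([8.0, 1.0, 1.0])
        red, _ = pca_reduce(x, var_frac=0.99)
        assert red.n_components == 3
        red2, _ = pca_reduce(x, var_frac=0.85)
        assert red2.n_components == 2

    def test_invalid_var_frac(self, rng):
        with pytest.raises(ValueError):
            pca_reduce(rng.standard_normal((10, 3)), var_frac=0.0)
        with pytest.raises(ValueError):
            pca_reduce(rng.standard_normal((10, 3)), var_frac=1.5)


class TestICA:
    def test_supergaussian_sources_recovered(self, rng):
        s = rng.laplace(size=(4000, 2))
        a = np.array([[1.0, 0.6], [0.4, 1.0]])
        x = s @ a.T
        ica = ica_decompose(x, seed=0)
        rec = ica.sources(x)
        c = np.abs(np.corrcoef(rec.T, s.T))[:2, 2:]
        # each source matches exactly one component up to permutation/sign
        assert np.all(np.sort(c, axis=0)[-1] > 0.95)

    def test_mixing_unmixing_inverse(self, rng):
        x = rng.laplace(size=(3000, 3))
        ica = ica_decompose(x, seed=1)
        assert np.allclose(ica.mixing @ ica.unmixing, np.eye(3), atol=1e-8)
        back = ica.reconstruct(x)
        assert np.allclose(back, x, atol=1e-6)

    def test_deterministic(self, rng):
        x = rng.laplace(size=(2000, 2))
        w1 = ica_decompose(x, seed=5).unmixing
        w2 = ica_decompose(x, seed=5).unmixing
        assert np.array_equal(w1, w2)

    def test_too_few_observations_rejected(self, rng):
        with pytest.raises(ValueError):
            ica_decompose(rng.standard_normal((20, 5)))

    def test_unknown_method_rejected(self, rng):
        with pytest.raises(ValueError):
            ica_decompose(rng.laplace(size=(2000, 2)), method="jade")


class TestMarkComponents:
    def test_component_equal_to_eog_marked(self, rng):
        s = rng.laplace(size=(3000, 3))
        from mrcpipe.preprocess import ICADecomposition

        ica = ICADecomposition(
            pca=PCAReduction(mean=np.zeros(3), basis=np.eye(3),
                             explained_variance_ratio=np.full(3, 1 / 3)),
            unmixing=np.eye(3), mixing=np.eye(3))
        eog = s[:, [1]]
        marked = mark_artifact_components(ica, s, eog)
        assert marked == frozenset({1})

    def test_orthogonal_component_not_marked(self, rng):
        from mrcpipe.preprocess import ICADecomposition

        s = rng.standard_normal((3000, 2))
        ica = ICADecomposition(
            pca=PCAReduction(mean=np.zeros(2), basis=np.eye(2),
                             explained_variance_ratio=np.full(2, 0.5)),
            unmixing=np.eye(2), mixing=np.eye(2))
        eog = rng.standard_normal((3000, 1))
        assert mark_artifact_components(ica, s, eog) == frozenset()

    def test_manual_override_unioned(self, rng):
        from mrcpipe.preprocess import ICADecomposition

        s = rng.standard_normal((1000, 2))
        ica = ICADecomposition(
            pca=PCAReduction(mean=np.zeros(2), basis=np.eye(2),
                             explained_variance_ratio=np.full(2, 0.5)),
            unmixing=np.eye(2), mixing=np.eye(2))
        marked = mark_artifact_components(ica, s, rng.standard_normal((1000, 1)),
                                          manual=[0])
        assert 0 in marked


class TestCleanBackproject:
    def _rec(self, rng, n=2000, k=4):
        mix = rng.standard_normal((k, k))
        x = rng.laplace(size=(n, k)) @ mix.T
        rec = ContinuousRecording(x, 250.0, [f"c{i}" for i in range(k)],
                                  ["EEG"] * k)
        red, xr = pca_reduce(x, var_frac=1.0)
        ica = ica_decompose(xr, seed=0, pca=red)
        return rec, ica

    def test_empty_set_full_rank_identity(self, rng):
        rec, ica = self._rec(rng)
        out = clean_backproject(rec, ica, frozenset())
        assert np.allclose(out.data, rec.data, atol=1e-6)

    def test_all_marked_zero_output(self, rng):
        rec, ica = self._rec(rng)
        out = clean_backproject(rec, ica, range(ica.n_components))
        centered = rec.data - rec.data.mean(axis=0)
        assert np.allclose(out.data - rec.data.mean(axis=0), 0.0, atol=1e-8)
        assert not np.allclose(centered, 0.0)

    def test_idempotent(self, rng):
        rec, ica = self._rec(rng)
        once = clean_backproject(rec, ica, {1})
        twice = clean_backproject(once, ica, {1})
        assert np.allclose(once.data, twice.data, atol=1e-8)

    def test_out_of_range_rejected(self, rng):
        rec, ica = self._rec(rng)
        with pytest.raises(ValueError):
            clean_backproject(rec, ica, {99})


class TestSessionCleaning:
    def test_blink_component_removed(self, session):
        """On a simulated session the ICA stage recovers the blink
        component and blink-locked frontal amplitude drops >= 80%."""
        import mrcpipe.preprocess as pp

        rec, trials = session
        wins = np.array([[t.index, t.trial_start, t.trial_end]
                         for t in trials if t.valid])
        cleaned = pp.preprocess_session(rec, wins)
        assert len(cleaned.ica.artifact_component_indices) >= 1
        blinks = rec.events.onsets("blink")
        blinks = blinks[(blinks > 2) & (blinks < rec.duration - 2)]
        i = rec.channel_index("Fp1")

        def locked_ptp(data):
            w = int(0.5 * rec.fs)
            segs = [data[int(round((t - 0.1) * rec.fs)):
                         int(round((t - 0.1) * rec.fs)) + w, i]
                    for t in blinks]
            return np.ptp(np.mean(segs, axis=0))

        reduction = 1 - locked_ptp(cleaned.recording.data) / locked_ptp(rec.data)
        assert reduction >= 0.8
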