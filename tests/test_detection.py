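"""Window rules, feature extraction, shrinkage LDA, time-locked CV."""

import numpy as np
import pytest

from mrcpipe import (
    ContinuousRecording,
    adjusted_wald_interval,
    crossvalidate_timelocked,
    downsample_10hz,
    extract_features,
    fit_slda,
    select_mi_window,
    select_rest_window,
)
from mrcpipe.detection import ShrinkageLDA, ledoit_wolf_gamma, stratified_folds
from helpers import make_detection_fixture


class TestSelectMiWindow:
    def _series_with_min(self, latency):
        t = np.linspace(-2.5, 2.5, 501)
        return -np.exp(-0.5 * ((t - latency) / 0.2) ** 2), t

    def test_early_peak_early_window(self):
        s, t = self._series_with_min(0.4)
        assert select_mi_window(s, t) == -1.0

    def test_late_peak_late_window(self):
        s, t = self._series_with_min(0.6)
        assert select_mi_window(s, t) == 0.0

    def test_boundary_is_strict(self):
        s, t = self._series_with_min(0.5)
        assert select_mi_window(s, t) == 0.0


class TestSelectRestWindow:
    def test_fits_after_io(self):
        assert select_rest_window(io_time=5.0, trial_end=15.5) == (4.0, 5.0)

    def test_switches_before_io(self):
        assert select_rest_window(io_time=11.0, trial_end=15.5) == (-5.0, -4.0)

    def test_exact_fit_boundary_inclusive(self):
        assert select_rest_window(io_time=10.5, trial_end=15.5) == (4.0, 5.0)


class TestExtractFeatures:
    def test_constant_signal(self):
        rec, trials = make_detection_fixture(n_trials=6, amp=0.0)
        rec = rec.copy_with(np.full_like(rec.data, 3.0))
        fs = extract_features(rec, trials, mi_start=0.0)
        assert np.all(fs.X == 3.0)

    def test_dimensionality_260(self):
        rec, trials = make_detection_fixture(n_trials=6)
        fs = extract_features(rec, trials, mi_start=-1.0)
        assert fs.X.shape[1] == 26 * 10
        assert set(fs.y) == {0, 1}
        # one MI and one REST observation per trial
        assert fs.X.shape[0] == 12

    def test_resampled_sinusoid_matches_analytic(self):
        """0.5 Hz sinusoid at 250 Hz, downsampled to 10 Hz, matches the
        analytic waveform within 2%."""
        fs = 250.0
        t = np.arange(int(60 * fs)) / fs
        x = np.sin(2 * np.pi * 0.5 * t)
        rec = ContinuousRecording(x[:, None], fs, ["Cz"], ["EEG"])
        rec10 = downsample_10hz(rec)
        t10 = np.arange(rec10.n_samples) / 10.0
        core = slice(50, -50)
        expected = np.sin(2 * np.pi * 0.5 * t10)
        err = np.abs(rec10.data[core, 0] - expected[core]).max()
        assert err < 0.02

    def test_non_integer_factor_rejected(self):
        rec = ContinuousRecording(np.zeros((100, 1)), 44.0, ["Cz"], ["EEG"])
        with pytest.raises(ValueError):
            downsample_10hz(rec)


class TestShrinkageLDA:
    def test_separated_gaussians_perfect_training_accuracy(self, rng):
        X = rng.standard_normal((100, 20))
        y = np.repeat([0, 1], 50)
        X[y == 1] += 10.0
        model = fit_slda(X, y)
        assert np.mean(model.predict(X) == y) == 1.0

    def test_gamma_one_is_mean_difference_direction(self, rng):
        X = rng.standard_normal((80, 10))
        y = np.repeat([0, 1], 40)
        X[y == 1] += [1.0] + [0.0] * 9
        model = ShrinkageLDA(shrinkage=1.0).fit(X, y)
        diff = X[y == 1].mean(0) - X[y == 0].mean(0)
        cos = model.weights @ diff / (
            np.linalg.norm(model.weights) * np.linalg.norm(diff))
        assert cos == pytest.approx(1.0, abs=1e-12)

    def test_underdetermined_fit_regularized(self, rng):
        """n_obs=30 << n_features=260 fits without singularity, gamma>0."""
        X = rng.standard_normal((30, 260))
        y = np.repeat([0, 1], 15)
        model = fit_slda(X, y)
        assert np.isfinite(model.weights).all()
        assert 0 < model.gamma_ <= 1

    def test_gamma_matches_sklearn_ledoit_wolf(self, rng):
        """Analytic shrinkage intensity agrees with the reference
        Ledoit-Wolf computation on class-centered data."""
        from sklearn.covariance import ledoit_wolf_shrinkage

        X = rng.standard_normal((60, 15)) @ rng.standard_normal((15, 15))
        y = np.repeat([0, 1], 30)
        Xc = X.copy()
        Xc[y == 0] -= Xc[y == 0].mean(0)
        Xc[y == 1] -= Xc[y == 1].mean(0)
        ours = ledoit_wolf_gamma(Xc)
        ref = ledoit_wolf_shrinkage(Xc, assume_centered=True)
        assert ours == pytest.approx(ref, rel=1e-6)

    def test_weights_match_sklearn_covariance_oracle(self, rng):
        """Weights agree with an independent construction from sklearn's
        covariance utilities: pooled empirical covariance, Ledoit-Wolf
        intensity, shrunk_covariance, then a direct solve.

        (sklearn's own lsqr+auto LDA shrinks each class covariance before
        pooling, so it is deliberately not the reference here — the
        standard ERP shrinkage-LDA pools first.)
        """
        from scipy.linalg import solve
        from sklearn.covariance import (empirical_covariance,
                                        ledoit_wolf_shrinkage,
                                        shrunk_covariance)

        X = rng.standard_normal((40, 60))
        y = np.repeat([0, 1], 20)
        X[y == 1, :5] += 1.0
        ours = fit_slda(X, y)
        Xc = X.copy()
        Xc[y == 0] -= Xc[y == 0].mean(0)
        Xc[y == 1] -= Xc[y == 1].mean(0)
        gamma = ledoit_wolf_shrinkage(Xc, assume_centered=True)
        sigma = shrunk_covariance(
            empirical_covariance(Xc, assume_centered=True), gamma)
        w_ref = solve(sigma, X[y == 1].mean(0) - X[y == 0].mean(0),
                      assume_a="pos")
        assert np.allclose(ours.weights, w_ref, rtol=1e-8)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_slda(rng.standard_normal((10, 3)), np.zeros(10))

    def test_proba_boundary_and_complement(self, rng):
        X = rng.standard_normal((40, 5))
        y = np.repeat([0, 1], 20)
        X[y == 1] += 3.0
        model = fit_slda(X, y)
        mid = (X[y == 0].mean(0) + X[y == 1].mean(0)) / 2
        assert model.predict_proba(mid[None])[0] == pytest.approx(0.5, abs=1e-9)
        p = model.predict_proba(X)
        assert np.all((p >= 0) & (p <= 1))
        assert np.allclose(p + (1 - p), 1.0)
        assert model.predict_proba(X[y == 1].mean(0)[None])[0] > 0.9

    def test_dimension_mismatch_rejected(self, rng):
        model = fit_slda(rng.standard_normal((20, 5)),
                         np.repeat([0, 1], 10))
        with pytest.raises(ValueError):
            model.predict(rng.standard_normal((3, 7)))


class TestAdjustedWald:
    def test_closed_form_n100(self):
        lo, hi = adjusted_wald_interval(100)
        assert hi == pytest.approx(0.596, abs=0.001)
        assert lo == pytest.approx(0.404, abs=0.001)

    def test_large_n_limit(self):
        lo, hi = adjusted_wald_interval(10**7)
        assert hi - lo < 1e-3
        assert (lo + hi) / 2 == pytest.approx(0.5, abs=1e-6)

    def test_monotone_in_n(self):
        assert adjusted_wald_interval(50)[1] > adjusted_wald_interval(200)[1]

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            adjusted_wald_interval(0)


class TestCrossvalidation:
    def test_stratified_folds_partition(self, rng):
        labels = np.array(["ID", "IDII", "EC"] * 10)
        folds = stratified_folds(labels, 5, rng)
        allidx = np.sort(np.concatenate(folds))
        assert np.array_equal(allidx, np.arange(30))
        for f in folds:
            vals, counts = np.unique(labels[f], return_counts=True)
            assert counts.max() - counts.min() <= 1

    def test_large_margin_fixture_is_perfect(self):
        rec, trials = make_detection_fixture(n_trials=30, amp=-6.0, noise=0.0)
        res = crossvalidate_timelocked(rec, trials, repeats=2, seed=0)
        assert res.accuracy == 100.0
        assert res.tpr == 100.0 and res.fpr == 0.0

    def test_window_rule_follows_training_peak(self):
        rec, trials = make_detection_fixture(n_trials=15, peak_latency=0.2,
                                             noise=0.1)
        res = crossvalidate_timelocked(rec, trials, repeats=1, seed=0)
        assert set(res.mi_window_start_per_fold) == {-1.0}
        rec2, trials2 = make_detection_fixture(n_trials=15, peak_latency=1.0,
                                               noise=0.1, seed=1)
        res2 = crossvalidate_timelocked(rec2, trials2, repeats=1, seed=0)
        assert set(res2.mi_window_start_per_fold) == {0.0}

    def test_training_ignores_test_trials(self):
        """No leakage: corrupting a test fold's data does not change the
        model fit on the training folds."""
        rec, trials = make_detection_fixture(n_trials=20, noise=0.2)
        train, test = trials[:16], trials[16:]
        f1 = extract_features(rec, train, mi_start=0.0)
        m1 = fit_slda(f1.X, f1.y)
        rec2 = rec.copy_with(rec.data.copy())
        for tr in test:  # corrupt only test-trial segments
            i0 = int(round(tr.trial_start * rec.fs))
            i1 = int(round(tr.trial_end * rec.fs))
            rec2.data[i0:i1] += 100.0
        f2 = extract_features(rec2, train, mi_start=0.0)
        m2 = fit_slda(f2.X, f2.y)
        assert np.array_equal(m1.weights, m2.weights)

    def test_too_few_trials_rejected(self):
        rec, trials = make_detection_fixture(n_trials=6)
        with pytest.raises(ValueError):
            crossvalidate_timelocked(rec, trials[:6], repeats=1, folds=5)

    def test_separability_scaling(self):
        """Accuracy is non-decreasing in template amplitude (one inversion
        from sampling noise allowed)."""
        accs = []
        for amp in (-0.5, -1.5, -4.0):
            vals = []
            for seed in range(3):
                rec, trials = make_detection_fixture(
                    n_trials=20, amp=amp, noise=1.0, seed=seed)
                res = crossvalidate_timelocked(rec, trials, repeats=1,
                                               seed=seed)
                vals.append(res.accuracy)
            accs.append(np.mean(vals))
        inversions = sum(b < a - 1e-9 for a, b in zip(accs, accs[1:]))
        assert inversions <= 1
        assert accs[-1] > accs[0]


class TestAdjustedWaldProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @staticmethod
    @given(n=st.integers(1, 100000),
           alpha=st.floats(0.001, 0.5),
           p0=st.floats(0.05, 0.95))
    @settings(derandomize=True, max_examples=80, deadline=None)
    def test_interval_brackets_p0_within_unit_range(n, alpha, p0):
        lo, hi = adjusted_wald_interval(n, alpha=alpha, p0=p0)
        assert 0.0 <= lo <= hi <= 1.0
        assert lo <= p0 <= hi or n < 5  # tiny n may clip asymmetrically
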