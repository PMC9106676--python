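import numpy as np
import pandas as pd
import pytest

from cuffbp.io import WaveformRecord
from cuffbp.uncertainty import (
    OUTLIER,
    HyperplanePiModel,
    PiConfig,
    build_pi_features,
    cluster_calibration,
    fit_pi_model,
    merci_score,
    select_pi_config,
)


# ---------------------------------------------------------------------------
# feature construction


class TestPiFeatures:
    def _record(self, n=512):
        rng = np.random.default_rng(0)
        return WaveformRecord("s", 64.0, rng.normal(size=n), rng.normal(size=n))

    def test_width_short_window_without_bp(self):
        cfg = PiConfig(tau=0.3, include_bp=False)
        F, kept = build_pi_features(self._record(), np.array([2.0, 4.0]), cfg)
        assert F.shape == (2, 38)

    def test_width_waveform_bp_append(self):
        cfg = PiConfig(tau=0.9, include_bp=True)
        rec = self._record()
        wf = np.full(rec.n_samples, 100.0)
        F, _ = build_pi_features(rec, np.array([2.0, 4.0]), cfg, est_waveform=wf)
        assert F.shape == (2, 171)  # 57 ECG + 57 PPG + 57 estimated BP samples

    def test_width_scalar_bp_append(self):
        cfg = PiConfig(tau=0.9, include_bp=True)
        F, _ = build_pi_features(
            self._record(), np.array([2.0, 4.0]), cfg, estimates=np.array([118.0, 121.0])
        )
        assert F.shape == (2, 115)  # 2*57 + 1 scalar estimate

    def test_window_before_start_dropped(self):
        cfg = PiConfig(tau=1.5, include_bp=False)
        F, kept = build_pi_features(self._record(), np.array([0.5, 4.0]), cfg)
        assert list(kept) == [1]

    def test_invalid_tau_rejected(self):
        with pytest.raises(ValueError, match="tau"):
            PiConfig(tau=0.4)


# ---------------------------------------------------------------------------
# hyperplane stack


@pytest.fixture(scope="module")
def gaussian_training():
    """2-D Gaussian features; error SD grows with radius (heteroscedastic)."""
    rng = np.random.default_rng(10)
    n = 2000
    X = rng.normal(size=(n, 2))
    radius = np.linalg.norm(X, axis=1)
    sigma = 2.0 + 3.0 * radius
    errors = rng.normal(0.0, 1.0, n) * sigma
    return X, errors, radius


@pytest.fixture(scope="module")
def fitted_model(gaussian_training):
    X, errors, _ = gaussian_training
    return fit_pi_model(X, errors)


class TestHyperplaneStack:
    def test_exactly_101_clusters(self, fitted_model):
        assert fitted_model.sigma_table_.size == 101
        assert np.isnan(fitted_model.sigma_table_[100])  # outlier cluster: no PI
        assert np.isfinite(fitted_model.sigma_table_[:100]).all()

    def test_outlier_fractions_match_levels(self, gaussian_training, fitted_model):
        X, _, _ = gaussian_training
        scores = fitted_model.decision_scores(X)
        n = X.shape[0]
        for lv in range(100):
            outside = int((scores < fitted_model.thresholds_[lv]).sum())
            assert abs(outside - np.ceil(lv * n / 100.0)) <= 1
        # no training point is an outlier (0% hyperplane encloses everything)
        assert (fitted_model.train_depths_ >= 0).all()

    def test_thresholds_nested(self, fitted_model):
        assert (np.diff(fitted_model.thresholds_) >= 0).all()

    def test_band_coverage(self, gaussian_training, fitted_model):
        X, _, _ = gaussian_training
        d = fitted_model.train_depths_
        n = X.shape[0]
        for i in range(0, 91, 10):
            frac = ((d >= i) & (d <= i + 9)).mean()
            assert abs(frac - 0.10) <= 0.02
        for i in (91, 95, 99):
            assert abs((d >= i).mean() - (100 - i) / 100.0) <= 0.02

    def test_homoscedastic_sigma_table_flat(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(2000, 3))
        errors = rng.normal(0.0, 5.0, 2000)
        model = fit_pi_model(X, errors)
        # 10%-wide bands (200 points each) estimate the SD tightly; the
        # deepest tail bands hold as few as 1% of points, so allow more slack
        assert np.all(np.abs(model.sigma_table_[:91] - 5.0) < 1.0)
        assert np.all(np.abs(model.sigma_table_[91:100] - 5.0) < 2.0)

    def test_heteroscedastic_sigma_decreases_with_depth(self, fitted_model):
        # deeper clusters (more central data) carry smaller error SD
        sig = fitted_model.sigma_table_[:100]
        assert sig[0] > sig[99]
        assert np.corrcoef(np.arange(100), sig)[0, 1] < -0.8

    def test_assignment_extremes(self, fitted_model):
        lo = fitted_model.thresholds_[0] - 1.0
        hi = fitted_model.thresholds_[-1] + 1.0
        d = fitted_model._depths_from_scores(np.array([lo, hi]))
        assert d[0] == OUTLIER and d[1] == 99

    def test_outlier_points_have_no_pi(self, fitted_model):
        far = np.array([[50.0, 50.0]])  # far outside the training cloud
        labels, pi = fitted_model.predict(far)
        assert labels[0] == OUTLIER and np.isnan(pi[0])

    def test_radial_toy_depth_matches_brute_force(self, gaussian_training, fitted_model):
        X, _, radius = gaussian_training
        rng = np.random.default_rng(12)
        probe = rng.normal(size=(200, 2))
        scores = fitted_model.decision_scores(probe)
        # brute-force depth: compare against every threshold directly
        brute = np.array(
            [max([x for x in range(100) if s >= fitted_model.thresholds_[x]], default=-1)
             for s in scores]
        )
        np.testing.assert_array_equal(fitted_model._depths_from_scores(scores), brute)
        # points at large radius receive larger PI than central points
        labels, pi = fitted_model.predict(probe)
        r = np.linalg.norm(probe, axis=1)
        inner, outer = pi[(r < 0.5) & (labels >= 0)], pi[(r > 2.0) & (labels >= 0)]
        assert inner.size and outer.size
        assert np.mean(outer) > np.mean(inner)

    def test_feature_width_mismatch_rejected(self, fitted_model):
        with pytest.raises(ValueError, match="width"):
            fitted_model.predict(np.zeros((3, 5)))

    def test_too_few_training_beats_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            fit_pi_model(np.zeros((50, 2)), np.zeros(50))


# ---------------------------------------------------------------------------
# MeRCI


class TestMerci:
    def test_perfectly_proportional_pi(self):
        assert merci_score([1, 2, 3], [1, 2, 3], alpha=100) == pytest.approx(2.0)

    def test_constant_pi(self):
        assert merci_score([0, 2, 4], [2, 2, 2], alpha=100) == pytest.approx(4.0)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(13)
        err = np.abs(rng.normal(size=500))
        pi = rng.uniform(1, 3, 500)
        s1 = merci_score(err, pi)
        s2 = merci_score(7.0 * err, 7.0 * pi)
        assert s2 == pytest.approx(7.0 * s1)

    def test_nonpositive_pi_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            merci_score([1.0], [0.0])

    def test_ideal_gaussian_ratio_three(self):
        # 99.7% of a normal distribution lies within +-3 SD
        rng = np.random.default_rng(14)
        pi = rng.uniform(2.0, 10.0, 100_000)
        err = np.abs(rng.normal(0.0, pi))
        assert merci_score(err, pi, alpha=99.7) / np.mean(pi) == pytest.approx(3.0, abs=0.15)


# ---------------------------------------------------------------------------
# configuration selection and calibration


class TestSelectPiConfig:
    def _setup(self):
        rng = np.random.default_rng(15)
        n, m = 1500, 800
        Xtr = rng.normal(size=(n, 2))
        Xte = rng.normal(size=(m, 2))
        sig_tr = 2.0 + 3.0 * np.linalg.norm(Xtr, axis=1)
        sig_te = 2.0 + 3.0 * np.linalg.norm(Xte, axis=1)
        etr = rng.normal(0, 1, n) * sig_tr
        ete = rng.normal(0, 1, m) * sig_te
        return Xtr, etr, Xte, ete

    def test_informative_features_beat_shuffled(self):
        Xtr, etr, Xte, ete = self._setup()
        rng = np.random.default_rng(16)
        good = PiConfig(tau=0.3, include_bp=False)
        bad = PiConfig(tau=0.6, include_bp=False)
        fit_feats = {good: Xtr, bad: rng.permutation(Xtr)}  # shuffled: uninformative
        test_feats = {good: Xte, bad: rng.permutation(Xte)}
        ranked = select_pi_config([good, bad], fit_feats, etr, test_feats, np.abs(ete))
        assert ranked[0][0] == good
        assert ranked[0][1] < ranked[1][1]

    def test_tie_keeps_declaration_order(self):
        Xtr, etr, Xte, ete = self._setup()
        a = PiConfig(tau=0.3, include_bp=False)
        b = PiConfig(tau=0.6, include_bp=False)
        ranked = select_pi_config(
            [a, b], {a: Xtr, b: Xtr}, etr, {a: Xte, b: Xte}, np.abs(ete)
        )
        assert [r[0] for r in ranked] == [a, b]

    def test_single_candidate_returned_as_best(self):
        Xtr, etr, Xte, ete = self._setup()
        only = PiConfig(tau=0.3, include_bp=False)
        ranked = select_pi_config([only], {only: Xtr}, etr, {only: Xte}, np.abs(ete))
        assert len(ranked) == 1 and ranked[0][0] == only


class TestClusterCalibration:
    def test_self_consistency_r_equals_one(self, gaussian_training, fitted_model):
        X, errors, _ = gaussian_training
        table, r = cluster_calibration(fitted_model, X, errors)
        np.testing.assert_allclose(table.sigma_train, table.sigma_test, rtol=1e-9)
        assert r == pytest.approx(1.0)

    def test_same_distribution_high_correlation(self, fitted_model):
        rng = np.random.default_rng(17)
        X = rng.normal(size=(5000, 2))
        sigma = 2.0 + 3.0 * np.linalg.norm(X, axis=1)
        errors = rng.normal(0, 1, 5000) * sigma
        _, r = cluster_calibration(fitted_model, X, errors)
        assert r > 0.8

    def test_single_depth_group_flagged_undefined(self, fitted_model):
        # identical points fall at one depth; the overlapping bands they
        # populate all share the same members, so no correlation is defined
        X = np.full((3, 2), 0.05)
        table, r = cluster_calibration(fitted_model, X, np.array([1.0, -1.0, 0.5]))
        assert table.sigma_test.nunique() <= 1 and np.isnan(r)
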