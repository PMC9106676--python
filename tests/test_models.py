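import numpy as np
import pytest
from types import SimpleNamespace

from cuffbp.estimators import (
    BootstrapMlpEnsemble,
    NarxEnsemble,
    PatLogRegressor,
    fit_pat_log,
)
from cuffbp.io import WaveformRecord
from cuffbp.preprocess import build_regression_frame, znorm_stats
from cuffbp.simulate import SimulationParams, render_recording


class TestPatLog:
    def test_noiseless_exact_recovery(self):
        rng = np.random.default_rng(0)
        pat = rng.uniform(0.15, 0.4, 50)
        sbp = 150.0 - 20.0 * np.log(pat)
        m = fit_pat_log(pat, sbp)
        assert m.a_ == pytest.approx(150.0, abs=1e-9)
        assert m.b_ == pytest.approx(-20.0, abs=1e-9)

    def test_constant_pat_is_singular(self):
        with pytest.raises(np.linalg.LinAlgError):
            fit_pat_log(np.full(10, 0.25), np.linspace(100, 120, 10))

    def test_predict_closed_forms(self):
        m = PatLogRegressor()
        m.a_, m.b_ = 150.0, -20.0
        out = m.predict([1.0, np.exp(-1.0), 0.0])
        assert out[0] == pytest.approx(150.0)
        assert out[1] == pytest.approx(170.0)
        assert np.isnan(out[2])  # nonpositive PAT -> missing estimate

    def test_too_few_beats_raises(self):
        with pytest.raises(ValueError, match="3 beats"):
            fit_pat_log([0.2, 0.3], [120, 110])

    def test_noisy_recovery_within_confidence_interval(self):
        # bias shrinks with n: at n=1000 the truth lies within ~3 SEs
        rng = np.random.default_rng(42)
        n = 1000
        pat = rng.uniform(0.12, 0.45, n)
        a0, b0 = 35.0, -60.0
        sbp = a0 + b0 * np.log(pat) + rng.normal(0, 4.0, n)
        m = fit_pat_log(pat, sbp)
        lp = np.log(pat)
        X = np.column_stack([np.ones(n), lp])
        resid = sbp - m.predict(pat)
        cov = np.linalg.inv(X.T @ X) * np.sum(resid**2) / (n - 2)
        se_a, se_b = np.sqrt(np.diag(cov))
        assert abs(m.a_ - a0) < 3 * se_a
        assert abs(m.b_ - b0) < 3 * se_b

    def test_parameter_recovery_from_generator(self, clean_recording):
        _, truth = clean_recording
        m = fit_pat_log(truth.beats.pat, truth.beats.sbp)
        a0, b0 = truth.params.pat_coeffs
        assert m.a_ == pytest.approx(a0, abs=1e-6)
        assert m.b_ == pytest.approx(b0, abs=1e-6)


class TestBootstrapMlp:
    def test_constant_target_learned(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(200, 5))
        m = BootstrapMlpEnsemble(n_members=1, random_state=0).fit(X, np.full(200, 104.0))
        np.testing.assert_allclose(m.predict(X), 104.0, atol=0.1)

    def test_same_seed_identical_weights(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(150, 4))
        y = X @ [1.0, -2.0, 0.5, 0.0] + 100
        m1 = BootstrapMlpEnsemble(n_members=3, random_state=7).fit(X, y)
        m2 = BootstrapMlpEnsemble(n_members=3, random_state=7).fit(X, y)
        for a, b in zip(m1.members_, m2.members_):
            for wa, wb in zip(a.coefs_, b.coefs_):
                np.testing.assert_array_equal(wa, wb)

    def test_learns_linear_signal_better_than_null(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(400, 6))
        beta = rng.normal(size=6)
        y = 110 + X @ beta
        m = BootstrapMlpEnsemble(n_members=2, random_state=0, max_iter=400).fit(X[:300], y[:300])
        rmse = np.sqrt(np.mean((m.predict(X[300:]) - y[300:]) ** 2))
        assert rmse < np.std(y[300:])

    def test_non_finite_inputs_rejected(self):
        X = np.zeros((120, 3))
        X[5, 1] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            BootstrapMlpEnsemble().fit(X, np.zeros(120))

    def test_width_mismatch_rejected(self):
        X = np.random.default_rng(0).normal(size=(120, 3))
        m = BootstrapMlpEnsemble(n_members=1).fit(X, np.zeros(120))
        with pytest.raises(ValueError, match="width"):
            m.predict(np.zeros((5, 4)))

    def test_member_permutation_invariance(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(150, 3))
        y = X.sum(axis=1)
        m = BootstrapMlpEnsemble(n_members=3, random_state=1).fit(X, y)
        before = m.predict(X)
        m.members_ = m.members_[::-1]
        np.testing.assert_allclose(m.predict(X), before)


def linear_member(n_inputs, fb1_weight=0.5, bias=60.0, fb1_index=None):
    """Identity-activation member implementing bp(k) = w*bp(k-1) + bias."""
    W1 = np.zeros((n_inputs, 1))
    W1[n_inputs - 2 if fb1_index is None else fb1_index, 0] = fb1_weight
    return SimpleNamespace(
        coefs_=[W1, np.array([[1.0]])],
        intercepts_=[np.array([0.0]), np.array([bias])],
        activation="identity",
    )


def make_test_record(n=256, fs=64.0):
    rng = np.random.default_rng(5)
    return WaveformRecord("s", fs, rng.normal(size=n), rng.normal(size=n),
                          bp=100 + 5 * rng.normal(size=n))


class TestNarx:
    def test_zero_network_outputs_constant(self):
        rec = make_test_record()
        member = SimpleNamespace(
            coefs_=[np.zeros((40, 1)), np.zeros((1, 1))],
            intercepts_=[np.zeros(1), np.array([100.0])],
            activation="tanh",
        )
        m = NarxEnsemble.from_members([member], n_inputs=40)
        wf = m.predict_free_run(rec, [100.0, 100.0])
        np.testing.assert_allclose(wf, 100.0)

    def test_linear_recursion_geometric_approach(self):
        # bp(k) = 0.5 bp(k-1) + 60 from (100, 100): 110, 115, 117.5, ... -> 120
        rec = make_test_record(n=64)
        m = NarxEnsemble.from_members([linear_member(40)], n_inputs=40)
        wf = m.predict_free_run(rec, [100.0, 100.0])
        k0 = 18
        expected = [110.0, 115.0, 117.5, 118.75]
        np.testing.assert_allclose(wf[k0 : k0 + 4], expected)
        assert abs(wf[-1] - 120.0) < 1e-3

    def test_ensemble_of_identical_members_equals_single(self):
        rec = make_test_record()
        one = NarxEnsemble.from_members([linear_member(40)], n_inputs=40)
        three = NarxEnsemble.from_members([linear_member(40)] * 3, n_inputs=40)
        np.testing.assert_allclose(
            one.predict_free_run(rec, [90, 90]), three.predict_free_run(rec, [90, 90])
        )

    def test_divergence_aborts(self):
        rec = make_test_record()
        m = NarxEnsemble.from_members([linear_member(40, fb1_weight=1.5, bias=10.0)], n_inputs=40)
        with pytest.raises(RuntimeError, match="diverged"):
            m.predict_free_run(rec, [200.0, 200.0])

    def test_missing_bp_channel_rejected(self):
        rec = WaveformRecord("s", 64.0, np.zeros(256), np.zeros(256))
        with pytest.raises(ValueError, match="BP channel"):
            NarxEnsemble(n_members=1).fit(rec)

    def test_bad_bp_init_rejected(self):
        m = NarxEnsemble.from_members([linear_member(40)], n_inputs=40)
        with pytest.raises(ValueError, match="two seed"):
            m.predict_free_run(make_test_record(), [100.0])


@pytest.fixture(scope="module")
def narx_training_setup():
    params = SimulationParams(duration=240.0, seed=21, noise_scale=0.0,
                              pat_jitter_sd=0.0, sbp_sd=6.0,
                              activity_schedule=[("sitting", 0.0, 240.0)],
                              train_sweep_mmhg=0.0)
    rec, _ = render_recording(params)
    stats = znorm_stats(rec.ppg)
    model = NarxEnsemble(n_members=2, max_iter=80, random_state=3).fit(rec, ppg_stats=stats)
    return rec, stats, model


class TestNarxTraining:
    def test_teacher_forced_rmse_below_2mmhg(self, narx_training_setup):
        rec, stats, model = narx_training_setup
        frame = build_regression_frame(rec, 19, include_bp_feedback=True, ppg_stats=stats)
        rmse = np.sqrt(np.mean((model.predict(frame.X) - frame.y) ** 2))
        assert rmse < 2.0

    def test_same_seed_identical_ensembles(self, narx_training_setup):
        rec, stats, model = narx_training_setup
        again = NarxEnsemble(n_members=2, max_iter=80, random_state=3).fit(rec, ppg_stats=stats)
        for a, b in zip(model.ensemble_.members_, again.ensemble_.members_):
            for wa, wb in zip(a.coefs_, b.coefs_):
                np.testing.assert_array_equal(wa, wb)

    def test_free_run_with_measured_feedback_equals_teacher_mode(self, narx_training_setup):
        rec, stats, model = narx_training_setup
        frame = build_regression_frame(rec, 19, include_bp_feedback=True, ppg_stats=stats)
        teacher = model.predict(frame.X)
        wf = model.predict_free_run(rec, rec.bp[:2], feedback_override=rec.bp)
        np.testing.assert_allclose(wf[18:], teacher, atol=1e-8)
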