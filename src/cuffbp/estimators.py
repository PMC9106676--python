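"""Blood-pressure estimators: logarithmic PAT model, direct feed-forward
ANN ensembles, and the NARX waveform-estimator ensemble.

All three are scikit-learn style estimators.  The ANN and NARX members are
single-hidden-layer tanh perceptrons (hidden size 19 by default, close to
the few-hundred-parameter scale of the reference architectures), five of
which are bootstrap-ensembled to reduce estimation variance.  The NARX is
trained series-parallel (teacher forcing with the measured BP at steps k-1
and k-2) and deployed as a recurrent network that feeds back its own
outputs (free-run).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPRegressor
from sklearn.utils.validation import check_is_fitted

from .preprocess import build_regression_frame, sliding_window_view, _zppg

log = logging.getLogger(__name__)

__all__ = [
    "PatLogRegressor",
    "BootstrapMlpEnsemble",
    "NarxEnsemble",
    "fit_pat_log",
    "predict_pat_log",
    "fit_ann_direct",
    "predict_ann_direct",
    "fit_narx",
    "predict_narx_freerun",
]

DIVERGENCE_LIMIT = 350.0  # mmHg; free-run aborts beyond this


class PatLogRegressor(RegressorMixin, BaseEstimator):
    """Logarithmic PAT model: ``SBP = a + b ln(PAT)``.

    Two tunable parameters, fitted by least squares on per-beat
    (PAT, SBP) pairs; the physiological inverse PAT-SBP relation gives b < 0.
    """

    def fit(self, X, y):
        pat = np.asarray(X, dtype=float).reshape(-1)
        sbp = np.asarray(y, dtype=float).reshape(-1)
        if pat.size != sbp.size:
            raise ValueError("PAT and SBP must be aligned")
        ok = np.isfinite(pat) & np.isfinite(sbp) & (pat > 0)
        pat, sbp = pat[ok], sbp[ok]
        if pat.size < 3:
            raise ValueError("need at least 3 beats with finite positive PAT")
        lp = np.log(pat)
        if np.ptp(lp) < 1e-12:
            raise np.linalg.LinAlgError("all PAT values equal: singular fit")
        A = np.column_stack([np.ones_like(lp), lp])
        coef, *_ = np.linalg.lstsq(A, sbp, rcond=None)
        self.a_, self.b_ = float(coef[0]), float(coef[1])
        self.n_beats_ = int(pat.size)
        return self

    def predict(self, X):
        check_is_fitted(self, "a_")
        pat = np.asarray(X, dtype=float).reshape(-1)
        out = np.full(pat.shape, np.nan)
        ok = np.isfinite(pat) & (pat > 0)
        if (~ok).any():
            log.warning("%d beats with nonpositive/missing PAT: estimate missing", int((~ok).sum()))
        out[ok] = self.a_ + self.b_ * np.log(pat[ok])
        return out


class BootstrapMlpEnsemble(RegressorMixin, BaseEstimator):
    """Bootstrap ensemble of single-hidden-layer tanh MLP regressors.

    Each member is trained on a resample-with-replacement of the rows; the
    ensemble prediction is the member mean.  Targets are z-scaled internally
    so training is well conditioned regardless of BP units.  Deterministic
    given ``random_state``.
    """

    def __init__(
        self,
        n_members: int = 5,
        hidden_size: int = 19,
        activation: str = "tanh",
        max_iter: int = 300,
        alpha: float = 1e-4,
        bootstrap: bool = True,
        random_state: int = 0,
    ):
        self.n_members = n_members
        self.hidden_size = hidden_size
        self.activation = activation
        self.max_iter = max_iter
        self.alpha = alpha
        self.bootstrap = bootstrap
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).reshape(-1)
        if X.ndim != 2 or X.shape[0] != y.size:
            raise ValueError("X must be 2-D and aligned with y")
        if not (np.isfinite(X).all() and np.isfinite(y).all()):
            raise ValueError("non-finite values in training data")
        if self.n_members < 1:
            raise ValueError("n_members must be >= 1")
        n = X.shape[0]
        self.y_mean_ = float(np.mean(y))
        self.y_scale_ = float(np.std(y)) or 1.0
        ys = (y - self.y_mean_) / self.y_scale_
        rng = np.random.default_rng(self.random_state)
        self.members_ = []
        self.bootstrap_indices_ = []
        for m in range(self.n_members):
            idx = rng.integers(0, n, n) if self.bootstrap else np.arange(n)
            seed = int(rng.integers(0, 2**31 - 1))
            member = MLPRegressor(
                hidden_layer_sizes=(self.hidden_size,),
                activation=self.activation,
                solver="lbfgs",
                alpha=self.alpha,
                max_iter=self.max_iter,
                random_state=seed,
            )
            with warnings.catch_warnings():
                # the epoch cap is an intentional training budget
                warnings.simplefilter("ignore", ConvergenceWarning)
                member.fit(X[idx], ys[idx])
            self.members_.append(member)
            self.bootstrap_indices_.append(idx)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "members_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"input width {X.shape[1]} does not match ensemble width {self.n_features_in_}"
            )
        preds = np.mean([m.predict(X) for m in self.members_], axis=0)
        return preds * self.y_scale_ + self.y_mean_


def _member_weights(member):
    """(W1, b1, W2, b2, activation) of an MLP-like object."""
    W1, W2 = member.coefs_
    b1, b2 = member.intercepts_
    act = getattr(member, "activation", "tanh")
    return np.asarray(W1), np.asarray(b1), np.asarray(W2).reshape(-1), float(np.asarray(b2).reshape(-1)[0]), act


class NarxEnsemble(RegressorMixin, BaseEstimator):
    """Nonlinear autoregressive BP-waveform estimator with exogenous inputs.

    Inputs at step k are the last ``lags`` samples of ECG and z-PPG plus the
    BP at steps k-1 and k-2.  Training is series-parallel (measured BP fed
    back); prediction runs closed-loop on the network's own outputs.  Inputs
    and targets are standardized with training statistics held by the model.
    """

    def __init__(
        self,
        lags: int = 19,
        n_members: int = 5,
        hidden_size: int = 19,
        activation: str = "tanh",
        max_iter: int = 60,
        alpha: float = 1e-4,
        random_state: int = 0,
    ):
        self.lags = lags
        self.n_members = n_members
        self.hidden_size = hidden_size
        self.activation = activation
        self.max_iter = max_iter
        self.alpha = alpha
        self.random_state = random_state

    # -- frame helpers -------------------------------------------------
    def _scale_X(self, X):
        return (X - self.x_mean_) / self.x_scale_

    def fit(self, records, ppg_stats=None):
        """Train on one or more records carrying a BP channel."""
        if not isinstance(records, (list, tuple)):
            records = [records]
        frames = []
        for rec in records:
            if rec.bp is None:
                raise ValueError("NARX training requires a BP channel")
            frames.append(
                build_regression_frame(
                    rec, lags=self.lags, include_bp_feedback=True, ppg_stats=ppg_stats
                )
            )
        X = np.vstack([f.X for f in frames])
        y = np.concatenate([f.y for f in frames])
        self.ppg_stats_ = ppg_stats
        self.x_mean_ = X.mean(axis=0)
        self.x_scale_ = np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
        self.ensemble_ = BootstrapMlpEnsemble(
            n_members=self.n_members,
            hidden_size=self.hidden_size,
            activation=self.activation,
            max_iter=self.max_iter,
            alpha=self.alpha,
            random_state=self.random_state,
        ).fit(self._scale_X(X), y)
        self.n_features_in_ = X.shape[1]
        return self

    @classmethod
    def from_members(cls, members, n_inputs, lags=19, x_mean=None, x_scale=None,
                     y_mean=0.0, y_scale=1.0):
        """Assemble an ensemble from hand-built members (objects exposing
        ``coefs_`` and ``intercepts_``); used for analytic checks."""
        self = cls(lags=lags, n_members=len(members))
        self.x_mean_ = np.zeros(n_inputs) if x_mean is None else np.asarray(x_mean, float)
        self.x_scale_ = np.ones(n_inputs) if x_scale is None else np.asarray(x_scale, float)
        self.ppg_stats_ = None
        self.n_features_in_ = n_inputs
        ens = BootstrapMlpEnsemble(n_members=len(members))
        ens.members_ = list(members)
        ens.y_mean_ = float(y_mean)
        ens.y_scale_ = float(y_scale)
        ens.n_features_in_ = n_inputs
        self.ensemble_ = ens
        return self

    def predict(self, X):
        """Teacher-forced one-step prediction on a feedback frame."""
        check_is_fitted(self, "ensemble_")
        return self.ensemble_.predict(self._scale_X(np.asarray(X, dtype=float)))

    def predict_free_run(
        self,
        record,
        bp_init,
        feedback_override: np.ndarray | None = None,
        chunk: int = 65536,
    ) -> np.ndarray:
        """Closed-loop BP waveform over a record.

        ``bp_init`` supplies the two seed feedback values (mmHg).  With
        ``feedback_override`` (a measured BP series aligned with the record)
        the recursion uses the measured feedback instead of its own outputs,
        which reproduces teacher-forced predictions exactly.  Aborts if the
        output leaves (-350, 350) mmHg.
        """
        check_is_fitted(self, "ensemble_")
        bp_init = np.asarray(bp_init, dtype=float).reshape(-1)
        if bp_init.size != 2:
            raise ValueError("bp_init must supply exactly two seed samples")
        n = record.n_samples
        lags = self.lags
        k0 = max(lags - 1, 2)
        zp = _zppg(record, self.ppg_stats_)
        ecg_w = sliding_window_view(record.ecg, lags)[k0 - (lags - 1):]
        ppg_w = sliding_window_view(zp, lags)[k0 - (lags - 1):]
        nk = n - k0

        ym, ysc = self.ensemble_.y_mean_, self.ensemble_.y_scale_
        xm, xs = self.x_mean_, self.x_scale_
        members = [
            _member_weights(m) for m in self.ensemble_.members_
        ]
        M = len(members)
        H = members[0][0].shape[1]
        W1e = np.stack([w[0][: 2 * lags] for w in members])        # (M, 2*lags, H)
        w_fb1 = np.stack([w[0][2 * lags] for w in members])        # (M, H)
        w_fb2 = np.stack([w[0][2 * lags + 1] for w in members])    # (M, H)
        b1 = np.stack([w[1] for w in members])                     # (M, H)
        W2 = np.stack([w[2] for w in members])                     # (M, H)
        b2 = np.array([w[3] for w in members])                     # (M,)
        acts = [w[4] for w in members]
        tanh_mask = np.array([a == "tanh" for a in acts])

        out = np.empty(nk)
        prev1, prev2 = bp_init[1], bp_init[0]
        for c0 in range(0, nk, chunk):
            c1 = min(c0 + chunk, nk)
            exog = np.hstack([ecg_w[c0:c1], ppg_w[c0:c1]])
            exog = (exog - xm[: 2 * lags]) / xs[: 2 * lags]
            # precompute exogenous contribution to every member's hidden layer
            eh = np.einsum("kd,mdh->kmh", exog, W1e) + b1  # (chunk, M, H)
            for j in range(c1 - c0):
                k = c0 + j
                if feedback_override is not None:
                    f1 = feedback_override[k0 + k - 1]
                    f2 = feedback_override[k0 + k - 2]
                else:
                    f1, f2 = prev1, prev2
                z1 = (f1 - xm[2 * lags]) / xs[2 * lags]
                z2 = (f2 - xm[2 * lags + 1]) / xs[2 * lags + 1]
                h = eh[j] + z1 * w_fb1 + z2 * w_fb2
                if tanh_mask.all():
                    h = np.tanh(h)
                elif tanh_mask.any():
                    h[tanh_mask] = np.tanh(h[tanh_mask])
                yk = float(np.mean(np.sum(h * W2, axis=1) + b2)) * ysc + ym
                if not np.isfinite(yk) or abs(yk) > DIVERGENCE_LIMIT:
                    raise RuntimeError(
                        f"NARX free-run diverged at step {k0 + k} (output {yk:.1f} mmHg)"
                    )
                out[k] = yk
                prev2, prev1 = prev1, yk
        waveform = np.empty(n)
        waveform[:k0] = bp_init[1]
        waveform[k0:] = out
        return waveform


# ---------------------------------------------------------------------------
# Thin functional wrappers

def fit_pat_log(pat, sbp) -> PatLogRegressor:
    return PatLogRegressor().fit(pat, sbp)


def predict_pat_log(model: PatLogRegressor, pat) -> np.ndarray:
    return model.predict(pat)


def fit_ann_direct(frame_X, target, n_members: int = 5, seed: int = 0,
                   hidden_size: int = 19, max_iter: int = 300) -> BootstrapMlpEnsemble:
    X = np.asarray(frame_X, dtype=float)
    if X.shape[0] < 100:
        raise ValueError("need at least 100 training rows for the direct ANN")
    return BootstrapMlpEnsemble(
        n_members=n_members, hidden_size=hidden_size, max_iter=max_iter, random_state=seed
    ).fit(X, target)


def predict_ann_direct(ensemble: BootstrapMlpEnsemble, frame_X) -> np.ndarray:
    return ensemble.predict(np.asarray(frame_X, dtype=float))


def fit_narx(records, lags: int = 19, n_members: int = 5, seed: int = 0,
             ppg_stats=None, hidden_size: int = 19, max_iter: int = 60) -> NarxEnsemble:
    return NarxEnsemble(
        lags=lags, n_members=n_members, hidden_size=hidden_size,
        max_iter=max_iter, random_state=seed,
    ).fit(records, ppg_stats=ppg_stats)


def predict_narx_freerun(ensemble: NarxEnsemble, record, bp_init) -> np.ndarray:
    return ensemble.predict_free_run(record, bp_init)
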