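"""Prediction-interval estimation via a one-class-SVM hyperplane stack.

A single one-class SVM (Gaussian kernel, nu = 0.5) is trained on per-beat
features; 100 nested hyperplanes at outlier percentages 0..99% are realized
as empirical percentiles of the training decision scores, which guarantees
nesting and exact outlier fractions.  The hyperplanes group data into 101
clusters: cluster i (i <= 90) spans hyperplanes i..i+9, clusters 91..99 are
"inside the i% hyperplane", and everything outside the 0% hyperplane is the
outlier cluster.  Each non-outlier cluster carries the standard deviation of
the training BP errors that fall in it; a new estimate assigned to a cluster
inherits that SD as its prediction interval (PI).  The outlier cluster has
no PI by definition (no training data lie there).

PI quality is scored with MeRCI: the alpha-th percentile of the normalized
absolute errors lambda_i = |err_i| / sigma_i times the mean PI.  For a
perfectly calibrated Gaussian PI and alpha = 99.7, MeRCI / mean(PI) -> 3.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from scipy.stats import pearsonr
from sklearn.base import BaseEstimator
from sklearn.preprocessing import StandardScaler
from sklearn.svm import OneClassSVM

log = logging.getLogger(__name__)

__all__ = [
    "OUTLIER",
    "PiConfig",
    "HyperplanePiModel",
    "build_pi_features",
    "fit_pi_model",
    "assign_cluster",
    "merci_score",
    "select_pi_config",
    "cluster_calibration",
]

OUTLIER = -1  # cluster label for points outside the 0% hyperplane


@dataclass(frozen=True)
class PiConfig:
    """Input configuration of a PI model.

    ``tau`` is the ECG/PPG segment length in seconds (a multiple of 0.3 in
    0.3..1.5); ``include_bp`` appends the estimated BP — the estimated
    waveform segment for a waveform model, the scalar estimate otherwise.
    """

    tau: float = 0.9
    include_bp: bool = True
    nu: float = 0.5
    band_width: int = 10

    def __post_init__(self):
        n = self.tau / 0.3
        if not (abs(n - round(n)) < 1e-9 and 1 <= round(n) <= 5):
            raise ValueError("tau must be 0.3*n seconds with n in 1..5")
        if not 0 < self.nu <= 1:
            raise ValueError("nu must be in (0, 1]")

    @property
    def n_lags(self) -> int:
        """Samples per channel window: 19 per 0.3 s at 64 Hz."""
        return 19 * int(round(self.tau / 0.3))

    def label(self) -> str:
        return f"tau={self.tau:g} {'w/ BP' if self.include_bp else 'w/o BP'}"


def build_pi_features(
    record,
    r_peaks: np.ndarray,
    config: PiConfig,
    estimates: np.ndarray | None = None,
    est_waveform: np.ndarray | None = None,
    ppg_stats=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-beat OCSVM inputs: the last ``19n`` samples of ECG and z-PPG
    ending at the R-peak, optionally followed by the estimated BP (waveform
    segment if ``est_waveform`` is given, else the scalar estimate).

    Returns ``(F, kept)`` where ``kept`` indexes beats whose window fits in
    the record; dropped beats are logged.
    """
    from .preprocess import _zppg

    L = config.n_lags
    zp = _zppg(record, ppg_stats)
    ks = np.round((np.asarray(r_peaks, dtype=float) - record.t0) * record.fs).astype(int)
    kept = np.nonzero((ks >= L - 1) & (ks < record.n_samples))[0]
    if kept.size < ks.size:
        log.info("%d beats dropped: PI window extends before record start", ks.size - kept.size)
    rows = []
    for i in kept:
        k = ks[i]
        row = [record.ecg[k - L + 1 : k + 1], zp[k - L + 1 : k + 1]]
        if config.include_bp:
            if est_waveform is not None:
                row.append(est_waveform[k - L + 1 : k + 1])
            else:
                if estimates is None:
                    raise ValueError("include_bp requires estimates or est_waveform")
                row.append(np.atleast_1d(estimates[i]))
        rows.append(np.concatenate(row))
    F = np.array(rows) if rows else np.empty((0, 2 * L + (L if est_waveform is not None else int(config.include_bp))))
    return F, kept


def _median_heuristic_gamma(X: np.ndarray, rng_seed: int = 0, max_points: int = 2000) -> float:
    """RBF bandwidth 1/(2 d_med^2) from the median pairwise distance."""
    if X.shape[0] > max_points:
        idx = np.random.default_rng(rng_seed).choice(X.shape[0], max_points, replace=False)
        X = X[idx]
    d = np.median(pdist(X))
    if not d > 0:
        d = 1.0
    return 1.0 / (2.0 * d * d)


class HyperplanePiModel(BaseEstimator):
    """One-class-SVM hyperplane stack mapping new estimates to a PI.

    Fitted attributes
    -----------------
    thresholds_ : (100,) decision-score cutoffs; the X% hyperplane encloses
        scores >= ``thresholds_[X]`` and exactly ceil(X*n/100) training
        points fall outside it (up to ties).
    sigma_table_ : (101,) error SD per cluster; index 100 is the outlier
        cluster and is NaN (no PI defined there).
    """

    N_LEVELS = 100
    N_CLUSTERS = 101

    def __init__(self, nu: float = 0.5, gamma="median", band_width: int = 10,
                 min_train: int = 200, config: PiConfig | None = None):
        self.nu = nu
        self.gamma = gamma
        self.band_width = band_width
        self.min_train = min_train
        self.config = config

    def fit(self, X, errors):
        """Fit on training features and *signed* BP estimation errors."""
        X = np.asarray(X, dtype=float)
        errors = np.asarray(errors, dtype=float).reshape(-1)
        if X.ndim != 2 or X.shape[0] != errors.size:
            raise ValueError("X must be 2-D and aligned with errors")
        n = X.shape[0]
        if n < self.min_train:
            raise ValueError(f"need at least {self.min_train} training beats, got {n}")
        if not (np.isfinite(X).all() and np.isfinite(errors).all()):
            raise ValueError("non-finite training inputs")
        self.scaler_ = StandardScaler().fit(X)
        Xs = self.scaler_.transform(X)
        self.gamma_ = (
            _median_heuristic_gamma(Xs) if self.gamma == "median" else float(self.gamma)
        )
        self.svm_ = OneClassSVM(kernel="rbf", nu=self.nu, gamma=self.gamma_).fit(Xs)
        scores = self.svm_.decision_function(Xs)
        order = np.sort(scores)
        ks = np.ceil(np.arange(self.N_LEVELS) * n / 100.0).astype(int)
        self.thresholds_ = order[np.minimum(ks, n - 1)]
        depths = self._depths_from_scores(scores)
        # training points all lie inside the 0% hyperplane by construction
        bw = self.band_width
        sig = np.full(self.N_LEVELS, np.nan)
        for i in range(self.N_LEVELS):
            hi = i + bw - 1
            sel = (depths >= i) & (depths <= hi) if hi < self.N_LEVELS else depths >= i
            if sel.sum() >= 2:
                sig[i] = np.std(errors[sel], ddof=1)
        if np.isnan(sig).any():
            defined = np.nonzero(~np.isnan(sig))[0]
            if defined.size == 0:
                raise ValueError("no populated clusters")
            warnings.warn("empty PI clusters interpolated from neighbours")
            sig = np.interp(np.arange(self.N_LEVELS), defined, sig[defined])
        self.sigma_table_ = np.append(sig, np.nan)  # index 100 = outlier cluster
        self.n_features_in_ = X.shape[1]
        self.train_depths_ = depths
        return self

    def _depths_from_scores(self, scores: np.ndarray) -> np.ndarray:
        """Largest X with score inside the X% hyperplane; -1 = outlier."""
        return np.searchsorted(self.thresholds_, scores, side="right") - 1

    def decision_scores(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature width mismatch")
        return self.svm_.decision_function(self.scaler_.transform(X))

    def predict(self, X) -> tuple[np.ndarray, np.ndarray]:
        """Cluster labels (0..99, or -1 for outliers) and PI in mmHg
        (NaN for outliers)."""
        depths = self._depths_from_scores(self.decision_scores(X))
        pi = np.where(depths >= 0, self.sigma_table_[np.maximum(depths, 0)], np.nan)
        return depths, pi

    def assign_one(self, feature_row) -> tuple[int, float]:
        labels, pi = self.predict(np.atleast_2d(feature_row))
        return int(labels[0]), float(pi[0])


def fit_pi_model(features_train, signed_errors_train, config: PiConfig | None = None) -> HyperplanePiModel:
    cfg = config or PiConfig()
    return HyperplanePiModel(nu=cfg.nu, band_width=cfg.band_width, config=cfg).fit(
        features_train, signed_errors_train
    )


def assign_cluster(model: HyperplanePiModel, feature_row) -> tuple[int, float]:
    return model.assign_one(feature_row)


def merci_score(abs_errors, pis, alpha: float = 99.7) -> float:
    """Mean rescaled PI covering ``alpha``% of normalized errors (Eq. style:
    percentile of |err|/sigma times mean sigma); lower is better."""
    abs_errors = np.asarray(abs_errors, dtype=float).reshape(-1)
    pis = np.asarray(pis, dtype=float).reshape(-1)
    if abs_errors.size != pis.size:
        raise ValueError("errors and PIs must be aligned")
    if abs_errors.size == 0:
        raise ValueError("empty inputs")
    if not (pis > 0).all():
        raise ValueError("all PIs must be positive (exclude outlier beats first)")
    lam = abs_errors / pis
    lam_alpha = np.percentile(lam, alpha)
    return float(lam_alpha * np.mean(pis))


def select_pi_config(
    configs,
    fit_features: dict,
    train_errors: np.ndarray,
    test_features: dict,
    test_abs_errors: np.ndarray,
    alpha: float = 99.7,
):
    """Rank candidate PI configurations by held-out MeRCI (ascending).

    ``fit_features``/``test_features`` map each config to its feature matrix
    (built with :func:`build_pi_features`); beats assigned to the outlier
    cluster are excluded from the score.  Ties keep declaration order.
    """
    configs = list(configs)
    if len(configs) < 2:
        if len(configs) == 1:
            model = fit_pi_model(fit_features[configs[0]], train_errors, configs[0])
            _, pi = model.predict(test_features[configs[0]])
            ok = np.isfinite(pi)
            return [(configs[0], merci_score(test_abs_errors[ok], pi[ok], alpha), model)]
        raise ValueError("need at least one candidate configuration")
    ranked = []
    for j, cfg in enumerate(configs):
        model = fit_pi_model(fit_features[cfg], train_errors, cfg)
        _, pi = model.predict(test_features[cfg])
        ok = np.isfinite(pi) & np.isfinite(test_abs_errors)
        score = merci_score(test_abs_errors[ok], pi[ok], alpha)
        ranked.append((score, j, cfg, model))
    ranked.sort(key=lambda r: (r[0], r[1]))
    return [(cfg, score, model) for score, _, cfg, model in ranked]


def cluster_calibration(
    model: HyperplanePiModel, features_test, errors_test
) -> tuple[pd.DataFrame, float]:
    """Per-cluster training sigma vs empirically recomputed test sigma.

    Returns the pair table and the Pearson correlation over clusters with at
    least two test members; with fewer than two populated clusters the
    correlation is NaN (flagged undefined).
    """
    errors_test = np.asarray(errors_test, dtype=float).reshape(-1)
    depths = model._depths_from_scores(model.decision_scores(features_test))
    bw = model.band_width
    rows = []
    for i in range(model.N_LEVELS):
        hi = i + bw - 1
        sel = (depths >= i) & (depths <= hi) if hi < model.N_LEVELS else depths >= i
        if sel.sum() >= 2:
            rows.append(
                {
                    "cluster": i,
                    "sigma_train": model.sigma_table_[i],
                    "sigma_test": float(np.std(errors_test[sel], ddof=1)),
                    "n_test": int(sel.sum()),
                }
            )
    table = pd.DataFrame(rows, columns=["cluster", "sigma_train", "sigma_test", "n_test"])
    if (
        len(table) < 2
        or np.std(table["sigma_train"]) == 0
        or np.std(table["sigma_test"]) == 0
    ):
        log.warning("degenerate cluster population: correlation undefined")
        return table, float("nan")
    r = pearsonr(table["sigma_train"], table["sigma_test"]).statistic
    return table, float(r)
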