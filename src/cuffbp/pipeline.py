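"""End-to-end orchestration: estimate -> prediction interval -> fuse ->
evaluate, on a session split into training head/tail and a test block.

The three-step process: (1) train the BP estimators on the two calibration
segments; (2) fit a hyperplane-stack PI model per estimator from its
training-segment errors; (3) fuse the per-beat estimates by covariance
intersection weighted by the PI, then evaluate every single model and every
fusion set on the test block.  Everything is reproducible given the seed;
training never touches test-span samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluation import (
    DEFAULT_LIMITS,
    EvalReport,
    activity_stats,
    error_stats,
    mae_delta_p_bins,
    standards_check,
    tradeoff_curve,
)
from .estimators import NarxEnsemble, PatLogRegressor, fit_ann_direct
from .fusion import fuse_estimates
from .io import SessionSplit, WaveformRecord, split_sessions
from .preprocess import (
    build_beat_frame,
    compute_pat,
    detect_r_peaks,
    extract_sbp_dbp,
    znorm_stats,
)
from .uncertainty import PiConfig, build_pi_features, fit_pi_model, merci_score

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

DEFAULT_FUSION_SETS = (
    ("narx", "ann"),
    ("narx", "patlog"),
    ("ann", "patlog"),
    ("narx", "ann", "patlog"),
)


@dataclass
class PipelineConfig:
    """Configuration of a full estimation/uncertainty/fusion run."""

    target: str = "sbp"
    train_minutes: float = 15.0
    models: tuple = ("narx", "ann", "patlog")
    fusion_sets: tuple = DEFAULT_FUSION_SETS
    pi_config: PiConfig = field(default_factory=PiConfig)
    sigma_t_list: tuple = (8.0, 9.0)
    tradeoff_thresholds: tuple = (4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0, 12.0, 15.0, float("inf"))
    strategy: str = "inverse_variance"
    pi_map: str = "variance"
    seed: int = 0
    lags: int = 19
    n_members: int = 5
    hidden_size: int = 19
    ann_max_iter: int = 200
    narx_max_iter: int = 60
    limits: dict = field(default_factory=lambda: dict(DEFAULT_LIMITS))

    def __post_init__(self):
        if self.target not in ("sbp", "dbp"):
            raise ValueError("target must be 'sbp' or 'dbp'")
        roster = set(self.models)
        if self.target == "dbp" and "patlog" in roster:
            raise ValueError("the PAT-log model estimates SBP only")
        for fset in self.fusion_sets:
            missing = set(fset) - roster
            if missing:
                raise ValueError(f"fusion set {fset} references untrained models: {sorted(missing)}")


@dataclass
class PipelineResult:
    reports: dict
    beats: pd.DataFrame
    models: dict
    pi_models: dict
    metadata: dict


def _segment_beats(seg: WaveformRecord) -> pd.DataFrame:
    """Detect beats in a segment and extract PAT, reference SBP/DBP and
    activity; times are absolute (segment t0 included)."""
    r_rel = detect_r_peaks(seg.ecg, seg.fs)
    pat = compute_pat(r_rel, seg.ppg, seg.fs)
    if seg.bp is not None:
        sbp, dbp = extract_sbp_dbp(seg.bp, r_rel, seg.fs)
    else:
        sbp = dbp = np.full(r_rel.size, np.nan)
    if seg.activity is not None:
        ks = np.minimum(np.round(r_rel * seg.fs).astype(int), seg.n_samples - 1)
        act = seg.activity[ks]
    else:
        act = np.full(r_rel.size, "other", dtype=object)
    return pd.DataFrame(
        {
            "t_rpeak": seg.t0 + r_rel,
            "t_rel": r_rel,
            "pat": pat,
            "sbp_ref": sbp,
            "dbp_ref": dbp,
            "activity": act,
        }
    )


class _SegmentData:
    """Per-segment working set: the record, its beat table, and per-model
    estimate columns filled in as models run."""

    def __init__(self, seg: WaveformRecord):
        self.record = seg
        self.beats = _segment_beats(seg)
        self.est: dict[str, np.ndarray] = {}
        self.waveform: dict[str, np.ndarray] = {}


def _run_models(cfg: PipelineConfig, split: SessionSplit, ppg_stats, target_col):
    """Train all models on the head+tail segments, produce per-beat
    estimates on every segment (train segments in free-run for NARX, so
    training errors reflect deployment conditions)."""
    head, tail, test = _SegmentData(split.train_head), _SegmentData(split.train_tail), _SegmentData(split.test)
    train_segs = [head, tail]
    models: dict[str, object] = {}

    if "patlog" in cfg.models:
        tr = pd.concat([s.beats for s in train_segs])
        ok = np.isfinite(tr["pat"]) & np.isfinite(tr[target_col])
        model = PatLogRegressor().fit(tr["pat"][ok], tr[target_col][ok])
        models["patlog"] = model
        for s in (head, tail, test):
            s.est["patlog"] = model.predict(s.beats["pat"].to_numpy())

    if "ann" in cfg.models:
        Xs, ys = [], []
        for s in train_segs:
            X, kept = build_beat_frame(s.record, s.beats["t_rpeak"].to_numpy(), cfg.lags, ppg_stats)
            y = s.beats[target_col].to_numpy()[kept]
            ok = np.isfinite(y)
            Xs.append(X[ok])
            ys.append(y[ok])
        model = fit_ann_direct(
            np.vstack(Xs), np.concatenate(ys), n_members=cfg.n_members,
            seed=cfg.seed + 101, hidden_size=cfg.hidden_size, max_iter=cfg.ann_max_iter,
        )
        models["ann"] = model
        for s in (head, tail, test):
            X, kept = build_beat_frame(s.record, s.beats["t_rpeak"].to_numpy(), cfg.lags, ppg_stats)
            est = np.full(len(s.beats), np.nan)
            if X.shape[0]:
                est[kept] = model.predict(X)
            s.est["ann"] = est

    if "narx" in cfg.models:
        model = NarxEnsemble(
            lags=cfg.lags, n_members=cfg.n_members, hidden_size=cfg.hidden_size,
            max_iter=cfg.narx_max_iter, random_state=cfg.seed + 202,
        ).fit([s.record for s in train_segs], ppg_stats=ppg_stats)
        models["narx"] = model
        for s in (head, tail, test):
            rec = s.record
            if rec.bp is not None:
                bp_init = rec.bp[:2]
            else:
                bp_init = np.full(2, np.nanmean(np.concatenate(
                    [t.beats[target_col].to_numpy() for t in train_segs])))
            wf = model.predict_free_run(rec, bp_init)
            s.waveform["narx"] = wf
            r_rel = s.beats["t_rel"].to_numpy()
            sbp_w, dbp_w = extract_sbp_dbp(wf, r_rel, rec.fs)
            s.est["narx"] = sbp_w if cfg.target == "sbp" else dbp_w
    return models, head, tail, test


def _pi_for_model(cfg: PipelineConfig, name, train_segs, test_seg, ppg_stats, target_col):
    """Fit the PI model from training-segment errors, assign PIs on test."""
    feats, errs = [], []
    for s in train_segs:
        F, kept = build_pi_features(
            s.record, s.beats["t_rpeak"].to_numpy(), cfg.pi_config,
            estimates=s.est[name], est_waveform=s.waveform.get(name), ppg_stats=ppg_stats,
        )
        e = (s.est[name] - s.beats[target_col].to_numpy())[kept]
        ok = np.isfinite(e) & np.isfinite(F).all(axis=1)
        feats.append(F[ok])
        errs.append(e[ok])
    pi_model = fit_pi_model(np.vstack(feats), np.concatenate(errs), cfg.pi_config)

    F, kept = build_pi_features(
        test_seg.record, test_seg.beats["t_rpeak"].to_numpy(), cfg.pi_config,
        estimates=test_seg.est[name], est_waveform=test_seg.waveform.get(name),
        ppg_stats=ppg_stats,
    )
    labels = np.full(len(test_seg.beats), np.nan)  # NaN = beat not assignable
    pis = np.full(len(test_seg.beats), np.nan)
    ok = np.isfinite(F).all(axis=1) & np.isfinite(test_seg.est[name])[kept]
    if ok.any():
        lab, pi = pi_model.predict(F[ok])
        labels[kept[ok]] = lab
        pis[kept[ok]] = pi
    return pi_model, labels, pis


def _evaluate(cfg: PipelineConfig, name, beats, est_col, pi_col, target_col) -> EvalReport:
    ok = np.isfinite(beats[est_col]) & np.isfinite(beats[target_col])
    sub = beats[ok]
    stats = error_stats(sub[est_col], sub[target_col])
    err = sub[est_col].to_numpy() - sub[target_col].to_numpy()
    pi = sub[pi_col].to_numpy(dtype=float)
    with_pi = np.isfinite(pi) & (pi > 0)
    merci = merci_score(np.abs(err[with_pi]), pi[with_pi]) if with_pi.sum() >= 2 else float("nan")
    df = pd.DataFrame(
        {"err": err, "abs_err": np.abs(err), "pi": pi, "activity": sub["activity"].to_numpy()}
    )
    m_range = (-6, 6) if cfg.target == "sbp" else (-4, 4)
    report = EvalReport(
        model_id=name,
        target=cfg.target,
        n_beats=int(len(sub)),
        mae=stats.mae,
        mu_err=stats.mu_err,
        sigma_err=stats.sigma_err,
        pearson_r=stats.r,
        merci=merci,
        mean_pi=float(np.mean(pi[with_pi])) if with_pi.any() else float("nan"),
        pct_outliers=100.0 * float(1.0 - with_pi.mean()) if len(sub) else float("nan"),
        delta_p_bins=mae_delta_p_bins(sub[est_col], sub[target_col], m_range=m_range),
        tradeoff=tradeoff_curve(df, cfg.tradeoff_thresholds),
        activity=activity_stats(df, cfg.sigma_t_list[0]),
    )
    report.standards = standards_check(report, cfg.limits)
    return report


def run_pipeline(record: WaveformRecord, config: PipelineConfig | None = None) -> PipelineResult:
    """Run estimation, PI fitting, fusion and evaluation on one session.

    The record must carry a BP reference channel; the head and tail
    ``train_minutes`` are used for training, the span in between for testing.
    """
    cfg = config or PipelineConfig()
    if record.bp is None:
        raise ValueError("pipeline requires a BP reference channel")
    target_col = "sbp_ref" if cfg.target == "sbp" else "dbp_ref"

    split = split_sessions(record, cfg.train_minutes)
    ppg_stats = znorm_stats(np.concatenate([split.train_head.ppg, split.train_tail.ppg]))

    try:
        models, head, tail, test = _run_models(cfg, split, ppg_stats, target_col)
    except Exception as exc:
        raise RuntimeError(f"[stage: estimation] {exc}") from exc

    beats = test.beats.copy()
    pi_models = {}
    for name in cfg.models:
        try:
            pi_model, labels, pis = _pi_for_model(cfg, name, [head, tail], test, ppg_stats, target_col)
        except Exception as exc:
            raise RuntimeError(f"[stage: prediction-interval/{name}] {exc}") from exc
        pi_models[name] = pi_model
        beats[f"est_{name}"] = test.est[name]
        beats[f"pi_{name}"] = pis
        beats[f"cluster_{name}"] = labels

    try:
        for fset in cfg.fusion_sets:
            fname = "+".join(fset)
            est = beats[[f"est_{m}" for m in fset]].set_axis(list(fset), axis=1)
            pi = beats[[f"pi_{m}" for m in fset]].set_axis(list(fset), axis=1)
            fused = fuse_estimates(est, pi, strategy=cfg.strategy, pi_map=cfg.pi_map)
            beats[f"est_{fname}"] = fused["fused"]
            beats[f"pi_{fname}"] = fused["fused_pi"]
    except Exception as exc:
        raise RuntimeError(f"[stage: fusion] {exc}") from exc

    entries = list(cfg.models) + ["+".join(f) for f in cfg.fusion_sets]
    reports = {}
    try:
        for name in entries:
            reports[name] = _evaluate(cfg, name, beats, f"est_{name}", f"pi_{name}", target_col)
    except Exception as exc:
        raise RuntimeError(f"[stage: evaluation] {exc}") from exc

    n_train = split.train_head.n_samples
    n = record.n_samples
    counts = {
        "n_train_beats": int(len(head.beats) + len(tail.beats)),
        "n_test_beats": int(len(test.beats)),
        "n_outlier_beats": {
            name: int((beats[f"cluster_{name}"] == -1).sum()) for name in cfg.models
        },
    }
    log.info("pipeline finished: %s", counts)
    return PipelineResult(
        reports=reports,
        beats=beats,
        models=models,
        pi_models=pi_models,
        metadata={
            "seed": cfg.seed,
            "target": cfg.target,
            "train_spans": [(0, n_train), (n - n_train, n)],
            "test_span": (n_train, n - n_train),
            "counts": counts,
        },
    )
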