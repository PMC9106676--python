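"""Evaluation suite: error statistics, MeRCI reporting, BP-deviation
binned error analysis, PI-threshold filtering with trade-off curves,
activity stratification, and device-standard limit checks.

All standard deviations are sample (n-1) SDs.  The BP-deviation analysis
(MAE over Delta-P bins) measures how well a model tracks excursions from
the subject's mean pressure: Delta-P is the deviation of reference and
estimate from the reference test-set mean, binned in 5-mmHg steps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .io import ACTIVITIES

__all__ = [
    "ErrorStats",
    "EvalReport",
    "error_stats",
    "mae_delta_p_bins",
    "filter_by_pi",
    "tradeoff_curve",
    "activity_stats",
    "standards_check",
    "DEFAULT_LIMITS",
]

# mu/sigma limits follow the AAMI convention; sigma = 8 mmHg is the anchored
# value, the others are conventional defaults and configurable.
DEFAULT_LIMITS = {"mu": 5.0, "sigma": 8.0, "mae": 6.0}


class ErrorStats(NamedTuple):
    mae: float
    mu_err: float
    sigma_err: float
    r: float


def error_stats(est, ref) -> ErrorStats:
    """MAE, mean error, error SD and Pearson r of aligned estimates."""
    est = np.asarray(est, dtype=float).reshape(-1)
    ref = np.asarray(ref, dtype=float).reshape(-1)
    if est.size != ref.size or est.size < 2:
        raise ValueError("need >= 2 aligned beats")
    err = est - ref
    mae = float(np.mean(np.abs(err)))
    mu = float(np.mean(err))
    sigma = float(np.std(err, ddof=1))
    if np.std(est) == 0 or np.std(ref) == 0:
        r = float("nan")  # correlation undefined for constant series
    else:
        r = float(pearsonr(est, ref).statistic)
    return ErrorStats(mae, mu, sigma, r)


def mae_delta_p_bins(
    est,
    ref,
    bin_width: float = 5.0,
    m_range: tuple[int, int] = (-6, 6),
    ref_mean: float | None = None,
    reference_bins: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """MAE of Delta-P tracking per 5-mmHg bin of the reference deviation.

    Delta-P is the deviation from the reference test-set mean (configurable
    via ``ref_mean``); bins are [5m, 5(m+1)) for m in ``m_range``.  With
    ``reference_bins`` (another model's table) an extra column holds the
    per-bin difference against it.  Empty bins are NaN.
    """
    est = np.asarray(est, dtype=float).reshape(-1)
    ref = np.asarray(ref, dtype=float).reshape(-1)
    if est.size != ref.size:
        raise ValueError("est and ref must be aligned")
    mu = float(np.mean(ref)) if ref_mean is None else float(ref_mean)
    dp_ref = ref - mu
    dp_est = est - mu
    rows = []
    for m in range(m_range[0], m_range[1] + 1):
        lo, hi = bin_width * m, bin_width * (m + 1)
        sel = (dp_ref >= lo) & (dp_ref < hi)
        mae = float(np.mean(np.abs(dp_est[sel] - dp_ref[sel]))) if sel.any() else float("nan")
        rows.append({"m": m, "lo": lo, "hi": hi, "n": int(sel.sum()), "mae_dp": mae})
    table = pd.DataFrame(rows)
    if reference_bins is not None:
        table["mae_dp_minus_ref"] = table["mae_dp"] - reference_bins["mae_dp"].to_numpy()
    return table


def group_bins_by_abs(table: pd.DataFrame) -> pd.DataFrame:
    """Group the signed Delta-P bins by |Delta-P| (bins m and -m-1 pair up)."""
    out = []
    mmax = int(table["m"].max())
    for m in range(0, mmax + 1):
        sel = table[(table["m"] == m) | (table["m"] == -m - 1)]
        n = int(sel["n"].sum())
        mae = float(np.nansum(sel["mae_dp"] * sel["n"]) / n) if n else float("nan")
        out.append({"abs_lo": 5.0 * m, "abs_hi": 5.0 * (m + 1), "n": n, "mae_dp": mae})
    return pd.DataFrame(out)


def filter_by_pi(
    beats: pd.DataFrame, sigma_t: float, pi_col: str = "pi", err_col: str = "abs_err"
) -> tuple[pd.DataFrame, float, pd.DataFrame]:
    """Keep beats with PI < sigma_t; beats with missing PI count as removed.

    Returns (kept beats, % removed, removal-fraction histogram over 1-mmHg
    absolute-error bins).
    """
    pi = beats[pi_col].to_numpy(dtype=float)
    keep = np.isfinite(pi) & (pi < sigma_t)
    pct_removed = 100.0 * (1.0 - keep.mean()) if len(beats) else 0.0
    err = np.abs(beats[err_col].to_numpy(dtype=float))
    edges = np.arange(0.0, np.nanmax(err) + 2.0 if len(beats) else 1.0, 1.0)
    hist_rows = []
    for lo in edges[:-1]:
        sel = (err >= lo) & (err < lo + 1.0)
        if sel.any():
            hist_rows.append(
                {"err_lo": lo, "err_hi": lo + 1.0, "n": int(sel.sum()),
                 "pct_removed": 100.0 * (1.0 - keep[sel].mean())}
            )
    return beats[keep], float(pct_removed), pd.DataFrame(hist_rows)


def tradeoff_curve(beats: pd.DataFrame, thresholds, pi_col: str = "pi",
                   err_col: str = "err") -> pd.DataFrame:
    """(sigma_t, sigma_err of kept beats, % kept) per threshold."""
    thresholds = list(thresholds)
    if not thresholds:
        raise ValueError("need at least one threshold")
    rows = []
    pi = beats[pi_col].to_numpy(dtype=float)
    err = beats[err_col].to_numpy(dtype=float)
    for st in thresholds:
        keep = np.isfinite(pi) & (pi < st)
        sigma = float(np.std(err[keep], ddof=1)) if keep.sum() >= 2 else float("nan")
        rows.append({"sigma_t": st, "sigma_err": sigma, "pct_kept": 100.0 * keep.mean()})
    return pd.DataFrame(rows)


def activity_stats(beats: pd.DataFrame, sigma_t: float, pi_col: str = "pi",
                   err_col: str = "err", activity_col: str = "activity") -> pd.DataFrame:
    """Per-activity error SD before/after PI < sigma_t filtering and % kept.

    Labels outside the fixed vocabulary are reported as 'other'; activities
    with fewer than 2 beats are omitted.
    """
    act = beats[activity_col].astype(str).to_numpy()
    act = np.where(np.isin(act, ACTIVITIES), act, "other")
    pi = beats[pi_col].to_numpy(dtype=float)
    err = beats[err_col].to_numpy(dtype=float)
    rows = []
    for name in ACTIVITIES:
        sel = act == name
        if sel.sum() < 2:
            continue
        keep = sel & np.isfinite(pi) & (pi < sigma_t)
        rows.append(
            {
                "activity": name,
                "n": int(sel.sum()),
                "sigma_err": float(np.std(err[sel], ddof=1)),
                "sigma_err_filtered": float(np.std(err[keep], ddof=1)) if keep.sum() >= 2 else float("nan"),
                "pct_kept": 100.0 * keep.sum() / sel.sum(),
            }
        )
    return pd.DataFrame(rows, columns=["activity", "n", "sigma_err", "sigma_err_filtered", "pct_kept"])


@dataclass
class EvalReport:
    """Full evaluation of one model (or fusion set) on a test span."""

    model_id: str
    target: str
    n_beats: int
    mae: float
    mu_err: float
    sigma_err: float
    pearson_r: float
    merci: float
    mean_pi: float
    pct_outliers: float
    standards: dict = field(default_factory=dict)
    delta_p_bins: pd.DataFrame | None = None
    tradeoff: pd.DataFrame | None = None
    activity: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("delta_p_bins", "tradeoff", "activity"):
            if d[key] is not None:
                d[key] = getattr(self, key).to_dict(orient="records")
        return d

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, default=float)


def standards_check(report: EvalReport | dict, limits: dict | None = None) -> dict:
    """Boolean pass flags against device-standard limits.

    |mu_err| <= mu limit, sigma_err <= sigma limit (8 mmHg anchored), and
    MAE <= mae limit; limits configurable.
    """
    lim = dict(DEFAULT_LIMITS)
    if limits:
        lim.update(limits)
    get = (lambda k: getattr(report, k)) if isinstance(report, EvalReport) else report.__getitem__
    return {
        "mu_pass": bool(abs(get("mu_err")) <= lim["mu"]),
        "sigma_pass": bool(get("sigma_err") <= lim["sigma"]),
        "mae_pass": bool(get("mae") <= lim["mae"]),
        "limits": lim,
    }
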