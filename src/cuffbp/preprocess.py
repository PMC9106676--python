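"""Beat detection, fiducial extraction and regression-frame construction.

Pulse arrival time (PAT) is the delay from the ECG R-peak to the point at
50% of the PPG foot-to-peak upstroke amplitude; it is measured on a 256-Hz
grid obtained by interpolating the 64-Hz PPG, which improves temporal
resolution fourfold.  Beat intervals are half-open ``[t_rpeak, next)``
throughout, and z-normalization statistics always come from a designated
reference (training) segment so test data never leak into scaling.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.interpolate import CubicSpline

log = logging.getLogger(__name__)

__all__ = [
    "detect_r_peaks",
    "compute_pat",
    "znormalize",
    "znorm_stats",
    "extract_sbp_dbp",
    "build_regression_frame",
    "build_beat_frame",
    "RegressionFrame",
]


def detect_r_peaks(ecg: np.ndarray, fs: float, refractory: float = 0.3) -> np.ndarray:
    """Adaptive-threshold R-peak detector; returns peak times on the sample grid.

    Local maxima above ``median + 0.5 * (99.9th percentile - median)`` with a
    refractory period (default 0.3 s).  A flat signal yields an empty result
    with a warning.
    """
    from scipy.signal import find_peaks

    ecg = np.asarray(ecg, dtype=float)
    if ecg.size < 2 * fs:
        raise ValueError("ecg must span at least 2 s")
    if np.ptp(ecg) < 1e-12:
        warnings.warn("flat ECG signal: no peaks detected")
        return np.array([])
    med = np.median(ecg)
    thr = med + 0.5 * (np.percentile(ecg, 99.9) - med)
    idx, _ = find_peaks(ecg, height=thr, distance=max(int(round(refractory * fs)), 1))
    return idx / fs


def compute_pat(
    r_peaks: np.ndarray,
    ppg: np.ndarray,
    fs_in: float,
    fs_pat: float = 256.0,
    interp: str = "cubic",
    max_pat: float = 1.0,
) -> np.ndarray:
    """Per-beat PAT in seconds, measured at ``fs_pat`` resolution.

    For each beat the PPG window from the R-peak to the next R-peak is
    upsampled by interpolation; the foot is the minimum preceding the pulse
    peak, and PAT is the time from the R-peak to the first crossing of
    ``foot + 0.5 * (peak - foot)``.  Beats without a usable upstroke get NaN.
    """
    r_peaks = np.asarray(r_peaks, dtype=float)
    ppg = np.asarray(ppg, dtype=float)
    n = ppg.size
    t = np.arange(n) / fs_in
    pat = np.full(r_peaks.size, np.nan)
    for i, r in enumerate(r_peaks):
        if i + 1 < r_peaks.size:
            end = r_peaks[i + 1]
        else:
            end = min(r + 1.5, t[-1])
        if end - r < 0.35:
            log.info("beat %d: window too short for PAT", i)
            continue
        i0 = max(int(np.floor(r * fs_in)) - 4, 0)
        i1 = min(int(np.ceil(end * fs_in)) + 5, n)
        if i1 - i0 < 5:
            continue
        grid = r + np.arange(0.0, end - r, 1.0 / fs_pat)
        if interp == "cubic":
            vals = CubicSpline(t[i0:i1], ppg[i0:i1])(grid)
        else:
            vals = np.interp(grid, t[i0:i1], ppg[i0:i1])
        peak = int(np.argmax(vals))
        if peak == 0:
            log.info("beat %d: no upstroke found", i)
            continue
        foot = int(np.argmin(vals[: peak + 1]))
        thr = vals[foot] + 0.5 * (vals[peak] - vals[foot])
        above = np.nonzero(vals[foot : peak + 1] >= thr)[0]
        if above.size == 0:
            log.info("beat %d: no 50%% crossing", i)
            continue
        j = foot + above[0]
        t_cross = grid[j]
        if j > foot and vals[j] > vals[j - 1]:  # sub-grid refinement
            frac = (thr - vals[j - 1]) / (vals[j] - vals[j - 1])
            t_cross = grid[j - 1] + frac * (grid[j] - grid[j - 1])
        p = t_cross - r
        if 0.0 < p < max_pat:
            pat[i] = p
        else:
            log.info("beat %d: PAT %.3f s out of range", i, p)
    return pat


def znorm_stats(x: np.ndarray) -> tuple[float, float]:
    """Mean and sample SD of a reference segment (for leak-free scaling)."""
    x = np.asarray(x, dtype=float)
    sd = float(np.std(x, ddof=1))
    if sd <= 0:
        raise ValueError("reference segment has zero variance")
    return float(np.mean(x)), sd


def znormalize(signal: np.ndarray, stats_source: np.ndarray) -> np.ndarray:
    """``(signal - mean(stats_source)) / sd(stats_source)`` with sample SD."""
    mean, sd = znorm_stats(stats_source)
    return (np.asarray(signal, dtype=float) - mean) / sd


def extract_sbp_dbp(
    bp: np.ndarray,
    r_peaks: np.ndarray,
    fs: float,
    min_interval: float = 0.25,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-beat SBP (max) and DBP (min) of the BP waveform over
    ``[t_rpeak, next t_rpeak)``.  The last beat (no closing interval) and
    intervals shorter than ``min_interval`` are NaN."""
    bp = np.asarray(bp, dtype=float)
    r_peaks = np.asarray(r_peaks, dtype=float)
    nb = r_peaks.size
    sbp = np.full(nb, np.nan)
    dbp = np.full(nb, np.nan)
    for i in range(nb - 1):
        if r_peaks[i + 1] - r_peaks[i] < min_interval:
            log.info("beat %d: interval below %.2f s, skipped", i, min_interval)
            continue
        k0 = int(np.ceil(r_peaks[i] * fs - 1e-9))
        k1 = int(np.ceil(r_peaks[i + 1] * fs - 1e-9))
        k1 = min(k1, bp.size)
        if k1 - k0 < 2:
            continue
        seg = bp[k0:k1]
        sbp[i] = seg.max()
        dbp[i] = seg.min()
    return sbp, dbp


@dataclass
class RegressionFrame:
    """Lagged input matrix with aligned targets and sample times.

    Rows correspond to time steps ``k``; each row holds the last ``lags``
    samples of ECG and z-normalized PPG (oldest first), optionally followed
    by the BP feedback terms ``bp(k-1), bp(k-2)``.
    """

    X: np.ndarray
    y: np.ndarray | None
    t: np.ndarray
    lags: int
    include_bp_feedback: bool

    @property
    def width(self) -> int:
        return self.X.shape[1]


def _zppg(record, ppg_stats):
    if ppg_stats is None:
        return znormalize(record.ppg, record.ppg)
    mean, sd = ppg_stats
    return (record.ppg - mean) / sd


def build_regression_frame(
    record,
    lags: int = 19,
    include_bp_feedback: bool = False,
    ppg_stats: tuple[float, float] | None = None,
) -> RegressionFrame:
    """Per-sample lagged frame for waveform regression.

    Row at step ``k``: ``[ecg(k-lags+1..k), zppg(k-lags+1..k)]`` plus
    ``[bp(k-1), bp(k-2)]`` when ``include_bp_feedback``; target is ``bp(k)``
    when the record carries a BP channel.
    """
    if lags < 1:
        raise ValueError("lags must be >= 1")
    n = record.n_samples
    if n < lags + 2:
        raise ValueError(f"record of {n} samples shorter than lags={lags}")
    if include_bp_feedback and record.bp is None:
        raise ValueError("BP feedback requested but record has no bp channel")
    zp = _zppg(record, ppg_stats)
    k0 = max(lags - 1, 2 if include_bp_feedback else 0)
    ecg_w = sliding_window_view(record.ecg, lags)[k0 - (lags - 1) :]
    ppg_w = sliding_window_view(zp, lags)[k0 - (lags - 1) :]
    cols = [ecg_w, ppg_w]
    if include_bp_feedback:
        ks = np.arange(k0, n)
        cols.append(np.column_stack([record.bp[ks - 1], record.bp[ks - 2]]))
    X = np.ascontiguousarray(np.hstack(cols))
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in regression frame")
    y = record.bp[k0:] if record.bp is not None else None
    t = record.t0 + np.arange(k0, n) / record.fs
    return RegressionFrame(X=X, y=y, t=t, lags=lags, include_bp_feedback=include_bp_feedback)


def build_beat_frame(
    record,
    r_peaks: np.ndarray,
    lags: int = 19,
    ppg_stats: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-beat lagged inputs: the ``lags``-sample ECG and z-PPG windows
    ending at each beat's R-peak sample.

    Returns ``(X, kept)`` where ``kept`` indexes the beats (relative to the
    record start) whose window fits inside the record.
    """
    if lags < 1:
        raise ValueError("lags must be >= 1")
    zp = _zppg(record, ppg_stats)
    ks = np.round((np.asarray(r_peaks, dtype=float) - record.t0) * record.fs).astype(int)
    kept = np.nonzero((ks >= lags - 1) & (ks < record.n_samples))[0]
    rows = []
    for k in ks[kept]:
        rows.append(np.concatenate([record.ecg[k - lags + 1 : k + 1], zp[k - lags + 1 : k + 1]]))
    X = np.array(rows) if rows else np.empty((0, 2 * lags))
    return X, kept
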