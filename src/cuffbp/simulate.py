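"""Synthetic ECG/PPG/BP session generator with known ground truth.

The generator emulates an ambulatory monitoring session: a calibration
segment at the start and end of the day (with commanded slow BP sweeps that
widen the training BP range) flanking a free-living test block in which the
subject sits, stands and walks.  Per-beat systolic pressure follows a
mean-reverting random walk around the subject mean plus activity-dependent
offsets; pulse arrival time (PAT) is generated by inverting a logarithmic
PAT-SBP coupling ``SBP = a0 + b0 ln(PAT)`` (b0 < 0), so a log-PAT regression
is well specified on clean data and misspecified only through injected
timing jitter and waveform noise.

Waveform construction guarantees the fiducials downstream stages look for:
the ECG has an unambiguous R-peak sample at every beat time, the PPG's
50%-of-foot-to-peak upstroke crossing lags the R-peak by exactly the
ground-truth PAT, and the BP channel attains its per-beat maximum/minimum
exactly at the ground-truth SBP/DBP.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io import ACTIVITIES, WaveformRecord

__all__ = [
    "SimulationParams",
    "GroundTruth",
    "simulate_bp_trajectory",
    "render_recording",
    "default_schedule",
]


@dataclass
class SimulationParams:
    """Conditions of a simulated monitoring session.

    Defaults describe a 6.5-h session at 64 Hz with two 15-min calibration
    segments, ~120/75 mmHg mean pressure, slow SBP variability of 10 mmHg SD
    (roughly +-30 mmHg daily range at 3 SD) and a walking artifact level five
    times the sitting level.
    """

    duration: float = 6.5 * 3600.0  # seconds
    fs: float = 64.0  # Hz
    seed: int = 0
    subject_id: str = "sim"
    mean_sbp: float = 120.0  # mmHg
    mean_dbp: float = 75.0  # mmHg
    sbp_sd: float = 10.0  # mmHg, stationary SD of the slow SBP walk
    dbp_sd: float = 4.0  # mmHg, independent slow DBP component
    bp_tau: float = 60.0  # s, mean-reversion time constant
    pat_coeffs: tuple[float, float] = (35.0, -60.0)  # SBP = a0 + b0 ln PAT
    hr_range: tuple[float, float] = (60.0, 100.0)  # beats/min
    train_minutes: float = 15.0
    train_sweep_mmhg: float = 15.0  # commanded BP sweep amplitude in training
    train_sweep_period: float = 150.0  # s
    activity_schedule: list[tuple[str, float, float]] | None = None
    activity_offsets: dict = field(
        default_factory=lambda: {"sitting": 0.0, "standing": 3.0, "walking": 8.0, "other": 0.0}
    )
    artifact_level: dict = field(
        default_factory=lambda: {"sitting": 1.0, "standing": 1.5, "walking": 5.0, "other": 1.0}
    )
    noise_scale: float = 0.02  # a.u., base additive waveform noise SD
    pat_jitter_sd: float = 0.010  # s, base PPG timing jitter SD
    pat_bounds: tuple[float, float] = (0.08, 0.47)  # s
    ppg_rise: float = 0.15  # s, foot-to-peak upstroke duration
    amplitude_jitter: float = 0.1  # relative per-beat PPG amplitude variation

    def __post_init__(self):
        if self.duration < 60.0:
            raise ValueError("duration must be at least 60 s")
        if self.fs < 32.0:
            raise ValueError("fs must be at least 32 Hz")
        a0, b0 = self.pat_coeffs
        if not b0 < 0:
            raise ValueError("pat_coeffs slope b0 must be negative (inverse PAT-SBP relation)")


@dataclass
class GroundTruth:
    """Per-beat generator truth: beat times, SBP/DBP, PAT, activity."""

    beats: pd.DataFrame  # columns t_rpeak, sbp, dbp, pat, activity
    params: SimulationParams

    def __post_init__(self):
        t = self.beats["t_rpeak"].to_numpy()
        if not np.all(np.diff(t) > 0):
            raise ValueError("beat times must be strictly increasing")
        if not np.all(self.beats["sbp"].to_numpy() > self.beats["dbp"].to_numpy()):
            raise ValueError("every beat must satisfy SBP > DBP")


def default_schedule(params: SimulationParams) -> list[tuple[str, float, float]]:
    """Activity schedule: short mixed blocks during the calibration segments,
    5-min blocks cycling sitting/standing/sitting/walking during the test."""
    t_train = params.train_minutes * 60.0
    sched: list[tuple[str, float, float]] = []

    def fill(start, end, cycle, block):
        t, i = start, 0
        while t < end:
            sched.append((cycle[i % len(cycle)], t, min(t + block, end)))
            t += block
            i += 1

    head_end = min(t_train, params.duration)
    tail_start = max(params.duration - t_train, head_end)
    fill(0.0, head_end, ("sitting", "standing", "walking"), 120.0)
    fill(head_end, tail_start, ("sitting", "standing", "sitting", "walking"), 300.0)
    fill(tail_start, params.duration, ("sitting", "standing", "walking"), 120.0)
    return sched


def _activity_per_sample(params: SimulationParams, n: int) -> np.ndarray:
    sched = params.activity_schedule
    if sched is None:
        sched = default_schedule(params)
    act = np.full(n, "other", dtype=object)
    for name, start, end in sched:
        if name not in ACTIVITIES:
            raise ValueError(f"unknown activity {name!r}")
        if start < 0 or end > params.duration + 1e-9 or end < start:
            raise ValueError(f"schedule entry ({name}, {start}, {end}) outside record duration")
        i0 = int(np.ceil(start * params.fs))
        i1 = min(int(np.ceil(end * params.fs)), n)
        act[i0:i1] = name
    return act


def _in_training(params: SimulationParams, t: np.ndarray) -> np.ndarray:
    t_train = params.train_minutes * 60.0
    return (t < t_train) | (t >= params.duration - t_train)


def simulate_bp_trajectory(
    params: SimulationParams,
    n_beats: int,
    beat_times: np.ndarray | None = None,
    activity: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-beat SBP/DBP as a bounded mean-reverting walk plus activity offsets.

    The slow component is a discrete Ornstein-Uhlenbeck process with
    stationary SD ``sbp_sd`` and time constant ``bp_tau``; walking/standing
    add positive offsets, and beats inside the calibration segments carry the
    commanded sinusoidal sweep of amplitude ``train_sweep_mmhg``.
    """
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if beat_times is None:
        beat_times = 0.8 * np.arange(n_beats)
    beat_times = np.asarray(beat_times, dtype=float)
    if activity is None:
        activity = np.full(n_beats, "sitting", dtype=object)

    dt = np.diff(beat_times, prepend=beat_times[0] - 0.8)
    phi = np.exp(-np.maximum(dt, 1e-6) / params.bp_tau)

    def ou(sd):
        x = np.empty(n_beats)
        x[0] = rng.normal(0.0, sd) if sd > 0 else 0.0
        eps = rng.normal(0.0, 1.0, n_beats)
        for k in range(1, n_beats):
            innov_sd = sd * np.sqrt(max(1.0 - phi[k] ** 2, 0.0))
            x[k] = phi[k] * x[k - 1] + innov_sd * eps[k]
        return x

    x = ou(params.sbp_sd)
    y = ou(params.dbp_sd)

    offsets = np.array([params.activity_offsets.get(a, 0.0) for a in activity])
    sweep = np.where(
        _in_training(params, beat_times),
        params.train_sweep_mmhg * np.sin(2 * np.pi * beat_times / params.train_sweep_period),
        0.0,
    )
    sbp = params.mean_sbp + x + offsets + sweep
    dbp = params.mean_dbp + 0.6 * x + y + 0.5 * offsets + 0.5 * sweep
    dbp = np.minimum(dbp, sbp - 15.0)  # physiological pulse-pressure floor
    return sbp, dbp


def _beat_times(params: SimulationParams, rng: np.random.Generator) -> np.ndarray:
    """Sample-grid-aligned R-peak times from a slowly wandering heart rate."""
    lo, hi = params.hr_range
    mid, half = 0.5 * (lo + hi), 0.5 * (hi - lo)
    times = []
    t = 0.5
    hr_dev = 0.0
    phi = np.exp(-0.8 / 120.0)  # HR wanders with ~2-min time constant
    sd = half / 2.0
    while t < params.duration - 1.5:
        times.append(round(t * params.fs) / params.fs)
        hr_dev = phi * hr_dev + sd * np.sqrt(1 - phi**2) * rng.normal()
        hr = float(np.clip(mid + hr_dev, lo, hi))
        t += 60.0 / hr
    times = np.array(times)
    # grid snapping cannot merge beats (RR >= 0.6 s >> 1/fs) but be safe
    keep = np.concatenate([[True], np.diff(times) > 0])
    return times[keep]


def _render_ppg(params, n, beat_times, pat, amp):
    """Piecewise-cosine pulse train: foot -> peak upstroke whose 50% crossing
    sits exactly at ``t_rpeak + pat``, then a smooth decay to the next foot."""
    fs = params.fs
    rise = params.ppg_rise
    foot = beat_times + pat - rise / 2.0
    peak = foot + rise
    t = np.arange(n) / fs
    ppg = np.zeros(n)
    # knots: [foot_0, peak_0, foot_1, peak_1, ...] + virtual trailing foot
    knots = np.empty(2 * len(beat_times) + 1)
    knots[0:-1:2] = foot
    knots[1:-1:2] = peak
    knots[-1] = min(peak[-1] + 1.0, t[-1] + 1.0 / fs)
    idx = np.searchsorted(knots, t, side="right") - 1
    valid = (idx >= 0) & (idx < 2 * len(beat_times))
    iv = idx[valid]
    seg_start = knots[iv]
    seg_end = knots[iv + 1]
    frac = (t[valid] - seg_start) / np.maximum(seg_end - seg_start, 1e-9)
    rising = iv % 2 == 0
    beat_of = iv // 2
    shape = np.where(rising, 0.5 * (1 - np.cos(np.pi * frac)), 0.5 * (1 + np.cos(np.pi * frac)))
    ppg[valid] = shape * amp[beat_of]
    return ppg


def _render_ecg(params, n, beat_samples):
    fs = params.fs
    ecg = np.zeros(n)
    w = int(round(0.08 * fs))
    k = np.arange(-w, w + 1)
    r_wave = np.exp(-0.5 * (k / (0.02 * fs)) ** 2)
    tw = int(round(0.05 * fs))
    kt = np.arange(-tw * 2, tw * 2 + 1)
    t_wave = 0.25 * np.exp(-0.5 * (kt / (0.05 * fs)) ** 2)
    t_off = int(round(0.25 * fs))
    for b in beat_samples:
        lo, hi = max(b - w, 0), min(b + w + 1, n)
        ecg[lo:hi] += r_wave[lo - (b - w) : lo - (b - w) + hi - lo]
        c = b + t_off
        lo, hi = max(c - 2 * tw, 0), min(c + 2 * tw + 1, n)
        if lo < hi:
            ecg[lo:hi] += t_wave[lo - (c - 2 * tw) : lo - (c - 2 * tw) + hi - lo]
    return ecg


def _render_bp(n, beat_samples, sbp, dbp):
    bp = np.empty(n)
    bp[: beat_samples[0]] = dbp[0]
    for i in range(len(beat_samples)):
        k0 = beat_samples[i]
        k1 = beat_samples[i + 1] if i + 1 < len(beat_samples) else n
        m = k1 - k0
        if m < 2:
            bp[k0:k1] = sbp[i]
            continue
        s = np.arange(m) / m
        shape = 0.5 * (1.0 - np.cos(2 * np.pi * s**0.8))  # fast rise, slower fall
        rng_ = shape.max() - shape.min()
        norm = (shape - shape.min()) / rng_ if rng_ > 0 else shape
        bp[k0:k1] = dbp[i] + (sbp[i] - dbp[i]) * norm
    return bp


def render_recording(params: SimulationParams) -> tuple[WaveformRecord, GroundTruth]:
    """Render a full session; returns the recording and its ground truth.

    Reproducible: identical params (including seed) give bit-identical output.
    """
    rng = np.random.default_rng(params.seed)
    fs = params.fs
    n = int(round(params.duration * fs))
    activity = _activity_per_sample(params, n)

    beat_times = _beat_times(params, rng)
    beat_samples = np.round(beat_times * fs).astype(int)
    act_beat = activity[np.minimum(beat_samples, n - 1)]
    mult_beat = np.array([params.artifact_level.get(a, 1.0) for a in act_beat])

    sbp, dbp = simulate_bp_trajectory(
        params, len(beat_times), beat_times=beat_times, activity=act_beat, rng=rng
    )
    a0, b0 = params.pat_coeffs
    pat_model = np.exp((sbp - a0) / b0)
    jitter = rng.normal(0.0, 1.0, len(beat_times)) * params.pat_jitter_sd * mult_beat
    pat = np.clip(pat_model + jitter, *params.pat_bounds)

    amp = 1.0 + params.amplitude_jitter * rng.uniform(-1.0, 1.0, len(beat_times))
    ppg = _render_ppg(params, n, beat_times, pat, amp)
    ecg = _render_ecg(params, n, beat_samples)
    bp = _render_bp(n, beat_samples, sbp, dbp)

    if params.noise_scale > 0:
        mult = np.array([params.artifact_level.get(a, 1.0) for a in activity])
        sigma = params.noise_scale * mult
        ppg = ppg + rng.normal(0.0, 1.0, n) * sigma
        ecg = ecg + rng.normal(0.0, 1.0, n) * (0.5 * sigma)
        # band-limited movement artifact on PPG + baseline wander on ECG
        excess = np.maximum(mult - 1.0, 0.0)
        if excess.any():
            sos = sps.butter(2, [0.5, 5.0], btype="bandpass", fs=fs, output="sos")
            artifact = sps.sosfiltfilt(sos, rng.normal(0.0, 1.0, n))
            ppg = ppg + 2.0 * params.noise_scale * excess * artifact
            wander = np.sin(2 * np.pi * 0.25 * np.arange(n) / fs + rng.uniform(0, 2 * np.pi))
            ecg = ecg + 1.5 * params.noise_scale * excess * wander

    record = WaveformRecord(
        subject_id=params.subject_id,
        fs=fs,
        ecg=ecg,
        ppg=ppg,
        bp=bp,
        activity=activity,
    )
    truth = GroundTruth(
        beats=pd.DataFrame(
            {
                "t_rpeak": beat_times,
                "sbp": sbp,
                "dbp": dbp,
                "pat": pat,
                "activity": act_beat,
            }
        ),
        params=replace(params),
    )
    return record, truth
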