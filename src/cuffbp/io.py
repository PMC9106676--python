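"""Waveform-record I/O and session splitting.

Recordings are uniformly sampled multichannel time series (ECG, PPG,
optionally an arterial BP reference and a per-sample activity label) stored
either as CSV with a one-line JSON header comment or as an HDF5 container.
A monitoring session is split into a training head, a free-living test block
and a training tail, mirroring the two 15-min calibration procedures that
flank a day of ambulatory monitoring.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ACTIVITIES = ("sitting", "standing", "walking", "other")

_MANDATORY = ("ecg", "ppg")
_KNOWN = ("ecg", "ppg", "bp", "activity")


class FormatError(ValueError):
    """Raised when a waveform file violates the expected layout."""


@dataclass
class WaveformRecord:
    """Uniformly sampled multichannel physiological recording.

    Sample index ``k`` maps to time ``t0 + k / fs`` (0-based).

    Parameters
    ----------
    subject_id : str
        Identifier of the monitored subject.
    fs : float
        Sampling rate in Hz (> 0).
    ecg, ppg : ndarray
        Waveforms in arbitrary units; no NaN allowed.
    bp : ndarray, optional
        Arterial blood-pressure reference in mmHg.
    activity : ndarray of str, optional
        Per-sample activity label from :data:`ACTIVITIES`.
    t0 : float
        Start time of the recording in seconds.
    extras : dict
        Additional named channels, preserved on round-trip.
    """

    subject_id: str
    fs: float
    ecg: np.ndarray
    ppg: np.ndarray
    bp: np.ndarray | None = None
    activity: np.ndarray | None = None
    t0: float = 0.0
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        self.ecg = np.asarray(self.ecg, dtype=float)
        self.ppg = np.asarray(self.ppg, dtype=float)
        n = self.ecg.size
        if self.ppg.size != n:
            raise ValueError("ecg and ppg must have equal length")
        for name in ("ecg", "ppg"):
            if np.isnan(getattr(self, name)).any():
                raise ValueError(f"NaN values in {name} channel")
        if self.bp is not None:
            self.bp = np.asarray(self.bp, dtype=float)
            if self.bp.size != n:
                raise ValueError("bp channel length mismatch")
        if self.activity is not None:
            self.activity = np.asarray(self.activity, dtype=object)
            if self.activity.size != n:
                raise ValueError("activity channel length mismatch")
            bad = set(np.unique(self.activity)) - set(ACTIVITIES)
            if bad:
                raise ValueError(f"unknown activity codes: {sorted(bad)}")
        for name, ch in self.extras.items():
            ch = np.asarray(ch)
            if ch.size != n:
                raise ValueError(f"extra channel {name!r} length mismatch")
            self.extras[name] = ch

    @property
    def n_samples(self) -> int:
        return self.ecg.size

    @property
    def duration(self) -> float:
        """Recording span in seconds."""
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def slice(self, start: int, stop: int) -> "WaveformRecord":
        """Sample-exact sub-record with adjusted start time."""
        return WaveformRecord(
            subject_id=self.subject_id,
            fs=self.fs,
            ecg=self.ecg[start:stop].copy(),
            ppg=self.ppg[start:stop].copy(),
            bp=None if self.bp is None else self.bp[start:stop].copy(),
            activity=None if self.activity is None else self.activity[start:stop].copy(),
            t0=self.t0 + start / self.fs,
            extras={k: v[start:stop].copy() for k, v in self.extras.items()},
        )


@dataclass
class SessionSplit:
    """Training head / free-living test / training tail partition."""

    train_head: WaveformRecord
    test: WaveformRecord
    train_tail: WaveformRecord

    @property
    def train_records(self) -> list[WaveformRecord]:
        return [self.train_head, self.train_tail]


def _infer_format(path: str, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    ext = os.path.splitext(path)[1].lower()
    if ext in (".h5", ".hdf5"):
        return "hdf5"
    return "csv"


def write_waveform_record(record: WaveformRecord, path: str, format: str | None = None) -> None:
    """Write a record as CSV (JSON header comment) or HDF5."""
    fmt = _infer_format(path, format)
    if fmt == "csv":
        meta = {"fs": record.fs, "subject_id": record.subject_id, "t0": record.t0}
        cols = {"ecg": record.ecg, "ppg": record.ppg}
        if record.bp is not None:
            cols["bp"] = record.bp
        if record.activity is not None:
            cols["activity"] = record.activity
        cols.update(record.extras)
        df = pd.DataFrame(cols)
        with open(path, "w") as fh:
            fh.write("# " + json.dumps(meta) + "\n")
            df.to_csv(fh, index=False, lineterminator="\n")
    elif fmt == "hdf5":
        import h5py

        with h5py.File(path, "w") as fh:
            fh.attrs["fs"] = record.fs
            fh.attrs["subject_id"] = record.subject_id
            fh.attrs["t0"] = record.t0
            fh.create_dataset("ecg", data=record.ecg)
            fh.create_dataset("ppg", data=record.ppg)
            if record.bp is not None:
                fh.create_dataset("bp", data=record.bp)
            if record.activity is not None:
                fh.create_dataset(
                    "activity", data=np.asarray(record.activity, dtype="S16")
                )
            for name, ch in record.extras.items():
                fh.create_dataset(name, data=np.asarray(ch, dtype=float))
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_waveform_record(path: str, format: str | None = None) -> WaveformRecord:
    """Read a record written by :func:`write_waveform_record`.

    Unknown columns/datasets are preserved in ``extras``.
    """
    fmt = _infer_format(path, format)
    if fmt == "csv":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("#"):
                raise FormatError("missing JSON header comment line")
            try:
                meta = json.loads(header.lstrip("#").strip())
            except json.JSONDecodeError as exc:
                raise FormatError(f"bad header: {exc}") from exc
            if "fs" not in meta:
                raise FormatError("header must declare fs")
            df = pd.read_csv(fh)
        channels = {c: df[c].to_numpy() for c in df.columns}
    elif fmt == "hdf5":
        import h5py

        with h5py.File(path, "r") as fh:
            if "fs" not in fh.attrs:
                raise FormatError("HDF5 file must declare fs attribute")
            meta = {
                "fs": float(fh.attrs["fs"]),
                "subject_id": str(fh.attrs.get("subject_id", "")),
                "t0": float(fh.attrs.get("t0", 0.0)),
            }
            channels = {}
            for name in fh.keys():
                data = fh[name][()]
                if name == "activity":
                    data = np.array([b.decode() for b in data], dtype=object)
                channels[name] = data
    else:
        raise ValueError(f"unknown format {fmt!r}")

    for name in _MANDATORY:
        if name not in channels:
            raise FormatError(f"missing mandatory channel {name!r}")
    activity = channels.get("activity")
    if activity is not None:
        activity = np.asarray(activity, dtype=object)
    extras = {k: v for k, v in channels.items() if k not in _KNOWN}
    return WaveformRecord(
        subject_id=str(meta.get("subject_id", "")),
        fs=float(meta["fs"]),
        t0=float(meta.get("t0", 0.0)),
        ecg=channels["ecg"],
        ppg=channels["ppg"],
        bp=channels.get("bp"),
        activity=activity,
        extras=extras,
    )


def split_sessions(record: WaveformRecord, train_minutes: float = 15.0) -> SessionSplit:
    """Partition a session into head / test / tail with sample-exact bounds.

    The head and tail each span ``train_minutes`` (the calibration
    procedures); the remainder in between is the test block.
    """
    n_train = int(round(train_minutes * 60.0 * record.fs))
    if record.n_samples <= 2 * n_train:
        raise ValueError(
            f"record of {record.duration:.0f} s too short for two "
            f"{train_minutes:g}-min training segments"
        )
    return SessionSplit(
        train_head=record.slice(0, n_train),
        test=record.slice(n_train, record.n_samples - n_train),
        train_tail=record.slice(record.n_samples - n_train, record.n_samples),
    )


def write_beat_table(beats: pd.DataFrame, path: str) -> None:
    """Export a per-beat table (one row per beat) as CSV."""
    beats.to_csv(path, index=False)


def read_beat_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path)
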