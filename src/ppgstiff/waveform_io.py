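"""Waveform record and cohort-metadata containers and their CSV round-trips.

A :class:`WaveformRecord` holds synchronized, equally sampled channels (PPG,
ECG, optionally continuous finger BP) plus event annotations in seconds from
record start (0-based sample indexing; annotations are stored in seconds, not
samples, to stay independent of the sampling rate).

Records serialize as tidy CSV — one row per sample with columns
``time_s, ppg, ecg[, bp]`` — plus a JSON sidecar (``<stem>.meta.json``)
carrying the sampling rate, identifiers and annotations. Cohort metadata is a
flat CSV with one row per subject.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SUPPORTED_FORMATS = ("csv",)

META_COLUMNS = ["subject_id", "age", "height", "sbp", "dbp", "hr", "cfpwv", "aopwv"]


class FormatError(ValueError):
    """Raised when a file does not conform to the documented record format."""


@dataclass
class WaveformRecord:
    """Synchronized multichannel sampled signals.

    Parameters
    ----------
    channels
        Mapping of channel role (``ppg``, ``ecg``, optional ``bp``) to a 1-D
        float array. All channels must have equal length.
    fs
        Sampling rate in Hz.
    subject_id, visit_id
        Identifiers; ``visit_id`` is 1 or 2 for the two-visit protocol.
    annotations
        Mapping of annotation name (e.g. ``onset``, ``r_wave``) to an array of
        event times in seconds from record start.
    """

    channels: dict[str, np.ndarray]
    fs: float
    subject_id: str = "anon"
    visit_id: int = 1
    annotations: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if "ppg" not in self.channels:
            raise FormatError("record is missing the required 'ppg' channel")
        lengths = {name: len(sig) for name, sig in self.channels.items()}
        if len(set(lengths.values())) > 1:
            bad = max(lengths, key=lambda k: abs(lengths[k] - lengths["ppg"]))
            raise FormatError(
                f"unequal channel lengths {lengths}; offending channel: {bad!r}"
            )
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        dur = self.duration
        for name, times in self.annotations.items():
            times = np.asarray(times, dtype=float)
            if times.size and (times.min() < 0 or times.max() > dur):
                raise ValueError(f"annotation {name!r} outside [0, {dur:.3f}] s")
            self.annotations[name] = times

    @property
    def n_samples(self) -> int:
        return len(self.channels["ppg"])

    @property
    def duration(self) -> float:
        """Record duration in seconds."""
        return self.n_samples / self.fs

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs


@dataclass
class SubjectMeta:
    """Per-subject clinical metadata row."""

    subject_id: str
    age: float
    height: float
    sbp: float
    dbp: float
    hr: float
    cfpwv: float | None = None
    aopwv: float | None = None

    def __post_init__(self) -> None:
        if not np.isnan(self.sbp) and not np.isnan(self.dbp):
            if not (self.sbp > self.dbp > 0):
                raise ValueError(
                    f"subject {self.subject_id}: require sbp > dbp > 0, "
                    f"got sbp={self.sbp}, dbp={self.dbp}"
                )
        if not np.isnan(self.height) and not (1.0 < self.height < 2.3):
            raise ValueError(
                f"subject {self.subject_id}: height {self.height} m outside (1.0, 2.3)"
            )


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".meta.json")


def write_record(record: WaveformRecord, path: str | Path, format: str = "csv") -> Path:
    """Write a record as tidy CSV plus a JSON sidecar; returns the CSV path."""
    if format not in SUPPORTED_FORMATS:
        raise ValueError(
            f"unsupported format {format!r}; supported formats: {SUPPORTED_FORMATS}"
        )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame({"time_s": record.time})
    for name in ("ppg", "ecg", "bp"):
        if name in record.channels:
            frame[name] = record.channels[name]
    frame.to_csv(path, index=False, float_format="%.9g")
    meta = {
        "fs": record.fs,
        "subject_id": record.subject_id,
        "visit_id": record.visit_id,
        "annotations": {k: list(map(float, v)) for k, v in record.annotations.items()},
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def read_record(path: str | Path, format: str = "csv") -> WaveformRecord:
    """Read a record written by :func:`write_record`.

    The sampling rate is recovered from the sidecar when present, otherwise
    from the median ``time_s`` increment.
    """
    if format not in SUPPORTED_FORMATS:
        raise ValueError(
            f"unsupported format {format!r}; supported formats: {SUPPORTED_FORMATS}"
        )
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path)
    if "ppg" not in frame.columns:
        raise FormatError(f"{path} is missing the required 'ppg' column")
    channels = {
        name: frame[name].to_numpy(dtype=float)
        for name in ("ppg", "ecg", "bp")
        if name in frame.columns
    }
    sidecar = _sidecar(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        fs = float(meta["fs"])
        annotations = {k: np.asarray(v, float) for k, v in meta.get("annotations", {}).items()}
        subject_id = meta.get("subject_id", "anon")
        visit_id = int(meta.get("visit_id", 1))
    else:
        dt = np.median(np.diff(frame["time_s"].to_numpy()))
        fs = 1.0 / dt
        annotations, subject_id, visit_id = {}, "anon", 1
    return WaveformRecord(channels, fs, subject_id, visit_id, annotations)


def write_cohort_meta(rows: list[SubjectMeta], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame(
        [
            {
                "subject_id": m.subject_id,
                "age": m.age,
                "height": m.height,
                "sbp": m.sbp,
                "dbp": m.dbp,
                "hr": m.hr,
                "cfpwv": m.cfpwv,
                "aopwv": m.aopwv,
            }
            for m in rows
        ],
        columns=META_COLUMNS,
    )
    frame.to_csv(path, index=False)
    return path


def read_cohort_meta(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort metadata CSV.

    Returns a DataFrame indexed by ``subject_id``. Rows violating the unit
    sanity checks (e.g. sbp <= dbp) raise a validation error naming the
    subject. An empty file yields an empty table with a warning.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    if frame.empty:
        logger.warning("cohort metadata file %s is empty", path)
        return pd.DataFrame(columns=META_COLUMNS).set_index("subject_id")
    missing = [c for c in META_COLUMNS[:6] if c not in frame.columns]
    if missing:
        raise FormatError(f"{path} is missing required columns: {missing}")
    for _, row in frame.iterrows():
        SubjectMeta(
            subject_id=str(row["subject_id"]),
            age=float(row["age"]),
            height=float(row["height"]),
            sbp=float(row["sbp"]),
            dbp=float(row["dbp"]),
            hr=float(row["hr"]),
            cfpwv=float(row["cfpwv"]) if "cfpwv" in row and pd.notna(row["cfpwv"]) else None,
            aopwv=float(row["aopwv"]) if "aopwv" in row and pd.notna(row["aopwv"]) else None,
        )
    return frame.set_index(frame["subject_id"].astype(str)).drop(columns=["subject_id"])
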