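"""EMG record container and its on-disk CSV + JSON sidecar format.

One record is one channel of one trial: an amplitude series at a fixed
sampling rate, identified by (subject, trial, channel) keys, with labelled
sample spans marking the perceived-fatigue state ("easy" early in the
trial, "difficult" late).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

LABELS = ("easy", "difficult")


@dataclass
class EMGRecord:
    """A single-channel surface-EMG trial.

    Parameters
    ----------
    samples : ndarray
        Amplitude series in arbitrary µV-like units.
    fs : float
        Sampling rate in Hz.
    subject_id, trial_id, channel_id : int
        Identity keys within the dataset.
    label_windows : list of (start, end, label)
        Half-open sample spans ``[start, end)`` with label ``"easy"`` or
        ``"difficult"``; non-overlapping and within the record.
    meta : dict
        Free-form provenance (e.g. the generating configuration).
    """

    samples: np.ndarray
    fs: float
    subject_id: int
    trial_id: int
    channel_id: int
    label_windows: list[tuple[int, int, str]] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        n = self.samples.size
        spans = sorted(self.label_windows)
        for start, end, label in spans:
            if not (0 <= start < end <= n):
                raise ValueError(f"label window ({start}, {end}) outside [0, {n})")
            if label not in LABELS:
                raise ValueError(f"unknown label {label!r}")
        for (_, e0, _), (s1, _, _) in zip(spans, spans[1:]):
            if s1 < e0:
                raise ValueError("label windows overlap")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def key(self) -> tuple[int, int, int]:
        return (self.subject_id, self.trial_id, self.channel_id)

    def time(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs


def record_basename(record: EMGRecord) -> str:
    return f"s{record.subject_id:02d}_t{record.trial_id:02d}_c{record.channel_id:02d}"


def write_record(record: EMGRecord, directory: str | Path) -> tuple[Path, Path]:
    """Write one record as ``<key>.csv`` (time_s, amplitude) plus a JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    base = record_basename(record)
    csv_path = directory / f"{base}.csv"
    json_path = directory / f"{base}.json"
    pd.DataFrame({"time_s": record.time(), "amplitude": record.samples}).to_csv(
        csv_path, index=False, float_format="%.10g"
    )
    sidecar = {
        "fs": record.fs,
        "subject_id": record.subject_id,
        "trial_id": record.trial_id,
        "channel_id": record.channel_id,
        "label_windows": [[int(s), int(e), lab] for s, e, lab in record.label_windows],
        "meta": record.meta,
    }
    json_path.write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return csv_path, json_path


def read_record(csv_path: str | Path) -> EMGRecord:
    """Load a record written by :func:`write_record`."""
    csv_path = Path(csv_path)
    sidecar = json.loads(csv_path.with_suffix(".json").read_text())
    frame = pd.read_csv(csv_path)
    return EMGRecord(
        samples=frame["amplitude"].to_numpy(),
        fs=float(sidecar["fs"]),
        subject_id=int(sidecar["subject_id"]),
        trial_id=int(sidecar["trial_id"]),
        channel_id=int(sidecar["channel_id"]),
        label_windows=[(int(s), int(e), lab) for s, e, lab in sidecar["label_windows"]],
        meta=sidecar.get("meta", {}),
    )


def write_manifest(records: list[EMGRecord], directory: str | Path) -> Path:
    """Index all records of a dataset in one manifest CSV."""
    directory = Path(directory)
    rows = [
        {
            "subject_id": r.subject_id,
            "trial_id": r.trial_id,
            "channel_id": r.channel_id,
            "fs": r.fs,
            "n_samples": r.n_samples,
            "file": f"{record_basename(r)}.csv",
        }
        for r in records
    ]
    path = directory / "manifest.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
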