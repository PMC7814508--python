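"""Reading and writing ECG records, beat annotations, and predictions.

Two on-disk dialects are supported behind one interface:

* ``csv`` — the canonical plain-text dialect.  A record is a two-column
  CSV ``sample_index,value`` (the sampling rate travels separately, e.g.
  in a cohort manifest); annotations are ``sample_index,label``.
* ``wfdb`` — best-effort PhysioNet WFDB support (single-signal format-16
  records, MIT-format beat annotations) so MIT-BIH-style data can be
  loaded when a user supplies it.

All coordinates are 0-based sample indices.  Amplitude units are carried
through untouched; nothing here interprets them.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import _wfdb

__all__ = [
    "BEAT_LABELS",
    "PREDICTION_LABELS",
    "EcgRecord",
    "BeatAnnotation",
    "read_record",
    "write_record",
    "read_annotations",
    "write_annotations",
    "validate_annotations",
    "write_predictions",
    "read_predictions",
]

#: Beat classes understood by the annotation readers.
BEAT_LABELS = frozenset({"N", "V", "A", "F", "S"})

#: Labels a classifier may emit (the two modelled classes plus the anomaly path).
PREDICTION_LABELS = frozenset({"N", "V", "ANOMALY"})

PREDICTIONS_HEADER = ["patient_id", "window_index", "true_label", "predicted_label", "distance"]


@dataclass
class EcgRecord:
    """One patient's single-lead ECG: raw signal, sampling rate, identity.

    Parameters
    ----------
    patient_id:
        Opaque identifier; used to pair records with annotations and models.
    fs:
        Sampling rate in Hz (must be positive; 180 Hz in the reference setup).
    signal:
        Amplitude samples in whatever units the source file carries.
    """

    patient_id: str
    fs: float
    signal: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 1 or self.signal.size < 1:
            raise ValueError("empty signal")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite values")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")

    @property
    def n_samples(self) -> int:
        """Record length L in samples."""
        return int(self.signal.size)


@dataclass(frozen=True, order=True)
class BeatAnnotation:
    """A beat fiducial: 0-based sample index plus its class label."""

    sample_index: int
    label: str

    def __post_init__(self) -> None:
        if self.sample_index < 0:
            raise ValueError(f"negative sample index: {self.sample_index}")
        if self.label not in BEAT_LABELS:
            raise ValueError(f"unknown label {self.label!r} (expected one of {sorted(BEAT_LABELS)})")


def read_record(path: str, format: str = "csv", *, fs: float | None = None,
                patient_id: str | None = None) -> EcgRecord:
    """Read an ECG record.

    For ``format="csv"`` the file must have columns ``sample_index,value``
    and ``fs`` must be supplied (CSV carries no rate).  For ``format="wfdb"``,
    ``path`` is the record base name (without extension) or the ``.hea`` path;
    the rate comes from the header.
    """
    if format == "csv":
        if fs is None:
            raise ValueError("fs is required for csv records (the dialect carries no rate)")
        df = pd.read_csv(path, float_precision="round_trip")
        if df.shape[1] < 2:
            raise ValueError(f"expected two columns (sample_index,value) in {path}")
        if len(df) == 0:
            raise ValueError("empty signal")
        values = pd.to_numeric(df.iloc[:, 1], errors="raise").to_numpy(dtype=np.float64)
        pid = patient_id or _stem(path)
        return EcgRecord(patient_id=pid, fs=float(fs), signal=values)
    if format == "wfdb":
        base = path[:-4] if path.endswith(".hea") else path
        signal, header_fs = _wfdb.read_signal(base)
        if len(signal) == 0:
            raise ValueError("empty signal")
        return EcgRecord(patient_id=patient_id or os.path.basename(base),
                         fs=header_fs, signal=signal)
    raise ValueError(f"unknown record format {format!r}")


def write_record(path: str, record: EcgRecord, format: str = "csv") -> None:
    """Write a record in the requested dialect (see :func:`read_record`)."""
    if format == "csv":
        df = pd.DataFrame({"sample_index": np.arange(record.n_samples, dtype=np.int64),
                           "value": record.signal})
        df.to_csv(path, index=False)
    elif format == "wfdb":
        base = path[:-4] if path.endswith(".hea") else path
        _wfdb.write_signal(base, record.signal, record.fs)
    else:
        raise ValueError(f"unknown record format {format!r}")


def read_annotations(path: str, format: str = "csv") -> list[BeatAnnotation]:
    """Read beat annotations, sorted check included.

    Annotations must be strictly increasing in sample index and carry only
    known labels; violations raise rather than silently reorder.
    """
    if format == "csv":
        df = pd.read_csv(path)
        pairs = [(int(i), str(lab)) for i, lab in zip(df.iloc[:, 0], df.iloc[:, 1])]
    elif format == "wfdb":
        atr = path if path.endswith(".atr") else path + ".atr"
        pairs = _wfdb.read_annotations(atr)
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    annotations = [BeatAnnotation(sample_index=i, label=lab) for i, lab in pairs]
    for prev, cur in zip(annotations, annotations[1:]):
        if cur.sample_index <= prev.sample_index:
            raise ValueError(
                f"annotations out of order at sample {cur.sample_index} (after {prev.sample_index})")
    return annotations


def write_annotations(path: str, annotations: Sequence[BeatAnnotation],
                      format: str = "csv") -> None:
    if format == "csv":
        df = pd.DataFrame({"sample_index": [a.sample_index for a in annotations],
                           "label": [a.label for a in annotations]})
        df.to_csv(path, index=False)
    elif format == "wfdb":
        atr = path if path.endswith(".atr") else path + ".atr"
        _wfdb.write_annotations(atr, [(a.sample_index, a.label) for a in annotations])
    else:
        raise ValueError(f"unknown annotation format {format!r}")


def validate_annotations(record: EcgRecord, annotations: Sequence[BeatAnnotation]) -> None:
    """Check that every annotation falls inside the record."""
    for ann in annotations:
        if ann.sample_index >= record.n_samples:
            raise ValueError(
                f"annotation at sample {ann.sample_index} outside record of length {record.n_samples}")


def write_predictions(path: str, rows: Iterable[tuple]) -> None:
    """Write a predictions CSV with the fixed schema.

    ``rows`` holds ``(patient_id, window_index, true_label, predicted_label,
    distance)`` tuples; output is sorted by (patient_id, window_index) so
    reruns are byte-comparable.
    """
    rows = list(rows)
    for row in rows:
        if len(row) != 5:
            raise ValueError(f"prediction row must have 5 fields, got {row!r}")
        if row[3] not in PREDICTION_LABELS:
            raise ValueError(f"predicted label must be one of {sorted(PREDICTION_LABELS)}, got {row[3]!r}")
    df = pd.DataFrame(rows, columns=PREDICTIONS_HEADER)
    df = df.sort_values(["patient_id", "window_index"], kind="mergesort")
    df.to_csv(path, index=False)


def read_predictions(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    if list(df.columns) != PREDICTIONS_HEADER:
        raise ValueError(f"unexpected predictions header {list(df.columns)}")
    return df


def _stem(path: str) -> str:
    return os.path.splitext(os.path.basename(path))[0]
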