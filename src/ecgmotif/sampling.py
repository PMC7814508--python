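"""Training-sample sizing, fixed-grid segmentation, and beat labeling.

The model treats an ECG record as a sequence of fixed-length "pattern
units": with a 180 Hz device one 180-sample window holds roughly one
heartbeat.  Given a training ratio ``t`` the first ``S = floor(L * t)``
samples are the training stretch, and a stretch of ``S`` samples yields
``M = floor(S / W)`` consecutive non-overlapping windows (any trailing
remainder shorter than a window is discarded).  Windows are then labeled
from the beat annotations: a window keeps exactly one fiducial whose class
is retained (by default N and V); everything else — empty windows, windows
with several fiducials, excluded pathology labels — is treated as noisy
and dropped, with the reason reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import BEAT_LABELS, BeatAnnotation, EcgRecord

__all__ = [
    "SamplingConfig",
    "Heartbeat",
    "DiscardedWindow",
    "compute_sample_length",
    "segment",
    "label_windows",
    "stratified_prefix_split",
    "discard_report",
]

#: Default pattern-unit length in samples (one second at the 180 Hz device rate).
DEFAULT_WINDOW = 180


@dataclass(frozen=True)
class SamplingConfig:
    """Sampling parameters: training ratio, window length, retained labels."""

    t: float = 0.1
    window_length: int = DEFAULT_WINDOW
    keep_labels: frozenset[str] = frozenset({"N", "V"})

    def __post_init__(self) -> None:
        if not 0 < self.t <= 1:
            raise ValueError(f"training ratio t must be in (0, 1], got {self.t}")
        if self.window_length < 2:
            raise ValueError(f"window length must be >= 2, got {self.window_length}")
        if not self.keep_labels or not self.keep_labels <= BEAT_LABELS:
            raise ValueError(f"keep_labels must be a non-empty subset of {sorted(BEAT_LABELS)}")


@dataclass(frozen=True)
class Heartbeat:
    """One labeled pattern unit cut from a record."""

    patient_id: str
    window_index: int
    vector: np.ndarray = field(repr=False, compare=False)
    label: str
    start_sample: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "vector", np.asarray(self.vector, dtype=np.float64))


@dataclass(frozen=True)
class DiscardedWindow:
    """A window dropped during labeling, with the rule that dropped it."""

    patient_id: str
    window_index: int
    reason: str  # no_annotation | multiple_annotations | excluded_label


def compute_sample_length(L: int, t: float) -> int:
    """Length of the training stretch: ``S = floor(L * t)``.

    ``t = 1`` is allowed so a whole record can be segmented in one call.
    """
    if L < 1:
        raise ValueError(f"record length must be >= 1, got {L}")
    if not 0 < t <= 1:
        raise ValueError(f"training ratio t must be in (0, 1], got {t}")
    return math.floor(L * t)


def segment(record: EcgRecord, S: int, W: int = DEFAULT_WINDOW) -> np.ndarray:
    """Cut the first ``S`` samples into ``M = floor(S / W)`` windows.

    Returns an ``(M, W)`` array of consecutive non-overlapping windows
    starting at sample 0; a trailing remainder shorter than ``W`` is
    discarded.  Raises if not even one window fits.
    """
    if S > record.n_samples:
        raise ValueError(f"S={S} exceeds record length {record.n_samples}")
    if W < 2:
        raise ValueError(f"window length must be >= 2, got {W}")
    M = S // W
    if M == 0:
        raise ValueError(f"sample too short for one pattern unit (S={S} < W={W})")
    return record.signal[: M * W].reshape(M, W)


def label_windows(windows: np.ndarray, annotations: Sequence[BeatAnnotation],
                  patient_id: str,
                  keep_labels: frozenset[str] = frozenset({"N", "V"}),
                  ) -> tuple[list[Heartbeat], list[DiscardedWindow]]:
    """Assign one class per window from the beat fiducials inside it.

    A window ``[start, start + W)`` becomes a :class:`Heartbeat` iff it
    contains exactly one fiducial and that fiducial's label is retained.
    Returns the kept beats (in window order) and the discard report.
    """
    M, W = windows.shape
    starts = [a.sample_index // W for a in annotations]
    per_window: dict[int, list[BeatAnnotation]] = {}
    for w, ann in zip(starts, annotations):
        if 0 <= w < M:
            per_window.setdefault(w, []).append(ann)

    beats: list[Heartbeat] = []
    discards: list[DiscardedWindow] = []
    for w in range(M):
        anns = per_window.get(w, [])
        if len(anns) == 0:
            discards.append(DiscardedWindow(patient_id, w, "no_annotation"))
        elif len(anns) > 1:
            discards.append(DiscardedWindow(patient_id, w, "multiple_annotations"))
        elif anns[0].label not in keep_labels:
            discards.append(DiscardedWindow(patient_id, w, "excluded_label"))
        else:
            beats.append(Heartbeat(patient_id=patient_id, window_index=w,
                                   vector=windows[w], label=anns[0].label,
                                   start_sample=w * W))
    return beats, discards


def stratified_prefix_split(beats: Sequence[Heartbeat], t: float,
                            ) -> tuple[list[Heartbeat], list[Heartbeat]]:
    """Per-class temporal prefix split for the personalized model.

    For each class present, the first ``ceil(t * n_class)`` beats (in time
    order) go to training; everything else is the test set.  ``ceil`` of a
    positive quantity is at least 1, so any class with at least one beat is
    represented in training.  Classes absent from the record simply
    contribute nothing.
    """
    if not 0 < t < 1:
        raise ValueError(f"training ratio t must be in (0, 1), got {t}")
    counts: dict[str, int] = {}
    for b in beats:
        counts[b.label] = counts.get(b.label, 0) + 1
    quota = {label: math.ceil(t * n) for label, n in counts.items()}
    taken: dict[str, int] = {label: 0 for label in counts}
    train: list[Heartbeat] = []
    test: list[Heartbeat] = []
    for b in beats:
        if taken[b.label] < quota[b.label]:
            train.append(b)
            taken[b.label] += 1
        else:
            test.append(b)
    return train, test


def discard_report(discards: Sequence[DiscardedWindow]) -> pd.DataFrame:
    """Discard report as a DataFrame (patient_id, window_index, discard_reason)."""
    return pd.DataFrame(
        [(d.patient_id, d.window_index, d.reason) for d in discards],
        columns=["patient_id", "window_index", "discard_reason"],
    )
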