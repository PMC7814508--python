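"""Training samplers for the three monitoring models.

All three models share the same motif discovery and logical-network
classifier; they differ only in where training beats come from:

* **PMM** (personalized): per patient, the first ``t`` fraction of that
  patient's N beats and the first ``t`` fraction of its V beats; one model
  per patient, tested only on that patient's remaining beats.
* **GMM1** (pooled, prefix): the first ``t`` fraction of each patient's
  beats (classes mixed, time order) pooled into one training set; one
  model tests every patient's remainder.
* **GMM2** (pooled, random): ``t`` fraction of all N beats cohort-wide and
  ``t`` fraction of all V beats, drawn uniformly without replacement with
  a recorded seed; test sets are each patient's un-drawn beats.

Per-patient test sets are identical for PMM — per-class prefixes — versus
GMM1 only when every patient's class mix makes the mixed and per-class
prefixes coincide; both are prefix-based, so accuracy differences are
attributable to training composition.  GMM2's test sets differ by
construction and are reported separately.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .sampling import Heartbeat, stratified_prefix_split

__all__ = ["POLICIES", "CohortSplit", "gmm1_split", "gmm2_split", "pmm_split", "cohort_split"]

POLICIES = ("pmm", "gmm1", "gmm2")


@dataclass(frozen=True)
class CohortSplit:
    """Train/test assignment for one policy on one cohort.

    For the pooled policies ``train_beats`` holds the single cohort-wide
    training pool; for the personalized policy the pool is per patient in
    ``per_patient_train``.
    """

    policy: str
    train_beats: tuple[Heartbeat, ...]
    per_patient_train: Mapping[str, tuple[Heartbeat, ...]] = field(default_factory=dict)
    per_patient_test: Mapping[str, tuple[Heartbeat, ...]] = field(default_factory=dict)
    seed: int | None = None


def _prefix_count(t: float, n: int) -> int:
    """Training share of a pool of ``n``: ``ceil(t * n)`` (>= 1 when n >= 1)."""
    return math.ceil(t * n) if n else 0


def gmm1_split(cohort: Mapping[str, Sequence[Heartbeat]], t: float) -> CohortSplit:
    """Pooled class-mixed prefix sampler (first generalized model)."""
    if not cohort:
        raise ValueError("cohort is empty")
    if not 0 < t < 1:
        raise ValueError(f"training ratio t must be in (0, 1), got {t}")
    train: list[Heartbeat] = []
    test: dict[str, tuple[Heartbeat, ...]] = {}
    for pid, beats in sorted(cohort.items()):
        n_train = _prefix_count(t, len(beats))
        train.extend(beats[:n_train])
        test[pid] = tuple(beats[n_train:])
    return CohortSplit(policy="gmm1", train_beats=tuple(train), per_patient_test=test)


def gmm2_split(cohort: Mapping[str, Sequence[Heartbeat]], t: float, seed: int) -> CohortSplit:
    """Pooled class-stratified random sampler (second generalized model).

    Draws ``ceil(t * n_class)`` beats per class uniformly without
    replacement across the whole cohort; a class absent cohort-wide simply
    contributes nothing (with a warning).
    """
    if not cohort:
        raise ValueError("cohort is empty")
    if not 0 < t < 1:
        raise ValueError(f"training ratio t must be in (0, 1), got {t}")
    all_beats: list[tuple[str, int, Heartbeat]] = []  # (pid, position, beat)
    for pid, beats in sorted(cohort.items()):
        all_beats.extend((pid, i, b) for i, b in enumerate(beats))

    labels = sorted({b.label for _, _, b in all_beats})
    rng = np.random.default_rng(seed)
    chosen: set[tuple[str, int]] = set()
    for label in labels:
        pool = [(pid, i) for pid, i, b in all_beats if b.label == label]
        if not pool:
            warnings.warn(f"class {label} absent from the cohort", stacklevel=2)
            continue
        n_draw = _prefix_count(t, len(pool))
        idx = rng.choice(len(pool), size=n_draw, replace=False)
        chosen.update(pool[i] for i in idx)

    train = tuple(b for pid, i, b in all_beats if (pid, i) in chosen)
    test = {pid: tuple(b for p2, i, b in all_beats if p2 == pid and (p2, i) not in chosen)
            for pid in sorted(cohort)}
    return CohortSplit(policy="gmm2", train_beats=train, per_patient_test=test, seed=seed)


def pmm_split(patient_beats: Sequence[Heartbeat], t: float,
              ) -> tuple[list[Heartbeat], list[Heartbeat]]:
    """Personalized per-class prefix split for a single patient."""
    return stratified_prefix_split(patient_beats, t)


def cohort_split(cohort: Mapping[str, Sequence[Heartbeat]], policy: str, t: float,
                 seed: int | None = None) -> CohortSplit:
    """Dispatch to the policy's sampler, normalized to a :class:`CohortSplit`."""
    if policy == "gmm1":
        return gmm1_split(cohort, t)
    if policy == "gmm2":
        if seed is None:
            raise ValueError("gmm2 requires a seed")
        return gmm2_split(cohort, t, seed)
    if policy == "pmm":
        train: dict[str, tuple[Heartbeat, ...]] = {}
        test: dict[str, tuple[Heartbeat, ...]] = {}
        for pid, beats in sorted(cohort.items()):
            tr, te = pmm_split(beats, t)
            train[pid], test[pid] = tuple(tr), tuple(te)
        return CohortSplit(policy="pmm", train_beats=(),
                           per_patient_train=train, per_patient_test=test)
    raise ValueError(f"unknown policy {policy!r} (expected one of {POLICIES})")
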