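"""Per-class motif discovery: radius-constrained greedy subsequence clustering.

A *motif circle* is the set of training subsequences lying strictly within
distance ``r`` of a chosen center subsequence.  Discovery is greedy,
largest-circle-first: the circle with the most members becomes the rank-1
motif, its members leave the candidate pool, and the process repeats until
``k`` motifs exist or the pool is empty.  Circles therefore never share a
subsequence, member counts are non-increasing with rank, and every center
is an actual training subsequence.  Two centers may lie closer than ``2r``
to each other as long as their member sets are disjoint.

Distances are Euclidean, either raw (``normalize="none"``) or on z-scored
copies divided by ``sqrt(W)`` (``normalize="znorm"``, the default).  The
normalized distance equals ``sqrt(2 * (1 - rho))`` for correlation ``rho``,
so it is amplitude- and offset-invariant and bounded by 2 — a radius grid
such as 0.8–1.6 then has the same meaning for every record regardless of
its physical units.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from ._ops import record_pairs
from .sampling import Heartbeat

__all__ = [
    "MotifParams",
    "Motif",
    "distance",
    "pairwise_distances",
    "discover_motifs",
    "save_motifs",
    "load_motifs",
]


@dataclass(frozen=True)
class MotifParams:
    """Discovery parameters: similarity radius ``r``, motif count ``k``, distance mode."""

    r: float
    k: int
    normalize: str = "znorm"

    def __post_init__(self) -> None:
        if self.r < 0:
            raise ValueError(f"similarity threshold r must be >= 0, got {self.r}")
        if self.k < 1:
            raise ValueError(f"motif count k must be >= 1, got {self.k}")
        if self.normalize not in ("none", "znorm"):
            raise ValueError(f"normalize must be 'none' or 'znorm', got {self.normalize!r}")


@dataclass(frozen=True)
class Motif:
    """A discovered motif: its center subsequence and circle bookkeeping.

    ``member_indices`` are positions into the training-beat sequence passed
    to :func:`discover_motifs` and always include the center's own index.
    """

    center: np.ndarray = field(repr=False, compare=False)
    label: str
    rank: int
    member_count: int
    member_indices: frozenset[int]
    radius: float
    center_window_index: int = -1

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=np.float64))


def znorm(v: np.ndarray) -> np.ndarray:
    """Z-score a vector; a constant vector has no shape and is rejected."""
    v = np.asarray(v, dtype=np.float64)
    sd = v.std()
    if sd == 0:
        raise ValueError("zero-variance subsequence cannot be z-normalized")
    return (v - v.mean()) / sd


def _preprocess(X: np.ndarray, normalize: str) -> np.ndarray:
    """Map vectors so plain Euclidean distance realizes the chosen mode."""
    X = np.asarray(X, dtype=np.float64)
    if normalize == "none":
        return X
    if normalize == "znorm":
        sd = X.std(axis=1, keepdims=True)
        if np.any(sd == 0):
            raise ValueError("zero-variance subsequence cannot be z-normalized")
        Z = (X - X.mean(axis=1, keepdims=True)) / sd
        return Z / math.sqrt(X.shape[1])
    raise ValueError(f"normalize must be 'none' or 'znorm', got {normalize!r}")


def distance(a: np.ndarray, b: np.ndarray, normalize: str = "znorm") -> float:
    """Distance between two equal-length subsequences under the chosen mode."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    X = _preprocess(np.stack([a, b]), normalize)
    record_pairs(1)
    return float(np.linalg.norm(X[0] - X[1]))


def _beat_matrix(beats: Sequence[Heartbeat]) -> np.ndarray:
    if len(beats) == 0:
        raise ValueError("need at least one beat")
    lengths = {len(b.vector) for b in beats}
    if len(lengths) != 1:
        raise ValueError(f"mixed window lengths: {sorted(lengths)}")
    return np.stack([b.vector for b in beats])


def pairwise_distances(beats: Sequence[Heartbeat], normalize: str = "znorm") -> np.ndarray:
    """Symmetric zero-diagonal matrix of all pairwise subsequence distances."""
    X = _preprocess(_beat_matrix(beats), normalize)
    n = len(beats)
    record_pairs(n * (n - 1) // 2)
    if n == 1:
        return np.zeros((1, 1))
    return squareform(pdist(X, metric="euclidean"))


#: Node budget for the lookahead tie resolver.  Exhausting it degrades the
#: tie-break to smallest-window-index for the affected decision only; the
#: result stays deterministic either way.
LOOKAHEAD_BUDGET = 200_000


class _CirclePicker:
    """Selects circles greedily, resolving size ties by lexicographic lookahead.

    The selection maximizes the sequence of circle member counts
    lexicographically.  At each step only maximum-count circles can appear
    in the optimal sequence, so the picker branches solely over the
    *distinct member sets* among tied maximum-count circles and compares
    their full continuations (to pool exhaustion, memoized).  Using the
    full horizon rather than the remaining ``k`` makes the choice — and
    hence the discovered motifs — independent of ``k``: smaller-``k``
    output is a prefix of larger-``k`` output.
    """

    def __init__(self, circles: list[frozenset[int]], order_key: Sequence[int]):
        self.circles = circles
        self.order_key = list(order_key)
        self._memo: dict[frozenset[int], tuple[int, ...]] = {}
        self._nodes = 0

    def _tied_sets(self, pool: frozenset[int]) -> tuple[int, list[tuple[frozenset[int], int]]]:
        """Max member count and the distinct tied member sets (with min-key center)."""
        best = 0
        by_set: dict[frozenset[int], int] = {}
        for i in pool:
            members = self.circles[i] & pool
            c = len(members)
            if c > best:
                best = c
                by_set = {members: i}
            elif c == best:
                prev = by_set.get(members)
                if prev is None or self.order_key[i] < self.order_key[prev]:
                    by_set[members] = i
        return best, sorted(by_set.items(), key=lambda kv: self.order_key[kv[1]])

    def _best_sequence(self, pool: frozenset[int]) -> tuple[int, ...]:
        """Lexicographically maximal count sequence achievable on ``pool``."""
        if not pool:
            return ()
        cached = self._memo.get(pool)
        if cached is not None:
            return cached
        self._nodes += 1
        best, tied = self._tied_sets(pool)
        if best == 1:
            # only singletons remain, so the rest of the sequence is all ones
            seq = (1,) * len(pool)
        elif self._nodes > LOOKAHEAD_BUDGET:
            # budget exhausted: keep the first branch (smallest window
            # index); the result is still deterministic
            seq = (best,) + self._best_sequence(pool - tied[0][0])
        else:
            seq = max((best,) + self._best_sequence(pool - members)
                      for members, _ in tied)
        self._memo[pool] = seq
        return seq

    def pick(self, pool: frozenset[int]) -> tuple[int, frozenset[int]]:
        """Choose the next center; returns (center index, members within pool)."""
        best, tied = self._tied_sets(pool)
        if len(tied) > 1 and best > 1 and self._nodes <= LOOKAHEAD_BUDGET:
            tied.sort(key=lambda kv: (tuple(-c for c in self._best_sequence(pool - kv[0])),
                                      self.order_key[kv[1]]))
        members, center = tied[0]
        return center, members


def discover_motifs(beats: Sequence[Heartbeat], params: MotifParams,
                    label: str | None = None) -> list[Motif]:
    """Greedy largest-circle-first motif discovery on one class's beats.

    ``beats`` should already be filtered to a single class; ``label``
    overrides the label recorded on the motifs (defaults to the first
    beat's label).  The circle with the most members becomes the next
    motif; size ties resolve by lexicographic lookahead (see
    :class:`_CirclePicker`), then by smaller window index, so discovery is
    deterministic and its member-count sequence is the lexicographic
    maximum over all admissible center choices.  If the pool runs out
    before ``k`` motifs exist, the shorter list is returned with a warning.
    """
    D = pairwise_distances(beats, params.normalize)
    n = len(beats)
    label = label if label is not None else beats[0].label
    inside = D < params.r  # strict, per circle-membership rule
    np.fill_diagonal(inside, True)  # a center always belongs to its own circle

    circles = [frozenset(np.flatnonzero(inside[i]).tolist()) for i in range(n)]
    picker = _CirclePicker(circles, [b.window_index for b in beats])
    pool = frozenset(range(n))
    motifs: list[Motif] = []
    while len(motifs) < params.k and pool:
        center, members = picker.pick(pool)
        motifs.append(Motif(
            center=beats[center].vector,
            label=label,
            rank=len(motifs) + 1,
            member_count=len(members),
            member_indices=members,
            radius=params.r,
            center_window_index=int(beats[center].window_index),
        ))
        pool = pool - members
    if len(motifs) < params.k:
        warnings.warn(
            f"only {len(motifs)} of {params.k} motifs discoverable for class {label}",
            stacklevel=2)
    return motifs


def save_motifs(path: str, patient_id: str, motifs: Sequence[Motif],
                params: MotifParams) -> None:
    """Serialize one patient's motifs to JSON (sorted keys, fixed float format)."""
    payload = {
        "patient_id": patient_id,
        "r": params.r,
        "k": params.k,
        "normalize": params.normalize,
        "motifs": [
            {
                "label": m.label,
                "rank": m.rank,
                "member_count": m.member_count,
                "center_window_index": m.center_window_index,
                "center": [round(float(x), 9) for x in m.center],
            }
            for m in motifs
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, sort_keys=True, indent=1)
        fh.write("\n")


def load_motifs(path: str) -> tuple[str, list[Motif], MotifParams]:
    with open(path) as fh:
        payload = json.load(fh)
    params = MotifParams(r=payload["r"], k=payload["k"], normalize=payload["normalize"])
    motifs = [
        Motif(center=np.asarray(m["center"]), label=m["label"], rank=m["rank"],
              member_count=m["member_count"], member_indices=frozenset(),
              radius=params.r, center_window_index=m.get("center_window_index", -1))
        for m in payload["motifs"]
    ]
    return payload["patient_id"], motifs, params
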