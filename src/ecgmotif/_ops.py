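"""Lightweight counters for distance computations.

Training cost of the personalized model scales with the per-patient pool
sizes while the pooled baselines scale with the cohort-wide pool, so the
number of pairwise-distance evaluations is the natural hardware-independent
cost measure.  Any code path that evaluates subsequence distances reports
the number of vector pairs it touched here; callers observe them with
:func:`count_distance_ops`.
"""

from __future__ import annotations

from contextlib import contextmanager
from dataclasses import dataclass

__all__ = ["OpCounter", "count_distance_ops"]


@dataclass
class OpCounter:
    """Accumulates the number of vector-pair distance evaluations."""

    pairs: int = 0


_active: list[OpCounter] = []


def record_pairs(n: int) -> None:
    """Credit ``n`` distance evaluations to every active counter."""
    for counter in _active:
        counter.pairs += n


@contextmanager
def count_distance_ops():
    """Context manager yielding an :class:`OpCounter` active inside the block.

    Counters nest: an inner block's pairs are also credited to outer blocks.
    """
    counter = OpCounter()
    _active.append(counter)
    try:
        yield counter
    finally:
        _active.remove(counter)
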