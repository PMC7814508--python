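"""The artificial logical network: nearest-motif classification with an anomaly path.

Each discovered motif becomes a class-tagged evaluation node (N nodes first,
ordered by rank, then V nodes).  A test subsequence is compared against every
node; the nearest node's class is the prediction, unless even the nearest
node lies at distance ``>= r`` — then no node's matching criterion is met and
the beat is flagged ``ANOMALY`` for future learning.  Exact distance ties
resolve to the earlier node in the fixed ordering, so classification is
deterministic.

The network can grow: :func:`add_node` returns a new network with an extra
motif appended after the existing nodes of its class, which is how a
clinician-confirmed anomaly motif would be pushed into a running model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from ._ops import record_pairs
from .motifs import Motif, _preprocess
from .sampling import Heartbeat

__all__ = [
    "LogicalNetwork",
    "Prediction",
    "build_network",
    "classify",
    "classify_batch",
    "add_node",
    "save_network",
    "load_network",
]


@dataclass(frozen=True)
class LogicalNetwork:
    """An ordered set of class-tagged motif nodes plus the matching radius."""

    patient_id: str  # "pooled" for the generalized models
    nodes: tuple[Motif, ...]
    r: float
    normalize: str = "znorm"

    def __post_init__(self) -> None:
        if len(self.nodes) == 0:
            raise ValueError("a logical network needs at least one node")
        widths = {len(n.center) for n in self.nodes}
        if len(widths) != 1:
            raise ValueError(f"mixed node window lengths: {sorted(widths)}")
        if self.r < 0:
            raise ValueError(f"matching radius r must be >= 0, got {self.r}")

    @property
    def window_length(self) -> int:
        return len(self.nodes[0].center)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(n.label for n in self.nodes)


@dataclass(frozen=True)
class Prediction:
    """Outcome for one test beat.

    ``predicted`` is ``ANOMALY`` exactly when the best distance is ``>= r``
    (or the beat could not be compared at all, see ``reason``); otherwise it
    is the arg-min node's class.
    """

    window_index: int
    predicted: str
    best_distance: float
    best_node_rank: int | None
    best_node_label: str | None = None
    reason: str | None = None
    true_label: str | None = field(default=None, compare=False)


def build_network(n_motifs: Sequence[Motif], v_motifs: Sequence[Motif],
                  r: float, normalize: str = "znorm",
                  patient_id: str = "unknown") -> LogicalNetwork:
    """Assemble a network: N motifs by rank, then V motifs by rank."""
    nodes = tuple(sorted(n_motifs, key=lambda m: m.rank)) + \
        tuple(sorted(v_motifs, key=lambda m: m.rank))
    return LogicalNetwork(patient_id=patient_id, nodes=nodes, r=r, normalize=normalize)


def _node_matrix(network: LogicalNetwork) -> np.ndarray:
    return _preprocess(np.stack([n.center for n in network.nodes]), network.normalize)


def classify(vector: np.ndarray, network: LogicalNetwork,
             window_index: int = 0, true_label: str | None = None) -> Prediction:
    """Classify one beat vector against every node; nearest wins inside r."""
    vector = np.asarray(vector, dtype=np.float64)
    if vector.shape != (network.window_length,):
        raise ValueError(
            f"beat length {vector.shape} does not match node length {network.window_length}")
    return classify_batch(
        [Heartbeat(patient_id=network.patient_id, window_index=window_index,
                   vector=vector, label=true_label or "N", start_sample=0)],
        network, true_labels=[true_label])[0]


def classify_batch(beats: Sequence[Heartbeat], network: LogicalNetwork,
                   true_labels: Sequence[str | None] | None = None,
                   ) -> list[Prediction]:
    """Classify beats elementwise, order preserved.

    A beat that cannot be z-normalized (constant vector) cannot be compared
    to any node under the ``znorm`` mode and is flagged ``ANOMALY`` with
    ``reason="zero_variance"`` rather than raising.
    """
    if len(beats) == 0:
        return []
    X = np.stack([b.vector for b in beats]).astype(np.float64)
    if X.shape[1] != network.window_length:
        raise ValueError(
            f"beat length {X.shape[1]} does not match node length {network.window_length}")
    if true_labels is None:
        true_labels = [b.label for b in beats]

    degenerate = np.zeros(len(beats), dtype=bool)
    if network.normalize == "znorm":
        degenerate = X.std(axis=1) == 0
    nodes = _node_matrix(network)
    predictions: list[Prediction] = [None] * len(beats)  # type: ignore[list-item]

    ok = np.flatnonzero(~degenerate)
    if ok.size:
        Xok = _preprocess(X[ok], network.normalize)
        D = cdist(Xok, nodes, metric="euclidean")
        record_pairs(int(D.size))
        best_idx = D.argmin(axis=1)  # argmin returns the first minimum: node-order tie-break
        best_dist = D[np.arange(len(ok)), best_idx]
        for row, i in enumerate(ok):
            node = network.nodes[best_idx[row]]
            dist = float(best_dist[row])
            if dist < network.r:
                predicted = node.label
            else:
                predicted = "ANOMALY"
            predictions[i] = Prediction(
                window_index=beats[i].window_index, predicted=predicted,
                best_distance=dist, best_node_rank=int(node.rank),
                best_node_label=node.label, true_label=true_labels[i])
    for i in np.flatnonzero(degenerate):
        predictions[i] = Prediction(
            window_index=beats[i].window_index, predicted="ANOMALY",
            best_distance=float("inf"), best_node_rank=None,
            best_node_label=None, reason="zero_variance",
            true_label=true_labels[i])
    return predictions


def add_node(network: LogicalNetwork, motif: Motif) -> LogicalNetwork:
    """Return a network with ``motif`` appended after its class's nodes.

    If the network holds no node of that class yet, the motif goes to the
    end.  Existing nodes (and hence previously computed classifications)
    are untouched; the added node gets the next rank within its class.
    """
    if len(motif.center) != network.window_length:
        raise ValueError(
            f"motif length {len(motif.center)} does not match node length {network.window_length}")
    same = [i for i, n in enumerate(network.nodes) if n.label == motif.label]
    insert_at = same[-1] + 1 if same else len(network.nodes)
    next_rank = max((n.rank for n in network.nodes if n.label == motif.label), default=0) + 1
    motif = replace(motif, rank=next_rank)
    nodes = network.nodes[:insert_at] + (motif,) + network.nodes[insert_at:]
    return replace(network, nodes=nodes)


def save_network(path: str, network: LogicalNetwork) -> None:
    """Serialize a network to JSON (sorted keys, fixed float format)."""
    payload = {
        "patient_id": network.patient_id,
        "r": network.r,
        "normalize": network.normalize,
        "nodes": [
            {
                "label": n.label,
                "rank": n.rank,
                "member_count": n.member_count,
                "center_window_index": n.center_window_index,
                "center": [round(float(x), 9) for x in n.center],
            }
            for n in network.nodes
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, sort_keys=True, indent=1)
        fh.write("\n")


def load_network(path: str) -> LogicalNetwork:
    with open(path) as fh:
        payload = json.load(fh)
    nodes = tuple(
        Motif(center=np.asarray(n["center"]), label=n["label"], rank=n["rank"],
              member_count=n["member_count"], member_indices=frozenset(),
              radius=payload["r"], center_window_index=n.get("center_window_index", -1))
        for n in payload["nodes"]
    )
    return LogicalNetwork(patient_id=payload["patient_id"], nodes=nodes,
                          r=payload["r"], normalize=payload["normalize"])
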