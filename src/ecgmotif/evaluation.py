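"""Accuracy evaluation and the (R, K, T) parameter sweep.

Accuracy is the fraction of tested heartbeats predicted correctly.  Beats
the network flags as anomalies (no node within the matching radius) are
counted as incorrect by default; an alternative mode excludes them from
the denominator, and both numbers are reported on every row.  The cohort
``AVERAGE`` row is the unweighted mean of per-patient accuracies (a
pooled-beat accuracy column is carried alongside for reference).

The sweep crosses similarity radius R, motif count K, and training ratio T
for each policy.  Because greedy discovery at a smaller ``k`` is a prefix
of discovery at a larger one, motifs are discovered once per
(policy, r, t) at the largest K and sliced per cell; reported training
operation counts are the pairwise-distance evaluations of that discovery,
which do not depend on ``k``.  Wall-clock time is recorded for context but
is never an oracle — the distance-operation counters are the
hardware-independent cost measure.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from ._ops import count_distance_ops
from .baselines import POLICIES, CohortSplit, cohort_split
from .io import BeatAnnotation, EcgRecord
from .motifs import Motif, MotifParams, discover_motifs
from .network import LogicalNetwork, build_network, classify_batch
from .sampling import Heartbeat, label_windows, segment

__all__ = [
    "SweepGrid",
    "accuracy",
    "prepare_cohort_beats",
    "train_networks",
    "run_cell",
    "run_sweep",
    "plot_sweep",
]

RESULT_COLUMNS = [
    "policy", "r", "k", "t", "patient_id", "n_test", "n_correct", "n_anomaly",
    "accuracy", "accuracy_excl_anomaly", "pooled_accuracy",
    "train_ops", "test_ops", "wall_time_s",
]


@dataclass(frozen=True)
class SweepGrid:
    """Parameter grid; defaults reproduce the reference evaluation design."""

    r_values: tuple[float, ...] = (0.8, 1.0, 1.2, 1.4, 1.6)
    k_values: tuple[int, ...] = (2, 4, 6, 8, 10)
    t_values: tuple[float, ...] = (0.10, 0.15, 0.20, 0.25)
    policies: tuple[str, ...] = ("pmm", "gmm1", "gmm2")
    seed: int = 0
    normalize: str = "znorm"

    def __post_init__(self) -> None:
        if not (self.r_values and self.k_values and self.t_values and self.policies):
            raise ValueError("all grid dimensions must be non-empty")
        for p in self.policies:
            if p not in POLICIES:
                raise ValueError(f"unknown policy {p!r}")


def accuracy(predicted: Sequence[str], truths: Sequence[str],
             anomaly_excluded: bool = False) -> float:
    """Fraction of beats predicted correctly.

    ``ANOMALY`` predictions count as incorrect unless ``anomaly_excluded``
    removes those beats from the denominator.  Returns NaN when the
    denominator is empty.
    """
    if len(predicted) != len(truths):
        raise ValueError("predicted and truth sequences differ in length")
    pairs = list(zip(predicted, truths))
    if anomaly_excluded:
        pairs = [(p, y) for p, y in pairs if p != "ANOMALY"]
    if not pairs:
        return float("nan")
    return sum(p == y for p, y in pairs) / len(pairs)


def prepare_cohort_beats(
    cohort: Mapping[str, tuple[EcgRecord, Sequence[BeatAnnotation]]],
    window_length: int = 180,
    keep_labels: frozenset[str] = frozenset({"N", "V"}),
) -> dict[str, list[Heartbeat]]:
    """Segment and label every record of a cohort into kept heartbeats."""
    out: dict[str, list[Heartbeat]] = {}
    for pid, (record, annotations) in sorted(cohort.items()):
        windows = segment(record, record.n_samples, window_length)
        beats, _ = label_windows(windows, annotations, patient_id=pid,
                                 keep_labels=keep_labels)
        out[pid] = beats
    return out


def _discover_per_class(beats: Sequence[Heartbeat], params: MotifParams,
                        ) -> dict[str, list[Motif]]:
    by_class: dict[str, list[Motif]] = {}
    for label in sorted({b.label for b in beats}):
        class_beats = [b for b in beats if b.label == label]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            by_class[label] = discover_motifs(class_beats, params, label=label)
    return by_class


def train_networks(split: CohortSplit, params: MotifParams,
                   ) -> tuple[dict[str, LogicalNetwork], dict[str, int]]:
    """Discover motifs on a split's training pool(s) and build network(s).

    Returns ``(networks, train_ops)``.  For the pooled policies both maps
    have the single key ``"pooled"``; for the personalized policy one
    entry per patient (patients with no training beats are skipped with a
    warning).
    """
    networks: dict[str, LogicalNetwork] = {}
    ops: dict[str, int] = {}
    if split.policy == "pmm":
        pools = dict(split.per_patient_train)
    else:
        pools = {"pooled": split.train_beats}
    for name, beats in pools.items():
        if not beats:
            warnings.warn(f"no training beats for {name}; skipping", stacklevel=2)
            continue
        with count_distance_ops() as counter:
            by_class = _discover_per_class(beats, params)
        networks[name] = build_network(
            by_class.get("N", []), by_class.get("V", []),
            r=params.r, normalize=params.normalize, patient_id=name)
        ops[name] = counter.pairs
    return networks, ops


class _SweepCache:
    """Memoizes (policy, r, t) training so K cells slice discovered motifs."""

    def __init__(self, cohort_beats: Mapping[str, Sequence[Heartbeat]],
                 kmax: int, normalize: str, seed: int):
        self.cohort_beats = cohort_beats
        self.kmax = kmax
        self.normalize = normalize
        self.seed = seed
        self._store: dict[tuple, tuple] = {}

    def trained(self, policy: str, r: float, t: float):
        key = (policy, round(r, 12), round(t, 12))
        if key not in self._store:
            split = cohort_split(self.cohort_beats, policy, t, seed=self.seed)
            params = MotifParams(r=r, k=self.kmax, normalize=self.normalize)
            networks, ops = train_networks(split, params)
            self._store[key] = (split, networks, ops)
        return self._store[key]


def _slice_network(network: LogicalNetwork, k: int) -> LogicalNetwork:
    """Keep the first ``k`` motifs per class (valid because discovery at a
    smaller k is a prefix of discovery at a larger one)."""
    nodes = [n for n in network.nodes if n.rank <= k]
    return LogicalNetwork(patient_id=network.patient_id, nodes=tuple(nodes),
                          r=network.r, normalize=network.normalize)


def run_cell(cohort_beats: Mapping[str, Sequence[Heartbeat]], policy: str,
             r: float, k: int, t: float, seed: int = 0,
             normalize: str = "znorm", _cache: _SweepCache | None = None,
             ) -> pd.DataFrame:
    """Train one policy at one (r, k, t) and score every patient's test set.

    Emits one row per patient plus an ``AVERAGE`` row whose accuracy is the
    unweighted mean over patients with a non-empty test set.
    """
    start = time.perf_counter()
    cache = _cache or _SweepCache(cohort_beats, kmax=k, normalize=normalize, seed=seed)
    split, networks, train_ops = cache.trained(policy, r, t)

    rows: list[dict] = []
    total_correct = total_test = 0
    for pid in sorted(split.per_patient_test):
        test_beats = split.per_patient_test[pid]
        network = networks.get(pid if policy == "pmm" else "pooled")
        if network is None:
            continue
        network_k = _slice_network(network, k)
        if not test_beats:
            warnings.warn(f"patient {pid} has no test beats; excluded from average",
                          stacklevel=2)
            rows.append(_row(policy, r, k, t, pid, [], [], 0,
                             train_ops.get(pid if policy == "pmm" else "pooled", 0), 0.0))
            continue
        with count_distance_ops() as test_counter:
            predictions = classify_batch(test_beats, network_k)
        predicted = [p.predicted for p in predictions]
        truths = [b.label for b in test_beats]
        rows.append(_row(policy, r, k, t, pid, predicted, truths,
                         sum(p == "ANOMALY" for p in predicted),
                         train_ops.get(pid if policy == "pmm" else "pooled", 0),
                         test_counter.pairs))
        total_correct += sum(p == y for p, y in zip(predicted, truths))
        total_test += len(truths)

    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    scored = df[df["n_test"] > 0]
    avg = {
        "policy": policy, "r": r, "k": k, "t": t, "patient_id": "AVERAGE",
        "n_test": int(df["n_test"].sum()),
        "n_correct": int(df["n_correct"].sum()),
        "n_anomaly": int(df["n_anomaly"].sum()),
        "accuracy": float(scored["accuracy"].mean()) if len(scored) else float("nan"),
        "accuracy_excl_anomaly": float(scored["accuracy_excl_anomaly"].mean())
        if len(scored) else float("nan"),
        "pooled_accuracy": total_correct / total_test if total_test else float("nan"),
        "train_ops": int(sum(train_ops.values())),
        "test_ops": int(df["test_ops"].sum()),
        "wall_time_s": time.perf_counter() - start,
    }
    return pd.concat([df, pd.DataFrame([avg])], ignore_index=True)


def _row(policy, r, k, t, pid, predicted, truths, n_anomaly, train_ops, test_ops) -> dict:
    n_test = len(truths)
    n_correct = sum(p == y for p, y in zip(predicted, truths))
    return {
        "policy": policy, "r": r, "k": k, "t": t, "patient_id": pid,
        "n_test": n_test, "n_correct": n_correct, "n_anomaly": n_anomaly,
        "accuracy": accuracy(predicted, truths) if n_test else float("nan"),
        "accuracy_excl_anomaly": accuracy(predicted, truths, anomaly_excluded=True)
        if n_test else float("nan"),
        "pooled_accuracy": float("nan"),
        "train_ops": train_ops, "test_ops": test_ops, "wall_time_s": float("nan"),
    }


def run_sweep(cohort_beats: Mapping[str, Sequence[Heartbeat]],
              grid: SweepGrid = SweepGrid()) -> pd.DataFrame:
    """Cross every grid cell for every policy; long-format results."""
    kmax = max(grid.k_values)
    frames: list[pd.DataFrame] = []
    for policy in grid.policies:
        cache = _SweepCache(cohort_beats, kmax=kmax, normalize=grid.normalize,
                            seed=grid.seed)
        for t in grid.t_values:
            for r in grid.r_values:
                for k in grid.k_values:
                    frames.append(run_cell(cohort_beats, policy, r, k, t,
                                           seed=grid.seed, normalize=grid.normalize,
                                           _cache=cache))
    return pd.concat(frames, ignore_index=True)


def plot_sweep(results: pd.DataFrame, out_dir: str) -> list[str]:
    """Line plots of AVERAGE accuracy vs R, K and T per policy, plus
    per-patient bar charts; returns the files written."""
    import os

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    os.makedirs(out_dir, exist_ok=True)
    written: list[str] = []
    avg = results[results["patient_id"] == "AVERAGE"]
    for param in ("r", "k", "t"):
        fig, ax = plt.subplots(figsize=(5, 3.2))
        for policy, sub in avg.groupby("policy"):
            curve = sub.groupby(param)["accuracy"].mean()
            ax.plot(curve.index, curve.values, marker="o", label=policy.upper())
        ax.set_xlabel(param.upper())
        ax.set_ylabel("average accuracy")
        ax.set_ylim(0, 1.05)
        ax.legend()
        fig.tight_layout()
        path = os.path.join(out_dir, f"accuracy_vs_{param}.png")
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

    per_patient = results[results["patient_id"] != "AVERAGE"]
    for policy, sub in per_patient.groupby("policy"):
        pivot = sub.pivot_table(index="patient_id", columns="t", values="accuracy",
                                aggfunc="mean")
        fig, ax = plt.subplots(figsize=(6, 3.2))
        pivot.plot.bar(ax=ax)
        ax.set_ylabel("accuracy")
        ax.set_ylim(0, 1.05)
        ax.set_title(policy.upper())
        ax.legend(title="T", fontsize=7)
        fig.tight_layout()
        path = os.path.join(out_dir, f"per_patient_{policy}.png")
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written
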