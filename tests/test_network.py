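import warnings

import numpy as np
import pytest

from ecgmotif import (Motif, MotifParams, add_node, build_network, classify,
                      classify_batch, discover_motifs, load_network,
                      save_network)
from ecgmotif.motifs import _preprocess

from conftest import make_beats


def motif_from(vector, label, rank, r=1.0):
    return Motif(center=np.asarray(vector, float), label=label, rank=rank,
                 member_count=1, member_indices=frozenset({0}), radius=r)


@pytest.fixture()
def six_node_network(rng):
    centers = rng.normal(size=(6, 40))
    n = [motif_from(centers[i], "N", i + 1) for i in range(3)]
    v = [motif_from(centers[i + 3], "V", i + 1) for i in range(3)]
    return build_network(n, v, r=1.2, normalize="none")


class TestBuild:
    def test_node_ordering_n_then_v_by_rank(self, rng):
        n = [motif_from(rng.normal(size=8), "N", r) for r in (2, 1)]
        v = [motif_from(rng.normal(size=8), "V", r) for r in (2, 1)]
        net = build_network(n, v, r=1.0)
        assert net.labels == ("N", "N", "V", "V")
        assert [m.rank for m in net.nodes] == [1, 2, 1, 2]

    def test_zero_motifs_rejected(self):
        with pytest.raises(ValueError, match="at least one node"):
            build_network([], [], r=1.0)

    def test_single_class_network_allowed(self, rng):
        net = build_network([motif_from(rng.normal(size=8), "N", 1)], [], r=1.0)
        assert net.labels == ("N",)


class TestClassify:
    def test_exact_center_match(self, six_node_network):
        node = six_node_network.nodes[0]
        pred = classify(node.center, six_node_network)
        assert pred.predicted == "N"
        assert pred.best_distance == 0
        assert pred.best_node_rank == 1

    def test_far_beat_is_anomaly(self, six_node_network, rng):
        pred = classify(rng.normal(size=40) + 100, six_node_network)
        assert pred.predicted == "ANOMALY"
        assert pred.best_distance >= six_node_network.r

    def test_matches_brute_force_argmin(self, six_node_network, rng):
        for _ in range(20):
            beat = rng.normal(size=40)
            pred = classify(beat, six_node_network)
            dists = [np.linalg.norm(beat - node.center)
                     for node in six_node_network.nodes]
            best = int(np.argmin(dists))
            assert pred.best_distance == pytest.approx(dists[best])
            expected = (six_node_network.nodes[best].label
                        if dists[best] < six_node_network.r else "ANOMALY")
            assert pred.predicted == expected

    def test_equal_distance_tie_goes_to_earlier_node(self):
        c = np.array([0.0, 1.0, 2.0, 3.0])
        net = build_network([motif_from(c + 1, "N", 1)], [motif_from(c - 1, "V", 1)],
                            r=10.0, normalize="none")
        pred = classify(c, net)  # equidistant from both nodes
        assert pred.predicted == "N"

    def test_constant_beat_flagged_not_crashed(self, rng):
        net = build_network([motif_from(rng.normal(size=8), "N", 1)], [], r=1.0,
                            normalize="znorm")
        pred = classify(np.full(8, 3.0), net)
        assert pred.predicted == "ANOMALY"
        assert pred.reason == "zero_variance"

    def test_length_mismatch_rejected(self, six_node_network):
        with pytest.raises(ValueError, match="length"):
            classify(np.zeros(39), six_node_network)


class TestClassifyBatch:
    def test_empty_input(self, six_node_network):
        assert classify_batch([], six_node_network) == []

    def test_equals_map_of_single_calls(self, six_node_network, rng):
        beats = make_beats(rng.normal(size=(12, 40)))
        batch = classify_batch(beats, six_node_network)
        assert [p.window_index for p in batch] == list(range(12))
        for beat, pred in zip(beats, batch):
            single = classify(beat.vector, six_node_network,
                              window_index=beat.window_index, true_label=beat.label)
            assert pred == single


class TestRadiusMonotonicity:
    def test_raising_r_only_unflags_anomalies(self, rng):
        centers = rng.normal(size=(4, 30))
        beats = make_beats(rng.normal(size=(50, 30)))
        preds = {}
        for r in (0.5, 1.0, 2.0, 8.0):
            net = build_network(
                [motif_from(centers[0], "N", 1), motif_from(centers[1], "N", 2)],
                [motif_from(centers[2], "V", 1), motif_from(centers[3], "V", 2)],
                r=r, normalize="none")
            preds[r] = classify_batch(beats, net)
        radii = sorted(preds)
        for lo, hi in zip(radii, radii[1:]):
            for a, b in zip(preds[lo], preds[hi]):
                assert a.best_distance == pytest.approx(b.best_distance)
                assert a.best_node_rank == b.best_node_rank  # arg-min unchanged
                if a.predicted != "ANOMALY":
                    assert b.predicted == a.predicted  # label never re-flagged


class TestAddNode:
    def test_appends_after_class(self, six_node_network, rng):
        new = motif_from(rng.normal(size=40), "N", 99)
        grown = add_node(six_node_network, new)
        assert len(grown.nodes) == 7
        assert grown.labels == ("N", "N", "N", "N", "V", "V", "V")
        assert grown.nodes[3].rank == 4  # renumbered within class
        # original untouched
        assert len(six_node_network.nodes) == 6

    def test_anomaly_reclassified_after_learning_new_motif(self, rng):
        base = rng.normal(size=20)
        net = build_network([motif_from(base, "N", 1)], [], r=1.0, normalize="none")
        odd_beat = base + 50
        assert classify(odd_beat, net).predicted == "ANOMALY"
        grown = add_node(net, motif_from(odd_beat, "V", 1))
        assert classify(odd_beat, grown).predicted == "V"

    def test_duplicate_node_changes_nothing(self, six_node_network, rng):
        beats = make_beats(rng.normal(size=(20, 40)))
        before = [p.predicted for p in classify_batch(beats, six_node_network)]
        dup = add_node(six_node_network, six_node_network.nodes[0])
        after = [p.predicted for p in classify_batch(beats, dup)]
        assert before == after

    def test_length_mismatch_rejected(self, six_node_network, rng):
        with pytest.raises(ValueError, match="length"):
            add_node(six_node_network, motif_from(rng.normal(size=13), "N", 1))


def test_network_round_trips_through_json(tmp_path, rng):
    beats = make_beats(rng.normal(size=(12, 20)), ["N"] * 8 + ["V"] * 4)
    params = MotifParams(r=1.2, k=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        n = discover_motifs([b for b in beats if b.label == "N"], params)
        v = discover_motifs([b for b in beats if b.label == "V"], params)
    net = build_network(n, v, r=params.r, patient_id="p7")
    path = str(tmp_path / "net.json")
    save_network(path, net)
    back = load_network(path)
    assert back.patient_id == "p7"
    assert back.labels == net.labels
    assert back.r == net.r
    test = make_beats(rng.normal(size=(10, 20)))
    got = [p.predicted for p in classify_batch(test, back)]
    want = [p.predicted for p in classify_batch(test, net)]
    assert got == want
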