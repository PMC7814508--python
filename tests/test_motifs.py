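import json
import math

import numpy as np
import pytest

from ecgmotif import MotifParams, discover_motifs, distance, pairwise_distances
from ecgmotif.motifs import load_motifs, save_motifs

from conftest import make_beats


def brute_distance(a, b, normalize):
    """Independent direct-sum oracle for the two distance modes."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if normalize == "znorm":
        a = (a - a.mean()) / a.std()
        b = (b - b.mean()) / b.std()
        scale = math.sqrt(len(a))
    else:
        scale = 1.0
    return math.sqrt(sum((x - y) ** 2 for x, y in zip(a, b))) / scale


class TestDistance:
    def test_identical_vectors_are_at_zero(self, rng):
        v = rng.normal(size=180)
        assert distance(v, v, "none") == 0
        assert distance(v, v, "znorm") == pytest.approx(0, abs=1e-12)

    def test_closed_form_unit_offset(self):
        a, b = np.zeros(180), np.ones(180)
        assert distance(a, b, "none") == pytest.approx(math.sqrt(180))

    @pytest.mark.parametrize("normalize", ["none", "znorm"])
    def test_matches_direct_sum_oracle(self, normalize, rng):
        for _ in range(10):
            a, b = rng.normal(size=(2, 60))
            assert distance(a, b, normalize) == pytest.approx(
                brute_distance(a, b, normalize), abs=1e-12)

    def test_symmetry_and_amplitude_invariance(self, rng):
        a, b = rng.normal(size=(2, 60))
        assert distance(a, b, "znorm") == pytest.approx(distance(b, a, "znorm"))
        # znorm mode ignores offset and scale
        assert distance(3 * a + 5, b, "znorm") == pytest.approx(
            distance(a, b, "znorm"), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            distance(np.zeros(10), np.zeros(11))

    def test_constant_vector_rejected_under_znorm(self):
        with pytest.raises(ValueError, match="zero-variance"):
            distance(np.zeros(10), np.ones(10), "znorm")


class TestPairwise:
    def test_single_beat_zero_matrix(self):
        beats = make_beats(np.random.default_rng(0).normal(size=(1, 20)))
        np.testing.assert_array_equal(pairwise_distances(beats, "none"), [[0.0]])

    def test_matches_looped_single_calls(self, rng):
        beats = make_beats(rng.normal(size=(10, 30)))
        D = pairwise_distances(beats, "znorm")
        assert D.shape == (10, 10)
        np.testing.assert_allclose(D, D.T)
        np.testing.assert_allclose(np.diag(D), 0, atol=1e-12)
        for i in range(10):
            for j in range(i + 1, 10):
                assert D[i, j] == pytest.approx(
                    distance(beats[i].vector, beats[j].vector, "znorm"), abs=1e-10)

    def test_mixed_lengths_rejected(self, rng):
        beats = make_beats(rng.normal(size=(2, 8)))
        beats += make_beats(rng.normal(size=(1, 9)))
        with pytest.raises(ValueError, match="mixed"):
            pairwise_distances(beats)


class TestDiscoverMotifs:
    def test_two_tight_clusters(self, rng):
        # clusters of 4 and 2 with diameter << r and separation >> 2r
        base = rng.normal(size=8)
        cluster1 = base + 0.01 * rng.normal(size=(4, 8))
        cluster2 = base + 10 + 0.01 * rng.normal(size=(2, 8))
        beats = make_beats(np.vstack([cluster1, cluster2]))
        motifs = discover_motifs(beats, MotifParams(r=1.0, k=2, normalize="none"))
        assert [m.member_count for m in motifs] == [4, 2]
        assert motifs[0].member_indices == frozenset({0, 1, 2, 3})
        assert motifs[1].member_indices == frozenset({4, 5})

    def test_single_beat_warns_and_returns_one_motif(self, rng):
        beats = make_beats(rng.normal(size=(1, 8)))
        with pytest.warns(UserWarning, match="motifs discoverable"):
            motifs = discover_motifs(beats, MotifParams(r=0.5, k=5, normalize="none"))
        assert len(motifs) == 1
        assert motifs[0].member_count == 1

    def test_structural_invariants_on_random_instances(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 20))
            beats = make_beats(rng.normal(size=(n, 6)))
            r = float(rng.uniform(0.5, 4.0))
            k = int(rng.integers(1, 6))
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                motifs = discover_motifs(beats, MotifParams(r=r, k=k, normalize="none"))
            D = pairwise_distances(beats, "none")
            seen = set()
            counts = []
            for m in motifs:
                assert not (m.member_indices & seen), "circles share a subsequence"
                seen |= m.member_indices
                counts.append(m.member_count)
                center_idx = next(i for i in m.member_indices
                                  if beats[i].window_index == m.center_window_index)
                for j in m.member_indices - {center_idx}:
                    assert D[center_idx, j] < r
            assert counts == sorted(counts, reverse=True)

    def test_deterministic_and_prefix_consistent_in_k(self, rng):
        beats = make_beats(rng.normal(size=(15, 6)))
        params10 = MotifParams(r=2.5, k=10, normalize="none")
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = discover_motifs(beats, params10)
            b = discover_motifs(beats, params10)
            small = discover_motifs(beats, MotifParams(r=2.5, k=2, normalize="none"))
        assert [m.member_indices for m in a] == [m.member_indices for m in b]
        assert [m.member_indices for m in small] == [m.member_indices for m in a[:2]]

    def test_serialization_round_trip(self, tmp_path, rng):
        beats = make_beats(rng.normal(size=(6, 8)))
        params = MotifParams(r=3.0, k=2, normalize="none")
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            motifs = discover_motifs(beats, params)
        path = str(tmp_path / "motifs.json")
        save_motifs(path, "p", motifs, params)
        pid, back, back_params = load_motifs(path)
        assert pid == "p"
        assert back_params == params
        assert [m.rank for m in back] == [m.rank for m in motifs]
        np.testing.assert_allclose(back[0].center, motifs[0].center, atol=1e-9)
        # serialized form is stable across writes
        save_motifs(str(tmp_path / "motifs2.json"), "p", motifs, params)
        assert (tmp_path / "motifs.json").read_text() == (tmp_path / "motifs2.json").read_text()


def test_params_validation():
    with pytest.raises(ValueError):
        MotifParams(r=-0.1, k=2)
    with pytest.raises(ValueError):
        MotifParams(r=1.0, k=0)
    with pytest.raises(ValueError):
        MotifParams(r=1.0, k=2, normalize="l2")
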