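"""Unit and property tests for the prototype-network emulator."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from olivesort.rce import (
    CapacityError,
    NetworkProfile,
    RceNetwork,
    VectorLengthError,
    distance,
    load_model,
    save_model,
)
from conftest import make_random_network


def brute_force_rbf(net, v):
    """Exhaustive-scan oracle for RBF winner-takes-all recognition."""
    firing = []
    for n in net.neurons:
        d = int(np.abs(n.prototype.astype(int) - np.asarray(v)).sum())
        if d < n.aif:
            firing.append((d, n.commit_index, n.category))
    if not firing:
        return ("unknown", None, None)
    firing.sort()
    cats = {c for _, _, c in firing}
    status = "identified" if len(cats) == 1 else "uncertain"
    return (status, firing[0][2], firing[0][0])


def brute_force_knn(net, v, k):
    """Sort-all oracle for KNN ranking."""
    ds = [
        (int(np.abs(n.prototype.astype(int) - np.asarray(v)).sum()),
         n.commit_index, n.category)
        for n in net.neurons
    ]
    ds.sort()
    return [(c, d) for d, _, c in ds[:k]]


class TestDistance:
    def test_identity_is_zero(self):
        assert distance([0, 0, 0, 0], [0, 0, 0, 0]) == 0
        assert distance([7, 200], [7, 200]) == 0

    def test_maximal_two_component(self):
        assert distance([255, 0], [0, 255]) == 510

    def test_matches_componentwise_loop(self, rng):
        for _ in range(50):
            a = rng.integers(0, 256, size=256)
            b = rng.integers(0, 256, size=256)
            expected = sum(abs(int(x) - int(y)) for x, y in zip(a, b))
            assert distance(a, b) == expected
            assert distance(b, a) == expected

    def test_length_mismatch_raises(self):
        with pytest.raises(VectorLengthError):
            distance([1, 2], [1, 2, 3])


class TestProfiles:
    def test_builtin_capacities(self):
        cm1k = NetworkProfile.builtin("cm1k")
        assert (cm1k.vector_len, cm1k.max_neurons) == (256, 1024)
        curie = NetworkProfile.builtin("curie")
        assert (curie.vector_len, curie.max_neurons) == (128, 128)

    def test_invalid_profiles_rejected(self):
        with pytest.raises(ValueError):
            NetworkProfile("x", vector_len=0, max_neurons=1)
        with pytest.raises(ValueError):
            NetworkProfile("x", vector_len=1, max_neurons=1, min_if=5, max_if=4)
        with pytest.raises(KeyError):
            NetworkProfile.builtin("cm2k")


class TestLearn:
    def test_first_commit_gets_max_if(self, tiny_profile):
        net = RceNetwork(tiny_profile)
        assert net.learn([1] * 8, "a") is True
        assert len(net) == 1
        assert net.neurons[0].aif == tiny_profile.max_if

    def test_representation_commits_nothing(self, tiny_profile):
        net = RceNetwork(tiny_profile)
        v = [9, 0, 0, 0, 0, 0, 0, 9]
        assert net.learn(v, "a") is True
        assert net.learn(v, "a") is False
        assert len(net) == 1

    def test_wrong_fire_shrinks_aif(self):
        p = NetworkProfile("t", vector_len=2, max_neurons=8, min_if=2, max_if=100)
        net = RceNetwork(p)
        net.learn([0, 0], "a")
        net.learn([10, 10], "b")  # distance 20 < aif 100: "a" neuron shrinks
        assert net.neurons[0].aif == 20
        # the new "b" neuron's field reaches exactly to the "a" prototype
        assert net.neurons[1].aif == 20

    def test_aif_floor_at_min_if(self):
        p = NetworkProfile("t", vector_len=2, max_neurons=8, min_if=5, max_if=100)
        net = RceNetwork(p)
        net.learn([0, 0], "a")
        net.learn([1, 0], "b")  # distance 1 < min_if: both clamp to the floor
        assert net.neurons[0].aif == 5
        assert net.neurons[1].aif == 5

    def test_capacity_error_leaves_model_unchanged(self, tiny_profile):
        net = RceNetwork(tiny_profile)
        for i in range(tiny_profile.max_neurons):
            net.learn([i * 30] * 8, f"c{i}")
        snapshot = [(n.category, n.aif) for n in net.neurons]
        with pytest.raises(CapacityError):
            net.learn([250] * 8, "overflow")
        assert [(n.category, n.aif) for n in net.neurons] == snapshot

    def test_cm1k_capacity_is_1024(self, rng):
        """Distant patterns fill the chip; pattern 1025 must be refused."""
        net = RceNetwork(NetworkProfile.builtin("cm1k"))
        vectors = rng.integers(0, 256, size=(1025, 256))
        for i in range(1024):
            net.learn(vectors[i], f"c{i % 7}")
        assert len(net) == 1024
        with pytest.raises(CapacityError):
            net.learn(vectors[1024], "c0")

    def test_learned_example_immediately_recognized(self, tiny_profile):
        net = RceNetwork(tiny_profile)
        net.learn([5] * 8, "a")
        rec = net.classify_rbf([5] * 8)
        assert (rec.status, rec.category, rec.distance) == ("identified", "a", 0)


class TestClassifyRbf:
    def test_empty_network_is_unknown(self, tiny_profile):
        rec = RceNetwork(tiny_profile).classify_rbf([0] * 8)
        assert rec.status == "unknown"
        assert rec.category is None
        assert rec.firing == ()

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(50):
            net = make_random_network(rng, int(rng.integers(1, 33)), 16)
            v = rng.integers(0, 256, size=16)
            rec = net.classify_rbf(v)
            status, cat, dist = brute_force_rbf(net, v)
            assert rec.status == status
            if status != "unknown":
                assert (rec.category, rec.distance) == (cat, dist)
                # reported distance is the minimum over firing neurons
                assert rec.distance == min(d for _, _, d in rec.firing)

    def test_winner_tie_breaks_on_commit_order(self):
        p = NetworkProfile("t", vector_len=2, max_neurons=4, max_if=50)
        net = RceNetwork(p)
        net.learn([0, 10], "a")
        net.learn([10, 0], "b")
        rec = net.classify_rbf([5, 5])  # both at distance 10
        assert rec.category == "a"
        assert rec.status == "uncertain"


class TestClassifyKnn:
    def test_single_neuron_k1(self, tiny_profile):
        net = RceNetwork(tiny_profile)
        net.learn([3] * 8, "a")
        res = net.classify_knn([100] * 8, 1)
        assert res.category == "a"
        assert not res.truncated

    def test_learned_vector_at_distance_zero(self, tiny_profile):
        net = RceNetwork(tiny_profile)
        net.learn([4] * 8, "z")
        assert net.classify_knn([4] * 8, 1).neighbors == (("z", 0),)

    def test_matches_sort_all_oracle(self, rng):
        for _ in range(50):
            net = make_random_network(rng, int(rng.integers(2, 33)), 16)
            v = rng.integers(0, 256, size=16)
            k = int(rng.integers(1, len(net) + 1))
            assert list(net.classify_knn(v, k).neighbors) == brute_force_knn(net, v, k)

    def test_k_beyond_count_truncates_and_flags(self, tiny_profile):
        net = RceNetwork(tiny_profile)
        net.learn([0] * 8, "a")
        res = net.classify_knn([0] * 8, 5)
        assert res.truncated
        assert len(res.neighbors) == 1

    def test_ignores_influence_fields(self, rng):
        net = make_random_network(rng, 8, 16, min_if=2, max_if=3)
        v = rng.integers(0, 256, size=16)
        assert net.classify_rbf(v).status == "unknown"  # tiny fields: none fire
        assert len(net.classify_knn(v, 3).neighbors) == 3


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.lists(
    st.tuples(st.lists(st.integers(0, 255), min_size=6, max_size=6),
              st.sampled_from(["a", "b", "c"])),
    min_size=1, max_size=30,
))
def test_aif_monotone_and_learn_consistency(seq):
    """AIFs never grow after commitment; no trained example is ever
    identified with a wrong category afterwards."""
    p = NetworkProfile("t", vector_len=6, max_neurons=64, min_if=2, max_if=600)
    net = RceNetwork(p)
    history: dict[int, int] = {}
    for v, c in seq:
        net.learn(v, c)
        for n in net.neurons:
            assert p.min_if <= n.aif <= p.max_if
            if n.commit_index in history:
                assert n.aif <= history[n.commit_index]
            history[n.commit_index] = n.aif
    assert len(net) <= p.max_neurons
    # consistency is guaranteed once training stabilizes
    net.fit([v for v, _ in seq], [c for _, c in seq])
    for v, c in seq:
        rec = net.classify_rbf(v)
        assert not (rec.status == "identified" and rec.category != c)


def test_training_is_deterministic(tmp_path, rng):
    vecs = rng.integers(0, 256, size=(40, 8))
    cats = [f"c{i % 3}" for i in range(40)]
    p = NetworkProfile("t", vector_len=8, max_neurons=64, max_if=800)
    nets = []
    for _ in range(2):
        net = RceNetwork(p)
        net.fit(vecs, cats)
        nets.append(net)
    f1, f2 = tmp_path / "a.json", tmp_path / "b.json"
    save_model(nets[0], f1)
    save_model(nets[1], f2)
    assert f1.read_bytes() == f2.read_bytes()


class TestPersistence:
    def test_empty_round_trip(self, tiny_profile, tmp_path):
        path = tmp_path / "m.json"
        save_model(RceNetwork(tiny_profile), path)
        assert len(load_model(path)) == 0

    def test_round_trip_classifies_identically(self, rng, tmp_path):
        net = make_random_network(rng, 4, 16)
        path = tmp_path / "m.json"
        save_model(net, path)
        loaded = load_model(path)
        for _ in range(25):
            v = rng.integers(0, 256, size=16)
            a, b = net.classify_rbf(v), loaded.classify_rbf(v)
            assert (a.status, a.category, a.distance) == (b.status, b.category, b.distance)

    def test_serialize_twice_is_byte_identical(self, rng, tmp_path):
        net = make_random_network(rng, 6, 8)
        p1, p2 = tmp_path / "1.json", tmp_path / "2.json"
        save_model(net, p1)
        save_model(load_model(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_malformed_file_names_field(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"format": "olivesort-rce-model", "profile": {"name": "x"}}')
        with pytest.raises(Exception, match="vector_len"):
            load_model(path)
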