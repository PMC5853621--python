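"""Modularity, Louvain detection, fractional modularity, z-Rand, consensus."""

import numpy as np
import pytest

from netreconf.modularity import (
    Partition,
    allegiance_matrix,
    fractional_modularity,
    louvain_best,
    modularity_value,
    rand_z_score,
    representative_partition,
)

from conftest import (
    partitions_match,
    planted_partition_graph,
    random_binary_adjacency,
)


def brute_force_q(adj, labels, gamma=1.0):
    """Independent double-loop evaluation of the modularity sum."""
    adj = np.asarray(adj, dtype=float)
    n = adj.shape[0]
    w = adj.sum(axis=1)
    two_w = w.sum()
    q = 0.0
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += adj[i, j] - gamma * w[i] * w[j] / two_w
    return q / two_w


def two_cliques(k=5):
    a = np.zeros((2 * k, 2 * k), dtype=int)
    a[:k, :k] = 1
    a[k:, k:] = 1
    np.fill_diagonal(a, 0)
    labels = np.array([0] * k + [1] * k)
    return a, labels


class TestModularityValue:
    def test_single_community_zero(self):
        rng = np.random.default_rng(0)
        a = random_binary_adjacency(12, 0.4, rng)
        assert modularity_value(a, np.zeros(12, dtype=int)) == pytest.approx(0.0)

    def test_two_disconnected_cliques(self):
        a, labels = two_cliques()
        assert modularity_value(a, labels) == pytest.approx(0.5)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = rng.integers(5, 31)
            a = random_binary_adjacency(n, rng.uniform(0.1, 0.6), rng)
            if a.sum() == 0:
                continue
            labels = rng.integers(0, 4, n)
            gamma = rng.uniform(0.5, 2.0)
            assert modularity_value(a, labels, gamma) == pytest.approx(
                brute_force_q(a, labels, gamma), abs=1e-12
            )

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(2)
        a = random_binary_adjacency(15, 0.3, rng)
        labels = rng.integers(0, 3, 15)
        assert modularity_value(a, labels) == pytest.approx(
            modularity_value(a, (labels + 1) % 3)
        )

    def test_edgeless_graph_rejected(self):
        with pytest.raises(ValueError):
            modularity_value(np.zeros((4, 4)), np.zeros(4, dtype=int))


class TestLouvainBest:
    def test_recovers_disconnected_cliques(self):
        a, labels = two_cliques()
        part = louvain_best(a, restarts=10, seed=0)
        assert part.q == pytest.approx(0.5)
        assert partitions_match(part.labels, labels)

    def test_complete_graph_single_community(self):
        a = 1 - np.eye(10, dtype=int)
        part = louvain_best(a, restarts=10, seed=0)
        assert part.n_communities == 1
        assert part.q == pytest.approx(0.0)

    def test_q_self_consistent(self):
        rng = np.random.default_rng(3)
        a = random_binary_adjacency(25, 0.25, rng)
        part = louvain_best(a, restarts=5, seed=1)
        assert part.q == pytest.approx(modularity_value(a, part.labels))

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        a = random_binary_adjacency(30, 0.2, rng)
        p1 = louvain_best(a, restarts=5, seed=9)
        p2 = louvain_best(a, restarts=5, seed=9)
        assert np.array_equal(p1.labels, p2.labels) and p1.q == p2.q

    def test_more_restarts_never_worse(self):
        rng = np.random.default_rng(5)
        a, _ = planted_partition_graph(4, 10, 0.6, 0.15, rng)
        q1 = louvain_best(a, restarts=1, seed=3).q
        q20 = louvain_best(a, restarts=20, seed=3).q
        assert q20 >= q1 - 1e-12

    def test_gamma_sweep_sanity(self):
        rng = np.random.default_rng(6)
        a, _ = planted_partition_graph(4, 15, 0.8, 0.05, rng)
        n_low = louvain_best(a, gamma=0.01, restarts=5, seed=0).n_communities
        n_mid = louvain_best(a, gamma=1.0, restarts=5, seed=0).n_communities
        n_high = louvain_best(a, gamma=3.0, restarts=5, seed=0).n_communities
        assert n_low == 1
        assert n_low <= n_mid <= n_high

    def test_edgeless_rejected(self):
        with pytest.raises(ValueError):
            louvain_best(np.zeros((5, 5)), seed=0)


class TestFractionalModularity:
    def test_full_mask_equals_q(self):
        rng = np.random.default_rng(7)
        a = random_binary_adjacency(15, 0.3, rng)
        labels = rng.integers(0, 3, 15)
        mask = np.ones(15, dtype=bool)
        assert fractional_modularity(a, labels, mask, "both", "none") == (
            pytest.approx(modularity_value(a, labels))
        )

    def test_one_clique_half_of_q(self):
        a, labels = two_cliques()
        mask = labels == 0
        assert fractional_modularity(a, labels, mask, "both", "none") == (
            pytest.approx(0.25)
        )

    def test_conservation_decomposition(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            n = rng.integers(6, 30)
            a = random_binary_adjacency(n, 0.3, rng)
            if a.sum() == 0:
                continue
            labels = rng.integers(0, 3, n)
            mask = rng.random(n) < 0.4
            if not mask.any() or mask.all():
                continue
            total = fractional_modularity(
                a, labels, mask, "at_least_one", "none"
            ) + fractional_modularity(a, labels, ~mask, "both", "none")
            assert total == pytest.approx(modularity_value(a, labels), abs=1e-12)

    def test_normalizations(self):
        a, labels = two_cliques()
        mask = labels == 0
        raw = fractional_modularity(a, labels, mask, "both", "none")
        per_pair = fractional_modularity(a, labels, mask, "both", "pair_count")
        per_size = fractional_modularity(a, labels, mask, "both", "region_size")
        assert per_pair == pytest.approx(raw / 10)  # C(5, 2)
        assert per_size == pytest.approx(raw / 5)

    def test_empty_mask_rejected(self):
        a, labels = two_cliques()
        with pytest.raises(ValueError):
            fractional_modularity(a, labels, np.zeros(10, dtype=bool))


class TestRandZScore:
    def test_identical_nontrivial_partitions_positive(self):
        labels = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2, 2])
        assert rand_z_score(labels, labels).z_rand > 0

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(9)
        l1 = rng.integers(0, 4, 50)
        l2 = rng.integers(0, 4, 50)
        z_a = rand_z_score(l1, l2).z_rand
        z_b = rand_z_score(l1, (l2 + 1) % 4).z_rand
        assert z_a == pytest.approx(z_b)

    def test_null_calibration(self):
        # independent uniform partitions: z ~ mean 0, sd 1 (exact variance)
        rng = np.random.default_rng(10)
        zs = np.array([
            rand_z_score(rng.integers(0, 4, 100), rng.integers(0, 4, 100)).z_rand
            for _ in range(600)
        ])
        assert abs(zs.mean()) < 0.15
        assert 0.85 < zs.std() < 1.15

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            rand_z_score(np.array([0, 1, 0]), np.array([0, 0, 1]))

    def test_partition_objects_accepted(self):
        labels = np.array([0, 0, 1, 1, 2, 2])
        p = Partition(labels=labels, q=0.0)
        assert rand_z_score(p, p).z_rand > 0


class TestRepresentativePartition:
    def test_identical_partitions_returned_exactly(self):
        labels = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2])
        parts = [labels.copy() for _ in range(5)]
        rep = representative_partition(parts, seed=0, n_null=50, restarts=5)
        assert np.array_equal(rep.labels, labels)

    def test_allegiance_of_identical_partitions_binary(self):
        labels = np.array([0, 0, 1, 1])
        alleg = allegiance_matrix([labels, labels, labels])
        assert set(np.unique(alleg)) <= {0.0, 1.0}

    def test_recovers_majority_partition(self):
        rng = np.random.default_rng(11)
        planted = np.repeat(np.arange(4), 15)
        parts = [planted.copy() for _ in range(16)]
        parts += [rng.integers(0, 4, 60) for _ in range(4)]
        rep = representative_partition(
            parts, seed=1, n_null=200, restarts=20
        )
        assert partitions_match(rep.labels, planted)

    def test_needs_two_partitions(self):
        with pytest.raises(ValueError):
            representative_partition([np.array([0, 1])], seed=0)
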