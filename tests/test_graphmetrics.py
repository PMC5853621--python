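"""Efficiency, interaction strength, participation coefficient, flexibility."""

import numpy as np
import pytest

import netreconf as nr
from netreconf.graphmetrics import (
    areal_efficiency,
    flexibility,
    global_efficiency,
    interaction_strength,
    participation_coefficient,
    shortest_path_lengths,
    subnetwork_flexibility,
)

from conftest import random_binary_adjacency


def floyd_warshall_oracle(adj):
    """Independent brute-force all-pairs shortest paths."""
    n = adj.shape[0]
    d = np.where(adj > 0, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        d = np.minimum(d, d[:, k : k + 1] + d[k : k + 1, :])
    return d


def efficiency_oracle(adj):
    d = floyd_warshall_oracle(adj)
    n = adj.shape[0]
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    np.fill_diagonal(inv, 0.0)
    inv[np.isinf(d)] = 0.0
    return inv.sum() / (n * (n - 1))


def path_graph(n):
    a = np.zeros((n, n), dtype=int)
    for i in range(n - 1):
        a[i, i + 1] = a[i + 1, i] = 1
    return a


class TestShortestPaths:
    def test_complete_graph(self):
        a = 1 - np.eye(4, dtype=int)
        d = shortest_path_lengths(a)
        assert (d[~np.eye(4, dtype=bool)] == 1).all()

    def test_path_graph(self):
        d = shortest_path_lengths(path_graph(3))
        assert d[0, 2] == 2

    def test_matches_floyd_warshall_on_random_graphs(self):
        rng = np.random.default_rng(10)
        for _ in range(25):
            n = rng.integers(5, 51)
            a = random_binary_adjacency(n, rng.uniform(0.05, 0.5), rng)
            assert np.array_equal(
                shortest_path_lengths(a), floyd_warshall_oracle(a)
            )


class TestGlobalEfficiency:
    def test_complete_graph_is_one(self):
        assert global_efficiency(1 - np.eye(6, dtype=int)) == pytest.approx(1.0)

    def test_three_node_path(self):
        assert global_efficiency(path_graph(3)) == pytest.approx(5 / 6)

    def test_isolated_node_contributes_zero(self):
        a = np.zeros((3, 3), dtype=int)
        a[0, 1] = a[1, 0] = 1
        assert global_efficiency(a) == pytest.approx(1 / 3)

    def test_matches_oracle_on_random_graphs(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            n = rng.integers(4, 51)
            a = random_binary_adjacency(n, rng.uniform(0.05, 0.6), rng)
            assert global_efficiency(a) == pytest.approx(efficiency_oracle(a))

    def test_adding_edge_never_decreases(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            a = random_binary_adjacency(15, 0.2, rng)
            empty = np.argwhere(np.triu(a == 0, 1))
            i, j = empty[rng.integers(len(empty))]
            before = global_efficiency(a)
            a[i, j] = a[j, i] = 1
            assert global_efficiency(a) >= before - 1e-12


class TestArealEfficiency:
    def test_full_mask_equals_global(self):
        rng = np.random.default_rng(13)
        a = random_binary_adjacency(12, 0.3, rng)
        mask = np.ones(12, dtype=bool)
        assert areal_efficiency(a, mask) == pytest.approx(global_efficiency(a))

    def test_two_adjacent_nodes(self):
        a = path_graph(3)
        mask = np.array([True, True, False])
        assert areal_efficiency(a, mask) == pytest.approx(1.0)

    def test_paths_cannot_leave_region(self):
        # endpoints of a 3-path joined only through the excluded middle node
        a = path_graph(3)
        mask = np.array([True, False, True])
        assert areal_efficiency(a, mask) == 0.0

    def test_single_node_region_rejected(self):
        with pytest.raises(ValueError):
            areal_efficiency(path_graph(3), np.array([True, False, False]))


class TestInteractionStrength:
    def test_complete_graph_is_one(self):
        a = 1 - np.eye(6, dtype=int)
        act = np.array([True, True, False, False, False, False])
        assert interaction_strength(a, act, ~act) == pytest.approx(1.0)

    def test_no_cross_edges_is_zero(self):
        a = np.zeros((4, 4), dtype=int)
        a[0, 1] = a[1, 0] = 1
        a[2, 3] = a[3, 2] = 1
        act = np.array([True, True, False, False])
        assert interaction_strength(a, act, ~act) == 0.0

    def test_half_of_cross_pairs(self):
        a = np.zeros((4, 4), dtype=int)
        a[0, 2] = a[2, 0] = 1
        a[1, 3] = a[3, 1] = 1
        act = np.array([True, True, False, False])
        assert interaction_strength(a, act, ~act) == pytest.approx(0.5)

    def test_invariant_to_intra_region_edges(self):
        rng = np.random.default_rng(14)
        a = random_binary_adjacency(10, 0.4, rng)
        act = np.zeros(10, dtype=bool)
        act[:4] = True
        before = interaction_strength(a, act, ~act)
        b = a.copy()
        b[np.ix_(act, act)] = 0  # wipe all intra-Act edges
        assert interaction_strength(b, act, ~act) == pytest.approx(before)

    def test_overlapping_masks_rejected(self):
        a = 1 - np.eye(4, dtype=int)
        m = np.array([True, True, False, False])
        with pytest.raises(ValueError):
            interaction_strength(a, m, m)


class TestParticipationCoefficient:
    def test_all_edges_within_own_module(self):
        a = np.zeros((4, 4), dtype=int)
        a[0, 1] = a[1, 0] = 1
        labels = np.array([0, 0, 1, 1])
        pc = participation_coefficient(a, labels)
        assert pc[0] == 0.0

    def test_even_split_over_two_modules(self):
        # degree-4 node with 2 edges into each of 2 subnetworks
        a = np.zeros((5, 5), dtype=int)
        for j in range(1, 5):
            a[0, j] = a[j, 0] = 1
        labels = np.array([0, 0, 0, 1, 1])
        pc = participation_coefficient(a, labels)
        assert pc[0] == pytest.approx(0.5)

    def test_isolated_node_zero(self):
        a = np.zeros((3, 3), dtype=int)
        a[0, 1] = a[1, 0] = 1
        pc = participation_coefficient(a, np.array([0, 1, 1]))
        assert pc[2] == 0.0

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(15)
        a = random_binary_adjacency(20, 0.3, rng)
        labels = rng.integers(0, 4, 20)
        relabeled = (labels + 2) % 4
        assert np.allclose(
            participation_coefficient(a, labels),
            participation_coefficient(a, relabeled),
        )

    def test_bounds(self):
        rng = np.random.default_rng(16)
        a = random_binary_adjacency(30, 0.3, rng)
        pc = participation_coefficient(a, rng.integers(0, 5, 30))
        assert (pc >= 0).all() and (pc < 1).all()


class TestFlexibility:
    def test_identical_states_zero(self):
        pc = np.random.default_rng(17).random(10)
        assert not flexibility(pc, pc).any()

    def test_difference(self):
        assert flexibility(np.array([0.6]), np.array([0.2]))[0] == pytest.approx(0.4)

    def test_subnetwork_means_match_groupby(self):
        rng = np.random.default_rng(18)
        parc = nr.gen_parcellation(30, 3, seed=1)
        flex = rng.normal(size=30)
        means = subnetwork_flexibility(flex, parc)
        for lab, val in means.items():
            assert val == pytest.approx(flex[parc.subnetwork == lab].mean())

    def test_excluded_subnetworks_omitted(self):
        parc = nr.gen_parcellation(30, 3, seed=1, n_excluded=1)
        means = subnetwork_flexibility(np.zeros(30), parc)
        assert len(means) == 2
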