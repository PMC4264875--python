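"""Hub scoring, co-occurrence, community co-assignment, scaled inclusivity
and rewiring null networks."""

import itertools
import math

import numpy as np
import pytest

import _oracles
from conftest import random_binary_adjacency
from netrep import netbuild, synth
from netrep.hubs_comm import (
    CoAssignmentMatrix,
    coassignment_from_partition,
    consensus_coassignment,
    detect_communities,
    hub_cooccurrence,
    hub_score,
    null_ensemble,
    null_pvalue,
    probabilistic_si,
    scaled_inclusivity,
    scaled_inclusivity_all,
)
from netrep.measures import node_measures
from netrep.netbuild import BinaryNetwork, WeightedNetwork


def _binary(adj):
    n = adj.shape[0]
    return BinaryNetwork(adjacency=adj.astype(float),
                         density=adj.sum() / 2 / (n * (n - 1) / 2))


class TestHubScore:
    def test_star_center_is_hub(self):
        adj = np.zeros((6, 6))
        adj[0, 1:] = adj[1:, 0] = 1.0
        result = hub_score(node_measures(_binary(adj)))
        center = result.flags.iloc[0]
        assert center["high_degree"] and center["high_betweenness"]
        assert center["low_path_length"]
        assert center["hub_score"] >= 3
        assert 0 in result.hubs

    def test_ring_lattice_all_tie_all_hubs(self):
        # every node identical on every criterion: boundary ties flag everyone
        n = 8
        adj = np.zeros((n, n))
        for i in range(n):
            adj[i, (i + 1) % n] = adj[(i + 1) % n, i] = 1.0
            adj[i, (i + 2) % n] = adj[(i + 2) % n, i] = 1.0
        result = hub_score(node_measures(_binary(adj)))
        assert result.hubs == frozenset(range(n))

    def test_flags_match_exhaustive_sort_oracle(self):
        rng = np.random.default_rng(42)
        adj = random_binary_adjacency(rng, 20, 0.3)
        nm = node_measures(_binary(adj))
        result = hub_score(nm)
        table = nm.table[nm.table["included"]]
        n_flag = math.ceil(0.2 * len(table))
        for column, measure, largest in [
            ("high_degree", "degree", True),
            ("high_betweenness", "betweenness", True),
            ("low_path_length", "path_length", False),
        ]:
            vals = sorted(table[measure], reverse=largest)
            cutoff = vals[n_flag - 1]
            expected = {
                int(i) for i, row in table.iterrows()
                if (row[measure] >= cutoff if largest else row[measure] <= cutoff)
            }
            got = {int(i) for i in result.flags.index[result.flags[column] == 1]}
            assert got == expected, column

    def test_clustering_criterion_restricted_to_degree_two(self):
        # node 4 dangles with degree 1: clustering undefined there, never flagged
        adj = np.zeros((6, 6))
        for i, j in [(0, 1), (1, 2), (2, 0), (0, 3), (1, 3), (3, 4), (2, 5), (0, 5)]:
            adj[i, j] = adj[j, i] = 1.0
        result = hub_score(node_measures(_binary(adj)))
        assert result.flags.loc[4, "low_clustering"] == 0

    def test_too_few_nodes_rejected(self):
        adj = np.ones((4, 4)) - np.eye(4)
        with pytest.raises(ValueError, match="5 included"):
            hub_score(node_measures(_binary(adj)))


class TestHubCooccurrence:
    def test_perfect_agreement_is_one(self):
        assert hub_cooccurrence({1, 2, 3}, {1, 2, 3}) == 1.0

    def test_disjoint_sets_are_zero(self):
        assert hub_cooccurrence({1, 2}, {3, 4}) == 0.0

    def test_dice_example(self):
        assert hub_cooccurrence({1, 2, 3}, {2, 3, 4}) == pytest.approx(2 * 2 / 6)

    def test_both_empty_defined_as_one(self):
        assert hub_cooccurrence(set(), set()) == 1.0

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a = set(rng.choice(10, rng.integers(0, 6), replace=False).tolist())
            b = set(rng.choice(10, rng.integers(0, 6), replace=False).tolist())
            assert hub_cooccurrence(a, b) == hub_cooccurrence(b, a)

    def test_jaccard_option(self):
        assert hub_cooccurrence({1, 2, 3}, {2, 3, 4}, method="jaccard") == pytest.approx(2 / 4)


def _modularity(adj: np.ndarray, labels: np.ndarray) -> float:
    # direct Newman modularity, written out for the exhaustive oracle
    m2 = adj.sum()
    k = adj.sum(axis=1)
    q = 0.0
    n = adj.shape[0]
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += adj[i, j] - k[i] * k[j] / m2
    return q / m2


class TestDetectCommunities:
    def test_two_cliques_split_cleanly(self):
        adj = np.zeros((6, 6))
        for block in ([0, 1, 2], [3, 4, 5]):
            for i, j in itertools.combinations(block, 2):
                adj[i, j] = adj[j, i] = 1.0
        # oracle: exhaustive partition search confirms the two-clique split is
        # the unique modularity optimum
        best_q, best_partition = -np.inf, None
        for partition in _oracles.set_partitions(list(range(6))):
            labels = np.zeros(6, dtype=int)
            for c, block in enumerate(partition):
                for node in block:
                    labels[node] = c
            q = _modularity(adj, labels)
            if q > best_q:
                best_q, best_partition = q, partition
        assert sorted(map(sorted, best_partition)) == [[0, 1, 2], [3, 4, 5]]

        coassign = detect_communities(_binary(adj), 20, seed=0)
        expected = coassignment_from_partition(np.array([0, 0, 0, 1, 1, 1]))
        assert np.array_equal(coassign.prob, expected)

    def test_single_clique_all_ones(self):
        adj = np.ones((5, 5)) - np.eye(5)
        coassign = detect_communities(_binary(adj), 5, seed=1)
        assert np.array_equal(coassign.prob, np.ones((5, 5)))

    def test_diagonal_always_one(self):
        rng = np.random.default_rng(2)
        adj = random_binary_adjacency(rng, 10, 0.4)
        coassign = detect_communities(_binary(adj), 7, seed=3)
        assert np.array_equal(np.diag(coassign.prob), np.ones(10))

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            detect_communities(_binary(np.zeros((4, 4))), 5, seed=0)


class TestScaledInclusivity:
    def test_identical_modules_give_one(self):
        part = {0: 0, 1: 0, 2: 1, 3: 1}
        assert scaled_inclusivity(part, dict(part), 0) == 1.0

    def test_partial_overlap(self):
        part_a = {1: 0, 2: 0, 3: 1}
        part_b = {1: 0, 2: 0, 3: 0}
        # C_a = {1,2}, C_b = {1,2,3}: 2^2/(2*3)
        assert scaled_inclusivity(part_a, part_b, 1) == pytest.approx(4 / 6)

    def test_disjoint_except_node(self):
        part_a = {0: 0, 1: 0, 2: 0, 3: 1, 4: 1}
        part_b = {0: 0, 1: 1, 2: 1, 3: 0, 4: 0}
        # modules of size 3 sharing only node 0
        assert scaled_inclusivity(part_a, part_b, 0) == pytest.approx(1 / 9)


class TestProbabilisticSI:
    def test_reduces_to_si_on_all_small_partition_pairs(self):
        nodes = list(range(4))
        partitions = [
            _oracles.partition_to_labels(p, 4) for p in _oracles.set_partitions(nodes)
        ]
        for part_a, part_b in itertools.product(partitions, repeat=2):
            ca = CoAssignmentMatrix(coassignment_from_partition(part_a), 1)
            cb = CoAssignmentMatrix(coassignment_from_partition(part_b), 1)
            psi, _ = probabilistic_si(ca, cb)
            si = scaled_inclusivity_all(part_a, part_b)
            assert np.abs(psi - si).max() < 1e-12

    def test_identical_binary_rows_give_one(self):
        part = {0: 0, 1: 0, 2: 1, 3: 1, 4: 2}
        c = CoAssignmentMatrix(coassignment_from_partition(part), 1)
        psi, mean_psi = probabilistic_si(c, c)
        assert np.allclose(psi, 1.0)
        assert mean_psi == 1.0

    def test_bounded_by_one_on_random_matrices(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            mats = []
            for _ in range(2):
                p = rng.random((8, 8))
                p = (p + p.T) / 2
                np.fill_diagonal(p, 1.0)
                mats.append(CoAssignmentMatrix(p, 1))
            psi, mean_psi = probabilistic_si(*mats)
            assert (psi <= 1.0 + 1e-12).all()
            assert 0.0 <= mean_psi <= 1.0 + 1e-12

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(5)
        p1 = rng.random((6, 6)); p1 = (p1 + p1.T) / 2; np.fill_diagonal(p1, 1.0)
        p2 = rng.random((6, 6)); p2 = (p2 + p2.T) / 2; np.fill_diagonal(p2, 1.0)
        a, b = CoAssignmentMatrix(p1, 1), CoAssignmentMatrix(p2, 1)
        assert probabilistic_si(a, b)[1] == pytest.approx(probabilistic_si(b, a)[1])


class TestConsensus:
    def test_identical_inputs_unchanged(self):
        part = {0: 0, 1: 0, 2: 1, 3: 1}
        c = CoAssignmentMatrix(coassignment_from_partition(part), 1)
        consensus, groups = consensus_coassignment([c, c])
        assert np.array_equal(consensus.prob, c.prob)
        assert groups == [frozenset({0, 1}), frozenset({2, 3})]

    def test_disagreement_excluded_from_stable_groups(self):
        a = coassignment_from_partition({0: 0, 1: 0, 2: 1})
        b = coassignment_from_partition({0: 0, 1: 1, 2: 2})
        ca, cb = CoAssignmentMatrix(a, 1), CoAssignmentMatrix(b, 1)
        consensus, groups = consensus_coassignment([ca, cb])
        assert consensus.prob[0, 1] == 0.5
        assert groups == []

    def test_stable_groups_partition_property(self):
        rng = np.random.default_rng(6)
        mats = []
        for _ in range(3):
            p = rng.random((10, 10))
            p = (p + p.T) / 2
            np.fill_diagonal(p, 1.0)
            mats.append(CoAssignmentMatrix(p, 1))
        _, groups = consensus_coassignment(mats, stable_threshold=0.5)
        seen = set()
        for g in groups:
            assert not (g & seen)
            seen |= g

    def test_planted_blocks_recovered(self, small_gt):
        # co-assignment matrices from two independently detected community
        # structures of the same planted network recover the blocks
        assoc_strength = np.abs(np.arctanh(
            np.clip(small_gt.partial_corr - np.eye(12), -0.99, 0.99)
        )) * 10
        np.fill_diagonal(assoc_strength, 0.0)
        assoc = netbuild.AssociationMatrix(assoc_strength, 500)
        net = netbuild.to_weighted(assoc)
        ca = detect_communities(net, 20, seed=1)
        cb = detect_communities(net, 20, seed=2)
        _, groups = consensus_coassignment([ca, cb])
        expected = [
            frozenset(np.where(small_gt.module_labels == m)[0].tolist())
            for m in range(3)
        ]
        assert sorted(groups, key=min) == sorted(expected, key=min)


class TestNullEnsemble:
    def test_binary_nulls_preserve_degree_sequence(self):
        rng = np.random.default_rng(7)
        adj = random_binary_adjacency(rng, 15, 0.3)
        net = _binary(adj)
        ensemble = null_ensemble(net, 20, seed=0)
        for null in ensemble.networks:
            assert np.array_equal(null.adjacency.sum(1), adj.sum(1))

    def test_weighted_nulls_preserve_weight_multiset(self):
        rng = np.random.default_rng(8)
        w = np.triu(rng.random((12, 12)) * (rng.random((12, 12)) < 0.4), 1)
        w = w + w.T
        net = WeightedNetwork(weights=w)
        ensemble = null_ensemble(net, 20, seed=1)
        iu = np.triu_indices(12, 1)
        original = np.sort(w[iu][w[iu] > 0])
        for null in ensemble.networks:
            vals = np.sort(null.weights[iu][null.weights[iu] > 0])
            assert np.array_equal(vals, original)

    def test_rewiring_changes_topology(self):
        rng = np.random.default_rng(9)
        adj = random_binary_adjacency(rng, 15, 0.3)
        ensemble = null_ensemble(_binary(adj), 10, seed=2)
        assert any(not np.array_equal(n.adjacency, adj) for n in ensemble.networks)

    def test_too_few_edges_rejected(self):
        adj = np.zeros((4, 4))
        adj[0, 1] = adj[1, 0] = 1.0
        with pytest.raises(ValueError, match="2 edges"):
            null_ensemble(_binary(adj), 5, seed=0)

    def test_null_pvalue_bounds_and_formula(self):
        assert null_pvalue(2.0, [1.0, 1.5, 3.0]) == pytest.approx(2 / 4)
        assert null_pvalue(10.0, [1.0] * 9) == pytest.approx(1 / 10)
        assert null_pvalue(-10.0, [1.0] * 9) == pytest.approx(1.0)

    def test_modular_hub_consistency_beats_weighted_null(self):
        # hubs of two noisy realizations of a strongly modular, hubbed weighted
        # network agree far better than weight-permuting rewired nulls do
        gt = synth.build_ground_truth(24, 3, 0.3, 0.0, 2, seed=5,
                                      hub_prob=1.0)
        base = np.abs(np.arctanh(np.clip(gt.partial_corr - np.eye(24), -0.99, 0.99))) * 10
        # per-node strength gradient: heterogeneous profiles keep the hub
        # ranking signal-determined rather than tie-noise-determined
        grad = np.linspace(0, 1.2, 24)[np.random.default_rng(0).permutation(24)]
        base = base + 0.5 * (grad[:, None] + grad[None, :])
        np.fill_diagonal(base, 0.0)
        rng = np.random.default_rng(10)
        wins = 0
        n_exp = 5
        for e in range(n_exp):
            nets = []
            for _ in range(2):
                noise = np.triu(rng.normal(0, 0.2, (24, 24)), 1)
                s = np.clip(base + noise + noise.T, 0, None)
                np.fill_diagonal(s, 0.0)
                assoc = netbuild.AssociationMatrix((s + s.T) / 2, 500)
                nets.append(netbuild.to_weighted(assoc))
            hubs = [hub_score(node_measures(n)).hubs for n in nets]
            observed = hub_cooccurrence(*hubs)
            nulls = null_ensemble(nets[0], 30, seed=100 + e)
            null_vals = [
                hub_cooccurrence(hub_score(node_measures(nn)).hubs, hubs[1])
                for nn in nulls.networks
            ]
            if observed > np.percentile(null_vals, 95):
                wins += 1
        assert wins >= 4
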