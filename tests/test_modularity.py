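"""Louvain modularity, null-model significance, hierarchical decomposition."""

import numpy as np
import pytest

from netrent import SpatialNetwork
from netrent.modularity import (
    coclassification,
    hierarchical_decompose,
    louvain_partition,
    modularity_significance,
)
from netrent.synth import make_hierarchical_modular, rewire_random


@pytest.fixture
def disjoint_cliques():
    """Four disjoint 10-cliques (trivially modular, leaves = cliques)."""
    edges = []
    for b in range(4):
        base = 10 * b
        edges += [[base + i, base + j] for i in range(10) for j in range(i + 1, 10)]
    coords = np.random.default_rng(0).random((40, 2))
    return SpatialNetwork([str(i) for i in range(40)], coords, edges)


class TestLouvain:
    def test_two_cliques_bridge_oracle(self, two_cliques4):
        part, q = louvain_partition(two_cliques4, seed=0)
        # hand evaluation: Q = 2 * (6/13 - (13/26)^2) = 0.42308
        assert q == pytest.approx(2 * (6 / 13 - 0.25), abs=1e-9)
        assert len(part) == 2

    def test_single_clique_q_zero(self):
        edges = [[i, j] for i in range(5) for j in range(i + 1, 5)]
        net = SpatialNetwork([str(i) for i in range(5)], np.random.default_rng(1).random((5, 2)), edges)
        _, q = louvain_partition(net, seed=0)
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_two_disjoint_cliques_q_half(self):
        edges = [[0, 1], [0, 2], [1, 2], [3, 4], [3, 5], [4, 5]]
        _, q = louvain_partition(np.array(edges), 6, seed=0)
        assert q == pytest.approx(0.5)

    def test_agrees_with_networkx_louvain(self, two_cliques4):
        """Independent cross-check against networkx's Louvain implementation."""
        import networkx as nx

        g = two_cliques4.to_networkx()
        comms = nx.community.louvain_communities(g, seed=7)
        q_nx = nx.community.modularity(g, comms)
        _, q = louvain_partition(two_cliques4, seed=0)
        assert q == pytest.approx(q_nx, abs=1e-9)

    def test_empty_edges_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            louvain_partition(np.zeros((0, 2), dtype=int), 4, seed=0)

    def test_q_bounds(self):
        for s in range(3):
            net = make_hierarchical_modular(2, 16, (0.05, 0.5), seed=s)
            _, q = louvain_partition(net, seed=s)
            assert -0.5 <= q <= 1.0


class TestSignificance:
    def test_modular_network_significant(self):
        net = make_hierarchical_modular(2, 32, (0.02, 0.9), seed=0)
        sig = modularity_significance(net, seed=1)
        assert sig.p_func < 0.05 and sig.p_rand < 0.05

    def test_observed_below_null_mean_gives_large_p(self):
        # a lattice ring has *lower* Q than its degree-matched rewirings?  No:
        # use an observed Q constructed below the null mean via a near-complete
        # graph whose own Q ~ 0 while sparse nulls keep structure; simplest is
        # to check the 1-tailed orientation directly on the helper.
        from netrent.modularity import _one_tailed_p

        p, _ = _one_tailed_p(0.1, np.array([0.3, 0.31, 0.29, 0.3, 0.32] * 4))
        assert p >= 0.5

    def test_pure_random_not_significant_most_seeds(self):
        hits = 0
        for s in range(10):
            net = make_hierarchical_modular(2, 32, (0.05, 0.4), seed=s)
            rnd = rewire_random(net, seed=s)
            sig = modularity_significance(rnd, seed=100 + s, n_null=50)
            hits += sig.p_rand < 0.05
        assert hits <= 2

    def test_degenerate_null_fallback(self):
        from netrent.modularity import _one_tailed_p

        p, degenerate = _one_tailed_p(0.5, np.full(20, 0.2))
        assert degenerate and 0 < p < 0.1

    def test_minimum_null_count_enforced(self, two_cliques4):
        with pytest.raises(ValueError):
            modularity_significance(two_cliques4, n_null=5, seed=0)


class TestDecomposition:
    def test_disjoint_cliques_depth_two(self, disjoint_cliques):
        tree = hierarchical_decompose(disjoint_cliques, seed=0, n_null=50)
        assert tree.depth() == 2
        leaf_sizes = sorted(c.members.size for c in tree.root.children)
        assert leaf_sizes == [10, 10, 10, 10]

    def test_hierarchical_generator_depth_three(self):
        net = make_hierarchical_modular(3, 64, (0.01, 0.3, 0.6), seed=3)
        tree = hierarchical_decompose(net, seed=4)
        assert tree.depth() >= 3

    def test_random_network_depth_one(self):
        net = make_hierarchical_modular(3, 64, (0.01, 0.3, 0.6), seed=5)
        rnd = rewire_random(net, seed=6)
        tree = hierarchical_decompose(rnd, seed=7)
        assert tree.depth() == 1

    def test_children_partition_parent(self):
        net = make_hierarchical_modular(3, 32, (0.01, 0.3, 0.6), seed=8)
        tree = hierarchical_decompose(net, seed=9, n_null=50)

        def check(node):
            if node.children:
                union = np.sort(np.concatenate([c.members for c in node.children]))
                assert np.array_equal(union, np.sort(node.members))
                for c in node.children:
                    check(c)

        check(tree.root)

    def test_min_module_size_leaves(self, two_cliques4):
        tree = hierarchical_decompose(two_cliques4, min_module_size=50, seed=0, n_null=50)
        assert tree.depth() == 1  # below min size: untested leaf

    def test_tree_serialises(self, disjoint_cliques):
        tree = hierarchical_decompose(disjoint_cliques, seed=0, n_null=50)
        doc = tree.to_dict()
        assert doc["depth"] == 2 and doc["tree"]["size"] == 40


class TestCoclassification:
    def test_disjoint_cliques_block_matrix(self, disjoint_cliques):
        res = coclassification(disjoint_cliques, runs=10, seed=0)
        block = np.arange(40) // 10
        same = block[:, None] == block[None, :]
        assert np.allclose(res.matrix[same], 1.0)
        assert np.allclose(res.matrix[~same], 0.0)

    def test_diagonal_is_one(self, two_cliques4):
        res = coclassification(two_cliques4, runs=5, seed=1)
        assert np.allclose(np.diag(res.matrix), 1.0)

    def test_symmetric(self, two_cliques4):
        res = coclassification(two_cliques4, runs=5, seed=2)
        assert np.allclose(res.matrix, res.matrix.T)

    def test_nested_structure_ordering(self):
        net = make_hierarchical_modular(3, 16, (0.02, 0.3, 0.9), seed=0)
        res = coclassification(net, runs=30, seed=1)
        n = net.n_nodes
        quarter = np.arange(n) // 16
        half = np.arange(n) // 32
        iu, ju = np.triu_indices(n, 1)
        within_q = res.matrix[iu, ju][quarter[iu] == quarter[ju]].mean()
        within_h = res.matrix[iu, ju][(half[iu] == half[ju]) & (quarter[iu] != quarter[ju])].mean()
        between = res.matrix[iu, ju][half[iu] != half[ju]].mean()
        assert within_q > within_h > between

    def test_runs_validated(self, two_cliques4):
        with pytest.raises(ValueError):
            coclassification(two_cliques4, runs=1)
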