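"""Correlation network construction, communities, annotation, layout."""

import numpy as np
import pandas as pd
import pytest

import cytogravity as cg
from cytogravity.network import CorrelationNetwork


def _df(X, names=None):
    names = names or [f"f{i}" for i in range(X.shape[1])]
    return pd.DataFrame(X, columns=names)


class TestBuildNetwork:
    def test_identical_columns_are_connected(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=16)
        X = np.column_stack([v, v, rng.normal(size=16)])
        net = cg.build_network(_df(X, ["a", "b", "c"]))
        i, j = net.nodes.index("a"), net.nodes.index("b")
        assert net.rho[i, j] == pytest.approx(1.0)
        assert net.adjacency[i, j]

    def test_edge_criterion_matches_bonferroni_rule(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(14, 8))
        X[:, 1] = X[:, 0] + rng.normal(0, 0.05, size=14)
        net = cg.build_network(_df(X))
        m = net.n_nodes * (net.n_nodes - 1) // 2
        for i in range(net.n_nodes):
            for j in range(i + 1, net.n_nodes):
                assert net.adjacency[i, j] == (net.p[i, j] * m < 0.05)
                assert net.p[i, j] == net.p[j, i]

    def test_p_values_match_exact_enumeration_at_n8(self):
        # at 8 rows spearman_rho_p enumerates all 8! permutations: an
        # independent oracle for the network's exact-tail p-values
        rng = np.random.default_rng(6)
        X = rng.normal(size=(8, 4))
        net = cg.build_network(_df(X))
        for i in range(4):
            for j in range(i + 1, 4):
                rho, p = cg.spearman_rho_p(X[:, i], X[:, j])
                assert net.rho[i, j] == pytest.approx(rho, abs=1e-12)
                assert net.p[i, j] == pytest.approx(p, abs=1e-9)

    def test_p_values_fall_back_to_t_beyond_exact_range(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(20, 3))
        net = cg.build_network(_df(X))
        for i in range(3):
            for j in range(i + 1, 3):
                rho, p = cg.spearman_rho_p(X[:, i], X[:, j])  # t approx at n=20
                assert net.p[i, j] == pytest.approx(p, abs=1e-12)

    def test_duplicating_rows_preserves_rho(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 4))
        net1 = cg.build_network(_df(X))
        net2 = cg.build_network(_df(np.vstack([X, X])))
        np.testing.assert_allclose(net1.rho, net2.rho, atol=1e-12)

    def test_constant_columns_excluded(self):
        rng = np.random.default_rng(3)
        X = np.column_stack([rng.normal(size=12), np.full(12, 2.0), rng.normal(size=12)])
        net = cg.build_network(_df(X, ["a", "const", "b"]))
        assert net.excluded == ["const"]
        assert net.nodes == ["a", "b"]

    def test_column_order_invariance(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(12, 5))
        names = list("abcde")
        net1 = cg.build_network(_df(X, names))
        perm = [3, 0, 4, 1, 2]
        net2 = cg.build_network(_df(X[:, perm], [names[i] for i in perm]))
        for a in names:
            for b in names:
                if a == b:
                    continue
                i1, j1 = net1.nodes.index(a), net1.nodes.index(b)
                i2, j2 = net2.nodes.index(a), net2.nodes.index(b)
                assert net1.adjacency[i1, j1] == net2.adjacency[i2, j2]
                assert net1.rho[i1, j1] == pytest.approx(net2.rho[i2, j2])


def _clique_network(sizes):
    n = sum(sizes)
    adjacency = np.zeros((n, n), dtype=bool)
    start = 0
    for s in sizes:
        adjacency[start:start + s, start:start + s] = True
        start += s
    np.fill_diagonal(adjacency, False)
    rho = np.where(adjacency, 0.9, 0.0)
    np.fill_diagonal(rho, 1.0)
    p = np.where(adjacency, 1e-12, 0.9)
    return CorrelationNetwork(
        nodes=[f"n{i}" for i in range(n)], rho=rho, p=p, adjacency=adjacency
    )


class TestCommunities:
    def test_two_disjoint_cliques(self):
        net = _clique_network([5, 5])
        labels = cg.detect_communities(net, seed=0)
        groups = {}
        for node, lab in labels.items():
            groups.setdefault(lab, []).append(node)
        assert len(groups) == 2
        assert sorted(map(len, groups.values())) == [5, 5]

    def test_edgeless_graph_gives_singletons(self):
        net = _clique_network([1] * 6)
        labels = cg.detect_communities(net, seed=0)
        assert len(set(labels.values())) == 6

    def test_partition_covers_all_nodes(self):
        net = _clique_network([4, 3, 1])
        labels = cg.detect_communities(net, seed=0)
        assert set(labels) == set(net.nodes)

    def test_deterministic_for_fixed_seed(self):
        net1 = _clique_network([5, 4, 3])
        net2 = _clique_network([5, 4, 3])
        assert cg.detect_communities(net1, seed=3) == cg.detect_communities(net2, seed=3)


class TestAnnotation:
    def test_uniform_community(self):
        labels = {("T", "CD25", "response"): 0, ("B", "CD25", "response"): 0}
        ann = cg.annotate_communities(labels)
        assert ann[0]["attribute"] == "CD25" and not ann[0]["tie"]

    def test_modal_marker_wins(self):
        labels = {(f"s{i}", "pSTAT5", "r"): 0 for i in range(6)}
        labels.update({(f"t{i}", "CD69", "r"): 0 for i in range(2)})
        ann = cg.annotate_communities(labels)
        assert ann[0]["attribute"] == "pSTAT5"

    def test_tie_broken_alphabetically_and_flagged(self):
        labels = {("a", "CD69", "r"): 0, ("b", "CD69", "r"): 0,
                  ("c", "CD25", "r"): 0, ("d", "CD25", "r"): 0}
        ann = cg.annotate_communities(labels)
        assert ann[0]["attribute"] == "CD25" and ann[0]["tie"]


class TestLayout:
    def test_deterministic_for_fixed_seed(self):
        net1 = _clique_network([4, 4])
        net2 = _clique_network([4, 4])
        l1 = cg.layout_2d(net1, seed=5)
        l2 = cg.layout_2d(net2, seed=5)
        for node in net1.nodes:
            assert l1[node] == l2[node]

    def test_single_node_at_origin(self):
        net = _clique_network([1])
        assert cg.layout_2d(net, seed=0) == {"n0": (0.0, 0.0)}

    def test_correlated_pair_closer_than_independent(self):
        rho = np.array([
            [1.0, 0.99, 0.01],
            [0.99, 1.0, 0.02],
            [0.01, 0.02, 1.0],
        ])
        closer = 0
        for seed in range(10):
            net = CorrelationNetwork(
                nodes=["a", "b", "c"], rho=rho, p=np.ones((3, 3)),
                adjacency=np.zeros((3, 3), dtype=bool),
            )
            layout = cg.layout_2d(net, seed=seed)
            a, b, c = (np.array(layout[k]) for k in "abc")
            d_ab = np.linalg.norm(a - b)
            d_ac = np.linalg.norm(a - c)
            closer += d_ab < d_ac
        assert closer >= 9

    def test_finite_for_near_constant_input(self):
        rho = np.full((5, 5), 0.9999)
        np.fill_diagonal(rho, 1.0)
        net = CorrelationNetwork(
            nodes=[f"n{i}" for i in range(5)], rho=rho, p=np.ones((5, 5)),
            adjacency=np.zeros((5, 5), dtype=bool),
        )
        layout = cg.layout_2d(net, seed=1)
        assert all(np.isfinite(v).all() for v in map(np.array, layout.values()))
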