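"""Overlap tests and shortest paths: oracles and invariants."""

import itertools

import networkx as nx
import numpy as np
import pytest
from scipy.stats import hypergeom

from hprna.datamodel import DataError, PathwayUniverse
from hprna.network import (
    ContingencyCounts,
    DistanceMatrix,
    all_pairs_shortest_paths,
    build_network,
    contingency,
    fisher_point_probability,
    fisher_pvalue,
    floyd_warshall,
    read_network_edges,
    write_network,
)


class TestContingency:
    def test_partial_overlap(self):
        u = PathwayUniverse([("Pi", ["g1", "g2"]), ("Pj", ["g2", "g3"])])
        c = contingency(u, "Pi", "Pj")
        assert (c.a, c.b, c.c, c.d) == (1, 1, 1, 0)

    def test_disjoint_sets_covering_universe(self):
        u = PathwayUniverse([("Pi", ["g1", "g2"]), ("Pj", ["g3", "g4"])])
        c = contingency(u, "Pi", "Pj")
        assert c.a == 0 and c.d == 0

    def test_identical_sets(self):
        u = PathwayUniverse([("Pi", ["g1", "g2"]), ("Pj", ["g1", "g2"]), ("Pk", ["g3"])])
        c = contingency(u, "Pi", "Pj")
        assert c.b == 0 and c.c == 0 and c.d == 1

    def test_margins_sum_to_m(self, small_dataset):
        universe = small_dataset[0]
        ids = universe.pathway_ids[:4]
        for i, j in itertools.combinations(ids, 2):
            c = contingency(universe, i, j)
            assert c.a + c.b == len(universe.genes(i))
            assert c.a + c.c == len(universe.genes(j))
            assert c.M == universe.M

    def test_same_pathway_rejected(self, toy_universe):
        with pytest.raises(DataError, match="itself"):
            contingency(toy_universe, "P1", "P1")

    def test_unknown_pathway_rejected(self, toy_universe):
        with pytest.raises(DataError, match="unknown pathway"):
            contingency(toy_universe, "P1", "P9")


class TestFisher:
    def test_point_probability_balanced_table(self):
        # 2/3: direct evaluation of the factorial formula for a=b=c=d=1
        assert fisher_point_probability(ContingencyCounts(1, 1, 1, 1)) == pytest.approx(2 / 3, abs=1e-12)

    def test_point_probability_diagonal_table(self):
        assert fisher_point_probability(ContingencyCounts(2, 0, 0, 2)) == pytest.approx(1 / 6, abs=1e-12)

    @pytest.mark.parametrize("a,d", [(0, 0), (3, 0), (0, 5)])
    def test_single_table_margins_give_one(self, a, d):
        # a=0 or d=0 with b=c=0: only one table has these margins
        assert fisher_point_probability(ContingencyCounts(a, 0, 0, d)) == pytest.approx(1.0)

    def test_degenerate_square_table_is_not_one(self):
        # b=c=0 alone does not pin the table: margins (4,4,4,4) admit five
        # tables and the observed all-diagonal one has mass 1/C(8,4)
        assert fisher_point_probability(ContingencyCounts(4, 0, 0, 4)) == pytest.approx(1 / 70)

    def test_greater_tail_balanced_table(self):
        # 5/6: sum of the a'=1 and a'=2 hypergeometric terms
        assert fisher_pvalue(ContingencyCounts(1, 1, 1, 1), "greater") == pytest.approx(5 / 6, abs=1e-12)

    def test_greater_equals_point_at_maximal_intersection(self):
        c = ContingencyCounts(3, 0, 2, 4)  # a == min(a+b, a+c)
        assert fisher_pvalue(c, "greater") == pytest.approx(fisher_point_probability(c), abs=1e-14)

    def test_greater_is_one_at_zero_intersection(self):
        assert fisher_pvalue(ContingencyCounts(0, 4, 3, 5), "greater") == pytest.approx(1.0)

    def test_matches_scipy_hypergeometric(self):
        """Independent oracle: point mass and survival function from scipy."""
        for M in (8, 15, 40):
            for K in (2, 5, 8):
                for n in (3, 6, 8):
                    for a in range(max(0, K + n - M), min(K, n) + 1):
                        c = ContingencyCounts(a, K - a, n - a, M - K - n + a)
                        assert fisher_point_probability(c) == pytest.approx(
                            hypergeom.pmf(a, M, K, n), abs=1e-12
                        )
                        assert fisher_pvalue(c, "greater") == pytest.approx(
                            hypergeom.sf(a - 1, M, K, n), abs=1e-12
                        )


class TestBuildNetwork:
    def test_pvalues_symmetric(self, small_dataset):
        network = build_network(small_dataset[0], p_threshold=0.001)
        assert np.allclose(network.pvalues, network.pvalues.T, equal_nan=True)

    def test_edge_set_monotone_in_threshold(self, small_dataset):
        network = build_network(small_dataset[0], p_threshold=0.001)
        previous: set = set()
        for p in (1e-6, 1e-4, 1e-2, 0.5, 1.0):
            edges = set(network.rethreshold(p).edges())
            assert previous <= edges
            previous = edges

    def test_toy_network_matches_hand_enumeration(self, toy_universe):
        """Three pairwise p-values enumerated with scipy, threshold between them."""
        M = toy_universe.M  # 4
        expected = {
            ("P1", "P2"): hypergeom.sf(1, M, 3, 3),  # a=2 of margins 3,3
            ("P1", "P3"): hypergeom.sf(-1, M, 3, 1),  # a=0 -> 1.0
            ("P2", "P3"): hypergeom.sf(0, M, 3, 1),  # a=1
        }
        network = build_network(toy_universe, p_threshold=1.0)
        for (i, j), want in expected.items():
            assert network.pvalue(i, j) == pytest.approx(want, abs=1e-12)
        cut = sorted(expected.values())  # pick a threshold between 1st and 2nd
        threshold = (cut[0] + cut[1]) / 2
        edges = network.rethreshold(threshold).edges()
        assert edges == [min(expected, key=expected.get)]

    def test_threshold_one_point_connects_all_multi_table_pairs(self, toy_universe):
        # every pair here admits >=2 tables, so each point probability is <1
        point = build_network(toy_universe, p_threshold=1.0, sidedness="point")
        assert point.edges() == [("P1", "P2"), ("P1", "P3"), ("P2", "P3")]
        # with tail p-values the strict inequality drops pairs at exactly 1.0
        greater = build_network(toy_universe, p_threshold=1.0, sidedness="greater")
        assert greater.edges() == [("P2", "P3")]

    def test_tiny_threshold_gives_edgeless_network(self, toy_universe):
        network = build_network(toy_universe, p_threshold=1e-12)
        assert network.n_edges == 0
        assert set(network.graph.nodes) == set(toy_universe.pathway_ids)

    def test_isolated_pathways_remain_nodes(self, small_dataset):
        network = build_network(small_dataset[0], p_threshold=1e-9)
        assert set(network.graph.nodes) == set(small_dataset[0].pathway_ids)

    def test_network_files_round_trip(self, tmp_path, small_dataset):
        network = build_network(small_dataset[0], p_threshold=0.001)
        write_network(network, tmp_path / "edges.tsv", tmp_path / "nodes.tsv")
        ids, edges = read_network_edges(tmp_path / "edges.tsv", tmp_path / "nodes.tsv")
        assert ids == network.ids
        assert sorted(edges) == network.edges()


class TestShortestPaths:
    def test_path_graph_distance(self):
        adj = np.full((3, 3), np.inf)
        adj[0, 1] = adj[1, 0] = 1.0
        adj[1, 2] = adj[2, 1] = 1.0
        D = floyd_warshall(adj)
        assert D[0, 2] == 2.0 and D[2, 0] == 2.0

    def test_disconnected_components_are_infinite(self):
        adj = np.full((4, 4), np.inf)
        adj[0, 1] = adj[1, 0] = 1.0
        adj[2, 3] = adj[3, 2] = 1.0
        D = floyd_warshall(adj)
        assert np.isinf(D[0, 2]) and D[0, 1] == 1.0 and D[2, 3] == 1.0

    def test_matches_bfs_on_random_graphs(self):
        """Per-source BFS (networkx) as the independent distance oracle."""
        rng = np.random.default_rng(11)
        for _ in range(30):
            n = int(rng.integers(2, 40))
            p = rng.uniform(0.02, 0.3)
            g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
            adj = np.full((n, n), np.inf)
            for u, v in g.edges:
                adj[u, v] = adj[v, u] = 1.0
            D = floyd_warshall(adj)
            assert np.allclose(D, D.T)
            assert np.all(np.diag(D) == 0)
            for src in g.nodes:
                lengths = nx.single_source_shortest_path_length(g, src)
                for dst in g.nodes:
                    want = lengths.get(dst, np.inf)
                    assert D[src, dst] == want

    def test_triangle_inequality(self, small_dataset):
        D = all_pairs_shortest_paths(build_network(small_dataset[0], 0.001)).values
        n = D.shape[0]
        finite = np.nan_to_num(D, posinf=1e9)
        for k in range(n):
            assert np.all(finite <= finite[:, k, None] + finite[None, k, :] + 1e-9)

    def test_distance_matrix_tsv_round_trip(self, tmp_path):
        D = DistanceMatrix(("P1", "P2", "P3"), np.array([[0, 1, np.inf], [1, 0, np.inf], [np.inf, np.inf, 0]], dtype=float))
        D.to_tsv(tmp_path / "d.tsv")
        back = DistanceMatrix.from_tsv(tmp_path / "d.tsv")
        assert back.ids == D.ids
        assert np.array_equal(back.values, D.values)
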