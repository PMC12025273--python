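"""Network separation, module distance, flow centrality: hand-worked cases,
oracle equivalence on random graphs, and structural properties."""

import networkx as nx
import numpy as np
import pytest

from conftest import random_connected_graph
from dims.proximity import (
    InteractionNetwork,
    flow_centrality,
    gene_total_distance,
    module_shortest_distance,
    separation,
)
from oracles import (
    bf_flow_centrality,
    bf_gene_total_distance,
    bf_module_distance,
    bf_separation,
)


class TestSeparation:
    def test_path_graph_hand_worked(self, path_graph):
        # 1-2-3-4-5: A={1,2}, B={4,5}; nearest cross distances 3,2,2,3 ->
        # d_AB=2.5; within-set nearest neighbours are adjacent -> d_AA=d_BB=1
        res = separation(path_graph, {"1", "2"}, {"4", "5"})
        assert res.d_ab == pytest.approx(2.5)
        assert res.d_aa == pytest.approx(1.0)
        assert res.d_bb == pytest.approx(1.0)
        assert res.s_ab == pytest.approx(1.5)

    def test_identical_sets_give_negative_separation(self, path_graph):
        res = separation(path_graph, {"2", "3"}, {"2", "3"})
        assert res.d_ab == 0.0
        assert res.s_ab == pytest.approx(-res.d_aa)
        assert res.s_ab < 0

    def test_symmetric_in_arguments(self, path_graph):
        ab = separation(path_graph, {"1", "2"}, {"4", "5"})
        ba = separation(path_graph, {"4", "5"}, {"1", "2"})
        assert ab.s_ab == ba.s_ab

    def test_singleton_set_rejected(self, path_graph):
        with pytest.raises(ValueError, match=">= 2"):
            separation(path_graph, {"1"}, {"4", "5"})

    def test_unmapped_genes_dropped_with_warning(self, path_graph):
        with pytest.warns(UserWarning, match="absent"):
            res = separation(path_graph, {"1", "2", "zzz"}, {"4", "5"})
        assert res.n_dropped == 1
        assert res.n_mapped_a == 2


class TestModuleDistance:
    def test_path_graph_hand_worked(self, path_graph):
        # pairs (1,4)=3 (1,5)=4 (2,4)=2 (2,5)=3 -> 12/4
        res = module_shortest_distance(path_graph, {"1", "2"}, {"4", "5"})
        assert res.d_shortest == pytest.approx(3.0)
        assert res.pairs_used == 4

    def test_complete_bipartite_join_is_one(self):
        g = nx.complete_bipartite_graph(3, 3)
        a, b = {0, 1, 2}, {3, 4, 5}
        res = module_shortest_distance(g, a, b)
        assert res.d_shortest == pytest.approx(1.0)


class TestFlowCentrality:
    def test_star_hub_carries_every_path(self, star_graph):
        res = flow_centrality(star_graph, {"l1", "l2"}, {"l3", "l4"},
                              candidates=["c"])
        assert res.fc_raw("c") == pytest.approx(4.0)
        assert res.fc_norm("c") == pytest.approx(1.0)

    def test_four_cycle_splits_paths_evenly(self):
        g = nx.Graph([("a", "x"), ("x", "b"), ("b", "y"), ("y", "a")])
        res = flow_centrality(g, {"a"}, {"b"}, candidates=["x", "y"])
        assert res.fc_norm("x") == pytest.approx(0.5)
        assert res.fc_norm("y") == pytest.approx(0.5)

    def test_normalized_value_bounded(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            g = random_connected_graph(rng)
            nodes = sorted(g.nodes())
            a, b = set(nodes[:2]), set(nodes[-2:])
            res = flow_centrality(g, a, b)
            assert (res.table.fc_norm >= 0).all()
            assert (res.table.fc_norm <= 1 + 1e-12).all()
            assert (res.table.fc_raw <= res.table.pairs_used + 1e-12).all()

    def test_empty_candidates_rejected(self, star_graph):
        with pytest.raises(ValueError, match="candidate"):
            with pytest.warns(UserWarning, match="absent"):
                flow_centrality(star_graph, {"l1", "l2"}, {"l3", "l4"},
                                candidates=["nope"])


class TestGeneTotalDistance:
    def test_star_center(self, star_graph):
        total, n = gene_total_distance(star_graph, "c",
                                       {"l1", "l2"}, {"l3", "l4"})
        assert total == 4.0 and n == 4

    def test_path_graph_middle_node(self, path_graph):
        total, n = gene_total_distance(path_graph, "3", {"1", "2"}, {"4", "5"})
        assert total == 6.0 and n == 4


class TestOracleEquivalence:
    def test_all_measures_match_bruteforce_on_random_graphs(self):
        rng = np.random.default_rng(2024)
        for _ in range(50):
            g = random_connected_graph(rng)
            nodes = sorted(g.nodes())
            k = max(2, len(nodes) // 3)
            a = set(rng.choice(nodes, size=k, replace=False))
            b = set(rng.choice(nodes, size=k, replace=False))
            if len(a) < 2 or len(b) < 2:
                continue
            net = InteractionNetwork(g)

            s = separation(net, a, b)
            bs, bd_ab, bd_aa, bd_bb = bf_separation(g, sorted(a), sorted(b))
            assert s.s_ab == pytest.approx(bs)
            assert (s.d_ab, s.d_aa, s.d_bb) == pytest.approx(
                (bd_ab, bd_aa, bd_bb)
            )

            md = module_shortest_distance(net, a, b)
            assert md.d_shortest == pytest.approx(bf_module_distance(g, a, b))

            fc = flow_centrality(net, a, b)
            for v in nodes:
                raw, used = bf_flow_centrality(g, sorted(a), sorted(b), v)
                assert fc.fc_raw(v) == pytest.approx(raw)
                assert fc.table.loc[v, "pairs_used"] == used

            for v in nodes[:3]:
                try:
                    total, n = gene_total_distance(net, v, a, b)
                except ValueError:
                    continue
                btotal, bn = bf_gene_total_distance(g, v, a, b)
                assert (total, n) == (btotal, bn)


class TestStructuralProperties:
    def test_adding_edge_never_increases_distances(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            g = random_connected_graph(rng)
            before = dict(nx.all_pairs_shortest_path_length(g))
            u, v = rng.choice(sorted(g.nodes()), size=2, replace=False)
            g2 = g.copy()
            g2.add_edge(u, v)
            after = dict(nx.all_pairs_shortest_path_length(g2))
            for x in g.nodes():
                for y in g.nodes():
                    assert after[x][y] <= before[x][y]

    def test_largest_component_restriction(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("x", "y")])
        with pytest.warns(UserWarning, match="largest connected"):
            net = InteractionNetwork(g)
        assert "x" not in net
        assert "a" in net
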