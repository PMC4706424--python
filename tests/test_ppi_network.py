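import itertools

import networkx as nx
import numpy as np
import pytest

from _oracles import steiner_optimum
from metanet import ppi_network as ppi
from metanet.deg_meta import DEGSet


class TestIntegrateBackground:
    def test_reversed_pairs_merge_with_source_count(self):
        G = ppi.integrate_background([("A", "B")], [("B", "A")])
        assert G.number_of_edges() == 1
        assert G["A"]["B"]["source_count"] == 2

    def test_self_loops_dropped(self):
        G = ppi.integrate_background([("A", "A"), ("A", "B")])
        assert list(G.edges) == [("A", "B")]

    def test_disjoint_lists_union(self):
        G = ppi.integrate_background([("A", "B")], [("C", "D")])
        assert set(G.nodes) == {"A", "B", "C", "D"}
        assert G.number_of_edges() == 2

    def test_idempotent_on_own_edge_list(self):
        G1 = ppi.integrate_background([("A", "B"), ("B", "C"), ("C", "A")])
        G2 = ppi.integrate_background(list(G1.edges), list(G1.edges))
        assert set(G1.edges) == set(G2.edges)
        assert set(G1.nodes) == set(G2.nodes)

    def test_empty_union_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ppi.integrate_background([("A", "A")])


class TestTerminals:
    def test_unmapped_degs_reported(self):
        G = ppi.integrate_background([("A", "B"), ("B", "C")])
        terms, unmapped = ppi.map_terminals(G, DEGSet(up={"A", "X"}, down={"C"}))
        assert terms == {"A", "C"}
        assert unmapped == {"X"}

    def test_case_mismatch_canonicalized(self):
        G = ppi.integrate_background([("MMP9", "BGH3")])
        terms, unmapped = ppi.map_terminals(G, DEGSet(up={"mmp9 "}))
        assert terms == {"MMP9"}
        assert unmapped == set()

    def test_zero_mapped_terminals_errors(self):
        G = ppi.integrate_background([("A", "B")])
        with pytest.raises(ValueError, match="no DEG"):
            ppi.map_terminals(G, DEGSet(up={"Z"}))

    def test_one_intermediary_candidates(self):
        # star: center adjacent to 3 terminals; pendant adjacent to 1
        G = nx.Graph([("HUB", "T1"), ("HUB", "T2"), ("HUB", "T3"), ("P", "T1"),
                      ("T1", "T2")])
        terms = {"T1", "T2", "T3"}
        assert ppi.one_intermediary_candidates(G, terms) == {"HUB"}


class TestSteiner:
    def test_path_between_terminals_is_unique_solution(self):
        G = nx.path_graph(["a", "b", "c"])
        st = ppi.steiner_subnetwork(G, {"a", "c"})
        assert set(st.graph.nodes) == {"a", "b", "c"}
        assert st.total_cost == 2

    def test_adjacent_terminals_give_spanning_tree(self):
        G = nx.complete_graph(["x", "y", "z"])
        st = ppi.steiner_subnetwork(G, {"x", "y", "z"})
        assert st.total_cost == 2
        assert set(st.graph.nodes) == {"x", "y", "z"}

    def test_isolated_terminal_returned_as_singleton_with_warning(self):
        G = nx.Graph([("a", "b")])
        G.add_node("lone")
        with pytest.warns(UserWarning, match="lone"):
            st = ppi.steiner_subnetwork(G, {"a", "b", "lone"})
        assert st.singleton_terminals == {"lone"}
        assert "lone" in st.graph

    def test_output_is_forest_containing_all_terminals(self):
        rng = np.random.default_rng(5)
        for trial in range(20):
            G = nx.gnp_random_graph(15, 0.2, seed=int(rng.integers(2**31)))
            G = nx.relabel_nodes(G, {i: f"N{i:02d}" for i in G})
            terms = set(rng.choice(sorted(G.nodes), size=5, replace=False))
            st = ppi.steiner_subnetwork(G, terms)
            assert terms <= set(st.graph.nodes)
            assert nx.is_forest(st.graph)
            # no prunable non-terminal leaf remains
            for n in st.graph:
                if st.graph.degree(n) == 1:
                    assert n in terms or st.graph.degree(n) == 0

    def test_cost_within_2x_of_exhaustive_optimum(self):
        rng = np.random.default_rng(17)
        done = 0
        while done < 25:
            G = nx.gnp_random_graph(12, 0.25, seed=int(rng.integers(2**31)))
            G = nx.relabel_nodes(G, {i: f"N{i:02d}" for i in G})
            terms = set(rng.choice(sorted(G.nodes), size=4, replace=False))
            if not all(
                nx.has_path(G, a, b)
                for a, b in itertools.combinations(terms, 2)
            ):
                continue
            done += 1
            cost = ppi.steiner_subnetwork(G, terms).total_cost
            assert cost <= 2 * steiner_optimum(G, terms)

    def test_deterministic_output(self):
        G = nx.gnp_random_graph(20, 0.15, seed=9)
        G = nx.relabel_nodes(G, {i: f"N{i:02d}" for i in G})
        comp = max(nx.connected_components(G), key=len)
        terms = set(sorted(comp)[:4])
        a = ppi.steiner_subnetwork(G, terms)
        b = ppi.steiner_subnetwork(G, terms)
        assert set(a.graph.edges) == set(b.graph.edges)


class TestAnalysisSubnetwork:
    def test_contains_steiner_nodes_candidates_and_induced_edges(self):
        # terminals T1..T3 linked through S; C is adjacent to two terminals
        G = nx.Graph(
            [("T1", "S"), ("T2", "S"), ("T3", "S"), ("C", "T1"), ("C", "T2"),
             ("T1", "T2"), ("Z", "T3")]
        )
        degs = DEGSet(up={"T1", "T2"}, down={"T3"})
        sub = ppi.analysis_subnetwork(G, degs)
        assert {"T1", "T2", "T3", "S", "C"} <= set(sub.nodes)
        assert "Z" not in sub  # adjacent to only one terminal, not on tree
        assert sub.has_edge("T1", "T2")  # induced edge restored
        assert sub.nodes["T1"]["is_deg"] and sub.nodes["T1"]["direction"] == "up"
        assert not sub.nodes["C"]["is_deg"]
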