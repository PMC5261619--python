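"""Network construction, centralities and broker/bridge classification."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from quartetnet import (
    assemble_gene_list,
    biggest_component,
    bridging_coefficient,
    brokering_score,
    build_network,
    centralities,
    classify_roles,
    compare_components,
    summary_stats,
)
from conftest import (
    brute_force_betweenness,
    brute_force_closeness,
    brute_force_clustering,
    two_cliques_with_bridge,
)

# printed centrality table of the biggest connected components:
# (sibling, gene, degree, clustering, expected brokering), n = 82 (M) / 68 (F)
PRINTED_CENTRALITY_ROWS = [
    ("M", "CAD", 14, 0.033, 0.167),
    ("M", "FGFR3", 6, 0.000, 0.074),
    ("M", "FYN", 10, 0.044, 0.118),
    ("M", "PDE6B", 6, 0.000, 0.074),
    ("M", "POLR3A", 8, 0.143, 0.085),
    ("F", "FLNC", 6, 0.133, 0.078),
    ("F", "FYN", 12, 0.015, 0.176),
    ("F", "ITGB4", 6, 0.133, 0.078),
    ("M", "FIGF", 2, 0.000, 0.025),
    ("M", "IDUA", 2, 0.000, 0.025),
    ("M", "NCKIPSD", 2, 0.000, 0.025),
    ("M", "NPR1", 3, 0.333, 0.025),
    ("F", "CTBP1", 2, 0.000, 0.030),
    ("F", "HTT", 2, 0.000, 0.030),
    ("F", "SPTBN4", 3, 0.000, 0.045),
]
COMPONENT_SIZE = {"M": 82, "F": 68}


def edge_frame(rows):
    return pd.DataFrame(rows, columns=["geneA", "geneB", "combined_score"])


class TestAssembleGeneList:
    def test_brain_filter_identity_when_all_brain(self):
        gl = assemble_gene_list("M", {"A"}, {"B"}, {"C"}, {"A", "B", "C"})
        assert gl.universe == {"A", "B", "C"}
        assert gl.brain_filter_applied

    def test_brain_filter_intersects(self):
        gl = assemble_gene_list("M", {"A", "B", "C"}, set(), set(), {"A", "C"})
        assert gl.cnv_genes == {"A", "C"}

    def test_disabled_filter_is_identity(self):
        gl = assemble_gene_list("M", {"A"}, set(), set(), None)
        assert not gl.brain_filter_applied and gl.universe == {"A"}

    def test_empty_universe_is_error(self):
        with pytest.raises(ValueError, match="empty gene universe"):
            assemble_gene_list("M", {"A"}, set(), set(), {"Z"})

    def test_provenance_sizes_at_study_scale(self):
        cnv = {f"C{i}" for i in range(70)}
        shared = {f"S{i}" for i in range(81)}
        excl = {f"E{i}" for i in range(105)}
        gl = assemble_gene_list("M", cnv, shared, excl, None)
        assert len(gl.universe) == 256
        prov = gl.provenance()
        assert all(prov[g] == {"cnv"} for g in cnv)


class TestBuildNetwork:
    def test_confidence_boundary(self):
        edges = edge_frame([("A", "B", 0.39), ("A", "C", 0.40)])
        net = build_network(edges, {"A", "B", "C"})
        assert not net.has_edge("A", "B") and net.has_edge("A", "C")

    def test_node_and_edge_counts(self):
        # isolated universe genes stay as degree-0 nodes
        edges = edge_frame([("A", "B", 0.9)])
        net = build_network(edges, {"A", "B", "C"})
        assert net.number_of_nodes() == 3 and net.number_of_edges() == 1

    def test_empty_universe(self):
        net = build_network(edge_frame([("A", "B", 0.9)]), set())
        assert net.number_of_nodes() == 0

    def test_database_scale_rescaled(self):
        edges = edge_frame([("A", "B", 900.0), ("A", "C", 150.0)])
        net = build_network(edges, {"A", "B", "C"})
        assert net.has_edge("A", "B") and not net.has_edge("A", "C")

    def test_duplicate_edges_keep_max_confidence(self):
        edges = edge_frame([("A", "B", 0.5), ("B", "A", 0.8)])
        net = build_network(edges, {"A", "B"})
        assert net["A"]["B"]["confidence"] == 0.8

    def test_self_loops_and_outside_universe_dropped(self):
        edges = edge_frame([("A", "A", 0.9), ("A", "Z", 0.9)])
        net = build_network(edges, {"A", "B"})
        assert net.number_of_edges() == 0


class TestSummaryStats:
    @pytest.mark.parametrize("n,e,avg", [(236, 129, 1.09), (204, 101, 0.99)])
    def test_average_degree_as_printed(self, n, e, avg):
        net = nx.gnm_random_graph(n, e, seed=0)
        stats = summary_stats(net)
        assert stats["n_nodes"] == n and stats["n_edges"] == e
        assert stats["average_degree"] == avg

    def test_percent_connected_truncates_as_printed(self):
        # 32 of 61 proteins connected prints as 52.45%
        net = nx.Graph()
        net.add_nodes_from(range(61))
        for i in range(0, 32, 2):
            net.add_edge(i, i + 1)
        assert summary_stats(net)["percent_connected"] == 52.45

    def test_empty_network(self):
        assert summary_stats(nx.Graph())["average_degree"] == 0.0


class TestBiggestComponent:
    def test_largest_by_node_count(self):
        g = nx.Graph()
        g.add_edges_from((f"a{i}", f"a{i+1}") for i in range(16))  # 17 nodes
        g.add_edges_from([("x", "y"), ("y", "z")])
        assert biggest_component(g).number_of_nodes() == 17

    def test_connected_graph_identity(self):
        g = nx.complete_graph(5)
        assert set(biggest_component(g).nodes) == set(g.nodes)

    def test_tie_break_lexicographic(self):
        g = nx.Graph()
        g.add_edge("C", "D")
        g.add_edge("A", "B")
        assert set(biggest_component(g).nodes) == {"A", "B"}


class TestCentralities:
    def test_path_graph_hand_values(self):
        g = nx.Graph([("A", "B"), ("B", "C")])
        rec = centralities(g)
        assert rec.loc["B", "betweenness"] == pytest.approx(1.0)
        assert rec.loc["B", "bridging_coefficient"] == pytest.approx(0.25)
        assert rec.loc["B", "bridging"] == pytest.approx(0.25)
        assert rec.loc["A", "betweenness"] == 0.0
        assert rec.loc["B", "closeness"] == pytest.approx(1.0)
        assert rec.loc["A", "closeness"] == pytest.approx(2 / 3)

    def test_clique_member_brokering_zero(self):
        g = nx.complete_graph(4)
        rec = centralities(g)
        assert (rec["clustering"] == 1.0).all()
        assert (rec["brokering"] == 0.0).all()

    def test_disconnected_input_rejected(self):
        g = nx.Graph([("A", "B"), ("C", "D")])
        with pytest.raises(ValueError, match="connected"):
            centralities(g)

    @pytest.mark.parametrize("sib,gene,degree,clustering,expected", PRINTED_CENTRALITY_ROWS)
    def test_brokering_reproduces_printed_table(self, sib, gene, degree, clustering, expected):
        n = COMPONENT_SIZE[sib]
        assert round(brokering_score(degree, clustering, n), 3) == expected

    def test_brokering_bounded_by_normalized_degree(self):
        g = nx.gnp_random_graph(9, 0.4, seed=3)
        g = g.subgraph(max(nx.connected_components(g), key=len)).copy()
        rec = centralities(g)
        n = g.number_of_nodes()
        assert (rec["brokering"] <= rec["degree"] / (n - 1) + 1e-12).all()

    def test_agrees_with_brute_force_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = int(rng.integers(4, 13))
            g = nx.gnp_random_graph(n, 0.45, seed=int(rng.integers(2**31)))
            comp = g.subgraph(max(nx.connected_components(g), key=len)).copy()
            if comp.number_of_nodes() < 2:
                continue
            rec = centralities(comp)
            bf_b = brute_force_betweenness(comp)
            bf_c = brute_force_closeness(comp)
            bf_k = brute_force_clustering(comp)
            for v in comp.nodes:
                assert rec.loc[v, "betweenness"] == pytest.approx(bf_b[v], abs=1e-9)
                assert rec.loc[v, "closeness"] == pytest.approx(bf_c[v], abs=1e-9)
                assert rec.loc[v, "clustering"] == pytest.approx(bf_k[v], abs=1e-9)

    def test_betweenness_sum_equals_interior_path_mass(self):
        g = nx.gnp_random_graph(8, 0.5, seed=5)
        comp = g.subgraph(max(nx.connected_components(g), key=len)).copy()
        rec = centralities(comp)
        total = 0.0
        for s, t in itertools.combinations(sorted(comp.nodes), 2):
            paths = list(nx.all_shortest_paths(comp, s, t))
            total += sum(len(p) - 2 for p in paths) / len(paths)
        assert rec["betweenness"].sum() == pytest.approx(total)


class TestRoles:
    def test_degenerate_equal_scores_all_qualify(self):
        g = nx.cycle_graph(6)
        rec = classify_roles(centralities(g))
        assert (rec["role"] == "both").all()

    def test_single_maximal_broker(self):
        g, _ = two_cliques_with_bridge(5)
        g.add_edge("HUB", "L1")
        for i in range(6):
            g.add_edge("HUB", f"S{i}")  # spokes: high degree, no triangles
        rec = classify_roles(centralities(g))
        top = rec["brokering"].idxmax()
        assert top == "HUB"
        assert rec.loc["HUB", "role"] in ("broker", "both")

    def test_planted_bridge_maximal_bridging(self):
        g, bridge = two_cliques_with_bridge(10)
        rec = centralities(g)
        assert rec["bridging"].idxmax() == bridge
        roles = classify_roles(rec)
        assert roles.loc[bridge, "role"] in ("bridge", "both")

    def test_broker_count_bounded_on_distinct_scores(self):
        rng = np.random.default_rng(2)
        g = nx.gnp_random_graph(40, 0.12, seed=9)
        comp = g.subgraph(max(nx.connected_components(g), key=len)).copy()
        rec = classify_roles(centralities(comp))
        n = len(rec)
        brokering = rec["brokering"].to_numpy()
        n_brokers = (rec["role"].isin(["broker", "both"])).sum()
        ties = (brokering == np.percentile(brokering, 95)).sum()
        assert 1 <= n_brokers <= int(np.ceil(0.05 * n)) + ties


class TestCompare:
    def test_study_scale_counts(self):
        a = {f"g{i}" for i in range(82)}
        b = {f"g{i}" for i in range(46)} | {f"h{i}" for i in range(22)}
        out = compare_components(a, b)
        assert len(out["shared"]) == 46
        assert len(out["exclusive_a"]) == 36
        assert len(out["exclusive_b"]) == 22

    def test_identical_sets(self):
        out = compare_components({"A", "B"}, {"A", "B"})
        assert out["exclusive_a"] == set() == out["exclusive_b"]

    def test_disjoint_sets(self):
        out = compare_components({"A"}, {"B"})
        assert out["shared"] == set()
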