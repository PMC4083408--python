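import json

import networkx as nx
import numpy as np
import pytest

from structppi.errors import FormatError, StructPPIError
from structppi.network import (NetworkEdge, annotate_and_summarize,
                               compute_degrees, export_network, load_edge_list,
                               load_protein_list, to_graph)
from structppi.synthetic import make_network_fixture


@pytest.fixture(scope="module")
def fixture_files(tmp_path_factory):
    d = tmp_path_factory.mktemp("net")
    proteins, edges = make_network_fixture(rng_seed=7)
    (d / "proteins.csv").write_text(proteins)
    (d / "edges.csv").write_text(edges)
    return d


class TestLoadProteinList:
    def test_three_rows(self, tmp_path):
        p = tmp_path / "p.csv"
        p.write_text("protein,degree\nIL10,0\nIL10RA,1\nA2M,1\n")
        assert load_protein_list(p) == [("IL10", 0), ("IL10RA", 1), ("A2M", 1)]

    def test_duplicate_collapsed(self, tmp_path):
        p = tmp_path / "p.csv"
        p.write_text("protein,degree\nIL10,0\nIL10,0\n")
        assert load_protein_list(p) == [("IL10", 0)]

    def test_empty_errors(self, tmp_path):
        p = tmp_path / "p.csv"
        p.write_text("protein,degree\n")
        with pytest.raises(FormatError):
            load_protein_list(p)


class TestLoadEdgeList:
    def test_threshold_is_strict(self, tmp_path):
        p = tmp_path / "e.csv"
        p.write_text("a,b,confidence\nX,Y,0.4\nX,Z,0.401\n")
        edges = load_edge_list(p)
        assert [(e.a, e.b) for e in edges] == [("X", "Z")]

    def test_below_threshold_dropped(self, tmp_path):
        p = tmp_path / "e.csv"
        p.write_text("a,b,confidence\nX,Y,0.9\nX,Z,0.39\n")
        assert len(load_edge_list(p)) == 1

    def test_undirected_dedup_keeps_max(self, tmp_path):
        p = tmp_path / "e.csv"
        p.write_text("a,b,confidence\nA,B,0.5\nB,A,0.7\n")
        edges = load_edge_list(p)
        assert len(edges) == 1
        assert edges[0].confidence == 0.7

    def test_self_loop_dropped(self, tmp_path):
        p = tmp_path / "e.csv"
        p.write_text("a,b,confidence\nA,A,0.9\nA,B,0.9\n")
        assert len(load_edge_list(p)) == 1

    def test_non_numeric_confidence_errors(self, tmp_path):
        p = tmp_path / "e.csv"
        p.write_text("a,b,confidence\nA,B,high\n")
        with pytest.raises(FormatError):
            load_edge_list(p)


def brute_force_distances(graph, seed):
    """All-pairs oracle: BFS by repeated adjacency expansion."""
    nodes = sorted(graph.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    A = np.zeros((len(nodes), len(nodes)), dtype=bool)
    for u, v in graph.edges:
        A[idx[u], idx[v]] = A[idx[v], idx[u]] = True
    dist = {seed: 0}
    frontier = np.zeros(len(nodes), dtype=bool)
    frontier[idx[seed]] = True
    seen = frontier.copy()
    d = 0
    while frontier.any():
        d += 1
        frontier = (A[frontier].any(axis=0)) & ~seen
        for i in np.flatnonzero(frontier):
            dist[nodes[i]] = d
        seen |= frontier
    return {n: dist.get(n) for n in nodes}


class TestComputeDegrees:
    def test_star_fixture_shells(self, fixture_files):
        edges = load_edge_list(fixture_files / "edges.csv")
        g = to_graph(None, edges)
        degrees = compute_degrees(g, "IL10")
        counts = {}
        for v in degrees.values():
            counts[v] = counts.get(v, 0) + 1
        assert counts[0] == 1
        assert counts[1] == 4
        assert counts[2] == 44  # one listed protein is only weakly attached

    def test_agrees_with_all_pairs_oracle(self, fixture_files):
        edges = load_edge_list(fixture_files / "edges.csv")
        g = to_graph(None, edges)
        assert compute_degrees(g, "IL10") == brute_force_distances(g, "IL10")

    def test_disconnected_node_flagged(self):
        g = nx.Graph()
        g.add_edge("S", "X")
        g.add_node("LONER")
        degrees = compute_degrees(g, "S")
        assert degrees["LONER"] is None

    def test_missing_seed_errors(self):
        g = nx.Graph()
        g.add_edge("A", "B")
        with pytest.raises(StructPPIError):
            compute_degrees(g, "NOPE")

    def test_declared_degrees_match_computed(self, fixture_files):
        proteins = load_protein_list(fixture_files / "proteins.csv")
        edges = load_edge_list(fixture_files / "edges.csv")
        degrees = compute_degrees(to_graph(None, edges), "IL10")
        for protein, declared in proteins:
            if degrees.get(protein) is not None:
                assert degrees[protein] == declared


def small_edges():
    return [NetworkEdge(*ab, confidence=0.9) for ab in
            [("S", "A"), ("S", "B"), ("A", "C"), ("A", "D"), ("B", "D"),
             ("C", "D"), ("B", "C")]]


class TestAnnotateAndSummarize:
    def test_status_counts(self):
        preds = {("A", "C"): object(), ("A", "D"): object(), ("B", "C"): object()}
        known = {("S", "A"), ("S", "B")}
        net = annotate_and_summarize(None, small_edges(), "S",
                                     predictions=preds, known_complexes=known)
        assert net.summary == {"nodes": 5, "edges": 7, "known": 2,
                               "modeled": 3, "unmodeled": 2}
        assert net.summary["known"] + net.summary["modeled"] + \
            net.summary["unmodeled"] == net.summary["edges"]

    def test_known_takes_precedence_over_modeled(self):
        net = annotate_and_summarize(None, small_edges(), "S",
                                     predictions={("S", "A"): object()},
                                     known_complexes={("S", "A")})
        edge = next(e for e in net.edges if e.key == ("A", "S"))
        assert edge.status == "known-complex"

    def test_no_predictions_leaves_unmodeled(self):
        net = annotate_and_summarize(None, small_edges(), "S",
                                     known_complexes={("S", "A")})
        assert net.summary["modeled"] == 0
        assert net.summary["unmodeled"] == 6

    def test_empty_network_errors(self):
        with pytest.raises(StructPPIError):
            annotate_and_summarize(None, [], "S")

    def test_prediction_for_missing_edge_ignored(self, caplog):
        net = annotate_and_summarize(None, small_edges(), "S",
                                     predictions={("S", "ZZ"): object()})
        assert net.summary["modeled"] == 0


class TestExport:
    def test_graphml_round_trip(self, tmp_path):
        net = annotate_and_summarize(None, small_edges(), "S")
        p = tmp_path / "n.graphml"
        export_network(net, p, "graphml")
        g = nx.read_graphml(p)
        assert g.number_of_nodes() == 5
        assert g.number_of_edges() == 7

    def test_tsv_row_count(self, tmp_path):
        net = annotate_and_summarize(None, small_edges(), "S")
        p = tmp_path / "n.tsv"
        export_network(net, p, "tsv")
        assert len(p.read_text().strip().splitlines()) == 1 + 7

    def test_json_summary_matches_memory(self, tmp_path):
        net = annotate_and_summarize(None, small_edges(), "S")
        p = tmp_path / "n.json"
        export_network(net, p, "json-report")
        assert json.loads(p.read_text())["summary"] == net.summary

    def test_unknown_format_errors(self, tmp_path):
        net = annotate_and_summarize(None, small_edges(), "S")
        with pytest.raises(ValueError):
            export_network(net, tmp_path / "x", "xlsx")
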