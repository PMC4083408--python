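"""Seed-centered structural PPI network: loading, annotation, summary, export.

The network is an undirected graph around a seed protein (first- and
second-degree neighbors).  Edges carry an interaction confidence in [0, 1] and
a structural status: *known-complex* (an experimental complex structure
exists), *modeled* (the prediction engine produced a pose), or *unmodeled*.
Edge lists are filtered at a strict confidence threshold (> 0.4 by default,
the conventional default confidence of interaction databases).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .docking import PredictedComplex
from .errors import FormatError, StructPPIError

log = logging.getLogger(__name__)

CONFIDENCE_THRESHOLD = 0.4


@dataclass
class NetworkNode:
    protein: str
    degree_from_seed: int | None  # None = unreachable from the seed
    structure_status: str = "none"  # experimental | homology-model | none
    representatives: list[str] = field(default_factory=list)


@dataclass
class NetworkEdge:
    a: str
    b: str
    confidence: float
    status: str = "unmodeled"  # known-complex | modeled | unmodeled
    best_prediction: PredictedComplex | None = None

    @property
    def key(self) -> tuple[str, str]:
        return tuple(sorted((self.a, self.b)))


@dataclass
class StructuralNetwork:
    seed: str
    nodes: dict[str, NetworkNode]
    edges: list[NetworkEdge]
    summary: dict[str, int]

    def recompute_summary(self) -> dict[str, int]:
        counts = {"nodes": len(self.nodes), "edges": len(self.edges),
                  "known": 0, "modeled": 0, "unmodeled": 0}
        for e in self.edges:
            if e.status == "known-complex":
                counts["known"] += 1
            elif e.status == "modeled":
                counts["modeled"] += 1
            else:
                counts["unmodeled"] += 1
        return counts


def load_protein_list(path) -> list[tuple[str, int]]:
    """(protein, declared degree-of-contiguity) rows; duplicates collapsed."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    lower = {c.lower(): c for c in df.columns}
    pcol = next((lower[c] for c in ("protein", "gene", "name") if c in lower), None)
    dcol = next((lower[c] for c in ("degree", "degree_from_seed", "contiguity")
                 if c in lower), None)
    if pcol is None or dcol is None:
        raise FormatError(f"{path}: need protein and degree columns")
    if df.empty:
        raise FormatError(f"{path}: empty protein list")
    out: dict[str, int] = {}
    for row in df.itertuples():
        protein = str(getattr(row, pcol)).strip()
        degree = int(getattr(row, dcol))
        if protein in out:
            log.warning("DUPLICATE-PROTEIN %s collapsed", protein)
            continue
        out[protein] = degree
    return list(out.items())


def load_edge_list(path, confidence_threshold: float = CONFIDENCE_THRESHOLD
                   ) -> list[NetworkEdge]:
    """Undirected edges with confidence strictly greater than the threshold.

    Self-loops are dropped with a warning; (a,b)/(b,a) duplicates collapse to
    one edge keeping the maximum confidence.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    lower = {c.lower(): c for c in df.columns}
    try:
        acol, bcol = lower["a"], lower["b"]
        ccol = next(lower[c] for c in ("confidence", "score") if c in lower)
    except (KeyError, StopIteration):
        raise FormatError(f"{path}: need columns a, b, confidence")
    best: dict[tuple[str, str], float] = {}
    for row in df.itertuples():
        a = str(getattr(row, acol)).strip()
        b = str(getattr(row, bcol)).strip()
        try:
            conf = float(getattr(row, ccol))
        except (TypeError, ValueError):
            raise FormatError(f"{path}: non-numeric confidence for ({a}, {b})")
        if a == b:
            log.warning("SELF-LOOP %s dropped", a)
            continue
        if conf <= confidence_threshold:  # strictly-greater-than filter
            continue
        key = tuple(sorted((a, b)))
        best[key] = max(best.get(key, 0.0), conf)
    return [NetworkEdge(a=k[0], b=k[1], confidence=v) for k, v in sorted(best.items())]


def to_graph(proteins: list[tuple[str, int]] | None, edges: list[NetworkEdge]) -> nx.Graph:
    g = nx.Graph()
    if proteins:
        for p, d in proteins:
            g.add_node(p, declared_degree=d)
    for e in edges:
        g.add_edge(e.a, e.b, confidence=e.confidence)
    return g


def compute_degrees(graph: nx.Graph, seed: str) -> dict[str, int | None]:
    """BFS distance from the seed; unreachable nodes map to None (flagged)."""
    if seed not in graph:
        raise StructPPIError(f"seed {seed!r} absent from the network")
    dist = nx.single_source_shortest_path_length(graph, seed)
    out: dict[str, int | None] = {}
    for node in graph.nodes:
        if node in dist:
            out[node] = dist[node]
        else:
            log.warning("UNREACHABLE %s flagged (no path from seed)", node)
            out[node] = None
    return out


def annotate_and_summarize(proteins: list[tuple[str, int]],
                           edges: list[NetworkEdge], seed: str,
                           predictions: dict[tuple[str, str], PredictedComplex]
                           | None = None,
                           known_complexes: set[tuple[str, str]] | None = None,
                           structure_status: dict[str, str] | None = None,
                           ) -> StructuralNetwork:
    """Assemble the annotated network; summary recomputed from scratch.

    Unreachable (structureless / filtered-out) proteins are excluded from the
    final node set but reported via warnings.  known-complex status takes
    precedence over modeled.
    """
    if not edges:
        raise StructPPIError("cannot assemble an empty network")
    predictions = {tuple(sorted(k)): v for k, v in (predictions or {}).items()}
    known = {tuple(sorted(k)) for k in (known_complexes or set())}
    graph = to_graph(proteins, edges)
    degrees = compute_degrees(graph, seed)
    edge_keys = {e.key for e in edges}
    for key in predictions:
        if key not in edge_keys:
            log.warning("PREDICTION-IGNORED %s is not a network edge", key)
    for e in edges:
        if e.key in known:
            e.status = "known-complex"
        elif e.key in predictions:
            e.status = "modeled"
            e.best_prediction = predictions[e.key]
        else:
            e.status = "unmodeled"
    nodes = {}
    for protein, degree in sorted(degrees.items()):
        if degree is None:
            continue
        nodes[protein] = NetworkNode(
            protein=protein, degree_from_seed=degree,
            structure_status=(structure_status or {}).get(protein, "none"))
    net = StructuralNetwork(seed=seed, nodes=nodes, edges=list(edges), summary={})
    net.summary = net.recompute_summary()
    return net


def export_network(network: StructuralNetwork, path, format: str = "graphml") -> None:
    """Write GraphML (node/edge attributes), TSV edge list, or JSON summary."""
    if format == "graphml":
        g = nx.Graph()
        for n in network.nodes.values():
            g.add_node(n.protein, degree_from_seed=n.degree_from_seed,
                       structure_status=n.structure_status)
        for e in network.edges:
            g.add_edge(e.a, e.b, confidence=e.confidence, status=e.status)
        nx.write_graphml(g, path)
    elif format == "tsv":
        lines = ["a\tb\tconfidence\tstatus"]
        for e in network.edges:
            lines.append(f"{e.a}\t{e.b}\t{e.confidence:.3f}\t{e.status}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
    elif format == "json-report":
        report = {"seed": network.seed, "summary": network.summary,
                  "degrees": {n.protein: n.degree_from_seed
                              for n in network.nodes.values()}}
        with open(path, "w") as fh:
            json.dump(report, fh, indent=1)
    else:
        raise ValueError(f"unknown export format {format!r}")
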