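"""Signed correlation networks: filtering scored pairs and graph IO.

An edge survives only if the evidence is strong (both directional scores
and their mean beyond ``minlogp`` in absolute value, with a common sign)
and the effect is large (both conditional frequencies shifted beyond the
``delta_f`` band: above 1−Δf for correlated pairs, below Δf for
anti-correlated ones).  Pairs whose two directions disagree in sign are
statistically pathological and are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx

from .scoring import CorrelationEdge, ResidueNode

__all__ = ["CorrelationNetwork", "build_network", "write_graph", "read_graph"]


@dataclass
class CorrelationNetwork:
    """A signed, weighted, undirected residue correlation network.

    ``graph`` is a networkx Graph whose nodes are vertex labels (e.g.
    ``"G71"``) with ``column``/``residue``/``count``/``frequency``
    attributes, and whose edges carry the signed mean score as ``weight``
    plus both directional scores and conditional frequencies.
    """

    graph: nx.Graph
    minlogp: float
    delta_f: float

    @property
    def vertices(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_weights(self) -> dict[tuple[str, str], float]:
        return {
            (u, v): d["weight"] for u, v, d in self.graph.edges(data=True)
        }


def _edge_passes(edge: CorrelationEdge, minlogp: float, delta_f: float) -> bool:
    s1, s2, m = edge.score_ab, edge.score_ba, edge.mean_score
    f1, f2 = edge.freq_b_given_a, edge.freq_a_given_b
    if s1 > minlogp and s2 > minlogp and m > minlogp:
        return f1 > 1.0 - delta_f and f2 > 1.0 - delta_f
    if s1 < -minlogp and s2 < -minlogp and m < -minlogp:
        return f1 < delta_f and f2 < delta_f
    return False


def build_network(
    edges: Iterable[CorrelationEdge], minlogp: float, delta_f: float
) -> CorrelationNetwork:
    """Filter scored pairs into a signed network.

    Vertices with no surviving edge are dropped (they may still exist as
    eligible residue nodes; they simply carry no significant correlation).
    """
    if minlogp <= 0:
        raise ValueError("minlogp must be positive")
    if not (0 < delta_f < 0.5):
        raise ValueError("delta_f must be in (0, 0.5)")
    g = nx.Graph()
    for edge in edges:
        if not _edge_passes(edge, minlogp, delta_f):
            continue
        for label, node in ((edge.label_a, edge.node_a), (edge.label_b, edge.node_b)):
            g.add_node(
                label,
                column=node.column,
                residue=node.residue,
                count=node.count,
                frequency=node.frequency,
            )
        g.add_edge(
            edge.label_a,
            edge.label_b,
            weight=edge.mean_score,
            score_ab=edge.score_ab,
            score_ba=edge.score_ba,
            f_b_given_a=edge.freq_b_given_a,
            f_a_given_b=edge.freq_a_given_b,
        )
    return CorrelationNetwork(graph=g, minlogp=minlogp, delta_f=delta_f)


def _quote(label: str) -> str:
    return '"' + label.replace('"', "'") + '"'


def write_graph(
    net: CorrelationNetwork | nx.Graph, path: str | Path, format: str = "pajek"
) -> None:
    """Serialise a network as Pajek ``.net``, GraphML or a TSV edge list.

    The Pajek dialect uses 1-based vertex indices, quoted labels and signed
    weights under ``*Edges`` (the input convention of classical community
    detection tools).  An empty network yields a valid file with no edges.
    """
    g = net.graph if isinstance(net, CorrelationNetwork) else net
    path = Path(path)
    if format == "pajek":
        labels = sorted(g.nodes)
        index = {lab: i + 1 for i, lab in enumerate(labels)}
        with open(path, "w") as fh:
            fh.write(f"*Vertices {len(labels)}\n")
            for lab in labels:
                fh.write(f"{index[lab]} {_quote(lab)}\n")
            fh.write("*Edges\n")
            for u, v, d in sorted(g.edges(data=True)):
                fh.write(f"{index[u]} {index[v]} {d['weight']:.10g}\n")
    elif format == "graphml":
        h = nx.Graph()
        h.add_nodes_from(g.nodes)
        for u, v, d in g.edges(data=True):
            h.add_edge(u, v, weight=float(d["weight"]))
        nx.write_graphml(h, str(path))
    elif format == "edgelist":
        with open(path, "w") as fh:
            fh.write("source\ttarget\tweight\n")
            for u, v, d in sorted(g.edges(data=True)):
                fh.write(f"{u}\t{v}\t{d['weight']:.10g}\n")
    else:
        raise ValueError(f"unknown graph format: {format!r}")


def read_graph(path: str | Path, format: str = "pajek") -> nx.Graph:
    """Read a graph written by :func:`write_graph` (labels + weights)."""
    path = Path(path)
    if format == "graphml":
        g = nx.read_graphml(str(path))
        out = nx.Graph()
        out.add_nodes_from(g.nodes)
        for u, v, d in g.edges(data=True):
            out.add_edge(u, v, weight=float(d["weight"]))
        return out
    if format == "edgelist":
        g = nx.Graph()
        with open(path) as fh:
            next(fh)  # header
            for line in fh:
                u, v, w = line.rstrip("\n").split("\t")
                g.add_edge(u, v, weight=float(w))
        return g
    if format != "pajek":
        raise ValueError(f"unknown graph format: {format!r}")
    g = nx.Graph()
    labels: dict[int, str] = {}
    mode = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            low = line.lower()
            if low.startswith("*vertices"):
                mode = "vertices"
                continue
            if low.startswith("*edges") or low.startswith("*arcs"):
                mode = "edges"
                continue
            if mode == "vertices":
                idx, rest = line.split(None, 1)
                label = rest.strip().strip('"')
                labels[int(idx)] = label
                g.add_node(label)
            elif mode == "edges":
                a, b, w = line.split()[:3]
                g.add_edge(labels[int(a)], labels[int(b)], weight=float(w))
    return g
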