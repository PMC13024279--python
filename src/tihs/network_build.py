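"""Construction of the DEG-induced, high-confidence resistance network.

The resistance network is the subgraph of a confidence-weighted protein
interaction graph induced on the differentially expressed genes: an edge is
kept only when both endpoints are DEGs and its confidence clears the
high-confidence threshold (0.7 by default, the STRING "high confidence"
level).  By default only the largest connected component is retained, since
eigenvector centrality is ill-behaved across disconnected components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

from .io_formats import DegRecord, EdgeRecord

log = logging.getLogger("tihs")


class EmptyNetworkError(ValueError):
    """The DEG set and edge list produce no qualifying network."""


@dataclass
class ResistanceNetwork:
    """Undirected confidence-weighted graph over DEG gene symbols.

    Attributes
    ----------
    graph : networkx.Graph
        Edges carry a ``confidence`` attribute in [0, 1].
    deg_annotation : dict
        gene → :class:`~tihs.io_formats.DegRecord` for every node.
    isolated_degs : list
        DEG symbols that had no qualifying edge (excluded from topology).
    min_confidence : float
        Threshold used at construction.
    """
    graph: nx.Graph
    deg_annotation: dict[str, DegRecord]
    isolated_degs: list[str] = field(default_factory=list)
    min_confidence: float = 0.7

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def log2fc(self, gene: str) -> float:
        return self.deg_annotation[gene].log2fc


def build_network(degs: Iterable[DegRecord],
                  edges: Iterable[EdgeRecord],
                  min_confidence: float = 0.7,
                  restrict_to_lcc: bool = True) -> ResistanceNetwork:
    """Induce the resistance network on the DEG symbols.

    Parameters
    ----------
    degs
        Differential-expression records; symbols are upper-cased for matching.
    edges
        Candidate interactions with confidence in [0, 1].
    min_confidence
        Inclusive lower bound on edge confidence.
    restrict_to_lcc
        Keep only the largest connected component (ties broken toward the
        component containing the alphabetically first node).

    Raises
    ------
    EmptyNetworkError
        If no edge survives, with a diagnostic of the DEG/edge-symbol overlap.
    """
    deg_index = {d.gene.upper(): d for d in degs}
    if not deg_index:
        raise EmptyNetworkError("no DEG records supplied")

    g = nx.Graph()
    edge_symbols: set[str] = set()
    for e in edges:
        a, b = e.node_a.upper(), e.node_b.upper()
        edge_symbols.update((a, b))
        if a == b or e.confidence < min_confidence:
            continue
        if a in deg_index and b in deg_index:
            prev = g.get_edge_data(a, b)
            conf = e.confidence if prev is None else max(prev["confidence"],
                                                         e.confidence)
            g.add_edge(a, b, confidence=conf)

    if g.number_of_edges() == 0:
        overlap = len(edge_symbols & deg_index.keys())
        raise EmptyNetworkError(
            f"no edge with confidence >= {min_confidence} connects two DEGs "
            f"({len(deg_index)} DEGs, {overlap} of them appear in the edge "
            "list) — check symbol conventions and the confidence threshold")

    if restrict_to_lcc:
        components = [sorted(c) for c in nx.connected_components(g)]
        components.sort(key=lambda c: (-len(c), c[0]))
        g = g.subgraph(components[0]).copy()

    isolated = sorted(set(deg_index) - set(g.nodes))
    net = ResistanceNetwork(
        graph=g,
        deg_annotation={n: deg_index[n] for n in g.nodes},
        isolated_degs=isolated,
        min_confidence=min_confidence,
    )
    log.info("build_network: %d nodes, %d edges (%d components before LCC "
             "restriction: %s), %d isolated DEGs excluded",
             net.n_nodes, net.n_edges,
             nx.number_connected_components(g), restrict_to_lcc, len(isolated))
    return net
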