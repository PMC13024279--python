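"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library code paths they check:
betweenness is re-derived by enumerating all shortest paths, MCC by
exhaustive subset enumeration, eigenvector centrality by a dense
eigendecomposition.
"""

from __future__ import annotations

import math
from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from tihs import DegRecord, EdgeRecord, build_network
from tihs.network_build import ResistanceNetwork


def net_from_edges(edges, default_conf: float = 0.9,
                   restrict_to_lcc: bool = True) -> ResistanceNetwork:
    """Build a ResistanceNetwork from (a, b) or (a, b, conf) tuples."""
    recs = []
    nodes = set()
    for e in edges:
        a, b = e[0], e[1]
        conf = e[2] if len(e) > 2 else default_conf
        recs.append(EdgeRecord(a, b, conf))
        nodes.update((a, b))
    degs = [DegRecord(n, 1.0, 0.01) for n in sorted(nodes)]
    return build_network(degs, recs, min_confidence=0.0,
                         restrict_to_lcc=restrict_to_lcc)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def betweenness_oracle(g: nx.Graph) -> dict:
    """All-pairs shortest-path enumeration: each unordered pair contributes
    (paths through v) / (total shortest paths) to every interior node v."""
    score = {v: 0.0 for v in g}
    for s, t in combinations(g.nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(g, s, t))
        except nx.NetworkXNoPath:
            continue
        for path in paths:
            for v in path[1:-1]:
                score[v] += 1.0 / len(paths)
    return score


def mcc_oracle(g: nx.Graph) -> dict:
    """Exhaustive subset enumeration of maximal cliques (graphs <= ~10 nodes)."""
    nodes = list(g.nodes)
    maximal = []
    for r in range(1, len(nodes) + 1):
        for subset in combinations(nodes, r):
            if not all(g.has_edge(a, b) for a, b in combinations(subset, 2)):
                continue
            s = set(subset)
            if any(all(g.has_edge(u, w) for w in s) for u in set(nodes) - s):
                continue       # extendable, not maximal
            maximal.append(s)
    score = {v: 0 for v in nodes}
    for clique in maximal:
        contrib = math.factorial(len(clique) - 1)
        for v in clique:
            score[v] += contrib
    return score


def eigenvector_oracle(g: nx.Graph) -> dict:
    """Dense eigendecomposition of the binary adjacency matrix."""
    nodes = list(g.nodes)
    a = nx.to_numpy_array(g, nodelist=nodes, weight=None)
    vals, vecs = np.linalg.eigh(a)
    v = np.abs(vecs[:, np.argmax(vals)])
    v /= np.linalg.norm(v)
    return dict(zip(nodes, v))


def connected_graphs(n: int):
    """Yield every connected labeled graph on exactly n nodes."""
    all_edges = list(combinations(range(n), 2))
    for r in range(n - 1, len(all_edges) + 1):
        for subset in combinations(all_edges, r):
            g = nx.Graph()
            g.add_nodes_from(range(n))
            g.add_edges_from(subset)
            if nx.is_connected(g):
                yield g


def random_connected_graph(n: int, p: float, rng) -> nx.Graph:
    while True:
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(0, 2**31)))
        if g.number_of_edges() and nx.is_connected(g):
            return g


@pytest.fixture
def triangle_net() -> ResistanceNetwork:
    return net_from_edges([("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture
def path_net() -> ResistanceNetwork:
    return net_from_edges([("A", "B"), ("B", "C")])


@pytest.fixture
def star5_net() -> ResistanceNetwork:
    return net_from_edges([("HUB", f"L{i}") for i in range(1, 6)])
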