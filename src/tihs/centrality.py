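"""The five raw node centralities: degree, betweenness, eigenvector, MCC, EPC.

All metrics are returned *unnormalised* (raw counts, raw shortest-path
totals, factorial clique sums): the downstream Z-score transform absorbs any
per-metric affine normalisation, so the raw convention is both the simplest
and provably inconsequential for the composite hubness score.

Metric definitions
------------------
degree       number of incident edges.
betweenness  shortest-path betweenness on the unweighted graph, each
             unordered pair counted once (edge confidence is ignored here).
eigenvector  principal eigenvector of the binary adjacency matrix,
             L2-normalised, computed by power iteration.
mcc          Maximal Clique Centrality: sum over all maximal cliques C
             containing the node of (|C| - 1)!  (the CytoHubba definition).
epc          Edge Percolated Component: for each Monte-Carlo realisation a
             threshold t ~ U(0,1) is drawn and every edge with
             confidence < t is deleted; the node's score in that realisation
             is the fraction of the network it can still reach (itself
             included), and EPC is the average over realisations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .network_build import ResistanceNetwork

log = logging.getLogger("tihs")

#: fixed metric order used throughout the package
METRICS = ("degree", "betweenness", "eigenvector", "mcc", "epc")


@dataclass
class CentralityMatrix:
    """Nodes × metrics matrix of raw centrality values X_ij."""
    nodes: list[str]
    values: np.ndarray                       # shape (n_nodes, 5), all >= 0
    metrics: tuple[str, ...] = METRICS
    epc_seed: int | None = None
    epc_realizations: int = 1000

    def column(self, metric: str) -> np.ndarray:
        return self.values[:, self.metrics.index(metric)]

    def as_dict(self, metric: str) -> dict[str, float]:
        col = self.column(metric)
        return {n: float(v) for n, v in zip(self.nodes, col)}


def degree_centrality(net: ResistanceNetwork) -> dict[str, int]:
    """Raw degree (edge count) per node."""
    return {n: d for n, d in net.graph.degree()}


def betweenness_centrality(net: ResistanceNetwork) -> dict[str, float]:
    """Unnormalised shortest-path betweenness on the unweighted graph."""
    return nx.betweenness_centrality(net.graph, normalized=False, weight=None)


def eigenvector_centrality(net: ResistanceNetwork,
                           tol: float = 1e-10,
                           max_iter: int = 10_000) -> dict[str, float]:
    """Principal eigenvector of the binary adjacency matrix (power iteration).

    Starts from the uniform vector and iterates on the shifted matrix A + I,
    which shares A's eigenvectors but makes the principal eigenvalue strictly
    dominant even on bipartite graphs (where plain power iteration
    oscillates); stops when the L2 change falls below ``tol``.  By
    Perron–Frobenius the limit is entrywise nonnegative on a connected graph.

    Raises
    ------
    RuntimeError
        If convergence is not reached within ``max_iter`` iterations.
    """
    nodes = list(net.graph.nodes)
    a = nx.to_numpy_array(net.graph, nodelist=nodes, weight=None)
    x = np.full(len(nodes), 1.0 / math.sqrt(len(nodes)))
    for _ in range(max_iter):
        y = a @ x + x                  # (A + I) x: same eigenvectors as A
        norm = np.linalg.norm(y)
        if norm == 0.0:            # edgeless graph; define as uniform
            break
        y /= norm
        if np.linalg.norm(y - x) < tol:
            x = y
            break
        x = y
    else:
        raise RuntimeError(
            f"eigenvector centrality did not converge in {max_iter} "
            "iterations; increase max_iter")
    x = np.abs(x)                  # orientation: nonnegative entries
    x /= np.linalg.norm(x)
    return {n: float(v) for n, v in zip(nodes, x)}


def mcc(net: ResistanceNetwork, max_cliques: int = 1_000_000) -> dict[str, int]:
    """Maximal Clique Centrality: MCC(v) = Σ_{C ∋ v} (|C| − 1)!.

    Maximal cliques are enumerated exactly (Bron–Kerbosch).  ``max_cliques``
    guards against factorial blow-up on pathological dense graphs.
    """
    scores = {n: 0 for n in net.graph.nodes}
    count = 0
    for clique in nx.find_cliques(net.graph):
        count += 1
        if count > max_cliques:
            raise RuntimeError(
                f"more than {max_cliques} maximal cliques; raise max_cliques "
                "if this is intended")
        contrib = math.factorial(len(clique) - 1)
        for v in clique:
            scores[v] += contrib
    return scores


def epc(net: ResistanceNetwork,
        realizations: int = 1000,
        seed: int | None = None) -> dict[str, float]:
    """Edge Percolated Component via Monte-Carlo edge percolation.

    For realisation k a global threshold t_k ~ Uniform(0, 1) is drawn and
    every edge with ``confidence < t_k`` (strict) is deleted, so an edge with
    confidence 1.0 always survives.  The per-node score is the reachable
    fraction of the network, averaged over realisations; deterministic for a
    fixed seed.

    Implementation note: realisations are processed in decreasing threshold
    order with an incremental union–find, so each edge is united exactly once
    over the whole sweep.
    """
    if realizations < 1:
        raise ValueError("realizations must be >= 1")
    nodes = list(net.graph.nodes)
    n = len(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    rng = np.random.default_rng(seed)
    thresholds = np.sort(rng.random(realizations))[::-1]   # descending

    edges = sorted(((d["confidence"], index[a], index[b])
                    for a, b, d in net.graph.edges(data=True)), reverse=True)

    parent = list(range(n))
    size = [1] * n

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    totals = np.zeros(n)
    e = 0
    for t in thresholds:
        while e < len(edges) and edges[e][0] >= t:
            _, i, j = edges[e]
            ri, rj = find(i), find(j)
            if ri != rj:
                if size[ri] < size[rj]:
                    ri, rj = rj, ri
                parent[rj] = ri
                size[ri] += size[rj]
            e += 1
        for i in range(n):
            totals[i] += size[find(i)]
    scores = totals / (realizations * n)
    return {v: float(scores[index[v]]) for v in nodes}


def compute_all(net: ResistanceNetwork,
                epc_realizations: int = 1000,
                seed: int | None = None) -> CentralityMatrix:
    """Compute all five metrics and assemble the nodes × metrics matrix.

    Row order equals the network's node order; column order is
    :data:`METRICS`.  The EPC seed and realisation count are recorded in the
    result for provenance.
    """
    nodes = list(net.graph.nodes)
    per_metric = {
        "degree": degree_centrality(net),
        "betweenness": betweenness_centrality(net),
        "eigenvector": eigenvector_centrality(net),
        "mcc": mcc(net),
        "epc": epc(net, realizations=epc_realizations, seed=seed),
    }
    values = np.array([[float(per_metric[m][v]) for m in METRICS]
                       for v in nodes])
    log.info("compute_all: %d nodes x %d metrics, epc_realizations=%d seed=%s",
             len(nodes), len(METRICS), epc_realizations, seed)
    return CentralityMatrix(nodes=nodes, values=values, epc_seed=seed,
                            epc_realizations=epc_realizations)
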