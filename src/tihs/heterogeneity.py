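"""Resistance-shift heterogeneity across models.

Builds a genes × models matrix of log2 fold changes restricted to genes
shared by every model, then summarises between-model structure by PCA on
the model-level shift vectors (centred, unscaled), pairwise Pearson
correlation across genes, complete-linkage clustering on 1 − r distance,
and a gene-level bootstrap of the PCA embedding that quantifies how stable
the model separation is under resampling of genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io_formats import DegRecord

log = logging.getLogger("tihs")


@dataclass
class ShiftMatrix:
    """genes × models log2FC matrix over the shared gene set."""
    genes: list[str]
    models: list[str]
    values: np.ndarray            # shape (n_genes, n_models), no missing

    def __post_init__(self) -> None:
        if len(self.genes) < 3 or len(self.models) < 2:
            raise ValueError("need >= 3 shared genes and >= 2 models")


@dataclass
class PcaResult:
    models: list[str]
    coordinates: np.ndarray       # models × components scores
    explained: np.ndarray         # variance fractions, sums to 1
    loadings: np.ndarray          # genes × components


def build_shift_matrix(deg_tables: Mapping[str, Sequence[DegRecord]]
                       ) -> ShiftMatrix:
    """Intersect the models' gene sets and assemble their log2FC columns.

    Genes are sorted alphabetically for determinism.  Only genes present in
    every model are retained (no imputation); an empty intersection is a
    hard error.
    """
    if len(deg_tables) < 2:
        raise ValueError("need at least 2 models")
    models = list(deg_tables)
    indexes = {m: {d.gene.upper(): d.log2fc for d in deg_tables[m]}
               for m in models}
    shared = set.intersection(*(set(ix) for ix in indexes.values()))
    if not shared:
        raise ValueError("no gene is shared by all models")
    genes = sorted(shared)
    values = np.array([[indexes[m][g] for m in models] for g in genes])
    log.info("build_shift_matrix: %d shared genes x %d models",
             len(genes), len(models))
    return ShiftMatrix(genes=genes, models=models, values=values)


def _align_pc_signs(loadings: np.ndarray, scores: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray]:
    # orient each PC so its largest-|loading| variable is positive
    for k in range(loadings.shape[1]):
        j = int(np.argmax(np.abs(loadings[:, k])))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1
    return loadings, scores


def pca_models(m: ShiftMatrix) -> PcaResult:
    """PCA with models as observations and genes as variables.

    Gene columns are centred but not scaled (prcomp(center=TRUE,
    scale=FALSE) semantics); components are sign-aligned so the
    largest-|loading| gene on each PC is positive.
    """
    x = m.values.T                              # models × genes
    centred = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    scores = u * s
    loadings = vt.T
    loadings, scores = _align_pc_signs(loadings, scores)
    var = s ** 2
    explained = var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    return PcaResult(models=list(m.models), coordinates=scores,
                     explained=explained, loadings=loadings)


def pairwise_pearson(m: ShiftMatrix) -> np.ndarray:
    """models × models Pearson correlation computed across genes.

    A zero-variance model column yields NaN entries with a warning rather
    than an error.
    """
    x = m.values
    sd = x.std(axis=0)
    if np.any(sd == 0):
        log.warning("pairwise_pearson: %d zero-variance model column(s); "
                    "their correlations are reported as NaN",
                    int(np.sum(sd == 0)))
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(x, rowvar=False)
    else:
        corr = np.corrcoef(x, rowvar=False)
    np.fill_diagonal(corr, 1.0)
    return corr


def cluster_models(corr: np.ndarray) -> np.ndarray:
    """Complete-linkage hierarchical clustering on 1 − r distance.

    Returns the scipy linkage matrix (merge list with heights).
    """
    corr = np.asarray(corr, dtype=float)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    return hierarchy.linkage(condensed, method="complete")


def linkage_to_newick(link: np.ndarray, labels: Sequence[str]) -> str:
    """Serialise a scipy linkage matrix to a Newick string with branch lengths."""
    tree = hierarchy.to_tree(link)

    def walk(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)});"


def bootstrap_pca(m: ShiftMatrix,
                  iterations: int = 500,
                  seed: int | None = None,
                  n_components: int = 2) -> np.ndarray:
    """Gene-level bootstrap of the PCA embedding.

    Each iteration resamples genes (rows) with replacement, recomputes the
    model-level PCA, and sign-aligns each component against the reference
    embedding (sign chosen to maximise agreement with the reference scores,
    preventing artificial bimodality from eigenvector sign flips).

    Returns an array of shape (iterations, n_models, n_components).
    """
    if iterations < 10:
        raise ValueError("iterations must be >= 10")
    reference = pca_models(m).coordinates
    rng = np.random.default_rng(seed)
    n_genes, n_models = m.values.shape
    k = min(n_components, n_models)
    clouds = np.zeros((iterations, n_models, k))
    for it in range(iterations):
        rows = rng.integers(0, n_genes, size=n_genes)
        x = m.values[rows].T
        centred = x - x.mean(axis=0)
        u, s, _ = np.linalg.svd(centred, full_matrices=False)
        scores = (u * s)[:, :k]
        for c in range(min(k, reference.shape[1])):
            if scores[:, c] @ reference[:, c] < 0:
                scores[:, c] *= -1
        clouds[it, :, :scores.shape[1]] = scores
    return clouds
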