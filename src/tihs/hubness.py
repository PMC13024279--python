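"""Normalisation, metric weighting and the Topology-Integrated Hubness Score.

Pipeline: raw centralities X_ij are Z-scored per metric,
Z_ij = (X_ij − μ_j) / σ_j (population σ), then shifted to strict positivity,
Z′_ij = Z_ij − min_i Z_ij + 0.001, so every metric column has minimum exactly
0.001.  Metric weights W_j (probability simplex) are derived either as
standard-deviation shares of min–max-rescaled raw columns (``std_share``) or
from the absolute PC1 loadings of the Z matrix (``pca_loading``).  The
composite hubness of node i is TIHS_i = Σ_j W_j · Z′_ij.

Because Z-scoring removes location and scale, TIHS is invariant to positive
affine transformations of any raw centrality column — the property that makes
the unnormalised centrality conventions safe.

Cross-dataset stability of weight vectors is assessed by cosine similarity
against the unified (averaged) vector, with 0.98 as the conventional
stability threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .centrality import METRICS, CentralityMatrix

log = logging.getLogger("tihs")

SHIFT_EPS = 0.001


@dataclass
class MetricStats:
    metric: str
    mu: float
    sigma: float
    min_z: float


@dataclass
class NormalizedMatrix:
    """Z-scored and shifted centrality matrix."""
    nodes: list[str]
    metrics: tuple[str, ...]
    z: np.ndarray                 # column mean 0, std 1 (or all-zero)
    z_shifted: np.ndarray         # column minimum exactly SHIFT_EPS
    stats: list[MetricStats] = field(default_factory=list)


@dataclass
class WeightVector:
    """Per-metric weights on the probability simplex."""
    weights: dict[str, float]
    mode: str = "std_share"       # "std_share" | "pca_loading" | "average" | "file"
    source: str = ""

    def as_array(self, metrics: Sequence[str] = METRICS) -> np.ndarray:
        return np.array([self.weights[m] for m in metrics])

    def __post_init__(self) -> None:
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {total}")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("weights must be nonnegative")


@dataclass
class HubnessTable:
    """Per-node composite hubness, sorted best-first."""
    nodes: list[str]              # descending TIHS, ties by name
    tihs: dict[str, float]
    z_shifted: dict[str, np.ndarray]
    weights: WeightVector

    def rank_of(self, gene: str) -> int:
        return self.nodes.index(gene) + 1

    def top_fraction(self, fraction: float) -> list[str]:
        k = max(1, int(np.floor(fraction * len(self.nodes))))
        return self.nodes[:k]


@dataclass
class StabilityReport:
    sources: list[str]
    cosine: dict[str, float]
    pearson: dict[str, float]
    below_threshold: list[str]
    threshold: float = 0.98


def zscore_shift(cm: CentralityMatrix) -> NormalizedMatrix:
    """Z-score each metric column (population σ) and shift to positivity.

    Degenerate columns (σ = 0) have Z set identically to 0, hence
    Z′ = ``SHIFT_EPS`` everywhere; any other column ends up with mean 0,
    std 1 and minimum exactly ``SHIFT_EPS`` after the shift.
    """
    x = cm.values
    if x.shape[0] < 2:
        raise ValueError("need at least 2 nodes to standardise centralities")
    mu = x.mean(axis=0)
    sigma = x.std(axis=0)          # population (ddof=0)
    z = np.zeros_like(x, dtype=float)
    nz = sigma > 0
    z[:, nz] = (x[:, nz] - mu[nz]) / sigma[nz]
    min_z = z.min(axis=0)
    z_shifted = z - min_z + SHIFT_EPS
    stats = [MetricStats(m, float(mu[j]), float(sigma[j]), float(min_z[j]))
             for j, m in enumerate(cm.metrics)]
    return NormalizedMatrix(nodes=list(cm.nodes), metrics=tuple(cm.metrics),
                            z=z, z_shifted=z_shifted, stats=stats)


def _minmax_rescale(x: np.ndarray) -> np.ndarray:
    lo, hi = x.min(axis=0), x.max(axis=0)
    span = hi - lo
    out = np.zeros_like(x, dtype=float)
    nz = span > 0
    out[:, nz] = (x[:, nz] - lo[nz]) / span[nz]
    return out


def derive_weights(nm: NormalizedMatrix,
                   cm: CentralityMatrix,
                   mode: str = "std_share",
                   source: str = "") -> WeightVector:
    """Derive metric weights W_j summing to 1.

    ``std_share``
        W_j = σ_j / Σ_k σ_k where σ_j is the (population) standard deviation
        of metric j's raw column after min–max rescaling to [0, 1].  The
        rescaling makes the shares unit-free: raw columns live on wildly
        different scales (factorial MCC vs fractional EPC) and Z columns
        would force σ = 1 for every metric.
    ``pca_loading``
        PCA of the Z matrix (already column-centred and standardised);
        W_j = |PC1 loading of metric j| renormalised to sum 1.  PC1 is
        sign-aligned so its largest-|loading| metric is positive.
    """
    if mode == "std_share":
        sigma = _minmax_rescale(cm.values).std(axis=0)
        if sigma.sum() == 0:
            raise ValueError("all centrality columns are degenerate")
        w = sigma / sigma.sum()
    elif mode == "pca_loading":
        z = nm.z
        if not np.any(z.std(axis=0) > 0):
            raise ValueError("all centrality columns are degenerate")
        # right singular vectors of the centred matrix = PC loadings
        _, _, vt = np.linalg.svd(z - z.mean(axis=0), full_matrices=False)
        pc1 = vt[0]
        if pc1[np.argmax(np.abs(pc1))] < 0:
            pc1 = -pc1
        w = np.abs(pc1)
        w = w / w.sum()
    else:
        raise ValueError(f"unknown weight mode {mode!r}")
    return WeightVector(weights={m: float(v) for m, v in zip(nm.metrics, w)},
                        mode=mode, source=source)


def compute_tihs(nm: NormalizedMatrix, w: WeightVector) -> HubnessTable:
    """TIHS_i = Σ_j W_j · Z′_ij, sorted descending (ties: node name)."""
    if set(nm.metrics) != set(w.weights):
        raise ValueError(
            f"metric mismatch: matrix has {sorted(nm.metrics)}, weights have "
            f"{sorted(w.weights)}")
    wa = w.as_array(nm.metrics)
    scores = nm.z_shifted @ wa
    order = sorted(range(len(nm.nodes)),
                   key=lambda i: (-scores[i], nm.nodes[i]))
    nodes = [nm.nodes[i] for i in order]
    return HubnessTable(
        nodes=nodes,
        tihs={nm.nodes[i]: float(scores[i]) for i in range(len(nm.nodes))},
        z_shifted={n: nm.z_shifted[i] for i, n in enumerate(nm.nodes)},
        weights=w,
    )


def average_weights(vectors: Sequence[WeightVector]) -> WeightVector:
    """Arithmetic mean of weight vectors, renormalised to sum exactly 1.

    This is the "unified" vector locked for application-stage analyses after
    being derived from the training cohorts.
    """
    if not vectors:
        raise ValueError("need at least one weight vector")
    metrics = list(vectors[0].weights)
    for v in vectors[1:]:
        if set(v.weights) != set(metrics):
            raise ValueError("weight vectors have differing metric sets")
    if len({v.mode for v in vectors}) > 1:
        log.warning("average_weights: averaging vectors of mixed modes %s",
                    sorted({v.mode for v in vectors}))
    mean = {m: float(np.mean([v.weights[m] for v in vectors])) for m in metrics}
    total = sum(mean.values())
    mean = {m: w / total for m, w in mean.items()}
    return WeightVector(weights=mean, mode="average",
                        source="+".join(v.source for v in vectors))


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(a @ b / (na * nb))


def cosine_stability(vectors: Sequence[WeightVector],
                     unified: WeightVector,
                     threshold: float = 0.98) -> StabilityReport:
    """Cosine and Pearson concordance of each weight vector with the unified one.

    Vectors are unit-normalised inside the cosine; a flag lists every source
    whose cosine falls below ``threshold``.
    """
    metrics = list(unified.weights)
    u = unified.as_array(metrics)
    cos: dict[str, float] = {}
    pear: dict[str, float] = {}
    below: list[str] = []
    for i, v in enumerate(vectors):
        name = v.source or f"dataset_{i + 1}"
        w = v.as_array(metrics)
        c = cosine_similarity(w, u)
        cos[name] = c
        if np.std(w) == 0 or np.std(u) == 0:
            pear[name] = float("nan")
        else:
            pear[name] = float(np.corrcoef(w, u)[0, 1])
        if c < threshold:
            below.append(name)
    return StabilityReport(sources=list(cos), cosine=cos, pearson=pear,
                           below_threshold=below, threshold=threshold)
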