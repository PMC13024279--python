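"""Synthetic fixtures with planted ground truth.

Generates confidence-weighted interaction networks with planted hub genes,
differential-expression tables in which the planted hubs are strongly
upregulated, and drug catalogs containing planted sensitive agents
(inhibitors of upregulated hubs at nM potency), planted resistant agents
(agonists of the same hubs) and decoys (inhibitors of random non-hub genes
at weak potency).  Because the ground truth is planted explicitly, every
downstream module can be exercised offline with crisp recovery assertions.

The generator emulates the *statistical shape* of a resistance study — a
post-DE gene universe, a scale-free-ish high-confidence network, a curated
activity table — not any particular cohort's distributions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .io_formats import DegRecord, DrugTargetRecord, EdgeRecord, \
    ValidationPairRecord

log = logging.getLogger("tihs")


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic generator.

    Defaults describe a mid-sized resistance cohort: 300 genes, 8 planted
    hubs wired to 30% of the network, 6 planted sensitive and 6 planted
    resistant drugs among 72 total, hub-drug potencies at 10–100 nM versus
    micromolar decoys, background log2FC dispersion 0.6.
    """
    n_genes: int = 300
    n_hubs: int = 8
    hub_attach_fraction: float = 0.30
    edge_prob: float = 0.02
    confidence_range: tuple[float, float] = (0.70, 1.0)
    log2fc_sd: float = 0.6
    planted_fc: float = 2.0
    n_drugs: int = 72
    n_planted_sensitive: int = 6
    potency_range_nm: tuple[float, float] = (10.0, 100.0)
    decoy_potency_range_nm: tuple[float, float] = (1000.0, 10_000.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hubs >= self.n_genes:
            raise ValueError("n_hubs must be < n_genes")
        if self.planted_fc < 1.0:
            raise ValueError("planted_fc must be >= 1.0 (the DEG cutoff)")
        for lo, hi in (self.confidence_range, self.potency_range_nm,
                       self.decoy_potency_range_nm):
            if lo > hi:
                raise ValueError("ranges must be ordered (low, high)")
        if 2 * self.n_planted_sensitive > self.n_drugs:
            raise ValueError("planted sensitive+resistant drugs exceed n_drugs")


@dataclass
class PlantedTruth:
    hub_genes: set[str] = field(default_factory=set)
    sensitive_drugs: set[str] = field(default_factory=set)
    resistant_drugs: set[str] = field(default_factory=set)


def _gene_names(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(1, n + 1)]


def generate_network(cfg: SyntheticConfig
                     ) -> tuple[list[EdgeRecord], PlantedTruth]:
    """Erdős–Rényi background plus hub over-attachment, random confidences.

    Every planted hub is additionally wired to ``hub_attach_fraction`` of all
    nodes (sampled without replacement), which guarantees hub degree well
    above the background mean degree ``edge_prob · n_genes``.  Edge
    confidences are Uniform over ``confidence_range``.  Deterministic for a
    fixed ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_names(cfg.n_genes)
    hubs = set(rng.choice(genes, size=cfg.n_hubs, replace=False).tolist())

    edges: set[tuple[str, str]] = set()
    pairs = list(combinations(range(cfg.n_genes), 2))
    mask = rng.random(len(pairs)) < cfg.edge_prob
    for (i, j), keep in zip(pairs, mask):
        if keep:
            edges.add((genes[i], genes[j]))

    n_attach = int(np.floor(cfg.hub_attach_fraction * cfg.n_genes))
    for hub in sorted(hubs):
        others = [g for g in genes if g != hub]
        partners = rng.choice(others, size=n_attach, replace=False)
        for p in partners:
            a, b = (hub, p) if hub < p else (p, hub)
            edges.add((a, b))

    lo, hi = cfg.confidence_range
    out = [EdgeRecord(a, b, float(lo + (hi - lo) * rng.random()))
           for a, b in sorted(edges)]
    log.info("generate_network: %d genes, %d hubs, %d edges",
             cfg.n_genes, cfg.n_hubs, len(out))
    return out, PlantedTruth(hub_genes=hubs)


def generate_deg_table(cfg: SyntheticConfig,
                       truth: PlantedTruth) -> list[DegRecord]:
    """Background log2FC ~ N(0, log2fc_sd), padj ~ U(0, 1); hubs planted.

    Planted hubs receive log2FC = +planted_fc and padj ~ U(0, 0.01), so they
    are guaranteed to survive the conventional DEG cut (|log2FC| >= 1,
    padj < 0.05).  Mean expression is log-normal.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    out = []
    for gene in _gene_names(cfg.n_genes):
        if gene in truth.hub_genes:
            log2fc = cfg.planted_fc
            padj = float(rng.uniform(0.0, 0.01))
        else:
            log2fc = float(rng.normal(0.0, cfg.log2fc_sd))
            padj = float(rng.uniform(0.0, 1.0))
        base_expr = float(rng.lognormal(mean=3.0, sigma=1.5))
        out.append(DegRecord(gene, log2fc, padj, base_expr))
    return out


def generate_drug_table(cfg: SyntheticConfig,
                        truth: PlantedTruth
                        ) -> tuple[list[DrugTargetRecord], PlantedTruth]:
    """Plant sensitive (hub inhibitors), resistant (hub agonists) and decoys.

    Sensitive drugs hit 2–3 planted hubs at ``potency_range_nm``; an equal
    number of resistant drugs are agonists of 2–3 hubs; the remaining decoys
    are inhibitors of 1–3 random non-hub genes at ``decoy_potency_range_nm``.
    Drug names encode their role for debuggability; the pipeline never reads
    them semantically.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    hubs = sorted(truth.hub_genes)
    non_hubs = [g for g in _gene_names(cfg.n_genes)
                if g not in truth.hub_genes]
    records: list[DrugTargetRecord] = []

    def potency(r: tuple[float, float]) -> float:
        return float(rng.uniform(*r))

    k = 0
    for i in range(cfg.n_planted_sensitive):
        k += 1
        name = f"SENS{i + 1:02d}"
        truth.sensitive_drugs.add(name)
        n_t = int(rng.integers(2, min(4, len(hubs) + 1)))
        for gene in rng.choice(hubs, size=n_t, replace=False):
            records.append(DrugTargetRecord(
                f"D{k:03d}", name, str(gene), potency(cfg.potency_range_nm),
                "IC50", "KINASE INHIBITOR"))
    for i in range(cfg.n_planted_sensitive):
        k += 1
        name = f"RESI{i + 1:02d}"
        truth.resistant_drugs.add(name)
        n_t = int(rng.integers(2, min(4, len(hubs) + 1)))
        for gene in rng.choice(hubs, size=n_t, replace=False):
            records.append(DrugTargetRecord(
                f"D{k:03d}", name, str(gene), potency(cfg.potency_range_nm),
                "EC50", "FULL AGONIST"))
    n_decoys = cfg.n_drugs - 2 * cfg.n_planted_sensitive
    for i in range(n_decoys):
        k += 1
        name = f"DECOY{i + 1:02d}"
        n_t = int(rng.integers(1, 4))
        for gene in rng.choice(non_hubs, size=n_t, replace=False):
            records.append(DrugTargetRecord(
                f"D{k:03d}", name, str(gene),
                potency(cfg.decoy_potency_range_nm), "IC50", "INHIBITOR"))
    return records, truth


def generate_validation_pairs(truth: PlantedTruth,
                              ranked,
                              dataset: str = "synthetic",
                              context: str = "planted"
                              ) -> list[ValidationPairRecord]:
    """Label the planted drugs with actual and predicted effects.

    Actual effect comes from the planted truth; predicted effect from the
    sign of the ranked sensitivity score (``not_observed`` when the drug was
    excluded or unmatched).  Directly consumable by the validation suite.
    """
    by_name = {r.drug_name.upper(): r for r in ranked}
    n = len(ranked)
    pairs = []
    for name in sorted(truth.sensitive_drugs | truth.resistant_drugs):
        actual = "sensitive" if name in truth.sensitive_drugs else "resistant"
        rec = by_name.get(name.upper())
        if rec is None or rec.n_targets == 0:
            pairs.append(ValidationPairRecord(dataset, context, name, actual,
                                              "not_observed", None, None))
            continue
        predicted = ("sensitive" if rec.sensitivity_score > 0
                     else "resistant")
        pairs.append(ValidationPairRecord(dataset, context, name, actual,
                                          predicted, rec.rank, n))
    return pairs


def write_fixture_files(cfg: SyntheticConfig, out_dir) -> PlantedTruth:
    """Generate one full fixture set and write it as TSV files.

    Writes ``deg.tsv``, ``links.tsv``, ``drugs.tsv`` and ``truth.tsv`` under
    ``out_dir`` and returns the planted truth.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    edges, truth = generate_network(cfg)
    degs = generate_deg_table(cfg, truth)
    drugs, truth = generate_drug_table(cfg, truth)

    with open(out / "deg.tsv", "w") as fh:
        fh.write("gene\tlog2FoldChange\tpadj\tbaseMean\n")
        for d in degs:
            fh.write(f"{d.gene}\t{d.log2fc:.6g}\t{d.padj:.6g}\t"
                     f"{d.base_expr:.6g}\n")
    with open(out / "links.tsv", "w") as fh:
        fh.write("gene_a\tgene_b\tconfidence\n")
        for e in edges:
            fh.write(f"{e.node_a}\t{e.node_b}\t{e.confidence:.6g}\n")
    with open(out / "drugs.tsv", "w") as fh:
        fh.write("drug_id\tdrug_name\ttarget_gene\tactivity_value\t"
                 "activity_unit\tactivity_type\tmechanism\n")
        for r in drugs:
            fh.write(f"{r.drug_id}\t{r.drug_name}\t{r.target_gene}\t"
                     f"{r.activity_nm:.6g}\tnM\t{r.activity_type}\t"
                     f"{r.mechanism}\n")
    with open(out / "truth.tsv", "w") as fh:
        fh.write("kind\tname\n")
        for g in sorted(truth.hub_genes):
            fh.write(f"hub_gene\t{g}\n")
        for d in sorted(truth.sensitive_drugs):
            fh.write(f"sensitive_drug\t{d}\n")
        for d in sorted(truth.resistant_drugs):
            fh.write(f"resistant_drug\t{d}\n")
    return truth
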