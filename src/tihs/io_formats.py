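"""Readers and writers for the tabular formats the pipeline consumes and emits.

Every external table — differential-expression (DE) results, STRING-style
protein links, curated drug–target activity tables, Cmax tables and
validation-pair tables — enters through a reader here that validates the
schema, normalises units and identifiers, and returns plain record objects.
Writers emit TSV with a fixed column order and deterministic row order so
that repeated runs are diffable.

Conventions
-----------
* Gene symbols are upper-cased on read; matching everywhere downstream is
  case-insensitive by construction.
* All drug activities are expressed in nM after reading.
* Floats are written with 6 significant digits.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

log = logging.getLogger("tihs")

#: default header names; override via the ``columns`` argument of the readers
DEG_COLUMNS = {"gene": "gene", "log2fc": "log2FoldChange", "padj": "padj",
               "base_expr": "baseMean"}

#: multiplicative factors to nM, keyed by lower-cased unit string
_UNIT_TO_NM = {"nm": 1.0, "um": 1e3, "µm": 1e3, "mm": 1e6, "m": 1e9}


class SchemaError(ValueError):
    """A required column is missing or a value cannot be parsed."""


# ---------------------------------------------------------------------------
# record types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DegRecord:
    """One gene's differential-expression result (resistant vs parental)."""
    gene: str
    log2fc: float
    padj: float
    base_expr: float | None = None


@dataclass(frozen=True)
class EdgeRecord:
    """An undirected protein–protein interaction with confidence in [0, 1]."""
    node_a: str
    node_b: str
    confidence: float


@dataclass(frozen=True)
class DrugTargetRecord:
    """One measured drug–target activity, standardised to nM."""
    drug_id: str
    drug_name: str
    target_gene: str
    activity_nm: float
    activity_type: str
    mechanism: str


@dataclass(frozen=True)
class CmaxRecord:
    drug_id: str
    cmax_nm: float


@dataclass(frozen=True)
class ValidationPairRecord:
    """A literature-curated drug–phenotype pair with its observed ranking."""
    dataset: str
    context: str
    drug_name: str
    actual_effect: str            # "sensitive" | "resistant"
    predicted_effect: str         # "sensitive" | "resistant" | "not_observed"
    rank_obs: int | None = None
    n_cand: int | None = None

    def __post_init__(self) -> None:
        if self.rank_obs is not None and self.n_cand is not None:
            if self.rank_obs > self.n_cand:
                raise ValueError(
                    f"rank_obs {self.rank_obs} exceeds n_cand {self.n_cand}")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _require(df: pd.DataFrame, cols: Iterable[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}; "
                          f"found {list(df.columns)}")


def _to_float(value, path, line: int, col: str) -> float:
    try:
        return float(value)
    except (TypeError, ValueError) as exc:
        raise SchemaError(
            f"{path}, line {line}: cannot parse {col}={value!r} as a number"
        ) from exc


def read_deg_table(path,
                   fc_cutoff: float = 1.0,
                   padj_cutoff: float = 0.05,
                   columns: Mapping[str, str] | None = None) -> list[DegRecord]:
    """Read a DE result table and keep significant genes.

    A gene is retained when ``|log2fc| >= fc_cutoff`` (inclusive) and
    ``padj < padj_cutoff`` (strict).  Duplicate gene symbols are collapsed to
    the record with the largest ``|log2fc|`` (ties: smaller padj, then first
    occurrence) so the strongest resistance signal survives.

    Parameters
    ----------
    path : path-like
        TSV with a header row.
    fc_cutoff, padj_cutoff : float
        Significance thresholds; ``fc_cutoff=0, padj_cutoff=1`` disables
        filtering (rows with non-finite values are still dropped).
    columns : mapping, optional
        Header-name overrides for ``gene``, ``log2fc``, ``padj`` and the
        optional ``base_expr``; defaults in :data:`DEG_COLUMNS`.
    """
    names = dict(DEG_COLUMNS)
    if columns:
        names.update(columns)
    df = pd.read_csv(path, sep="\t")
    _require(df, [names["gene"], names["log2fc"], names["padj"]], path)
    has_expr = names["base_expr"] in df.columns

    best: dict[str, DegRecord] = {}
    n_rows = n_pass = 0
    for line, row in enumerate(df.itertuples(index=False), start=2):
        row = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        gene = str(row[names["gene"]]).strip().upper()
        if not gene or gene == "NAN":
            raise SchemaError(f"{path}, line {line}: empty gene symbol")
        log2fc = _to_float(row[names["log2fc"]], path, line, names["log2fc"])
        padj = _to_float(row[names["padj"]], path, line, names["padj"])
        n_rows += 1
        if not (math.isfinite(log2fc) and math.isfinite(padj)):
            continue
        if not 0.0 <= padj <= 1.0:
            raise SchemaError(f"{path}, line {line}: padj {padj} outside [0, 1]")
        if abs(log2fc) < fc_cutoff or padj >= padj_cutoff:
            continue
        n_pass += 1
        expr = None
        if has_expr:
            v = row[names["base_expr"]]
            expr = None if pd.isna(v) else float(v)
        rec = DegRecord(gene, log2fc, padj, expr)
        old = best.get(gene)
        if (old is None
                or abs(rec.log2fc) > abs(old.log2fc)
                or (abs(rec.log2fc) == abs(old.log2fc) and rec.padj < old.padj)):
            best[gene] = rec
    log.info("read_deg_table: %d rows, %d pass filters, %d unique genes",
             n_rows, n_pass, len(best))
    return list(best.values())


def read_string_links(path,
                      mapping_path=None,
                      min_confidence: float = 0.7) -> list[EdgeRecord]:
    """Read a protein-link table in either of two dialects.

    The raw STRING ``protein_links`` dialect carries an integer
    ``combined_score`` in 0–999 which is divided by 1000; a pre-mapped
    edge list carries a real confidence in [0, 1].  The dialect is detected
    from the score range: a file whose scores all lie in [0, 1] is taken as
    already-normalised confidences.

    Protein identifiers are translated to gene symbols when ``mapping_path``
    (TSV ``protein_id<TAB>gene_symbol``) is given; edges with an unmapped
    endpoint are dropped and counted.  Self-loops are removed and reciprocal
    or duplicate edges are merged keeping the maximum confidence.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] < 3:
        raise SchemaError(f"{path}: expected 3 columns (node, node, score), "
                          f"got {df.shape[1]}")
    a_col, b_col, s_col = df.columns[:3]
    scores = pd.to_numeric(df[s_col], errors="coerce")
    if scores.isna().any():
        line = int(scores.index[scores.isna()][0]) + 2
        raise SchemaError(f"{path}, line {line}: unparseable score")
    divide = float(scores.max()) > 1.0        # raw STRING 0–999 dialect
    conf = scores / 1000.0 if divide else scores

    mapping = None
    if mapping_path is not None:
        mdf = pd.read_csv(mapping_path, sep="\t")
        if mdf.shape[1] < 2:
            raise SchemaError(f"{mapping_path}: expected 2 columns")
        mapping = {str(p).strip(): str(g).strip().upper()
                   for p, g in zip(mdf.iloc[:, 0], mdf.iloc[:, 1])}

    edges: dict[tuple[str, str], float] = {}
    n_unmapped = n_self = 0
    for a, b, c in zip(df[a_col], df[b_col], conf):
        if c < min_confidence:
            continue
        a, b = str(a).strip(), str(b).strip()
        if mapping is not None:
            if a not in mapping or b not in mapping:
                n_unmapped += 1
                continue
            a, b = mapping[a], mapping[b]
        a, b = a.upper(), b.upper()
        if a == b:
            n_self += 1
            continue
        key = (a, b) if a < b else (b, a)
        edges[key] = max(edges.get(key, 0.0), float(c))
    if mapping is not None and not edges and n_unmapped > 0:
        raise SchemaError(
            f"{mapping_path}: mapping covered 0 of {n_unmapped} candidate "
            "edges — wrong mapping file?")
    log.info("read_string_links: %d edges kept (>= %.3g), %d unmapped dropped, "
             "%d self-loops removed", len(edges), min_confidence, n_unmapped,
             n_self)
    return [EdgeRecord(a, b, c) for (a, b), c in edges.items()]


def read_drug_target_table(path) -> list[DrugTargetRecord]:
    """Read a curated drug–target activity table (ChEMBL-style TSV).

    Expected columns: ``drug_id drug_name target_gene activity_value
    activity_unit activity_type mechanism``.  Activities are converted to nM
    (supported units: nM, uM/µM, mM, M, case-insensitive); rows with missing
    or non-positive activity are dropped with a warning count.
    """
    df = pd.read_csv(path, sep="\t")
    required = ["drug_id", "drug_name", "target_gene", "activity_value",
                "activity_unit", "activity_type", "mechanism"]
    _require(df, required, path)
    out: list[DrugTargetRecord] = []
    n_dropped = 0
    for line, row in enumerate(df.itertuples(index=False), start=2):
        unit = str(row.activity_unit).strip().lower()
        if unit not in _UNIT_TO_NM:
            raise SchemaError(
                f"{path}, line {line}: unknown activity unit "
                f"{row.activity_unit!r}; supported: nM, uM, mM, M")
        value = pd.to_numeric(row.activity_value, errors="coerce")
        if pd.isna(value) or value <= 0:
            n_dropped += 1
            continue
        out.append(DrugTargetRecord(
            drug_id=str(row.drug_id).strip(),
            drug_name=str(row.drug_name).strip(),
            target_gene=str(row.target_gene).strip().upper(),
            activity_nm=float(value) * _UNIT_TO_NM[unit],
            activity_type=str(row.activity_type).strip(),
            mechanism=str(row.mechanism).strip(),
        ))
    if n_dropped:
        log.warning("read_drug_target_table: dropped %d rows with missing or "
                    "non-positive activity", n_dropped)
    return out


def read_cmax_table(path) -> list[CmaxRecord]:
    """Read a drug → Cmax (nM) table: TSV ``drug_id cmax_nm``."""
    df = pd.read_csv(path, sep="\t")
    _require(df, ["drug_id", "cmax_nm"], path)
    out = []
    for line, row in enumerate(df.itertuples(index=False), start=2):
        cmax = _to_float(row.cmax_nm, path, line, "cmax_nm")
        if cmax <= 0:
            raise SchemaError(f"{path}, line {line}: cmax_nm must be > 0")
        out.append(CmaxRecord(str(row.drug_id).strip(), cmax))
    return out


def read_expression_table(path) -> dict[str, float]:
    """Read a gene → expression table (TSV ``gene expression``)."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise SchemaError(f"{path}: expected 2 columns (gene, expression)")
    return {str(g).strip().upper(): float(v)
            for g, v in zip(df.iloc[:, 0], df.iloc[:, 1])}


def read_validation_pairs(path) -> list[ValidationPairRecord]:
    """Read a curated drug–phenotype validation table.

    TSV columns: ``dataset context drug_name actual_effect predicted_effect
    rank_obs n_cand`` with ``NA`` allowed in the last two.
    """
    df = pd.read_csv(path, sep="\t")
    required = ["dataset", "context", "drug_name", "actual_effect",
                "predicted_effect"]
    _require(df, required, path)
    out = []
    for line, row in enumerate(df.itertuples(index=False), start=2):
        actual = str(row.actual_effect).strip().lower()
        predicted = str(row.predicted_effect).strip().lower()
        if actual not in {"sensitive", "resistant"}:
            raise SchemaError(f"{path}, line {line}: actual_effect must be "
                              "'sensitive' or 'resistant'")
        if predicted not in {"sensitive", "resistant", "not_observed"}:
            raise SchemaError(f"{path}, line {line}: bad predicted_effect "
                              f"{predicted!r}")
        rank_obs = getattr(row, "rank_obs", None)
        n_cand = getattr(row, "n_cand", None)
        rank_obs = None if pd.isna(rank_obs) else int(rank_obs)
        n_cand = None if pd.isna(n_cand) else int(n_cand)
        out.append(ValidationPairRecord(
            str(row.dataset).strip(), str(row.context).strip(),
            str(row.drug_name).strip(), actual, predicted, rank_obs, n_cand))
    return out


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def _fmt(x) -> str:
    if isinstance(x, bool):
        return str(x)
    if isinstance(x, float):
        return f"{x:.6g}"
    return str(x)


def _write_tsv(df: pd.DataFrame, path) -> None:
    out = df.map(_fmt)
    out.to_csv(path, sep="\t", index=False)


HUBNESS_COLUMNS = ["gene", "degree", "betweenness", "eigenvector", "mcc",
                   "epc", "z_shifted_degree", "z_shifted_betweenness",
                   "z_shifted_eigenvector", "z_shifted_mcc", "z_shifted_epc",
                   "tihs"]

RANKED_COLUMNS = ["drug_id", "drug_name", "n_targets", "matched_genes",
                  "mean_activity_nm", "total_score", "effect_multiplier",
                  "sensitivity_score", "rank", "rank_fraction",
                  "tier1_pass", "tier2_pass", "tier3_pass"]


def write_hubness_table(df: pd.DataFrame, path) -> None:
    """Write the per-gene hubness table (columns :data:`HUBNESS_COLUMNS`).

    Rows are ordered by descending composite score, ties broken by gene name.
    """
    if df.empty:
        raise ValueError("refusing to write an empty hubness table")
    _require(df, HUBNESS_COLUMNS, path)
    df = df.sort_values(["tihs", "gene"], ascending=[False, True],
                        kind="mergesort")
    _write_tsv(df[HUBNESS_COLUMNS], path)


def write_ranked_drugs(df: pd.DataFrame, path) -> None:
    """Write the ranked drug table (columns :data:`RANKED_COLUMNS`)."""
    if df.empty:
        raise ValueError("refusing to write an empty drug table")
    _require(df, RANKED_COLUMNS, path)
    df = df.sort_values(["sensitivity_score", "drug_name"],
                        ascending=[False, True], kind="mergesort")
    _write_tsv(df[RANKED_COLUMNS], path)


def write_weight_vector(weights: Mapping[str, float], path) -> None:
    """Write metric → weight pairs as ``metric<TAB>weight`` lines."""
    if not weights:
        raise ValueError("refusing to write an empty weight vector")
    with open(path, "w") as fh:
        for metric, w in weights.items():
            fh.write(f"{metric}\t{w:.6g}\n")


def read_weight_vector(path) -> dict[str, float]:
    """Read a ``metric<TAB>weight`` file written by :func:`write_weight_vector`."""
    out: dict[str, float] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        metric, w = line.split("\t")
        out[metric] = float(w)
    return out


def write_edge_list(edges: Sequence[EdgeRecord], path) -> None:
    """Write edges as TSV ``gene_a gene_b confidence`` (sorted, 6 sig digits)."""
    if not edges:
        raise ValueError("refusing to write an empty edge list")
    rows = sorted((e.node_a, e.node_b, e.confidence) for e in edges)
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tconfidence\n")
        for a, b, c in rows:
            fh.write(f"{a}\t{b}\t{c:.6g}\n")
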