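"""Drug–target matching, sensitivity scoring, ranking and tiered filtering.

For each drug d the total matching score accumulates, over every matched
network target t and every metric j,

    (log2FC_t / activity_nM_{d,t}) · Z′_tj · 100 · W_j,

which factors algebraically to 100 · Σ_t (log2FC_t / activity_nM_{d,t}) · TIHS_t.
Both forms are computed and asserted equal, which guards the weight/shift
bookkeeping.  The signed Drug Sensitivity Score multiplies the total by a
mechanism-derived effect multiplier: +1 for inhibitory/suppressive drugs,
−1 for agonists/activators; a positive score predicts the drug is more
effective in the resistant state.

Candidates then pass through a three-tier false-positive control:

tier 1  positive score and rank within the top fraction (default 10%);
tier 2  ≥ 2 matched topological targets (buffers bypass-track resistance);
tier 3  every matched target detectably expressed, and mean matched-target
        potency within the clinically achievable plasma concentration (Cmax).
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .hubness import HubnessTable, NormalizedMatrix, WeightVector
from .io_formats import RANKED_COLUMNS, CmaxRecord, DrugTargetRecord

log = logging.getLogger("tihs")

# keyword lists for the effect multiplier; the +1 list is checked first so
# "antagonist" is classified before its "agonist" substring can match
_INHIBITORY = ("inhibitor", "antagonist", "blocker", "suppress",
               "negative modulator", "degrader")
_ACTIVATING = ("agonist", "activator", "opener", "positive modulator",
               "inducer")


@dataclass
class MatchedTarget:
    gene: str
    log2fc: float
    activity_nm: float
    contribution: float           # 100 * (log2fc/activity) * TIHS


@dataclass
class DrugScoreRecord:
    drug_id: str
    drug_name: str
    matched_targets: list[MatchedTarget] = field(default_factory=list)
    n_unmatched: int = 0
    total_score: float = 0.0
    effect_multiplier: int | None = None        # None = indeterminate
    sensitivity_score: float = 0.0
    rank: int | None = None
    rank_fraction: float | None = None
    tier1_pass: bool = False
    tier2_pass: bool = False
    tier3_pass: bool = False

    @property
    def n_targets(self) -> int:
        return len(self.matched_targets)

    @property
    def mean_activity_nm(self) -> float:
        if not self.matched_targets:
            return float("nan")
        return float(np.mean([t.activity_nm for t in self.matched_targets]))

    @property
    def passes_all(self) -> bool:
        return self.tier1_pass and self.tier2_pass and self.tier3_pass


@dataclass
class FilterConfig:
    top_fraction: float = 0.10
    min_targets: int = 2
    min_expression: float = 1.0
    cmax_table: Sequence[CmaxRecord] | None = None

    def __post_init__(self) -> None:
        if not 0 < self.top_fraction <= 1:
            raise ValueError("top_fraction must be in (0, 1]")
        if self.min_targets < 1:
            raise ValueError("min_targets must be >= 1")


def effect_multiplier(mechanism: str) -> int | None:
    """Map a free-text mechanism of action to {+1, −1} or None (indeterminate).

    Case-insensitive substring rule; inhibitory keywords take precedence so
    that "antagonist" never falls through to the "agonist" branch.
    Indeterminate drugs are excluded from ranking rather than defaulted,
    since a wrong sign is worse than a missing candidate.
    """
    m = mechanism.lower()
    if any(k in m for k in _INHIBITORY):
        return 1
    if any(k in m for k in _ACTIVATING):
        return -1
    return None


def _aggregate_activity(values: Sequence[float], how: str) -> float:
    if how == "median":
        return float(statistics.median(values))
    if how == "geometric_mean":
        return float(np.exp(np.mean(np.log(values))))
    if how == "minimum":
        return float(min(values))
    raise ValueError(f"unknown activity aggregation {how!r}")


def score_drug(drug_records: Sequence[DrugTargetRecord],
               hub: HubnessTable,
               deg_index: Mapping[str, float],
               weights: WeightVector,
               nm: NormalizedMatrix,
               activity_aggregation: str = "median") -> DrugScoreRecord:
    """Score one drug against the hubness table.

    ``drug_records`` are all activity rows for a single drug.  Multiple
    activities per (drug, target) are aggregated (median by default) before
    scoring.  Targets not present in the network contribute nothing but are
    counted as unmatched.  The per-metric accumulation and the TIHS-factored
    form are both computed; a mismatch beyond 1e-6 relative is a bug and
    raises.
    """
    if not drug_records:
        raise ValueError("score_drug needs at least one drug record")
    drug_ids = {r.drug_id for r in drug_records}
    if len(drug_ids) != 1:
        raise ValueError(f"records for multiple drugs supplied: {drug_ids}")
    rec0 = drug_records[0]

    by_target: dict[str, list[float]] = {}
    for r in drug_records:
        by_target.setdefault(r.target_gene.upper(), []).append(r.activity_nm)

    wa = weights.as_array(nm.metrics)
    matched: list[MatchedTarget] = []
    total_per_metric = 0.0
    total_factored = 0.0
    n_unmatched = 0
    for gene in sorted(by_target):
        if gene not in hub.tihs:
            n_unmatched += 1
            continue
        activity = _aggregate_activity(by_target[gene], activity_aggregation)
        fold = deg_index.get(gene, 0.0)
        ratio = fold / activity
        # per-metric accumulation: Σ_j ratio · Z′_gj · 100 · W_j
        total_per_metric += float(ratio * 100.0 * (hub.z_shifted[gene] @ wa))
        contribution = 100.0 * ratio * hub.tihs[gene]
        total_factored += contribution
        matched.append(MatchedTarget(gene, fold, activity, contribution))

    scale = max(1.0, abs(total_factored))
    if abs(total_per_metric - total_factored) > 1e-6 * scale:
        raise AssertionError(
            "per-metric and factored drug scores diverged: "
            f"{total_per_metric} vs {total_factored}")

    mech = effect_multiplier(rec0.mechanism)
    rec = DrugScoreRecord(
        drug_id=rec0.drug_id,
        drug_name=rec0.drug_name,
        matched_targets=matched,
        n_unmatched=n_unmatched,
        total_score=total_factored,
        effect_multiplier=mech,
        sensitivity_score=total_factored * mech if mech is not None else 0.0,
    )
    if mech is None:
        log.warning("drug %s: indeterminate mechanism %r — excluded from "
                    "ranking", rec0.drug_name, rec0.mechanism)
    return rec


def score_all_drugs(records: Sequence[DrugTargetRecord],
                    hub: HubnessTable,
                    deg_index: Mapping[str, float],
                    weights: WeightVector,
                    nm: NormalizedMatrix,
                    activity_aggregation: str = "median") -> list[DrugScoreRecord]:
    """Group activity rows by drug and score each; indeterminate drugs dropped."""
    by_drug: dict[str, list[DrugTargetRecord]] = {}
    for r in records:
        by_drug.setdefault(r.drug_id, []).append(r)
    scored = []
    n_excluded = 0
    for drug_id in sorted(by_drug):
        rec = score_drug(by_drug[drug_id], hub, deg_index, weights, nm,
                         activity_aggregation)
        if rec.effect_multiplier is None:
            n_excluded += 1
            continue
        scored.append(rec)
    log.info("score_all_drugs: %d drugs scored, %d excluded (indeterminate "
             "mechanism)", len(scored), n_excluded)
    return scored


def rank_drugs(records: Sequence[DrugScoreRecord]) -> list[DrugScoreRecord]:
    """Sort by sensitivity score (descending) and assign ranks.

    Ties are broken by number of matched targets (more first) then drug name;
    rank 1 is the best candidate and rank_fraction = rank / N.
    """
    if not records:
        raise ValueError("no scored drugs to rank")
    ranked = sorted(records, key=lambda r: (-r.sensitivity_score,
                                            -r.n_targets, r.drug_name))
    n = len(ranked)
    for i, rec in enumerate(ranked, start=1):
        rec.rank = i
        rec.rank_fraction = i / n
    return ranked


def apply_filters(ranked: Sequence[DrugScoreRecord],
                  cfg: FilterConfig,
                  expression: Mapping[str, float] | None = None
                  ) -> list[DrugScoreRecord]:
    """Annotate every ranked drug with the three tier flags (no rows dropped).

    Tier 3's Cmax comparison uses the mean matched-target potency as the
    potency proxy; drugs absent from the Cmax table pass that check with a
    warning.  An expression or Cmax table that is not supplied makes the
    corresponding check vacuously true.
    """
    if not ranked:
        raise ValueError("no ranked drugs to filter")
    cmax = ({c.drug_id: c.cmax_nm for c in cfg.cmax_table}
            if cfg.cmax_table else None)
    for rec in ranked:
        rec.tier1_pass = (rec.sensitivity_score > 0
                          and rec.rank_fraction <= cfg.top_fraction)
        rec.tier2_pass = rec.n_targets >= cfg.min_targets
        expr_ok = True
        if expression is not None:
            expr_ok = all(expression.get(t.gene, 0.0) >= cfg.min_expression
                          for t in rec.matched_targets)
        cmax_ok = True
        if cmax is not None and rec.matched_targets:
            if rec.drug_id in cmax:
                cmax_ok = rec.mean_activity_nm <= cmax[rec.drug_id]
            else:
                log.warning("drug %s missing from Cmax table — tier 3 Cmax "
                            "check passed by default", rec.drug_name)
        rec.tier3_pass = expr_ok and cmax_ok
    return list(ranked)


def intersect_candidates(pass_lists: Sequence[Iterable[str]]
                         ) -> tuple[set[str], pd.DataFrame]:
    """Intersect per-dataset passing-drug name sets (case-normalised).

    Returns the shared set and a full membership matrix (drug × dataset
    booleans) for Venn-style reporting.
    """
    if len(pass_lists) < 2:
        sets = [set(n.upper() for n in lst) for lst in pass_lists]
        shared = sets[0] if sets else set()
    else:
        sets = [set(n.upper() for n in lst) for lst in pass_lists]
        shared = set.intersection(*sets)
    all_drugs = sorted(set.union(*sets)) if sets else []
    matrix = pd.DataFrame(
        {f"dataset_{i + 1}": [d in s for d in all_drugs]
         for i, s in enumerate(sets)},
        index=pd.Index(all_drugs, name="drug_name"))
    return shared, matrix


def ranked_to_frame(ranked: Sequence[DrugScoreRecord]) -> pd.DataFrame:
    """Flatten ranked records to the output table schema."""
    rows = []
    for r in ranked:
        rows.append({
            "drug_id": r.drug_id,
            "drug_name": r.drug_name,
            "n_targets": r.n_targets,
            "matched_genes": ",".join(t.gene for t in r.matched_targets),
            "mean_activity_nm": r.mean_activity_nm,
            "total_score": r.total_score,
            "effect_multiplier": r.effect_multiplier,
            "sensitivity_score": r.sensitivity_score,
            "rank": r.rank,
            "rank_fraction": r.rank_fraction,
            "tier1_pass": r.tier1_pass,
            "tier2_pass": r.tier2_pass,
            "tier3_pass": r.tier3_pass,
        })
    return pd.DataFrame(rows, columns=RANKED_COLUMNS)
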