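"""Mechanism mapping, sensitivity scoring, ranking and tier filtering."""

import numpy as np
import pytest

from tihs import (METRICS, CmaxRecord, DrugTargetRecord, FilterConfig,
                  WeightVector, apply_filters, compute_tihs,
                  effect_multiplier, intersect_candidates, rank_drugs,
                  score_all_drugs, score_drug, zscore_shift)
from tihs.centrality import CentralityMatrix
from tihs.drug_rank import DrugScoreRecord, MatchedTarget


def uniform_weights():
    return WeightVector(weights={m: 0.2 for m in METRICS})


def hub_fixture(n=10, seed=0):
    rng = np.random.default_rng(seed)
    cm = CentralityMatrix(nodes=[f"G{i}" for i in range(n)],
                          values=rng.random((n, 5)) * [5, 40, 1, 100, 1])
    nm = zscore_shift(cm)
    w = uniform_weights()
    return compute_tihs(nm, w), nm, w


def dtr(drug, gene, nm, mech="inhibitor", drug_id=None):
    return DrugTargetRecord(drug_id or drug, drug, gene, nm, "IC50", mech)


class TestEffectMultiplier:
    @pytest.mark.parametrize("mech,expected", [
        ("KINASE INHIBITOR", 1),
        ("EGFR antagonist", 1),
        ("channel BLOCKER", 1),
        ("suppresses transcription", 1),
        ("negative modulator", 1),
        ("protein degrader", 1),
        ("FULL AGONIST", -1),
        ("receptor activator", -1),
        ("channel opener", -1),
        ("positive modulator", -1),
        ("transcription inducer", -1),
        ("SUBSTRATE", None),
        ("", None),
    ])
    def test_keyword_rule(self, mech, expected):
        assert effect_multiplier(mech) == expected

    def test_antagonist_precedes_agonist_substring(self):
        # "antagonist" contains "agonist": must classify as inhibitory
        assert effect_multiplier("selective antagonist") == 1


class TestScoreDrug:
    def test_single_target_hand_computation(self):
        """log2fc 2, activity 100 nM, TIHS 0.5 -> 2/100*100*0.5 = 1.0."""
        hub, nm, w = hub_fixture()
        gene = nm.nodes[0]
        hub.tihs[gene] = 0.5
        hub.z_shifted[gene] = np.full(5, 0.5)   # uniform weights -> TIHS 0.5
        rec = score_drug([dtr("DrugX", gene, 100.0)], hub,
                         {gene: 2.0}, w, nm)
        assert rec.total_score == pytest.approx(1.0, abs=1e-12)
        assert rec.sensitivity_score == pytest.approx(1.0, abs=1e-12)

    def test_agonist_flips_sign(self):
        hub, nm, w = hub_fixture()
        gene = nm.nodes[0]
        hub.tihs[gene] = 0.5
        hub.z_shifted[gene] = np.full(5, 0.5)
        rec = score_drug([dtr("DrugX", gene, 100.0, mech="full agonist")],
                         hub, {gene: 2.0}, w, nm)
        assert rec.effect_multiplier == -1
        assert rec.sensitivity_score == pytest.approx(-1.0, abs=1e-12)

    def test_factored_identity_on_random_fixtures(self):
        """Per-metric accumulation = 100 Σ_t (fc/activity)·TIHS_t to 1e-9."""
        rng = np.random.default_rng(1)
        for trial in range(20):
            hub, nm, w_uniform = hub_fixture(n=12, seed=trial)
            w = rng.random(5)
            w /= w.sum()
            wv = WeightVector(weights=dict(zip(METRICS, w)))
            hub = compute_tihs(nm, wv)
            deg_index = {g: float(rng.normal(0, 2)) for g in nm.nodes}
            targets = rng.choice(nm.nodes, size=4, replace=False)
            records = [dtr("D", str(t), float(rng.uniform(5, 5000)),
                           drug_id="D") for t in targets]
            rec = score_drug(records, hub, deg_index, wv, nm)
            expected = 100.0 * sum(
                deg_index[t.gene] / t.activity_nm * hub.tihs[t.gene]
                for t in rec.matched_targets)
            assert rec.total_score == pytest.approx(expected, abs=1e-9)

    def test_unmatched_targets_counted_not_scored(self):
        hub, nm, w = hub_fixture()
        recs = [dtr("D", nm.nodes[0], 100.0, drug_id="D"),
                dtr("D", "NOT_IN_NET", 100.0, drug_id="D")]
        rec = score_drug(recs, hub, {nm.nodes[0]: 1.0}, w, nm)
        assert rec.n_targets == 1 and rec.n_unmatched == 1

    def test_zero_matched_targets_scores_zero(self):
        hub, nm, w = hub_fixture()
        rec = score_drug([dtr("D", "ABSENT", 10.0)], hub, {}, w, nm)
        assert rec.n_targets == 0 and rec.total_score == 0.0

    def test_multiple_activities_aggregated_by_median(self):
        hub, nm, w = hub_fixture()
        gene = nm.nodes[0]
        recs = [dtr("D", gene, a, drug_id="D") for a in (10.0, 100.0, 1000.0)]
        rec = score_drug(recs, hub, {gene: 1.0}, w, nm)
        assert rec.matched_targets[0].activity_nm == 100.0

    def test_sign_equivariance_in_log2fc(self):
        hub, nm, w = hub_fixture(seed=3)
        deg_index = {g: float(i + 1) for i, g in enumerate(nm.nodes)}
        recs = [dtr("D", g, 50.0, drug_id="D") for g in nm.nodes[:3]]
        pos = score_drug(recs, hub, deg_index, w, nm)
        neg = score_drug(recs, hub, {g: -v for g, v in deg_index.items()},
                         w, nm)
        assert neg.total_score == pytest.approx(-pos.total_score, abs=1e-12)

    def test_activity_monotonicity(self):
        """For a positive-fc single-target inhibitor, DSS falls as potency
        worsens (activity_nm grows)."""
        hub, nm, w = hub_fixture()
        gene = nm.nodes[0]
        scores = [score_drug([dtr("D", gene, a)], hub, {gene: 2.0}, w,
                             nm).sensitivity_score
                  for a in (10.0, 100.0, 1000.0)]
        assert scores[0] > scores[1] > scores[2] > 0


class TestRankDrugs:
    def make(self, name, score, n_targets=1):
        r = DrugScoreRecord(drug_id=name, drug_name=name,
                            total_score=abs(score), effect_multiplier=1,
                            sensitivity_score=score)
        r.matched_targets = [MatchedTarget(f"G{i}", 1.0, 10.0, 0.0)
                             for i in range(n_targets)]
        return r

    def test_sign_and_order(self):
        ranked = rank_drugs([self.make("a", 1.0), self.make("b", 3.0),
                             self.make("c", -2.0)])
        assert [r.drug_name for r in ranked] == ["b", "a", "c"]
        assert [r.rank for r in ranked] == [1, 2, 3]
        assert ranked[-1].sensitivity_score < 0

    def test_tie_broken_by_n_targets_then_name(self):
        ranked = rank_drugs([self.make("zzz", 1.0, n_targets=3),
                             self.make("aaa", 1.0, n_targets=1)])
        assert ranked[0].drug_name == "zzz"
        ranked = rank_drugs([self.make("zzz", 1.0), self.make("aaa", 1.0)])
        assert ranked[0].drug_name == "aaa"

    def test_rank_fraction_seven_of_130(self):
        drugs = [self.make(f"d{i:03d}", 130.0 - i) for i in range(130)]
        ranked = rank_drugs(drugs)
        assert ranked[6].rank == 7
        assert ranked[6].rank_fraction == pytest.approx(7 / 130)
        assert round(100 * ranked[6].rank_fraction, 2) == 5.38


class TestApplyFilters:
    def ranked(self, scores, n_targets=2):
        recs = [DrugScoreRecord(drug_id=f"d{i}", drug_name=f"d{i}",
                                total_score=abs(s), effect_multiplier=1,
                                sensitivity_score=s)
                for i, s in enumerate(scores)]
        for r in recs:
            r.matched_targets = [MatchedTarget(f"G{j}", 1.0, 10.0, 0.0)
                                 for j in range(n_targets)]
        return rank_drugs(recs)

    def test_tier1_top_decile_positive(self):
        ranked = self.ranked([float(20 - i) for i in range(20)])
        out = apply_filters(ranked, FilterConfig(top_fraction=0.10))
        assert [r.tier1_pass for r in out] \
            == [True, True] + [False] * 18

    def test_tier1_rejects_rank_fraction_point2(self):
        ranked = self.ranked([float(10 - i) for i in range(10)])
        out = apply_filters(ranked, FilterConfig(top_fraction=0.10))
        # rank 2 of 10 -> fraction 0.2 > 0.1
        assert out[1].tier1_pass is False

    def test_tier1_requires_positive_score(self):
        ranked = self.ranked([-1.0, -2.0])
        out = apply_filters(ranked, FilterConfig(top_fraction=1.0))
        assert not any(r.tier1_pass for r in out)

    def test_tier2_min_targets(self):
        ranked = self.ranked([2.0], n_targets=1)
        out = apply_filters(ranked, FilterConfig(min_targets=2))
        assert out[0].tier2_pass is False

    def test_tier3_expression_and_cmax(self):
        ranked = self.ranked([2.0, 1.0])
        expr = {"G0": 5.0, "G1": 0.0}   # G1 below detectability
        out = apply_filters(ranked, FilterConfig(min_expression=1.0),
                            expression=expr)
        assert all(r.tier3_pass is False for r in out)
        cmax = [CmaxRecord("d0", 5.0)]   # mean activity 10 nM > 5 nM Cmax
        out = apply_filters(self.ranked([2.0]),
                            FilterConfig(cmax_table=cmax))
        assert out[0].tier3_pass is False
        cmax = [CmaxRecord("d0", 50.0)]
        out = apply_filters(self.ranked([2.0]),
                            FilterConfig(cmax_table=cmax))
        assert out[0].tier3_pass is True

    def test_filter_monotonicity(self):
        """Shrinking top_fraction or raising min_targets never adds passes."""
        rng = np.random.default_rng(4)
        ranked = self.ranked(list(rng.normal(size=30)), n_targets=2)
        passes = []
        for frac in (0.5, 0.3, 0.1):
            out = apply_filters(ranked, FilterConfig(top_fraction=frac))
            passes.append({r.drug_name for r in out if r.tier1_pass})
        assert passes[2] <= passes[1] <= passes[0]
        t2 = []
        for mt in (1, 2, 3):
            out = apply_filters(ranked, FilterConfig(min_targets=mt))
            t2.append({r.drug_name for r in out if r.tier2_pass})
        assert t2[2] <= t2[1] <= t2[0]

    def test_no_rows_dropped(self):
        ranked = self.ranked([1.0, -1.0, 0.5])
        out = apply_filters(ranked, FilterConfig())
        assert len(out) == 3


class TestIntersect:
    def test_intersection(self):
        shared, matrix = intersect_candidates([{"A", "B", "C"},
                                               {"B", "C"}, {"C"}])
        assert shared == {"C"}
        assert matrix.shape == (3, 3)

    def test_disjoint_is_empty_not_error(self):
        shared, _ = intersect_candidates([{"A"}, {"B"}])
        assert shared == set()

    def test_single_list_identity(self):
        shared, _ = intersect_candidates([{"a", "b"}])
        assert shared == {"A", "B"}

    def test_case_normalisation(self):
        shared, _ = intersect_candidates([{"Dasatinib"}, {"DASATINIB"}])
        assert shared == {"DASATINIB"}


def test_indeterminate_drugs_excluded_from_ranking():
    hub, nm, w = hub_fixture()
    recs = [dtr("Good", nm.nodes[0], 10.0),
            dtr("Mystery", nm.nodes[1], 10.0, mech="substrate")]
    scored = score_all_drugs(recs, hub, {n: 1.0 for n in nm.nodes}, w, nm)
    assert [r.drug_name for r in scored] == ["Good"]
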