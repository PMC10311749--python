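import datetime as dt
import random

import pytest

from oa_phenotyper.cohort_builder import DateInterval, STUDY_WINDOW, determine_extraction_period
from oa_phenotyper.records_io import (
    CodeSystem,
    DiagnosisEvent,
    DrugClaim,
    DrugClass,
    ProcedureEvent,
    Setting,
)
from oa_phenotyper.rule_engine import (
    CohortContext,
    Concept,
    Predicate,
    PredicateKind,
    RuleSpec,
    all_rules,
    build_context,
    combine_or,
    composite_classify,
    evaluate_predicate,
    evaluate_rule,
    oa_related_cost,
    step1_registry,
    step2_registry,
    step3_registry,
)
from oa_phenotyper.synthetic_claims import PANEL_EXPECTATIONS, plant_edge_cases

from conftest import dx, make_patient
from rule_oracle import evaluate_oracle, oracle_oa_cost

D = dt.date
W = DateInterval(D(2018, 7, 1), D(2019, 12, 31))
OA = Concept("dx", ("OA_HIP_KNEE",))


class TestRegistries:
    def test_registry_sizes(self):
        assert len(step1_registry()) == 20
        assert len(step2_registry()) == 14
        assert len(step3_registry()) == 6

    def test_indices_unique_within_step(self):
        for registry in (step1_registry(), step2_registry(), step3_registry()):
            indices = [r.index for r in registry]
            assert indices == sorted(set(indices))

    def test_descriptions_are_the_published_row_texts(self):
        step2 = step2_registry()
        assert "≥ 1 administration of HA or IA corticosteroids" in step2[6].description
        assert "at least 90 days apart" in step2[7].description
        step3 = step3_registry()
        assert "2 different classes of analgesics" in step3[0].description

    def test_round_trip_serialization(self):
        for rule in all_rules():
            assert RuleSpec.from_dict(rule.to_dict()) == rule


class TestPredicates:
    def test_count_within_span(self, code_sets):
        p = make_patient(diagnoses=[dx("pt1", D(2019, 1, 1)), dx("pt1", D(2019, 4, 11))])
        pred = Predicate(PredicateKind.WITHIN_SPAN, OA, k=2, days=183)
        assert evaluate_predicate(p, pred, W, code_sets)  # 100 days <= 183

    def test_near_anchor_injection(self, code_sets):
        p = make_patient(
            diagnoses=[dx("pt1", D(2019, 3, 1))],
            procedures=[ProcedureEvent("pt1", D(2019, 3, 26), "J7321", CodeSystem.HCPCS, 500.0)],
        )
        pred = Predicate(
            PredicateKind.NEAR_ANCHOR,
            Concept("proc", ("HA_INJECTION",)),
            anchor=OA, days=30, k=1,
        )
        assert evaluate_predicate(p, pred, W, code_sets)  # 25 days within +/-30

    @pytest.mark.parametrize("rule", all_rules(), ids=lambda r: f"s{r.step}r{r.index}")
    def test_empty_event_set_never_satisfies(self, code_sets, rule):
        """The vocabulary is negation-free: no rule fires on an empty record."""
        empty = make_patient()
        ctx = CohortContext(oa_cost={"pt1": 0.0}, mean_oa_cost=100.0)
        assert evaluate_rule(empty, rule, W, code_sets, ctx).satisfied is False

    def test_cost_rule_requires_context(self, code_sets):
        p = make_patient()
        pred = Predicate(PredicateKind.COST_VS_COHORT_MEAN, multiplier=1.3)
        with pytest.raises(ValueError, match="context"):
            evaluate_predicate(p, pred, W, code_sets, None)

    def test_cost_boundary_strict(self, code_sets):
        p = make_patient(procedures=[ProcedureEvent("pt1", D(2019, 1, 1), "20610", CodeSystem.CPT4, 130.0)])
        pred = Predicate(PredicateKind.COST_VS_COHORT_MEAN, multiplier=1.3)
        at = CohortContext(oa_cost={"pt1": 130.0}, mean_oa_cost=100.0)
        above = CohortContext(oa_cost={"pt1": 130.01}, mean_oa_cost=100.0)
        assert not evaluate_predicate(p, pred, W, code_sets, at)
        assert evaluate_predicate(p, pred, W, code_sets, above)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            Predicate(PredicateKind.COUNT_IN_WINDOW, OA, k=0)
        with pytest.raises(ValueError):
            Predicate(PredicateKind.NEAR_ANCHOR, OA, days=30)  # missing anchor
        with pytest.raises(ValueError):
            Predicate(PredicateKind.COST_VS_COHORT_MEAN)


class TestRuleSemantics:
    def test_boundary_panel_outcomes(self, synth_db, code_sets):
        db = plant_edge_cases(synth_db)
        rules = {(r.step, r.index): r for r in all_rules()}
        windows = {
            pid: determine_extraction_period(db.records[pid], STUDY_WINDOW, code_sets["ARTHROPLASTY"])
            for pid in PANEL_EXPECTATIONS
        }
        ctx = CohortContext(oa_cost={pid: 0.0 for pid in windows}, mean_oa_cost=1000.0)
        for pid, expectations in PANEL_EXPECTATIONS.items():
            for key, want in expectations.items():
                got = evaluate_rule(db.records[pid], rules[key], windows[pid], code_sets, ctx)
                assert got.satisfied is want, (pid, key)

    def test_arthroplasty_only_patient(self, code_sets):
        """Surgery alone satisfies step-3 #3 but not #1 (no prior analgesics)."""
        p = make_patient(procedures=[ProcedureEvent("pt1", D(2019, 6, 1), "27130", CodeSystem.CPT4, 15000.0)])
        rules = {r.index: r for r in step3_registry()}
        ctx = CohortContext(oa_cost={"pt1": 0.0}, mean_oa_cost=100.0)
        assert evaluate_rule(p, rules[3], W, code_sets, ctx).satisfied
        assert not evaluate_rule(p, rules[1], W, code_sets, ctx).satisfied

    def test_event_order_invariance(self, synth_db, code_sets, synth_windows):
        import dataclasses
        pid = sorted(synth_db.records)[60]
        rec = synth_db.records[pid]
        shuffled = dataclasses.replace(
            rec,
            diagnoses=list(reversed(rec.diagnoses)),
            procedures=list(reversed(rec.procedures)),
            drugs=list(reversed(rec.drugs)),
        )
        ctx = CohortContext(oa_cost={pid: 500.0}, mean_oa_cost=400.0)
        for rule in all_rules():
            a = evaluate_rule(rec, rule, synth_windows[pid], code_sets, ctx).satisfied
            b = evaluate_rule(shuffled, rule, synth_windows[pid], code_sets, ctx).satisfied
            assert a == b, (rule.step, rule.index)

    def test_monotone_under_event_insertion(self, synth_db, code_sets, synth_windows):
        """Adding events never flips a satisfied rule to unsatisfied."""
        import dataclasses
        rng = random.Random(13)
        pids = rng.sample(sorted(synth_db.records), 25)
        rules = all_rules()
        for pid in pids:
            rec, w = synth_db.records[pid], synth_windows[pid]
            ctx = CohortContext(oa_cost={pid: 300.0}, mean_oa_cost=400.0)
            before = {
                (r.step, r.index): evaluate_rule(rec, r, w, code_sets, ctx).satisfied
                for r in rules
            }
            mid = w.start + dt.timedelta(days=rng.randrange(w.days()))
            extra_dx = [dx(pid, mid), dx(pid, mid + dt.timedelta(days=40), "M16.12")]
            extra_proc = [ProcedureEvent(pid, mid, "20610", CodeSystem.CPT4, 250.0)]
            extra_drug = [DrugClaim(pid, mid, DrugClass.OPIOID_SA, 20.0)]
            bigger = dataclasses.replace(
                rec,
                diagnoses=rec.diagnoses + extra_dx,
                procedures=rec.procedures + extra_proc,
                drugs=rec.drugs + extra_drug,
            )
            after = {
                (r.step, r.index): evaluate_rule(bigger, r, w, code_sets, ctx).satisfied
                for r in rules
            }
            for key, was in before.items():
                if was:
                    assert after[key], (pid, key)


class TestBruteForceEquivalence:
    def test_engine_matches_oracle_on_cohort(self, synth_db, code_sets):
        """All 40 rules agree with naive nested-loop evaluation everywhere."""
        db = plant_edge_cases(synth_db)
        windows = {
            pid: determine_extraction_period(db.records[pid], STUDY_WINDOW, code_sets["ARTHROPLASTY"])
            for pid in db.records
        }
        ctx = build_context(db, windows, code_sets)
        # the cost context itself must match the oracle's recomputation
        oracle_costs = {
            pid: oracle_oa_cost(db.records[pid], windows[pid], code_sets)
            for pid in windows
        }
        for pid in windows:
            assert ctx.oa_cost[pid] == pytest.approx(oracle_costs[pid])
        rules = all_rules()
        mismatches = []
        for pid in sorted(db.records):
            rec, w = db.records[pid], windows[pid]
            for rule in rules:
                got = evaluate_rule(rec, rule, w, code_sets, ctx).satisfied
                want = evaluate_oracle(rule.step, rule.index, rec, w, code_sets, ctx.mean_oa_cost)
                if got != want:
                    mismatches.append((pid, rule.step, rule.index, got, want))
        assert not mismatches, mismatches[:10]


class TestCombination:
    def test_combine_or_basics(self):
        outcomes = {1: False, 2: True, 3: False, 4: False, 5: False}
        assert combine_or(outcomes, {1, 2, 3, 4, 5})
        assert not combine_or(outcomes, {1, 3, 4})
        with pytest.raises(ValueError):
            combine_or(outcomes, set())
        with pytest.raises(ValueError):
            combine_or(outcomes, {99})

    def test_composite_requires_all_three_steps(self):
        s1 = {1: True}
        s2 = {7: True}
        s3 = {3: False}
        assert not composite_classify((s1, s2, s3), ([1], [7], [3]))
        s3 = {3: True}
        assert composite_classify((s1, s2, s3), ([1], [7], [3]))

    def test_or_sensitivity_dominates_components(self, synth_db, code_sets, synth_windows):
        """OR-combination is a superset of every component's positives."""
        from oa_phenotyper.evaluation import rule_outcome_table
        table = rule_outcome_table(synth_db, synth_windows, step1_registry(), code_sets)
        selected = [(1, i) for i in (1, 3, 5)]
        combined = table[selected].any(axis=1)
        for col in selected:
            assert (combined | ~table[col]).all()

    def test_oa_cost_definition(self, code_sets):
        p = make_patient(
            procedures=[
                ProcedureEvent("pt1", D(2019, 1, 1), "20610", CodeSystem.CPT4, 300.0),
                ProcedureEvent("pt1", D(2019, 2, 1), "99213", CodeSystem.CPT4, 75.0),  # unrelated
            ],
            drugs=[
                DrugClaim("pt1", D(2019, 3, 1), DrugClass.OPIOID_SA, 25.0),
                DrugClaim("pt1", D(2019, 3, 2), DrugClass.H2_BLOCKER, 10.0),  # not analgesic
            ],
        )
        assert oa_related_cost(p, W, code_sets) == pytest.approx(325.0)
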