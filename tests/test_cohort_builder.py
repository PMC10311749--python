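import datetime as dt

import numpy as np
import pytest

from oa_phenotyper.cohort_builder import (
    CHARLSON_HIERARCHY,
    CHARLSON_WEIGHTS,
    DateInterval,
    STUDY_WINDOW,
    SelectionCriteria,
    charlson_category,
    clopper_pearson,
    comorbidity_present,
    determine_extraction_period,
    enriched_sample,
    ppv_ci_width,
    quan_charlson,
    quan_charlson_code_sets,
    select_cohort,
)
from oa_phenotyper.records_io import (
    CodeSystem,
    DiagnosisEvent,
    EnrollmentPeriod,
    PatientDB,
    PatientRecord,
    ProcedureEvent,
    Setting,
)

from conftest import dx, make_patient

D = dt.date


class TestExtractionPeriod:
    def test_default_terminus_is_study_end(self):
        p = make_patient()
        w = determine_extraction_period(p, STUDY_WINDOW)
        assert w == DateInterval(D(2018, 7, 1), D(2019, 12, 31))

    def test_arthroplasty_terminates_window(self, code_sets):
        p = make_patient(
            procedures=[ProcedureEvent("pt1", D(2018, 6, 1), "27447", CodeSystem.CPT4, 1.0)]
        )
        w = determine_extraction_period(p, STUDY_WINDOW, code_sets["ARTHROPLASTY"])
        # brute-force check: min over the three candidate termini, then
        # 18-calendar-month arithmetic
        assert w.end == min(D(2018, 6, 1), D(2019, 12, 31), D(2019, 12, 31))
        assert w == DateInterval(D(2016, 12, 2), D(2018, 6, 1))

    def test_disenrollment_terminates_window(self):
        p = make_patient()
        p.enrollments = [EnrollmentPeriod("pt1", D(2015, 1, 1), D(2017, 3, 31))]
        w = determine_extraction_period(p, STUDY_WINDOW)
        assert w.end == D(2017, 3, 31)

    def test_no_overlapping_enrollment_flagged(self):
        p = make_patient()
        p.enrollments = [EnrollmentPeriod("pt1", D(2010, 1, 1), D(2014, 12, 31))]
        with pytest.raises(ValueError, match="no enrollment"):
            determine_extraction_period(p, STUDY_WINDOW)

    def test_fixed_day_alternative(self):
        p = make_patient()
        w = determine_extraction_period(p, STUDY_WINDOW, fixed_days=548)
        assert w.days() == 548

    def test_window_invariants_on_cohort(self, synth_db, synth_windows):
        """Length <= 18 calendar months; end bounded; surgery only at the end."""
        for pid, w in synth_windows.items():
            assert w.end <= STUDY_WINDOW.end
            assert w.days() <= 550  # 18 calendar months is at most 550 days
            rec = synth_db.records[pid]
            for p in rec.procedures:
                if p.code in {"27447", "27130"} and w.contains(p.date):
                    assert p.date == w.end


class TestSelectCohort:
    def _db(self):
        db = PatientDB()
        # adult with OA, no cancer
        db.add(make_patient("ok", birth_year=1950,
                            diagnoses=[dx("ok", D(2019, 1, 1), "M17.0")]))
        # aged 17 at the anchor date
        db.add(make_patient("minor", birth_year=1998,
                            diagnoses=[dx("minor", D(2019, 1, 1))]))
        # cancer code alongside OA
        db.add(make_patient("onc", birth_year=1950,
                            diagnoses=[dx("onc", D(2019, 1, 1)),
                                       dx("onc", D(2019, 2, 1), "C50.911")]))
        # no OA diagnosis
        db.add(make_patient("noOA", birth_year=1950,
                            diagnoses=[dx("noOA", D(2019, 1, 1), "I10")]))
        # missing birth year
        db.add(make_patient("noby", birth_year=None,
                            diagnoses=[dx("noby", D(2019, 1, 1))]))
        return db

    def test_criteria(self, code_sets):
        selected = select_cohort(self._db(), SelectionCriteria(), code_sets)
        assert selected == ["ok"]

    def test_order_independent_and_idempotent(self, code_sets):
        db = self._db()
        shuffled = PatientDB()
        for pid in reversed(list(db.records)):
            shuffled.records[pid] = db.records[pid]
        a = select_cohort(db, SelectionCriteria(), code_sets)
        b = select_cohort(shuffled, SelectionCriteria(), code_sets)
        assert a == b == select_cohort(db, SelectionCriteria(), code_sets)

    def test_attrition_counts(self, code_sets):
        """600 OA-eligible patients of whom 29 carry cancer codes -> 571."""
        db = PatientDB()
        for i in range(600):
            pid = f"p{i:03d}"
            diagnoses = [dx(pid, D(2019, 1, 1))]
            if i < 29:
                diagnoses.append(dx(pid, D(2019, 3, 1), "C34.90"))
            db.add(make_patient(pid, birth_year=1950, diagnoses=diagnoses))
        assert len(select_cohort(db, SelectionCriteria(), code_sets)) == 571


class TestEnrichedSample:
    def test_quota_split(self):
        eligible = [f"e{i}" for i in range(500)] + [f"n{i}" for i in range(300)]
        flags = {pid: pid.startswith("e") for pid in eligible}
        sample = enriched_sample(eligible, flags, 600, 0.75, seed=3)
        assert len(sample) == 600
        assert sum(flags[p] for p in sample) == 450
        assert len(set(sample)) == 600

    def test_deterministic_under_seed(self):
        eligible = [f"p{i}" for i in range(100)]
        flags = {pid: i % 2 == 0 for i, pid in enumerate(eligible)}
        a = enriched_sample(eligible, flags, 40, 0.75, seed=11)
        b = enriched_sample(eligible, flags, 40, 0.75, seed=11)
        assert a == b
        assert a != enriched_sample(eligible, flags, 40, 0.75, seed=12)

    def test_infeasible_quota_is_error(self):
        eligible = [f"p{i}" for i in range(600)]
        flags = {pid: i < 100 for i, pid in enumerate(eligible)}
        with pytest.raises(ValueError, match="quota"):
            enriched_sample(eligible, flags, 600, 0.75, seed=0)


class TestComorbidityRule:
    W = DateInterval(D(2018, 7, 1), D(2019, 12, 31))

    def test_two_outpatient_45_days_apart(self, code_sets):
        p = make_patient(diagnoses=[dx("pt1", D(2019, 1, 1), "I10"),
                                    dx("pt1", D(2019, 2, 15), "I10")])
        assert comorbidity_present(p, code_sets["HYPERTENSION"], self.W)

    def test_two_outpatient_10_days_apart(self, code_sets):
        p = make_patient(diagnoses=[dx("pt1", D(2019, 1, 1), "I10"),
                                    dx("pt1", D(2019, 1, 11), "I10")])
        assert not comorbidity_present(p, code_sets["HYPERTENSION"], self.W)

    def test_30_day_boundary_inclusive(self, code_sets):
        p = make_patient(diagnoses=[dx("pt1", D(2019, 1, 1), "I10"),
                                    dx("pt1", D(2019, 1, 31), "I10")])
        assert comorbidity_present(p, code_sets["HYPERTENSION"], self.W)

    def test_single_inpatient_suffices(self, code_sets):
        p = make_patient(diagnoses=[dx("pt1", D(2019, 1, 1), "I10", setting=Setting.INPATIENT)])
        assert comorbidity_present(p, code_sets["HYPERTENSION"], self.W)

    def test_ed_visits_do_not_count(self, code_sets):
        p = make_patient(diagnoses=[dx("pt1", D(2019, 1, 1), "I10", setting=Setting.ED),
                                    dx("pt1", D(2019, 3, 1), "I10", setting=Setting.ED)])
        assert not comorbidity_present(p, code_sets["HYPERTENSION"], self.W)


def _ascertained(pid, code, dates, setting=Setting.OUTPATIENT_OFFICE):
    return [dx(pid, d, code, setting=setting) for d in dates]


class TestQuanCharlson:
    W = DateInterval(D(2018, 7, 1), D(2019, 12, 31))

    def test_no_comorbidity(self):
        assert quan_charlson(make_patient(), self.W).score == 0
        assert quan_charlson(make_patient(), self.W).category == "0"

    def test_uncomplicated_diabetes(self):
        p = make_patient(diagnoses=_ascertained("pt1", "E11.9", [D(2019, 1, 1), D(2019, 3, 1)]))
        res = quan_charlson(p, self.W)
        assert res.score == 1 and res.conditions == ("DIABETES",)

    def test_mi_plus_mild_liver(self):
        p = make_patient(diagnoses=(
            _ascertained("pt1", "I21.4", [D(2019, 1, 1), D(2019, 3, 1)])
            + _ascertained("pt1", "K70.0", [D(2019, 1, 5), D(2019, 4, 1)])
        ))
        assert quan_charlson(p, self.W).score == 2

    def test_hierarchy_complicated_diabetes_supersedes(self):
        p = make_patient(diagnoses=(
            _ascertained("pt1", "E11.9", [D(2019, 1, 1), D(2019, 3, 1)])
            + _ascertained("pt1", "E11.21", [D(2019, 1, 5), D(2019, 4, 1)])
        ))
        res = quan_charlson(p, self.W)
        assert res.score == 2 and "DIABETES" not in res.conditions

    def test_category_thresholds(self):
        assert [charlson_category(s) for s in (0, 1, 2, 3, 7)] == ["0", "1", "2", "3+", "3+"]

    def test_brute_force_rederivation(self, synth_db, synth_windows):
        """Score equals an independent enumerate-conditions re-derivation."""
        code_sets = quan_charlson_code_sets()
        pids = sorted(synth_db.records)[:200]
        for pid in pids:
            rec, w = synth_db.records[pid], synth_windows[pid]
            present = set()
            for name, cs in code_sets.items():
                inpt, out_dates = False, set()
                for d in rec.diagnoses:
                    if not (w.start <= d.date <= w.end):
                        continue
                    code = d.code.replace(".", "").upper()
                    hit = False
                    for system, pat in cs.patterns:
                        if system is not d.system:
                            continue
                        q = pat.replace(".", "").upper()
                        if (q.endswith("*") and code.startswith(q[:-1])) or code == q:
                            hit = True
                            break
                    if not hit:
                        continue
                    if d.setting is Setting.INPATIENT:
                        inpt = True
                    elif d.setting in {Setting.OUTPATIENT_OFFICE, Setting.OUTPATIENT_OTHER}:
                        out_dates.add(d.date)
                if inpt or (len(out_dates) >= 2 and (max(out_dates) - min(out_dates)).days >= 30):
                    present.add(name)
            for mild, severe in CHARLSON_HIERARCHY.items():
                if severe in present:
                    present.discard(mild)
            expected = sum(CHARLSON_WEIGHTS[c] for c in present)
            assert quan_charlson(rec, w).score == expected, pid


class TestClopperPearson:
    def test_single_observation_width(self):
        # oracle: exhaustive binomial tail inversion for n=1. With one
        # success, the lower bound solves P(X>=1)=p = alpha/2 -> 0.025 and
        # the upper bound is 1, so the width is 0.975.
        assert ppv_ci_width(0.5, 1, 0.95) == pytest.approx(0.975, abs=1e-9)

    def test_interval_bounds_match_binomial_inversion(self):
        # independent oracle: invert the binomial tails by bisection
        from scipy.stats import binom

        def invert(x, n, alpha=0.05):
            def bisect(f, lo, hi):
                for _ in range(80):
                    mid = (lo + hi) / 2
                    if f(mid):
                        hi = mid
                    else:
                        lo = mid
                return (lo + hi) / 2
            lower = 0.0 if x == 0 else bisect(lambda p: binom.sf(x - 1, n, p) > alpha / 2, 0, 1)
            upper = 1.0 if x == n else bisect(lambda p: binom.cdf(x, n, p) < alpha / 2, 0, 1)
            return lower, upper

        for x, n in [(480, 600), (8, 10), (1, 1), (0, 25), (25, 25)]:
            lo, up = clopper_pearson(x, n)
            olo, oup = invert(x, n)
            assert lo == pytest.approx(olo, abs=1e-6)
            assert up == pytest.approx(oup, abs=1e-6)

    def test_width_non_increasing_in_n(self):
        widths = [ppv_ci_width(0.8, n) for n in range(10, 1001, 30)]
        assert all(b <= a + 1e-12 for a, b in zip(widths, widths[1:]))

    def test_scan_recovers_denominator_for_published_width(self):
        """A 0.081-wide 95% CI at PPV 0.80 corresponds to ~400 positives."""
        best_n = min(range(50, 2001), key=lambda n: abs(ppv_ci_width(0.8, n) - 0.081))
        assert 350 <= best_n <= 450

    def test_errors(self):
        with pytest.raises(ValueError):
            ppv_ci_width(0.8, 0)
        with pytest.raises(ValueError):
            ppv_ci_width(1.0, 10)
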