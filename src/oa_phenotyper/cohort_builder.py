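"""Cohort construction for the claims phenotyping pipeline.

Covers patient selection (adult, hip/knee OA diagnosis, cancer-free),
per-patient 18-month extraction windows terminated by arthroplasty /
disenrollment / study end, enriched (oversampled) chart-review sampling,
the two-outpatient-or-one-inpatient comorbidity ascertainment rule, the
Quan-coded Charlson comorbidity index, and exact (Clopper-Pearson) binomial
confidence-interval widths used for PPV sample-size planning.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .records_io import (
    CodeSet,
    CodeSystem,
    PatientDB,
    PatientRecord,
    Setting,
    OUTPATIENT_SETTINGS,
    match_code,
)

__all__ = [
    "DateInterval",
    "SelectionCriteria",
    "CharlsonResult",
    "STUDY_WINDOW",
    "determine_extraction_period",
    "select_cohort",
    "enriched_sample",
    "comorbidity_present",
    "quan_charlson",
    "quan_charlson_code_sets",
    "CHARLSON_WEIGHTS",
    "clopper_pearson",
    "ppv_ci_width",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DateInterval:
    """Closed calendar-date interval (both ends inclusive)."""

    start: dt.date
    end: dt.date

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"interval start {self.start} after end {self.end}")

    def contains(self, date: dt.date) -> bool:
        return self.start <= date <= self.end

    def days(self) -> int:
        """Number of calendar days covered (closed interval)."""
        return (self.end - self.start).days + 1


#: Default study window.
STUDY_WINDOW = DateInterval(dt.date(2015, 1, 1), dt.date(2019, 12, 31))


@dataclass(frozen=True)
class SelectionCriteria:
    min_age: int = 18
    age_anchor: dt.date = dt.date(2015, 1, 1)
    required_dx: str = "OA_HIP_KNEE"
    exclusion_dx: str = "CANCER_EXCLUSION"
    study_window: DateInterval = STUDY_WINDOW


@dataclass(frozen=True)
class CharlsonResult:
    score: int
    category: str  # "0" | "1" | "2" | "3+"
    conditions: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("negative Charlson score")


def charlson_category(score: int) -> str:
    if score <= 0:
        return "0"
    if score == 1:
        return "1"
    if score == 2:
        return "2"
    return "3+"


# ---------------------------------------------------------------------------
# Extraction period
# ---------------------------------------------------------------------------


def _add_months(date: dt.date, months: int) -> dt.date:
    """Calendar-month shift with end-of-month clamping."""
    month_index = date.month - 1 + months
    year = date.year + month_index // 12
    month = month_index % 12 + 1
    # clamp the day to the target month's length
    if month == 12:
        last = 31
    else:
        last = (dt.date(year, month + 1, 1) - dt.timedelta(days=1)).day
    return dt.date(year, month, min(date.day, last))


class NonEvaluablePatient(ValueError):
    """Patient has no enrollment overlapping the study window."""


def determine_extraction_period(
    patient: PatientRecord,
    study_window: DateInterval = STUDY_WINDOW,
    arthroplasty_set: CodeSet | None = None,
    *,
    window_months: int = 18,
    fixed_days: int | None = None,
) -> DateInterval:
    """Most-recent observation window of at most 18 months for one patient.

    The window ends at the earliest of (1) the patient's first qualifying
    knee/hip arthroplasty inside the study window, (2) the end of the
    enrollment period covering that time, and (3) the study-window end. The
    terminating arthroplasty date itself is inside the window, so surgery is
    visible to the rules. The start is ``end`` minus 18 calendar months plus
    one day (closed interval), clipped to the study-window start; passing
    ``fixed_days`` (e.g. 548) switches to fixed day-count arithmetic.
    """
    overlapping = [
        e
        for e in patient.enrollments
        if e.start <= study_window.end and e.end >= study_window.start
    ]
    if not overlapping:
        raise NonEvaluablePatient(
            f"patient {patient.patient_id!r}: no enrollment overlapping study window"
        )
    # the most recent enrollment period determines the disenrollment terminus
    enrollment = max(overlapping, key=lambda e: (e.end, e.start))
    end = min(enrollment.end, study_window.end)

    if arthroplasty_set is not None:
        surgery_dates = sorted(
            p.date
            for p in patient.procedures
            if study_window.contains(p.date) and match_code(p.code, p.system, arthroplasty_set)
        )
        if surgery_dates:
            end = min(end, surgery_dates[0])

    if fixed_days is not None:
        start = end - dt.timedelta(days=fixed_days - 1)
    else:
        start = _add_months(end, -window_months) + dt.timedelta(days=1)
    start = max(start, study_window.start)
    return DateInterval(start, end)


# ---------------------------------------------------------------------------
# Patient selection and enriched sampling
# ---------------------------------------------------------------------------


def select_cohort(
    db: PatientDB,
    criteria: SelectionCriteria,
    code_sets: dict[str, CodeSet],
) -> list[str]:
    """Apply the study inclusion/exclusion criteria; deterministic output.

    Retains adults (age at the anchor date computed from birth year) with at
    least one hip/knee OA diagnosis and no excluding cancer diagnosis inside
    the study window. Patients missing a birth year are excluded with a
    logged warning.
    """
    required = code_sets[criteria.required_dx]
    exclusion = code_sets[criteria.exclusion_dx]
    window = criteria.study_window
    selected: list[str] = []
    for pid in db.patient_ids():
        rec = db.records[pid]
        if rec.birth_year is None:
            logger.warning("patient %s excluded: missing birth_year", pid)
            continue
        age = criteria.age_anchor.year - rec.birth_year
        if age < criteria.min_age:
            continue
        in_window = [d for d in rec.diagnoses if window.contains(d.date)]
        if not any(match_code(d.code, d.system, required) for d in in_window):
            continue
        if any(match_code(d.code, d.system, exclusion) for d in in_window):
            continue
        selected.append(pid)
    return selected


def enriched_sample(
    eligible: list[str],
    enriched_flags: dict[str, bool],
    target_n: int,
    enriched_fraction: float = 0.75,
    seed: int = 0,
) -> list[str]:
    """Disproportionate stratified sample: 75% from the enriched stratum.

    Samples without replacement ``round(target_n * enriched_fraction)``
    patients flagged as enriched (severity proxies) and the remainder from
    the non-enriched stratum. A stratum smaller than its quota is an error —
    there is no silent top-up from the other stratum.
    """
    if target_n > len(eligible):
        raise ValueError(f"target_n {target_n} exceeds eligible pool {len(eligible)}")
    if not 0 <= enriched_fraction <= 1:
        raise ValueError("enriched_fraction must be in [0, 1]")
    n_enriched = int(np.floor(target_n * enriched_fraction + 0.5))
    n_plain = target_n - n_enriched
    enriched = sorted(pid for pid in eligible if enriched_flags.get(pid, False))
    plain = sorted(pid for pid in eligible if not enriched_flags.get(pid, False))
    if len(enriched) < n_enriched:
        raise ValueError(
            f"enriched stratum has {len(enriched)} patients, quota is {n_enriched}"
        )
    if len(plain) < n_plain:
        raise ValueError(
            f"non-enriched stratum has {len(plain)} patients, quota is {n_plain}"
        )
    rng = np.random.default_rng(seed)
    take_e = list(rng.choice(enriched, size=n_enriched, replace=False)) if n_enriched else []
    take_p = list(rng.choice(plain, size=n_plain, replace=False)) if n_plain else []
    return sorted(str(p) for p in take_e + take_p)


# ---------------------------------------------------------------------------
# Comorbidity ascertainment and the Quan-coded Charlson index
# ---------------------------------------------------------------------------


def comorbidity_present(
    patient: PatientRecord,
    code_set: CodeSet,
    window: DateInterval,
) -> bool:
    """Claims comorbidity rule guarding against rule-out diagnoses.

    True iff the patient has two or more outpatient diagnoses in the code set
    on dates at least 30 days apart within the window, or at least one
    inpatient diagnosis in the code set within the window.
    """
    outpatient_dates: set[dt.date] = set()
    for d in patient.diagnoses:
        if not window.contains(d.date):
            continue
        if not match_code(d.code, d.system, code_set):
            continue
        if d.setting is Setting.INPATIENT:
            return True
        if d.setting in OUTPATIENT_SETTINGS:
            outpatient_dates.add(d.date)
    if len(outpatient_dates) >= 2:
        dates = sorted(outpatient_dates)
        if (dates[-1] - dates[0]).days >= 30:
            return True
    return False


_I9 = CodeSystem.ICD9CM
_I10 = CodeSystem.ICD10CM


def _qcs(name: str, icd9: list[str], icd10: list[str]) -> CodeSet:
    patterns = [(_I9, p) for p in icd9] + [(_I10, p) for p in icd10]
    return CodeSet(name=name, patterns=tuple(patterns), provenance="curated")


def quan_charlson_code_sets() -> dict[str, CodeSet]:
    """Quan (2005) ICD-9-CM / ICD-10 condition definitions, as prefix sets."""
    return {
        s.name: s
        for s in [
            _qcs("MI", ["410*", "412*"], ["I21*", "I22*", "I25.2*"]),
            _qcs(
                "CHF",
                ["398.91", "402.01", "402.11", "402.91", "404.01", "404.03",
                 "404.11", "404.13", "404.91", "404.93", "425.4", "425.5",
                 "425.6", "425.7", "425.8", "425.9", "428*"],
                ["I09.9", "I11.0", "I13.0", "I13.2", "I25.5", "I42.0", "I42.5",
                 "I42.6", "I42.7", "I42.8", "I42.9", "I43*", "I50*", "P29.0"],
            ),
            _qcs(
                "PVD",
                ["093.0", "437.3", "440*", "441*", "443.1", "443.2", "443.8",
                 "443.9", "447.1", "557.1", "557.9", "V43.4"],
                ["I70*", "I71*", "I73.1", "I73.8", "I73.9", "I77.1", "I79.0",
                 "I79.2", "K55.1", "K55.8", "K55.9", "Z95.8", "Z95.9"],
            ),
            _qcs(
                "CVD",
                ["362.34", "430*", "431*", "432*", "433*", "434*", "435*",
                 "436*", "437*", "438*"],
                ["G45*", "G46*", "H34.0", "I60*", "I61*", "I62*", "I63*",
                 "I64*", "I65*", "I66*", "I67*", "I68*", "I69*"],
            ),
            _qcs(
                "DEMENTIA",
                ["290*", "294.1", "331.2"],
                ["F00*", "F01*", "F02*", "F03*", "F05.1", "G30*", "G31.1"],
            ),
            _qcs(
                "CHRONIC_PULMONARY",
                ["416.8", "416.9", "490*", "491*", "492*", "493*", "494*",
                 "495*", "496*", "500*", "501*", "502*", "503*", "504*",
                 "505*", "506.4", "508.1", "508.8"],
                ["I27.8", "I27.9", "J40*", "J41*", "J42*", "J43*", "J44*",
                 "J45*", "J46*", "J47*", "J60*", "J61*", "J62*", "J63*",
                 "J64*", "J65*", "J66*", "J67*", "J68.4", "J70.1", "J70.3"],
            ),
            _qcs(
                "RHEUMATIC",
                ["446.5", "710.0", "710.1", "710.2", "710.3", "710.4",
                 "714.0", "714.1", "714.2", "714.8", "725*"],
                ["M05*", "M06*", "M31.5", "M32*", "M33*", "M34*", "M35.1",
                 "M35.3", "M36.0"],
            ),
            _qcs("PUD", ["531*", "532*", "533*", "534*"], ["K25*", "K26*", "K27*", "K28*"]),
            _qcs(
                "MILD_LIVER",
                ["070.22", "070.23", "070.32", "070.33", "070.44", "070.54",
                 "070.6", "070.9", "570*", "571.0", "571.2", "571.3", "571.4",
                 "571.5", "571.6", "571.8", "571.9", "573.3", "573.4",
                 "573.8", "573.9", "V42.7"],
                ["B18*", "K70.0", "K70.1", "K70.2", "K70.3", "K70.9", "K71.3",
                 "K71.4", "K71.5", "K71.7", "K73*", "K74*", "K76.0", "K76.2",
                 "K76.3", "K76.4", "K76.8", "K76.9", "Z94.4"],
            ),
            _qcs(
                "DIABETES",
                ["250.0*", "250.1*", "250.2*", "250.3*", "250.8*", "250.9*"],
                ["E10.0*", "E10.1*", "E10.6*", "E10.8*", "E10.9*",
                 "E11.0*", "E11.1*", "E11.6*", "E11.8*", "E11.9*",
                 "E13.0*", "E13.1*", "E13.6*", "E13.8*", "E13.9*"],
            ),
            _qcs(
                "DIABETES_COMPLICATED",
                ["250.4*", "250.5*", "250.6*", "250.7*"],
                ["E10.2*", "E10.3*", "E10.4*", "E10.5*", "E10.7*",
                 "E11.2*", "E11.3*", "E11.4*", "E11.5*", "E11.7*",
                 "E13.2*", "E13.3*", "E13.4*", "E13.5*", "E13.7*"],
            ),
            _qcs(
                "HEMIPLEGIA",
                ["334.1", "342*", "343*", "344.0", "344.1", "344.2", "344.3",
                 "344.4", "344.5", "344.6", "344.9"],
                ["G04.1", "G11.4", "G80.1", "G80.2", "G81*", "G82*", "G83.0",
                 "G83.1", "G83.2", "G83.3", "G83.4", "G83.9"],
            ),
            _qcs(
                "RENAL",
                ["403.01", "403.11", "403.91", "404.02", "404.03", "404.12",
                 "404.13", "404.92", "404.93", "582*", "583.0", "583.1",
                 "583.2", "583.4", "583.6", "583.7", "585*", "586*", "588.0",
                 "V42.0", "V45.1", "V56*"],
                ["I12.0", "I13.1", "N03.2", "N03.3", "N03.4", "N03.5",
                 "N03.6", "N03.7", "N05.2", "N05.3", "N05.4", "N05.5",
                 "N05.6", "N05.7", "N18*", "N19*", "N25.0", "Z49.0", "Z49.1",
                 "Z49.2", "Z94.0", "Z99.2"],
            ),
            _qcs(
                "MALIGNANCY",
                ["14*", "15*", "16*", "170*", "171*", "172*", "174*", "175*",
                 "176*", "179*", "18*", "190*", "191*", "192*", "193*",
                 "194*", "195*", "200*", "201*", "202*", "203*", "204*",
                 "205*", "206*", "207*", "208*", "238.6"],
                ["C0*", "C1*", "C2*", "C30*", "C31*", "C32*", "C33*", "C34*",
                 "C37*", "C38*", "C39*", "C40*", "C41*", "C43*", "C45*",
                 "C46*", "C47*", "C48*", "C49*", "C5*", "C6*", "C70*",
                 "C71*", "C72*", "C73*", "C74*", "C75*", "C76*", "C81*",
                 "C82*", "C83*", "C84*", "C85*", "C88*", "C90*", "C91*",
                 "C92*", "C93*", "C94*", "C95*", "C96*", "C97*"],
            ),
            _qcs(
                "SEVERE_LIVER",
                ["456.0", "456.1", "456.2", "572.2", "572.3", "572.4",
                 "572.8"],
                ["I85.0", "I85.9", "I86.4", "I98.2", "K70.4", "K71.1",
                 "K72.1", "K72.9", "K76.5", "K76.6", "K76.7"],
            ),
            _qcs("METASTATIC", ["196*", "197*", "198*", "199*"], ["C77*", "C78*", "C79*", "C80*"]),
            _qcs("HIV", ["042*", "043*", "044*"], ["B20*", "B21*", "B22*", "B24*"]),
        ]
    }


#: Original Charlson weights on the Quan condition set.
CHARLSON_WEIGHTS: dict[str, int] = {
    "MI": 1,
    "CHF": 1,
    "PVD": 1,
    "CVD": 1,
    "DEMENTIA": 1,
    "CHRONIC_PULMONARY": 1,
    "RHEUMATIC": 1,
    "PUD": 1,
    "MILD_LIVER": 1,
    "DIABETES": 1,
    "DIABETES_COMPLICATED": 2,
    "HEMIPLEGIA": 2,
    "RENAL": 2,
    "MALIGNANCY": 2,
    "SEVERE_LIVER": 3,
    "METASTATIC": 6,
    "HIV": 6,
}

#: Hierarchy: the severe form supersedes the mild one when both present.
CHARLSON_HIERARCHY: dict[str, str] = {
    "DIABETES": "DIABETES_COMPLICATED",
    "MILD_LIVER": "SEVERE_LIVER",
    "MALIGNANCY": "METASTATIC",
}


def quan_charlson(
    patient: PatientRecord,
    window: DateInterval,
    *,
    ascertainment: bool = True,
) -> CharlsonResult:
    """Charlson comorbidity score with Quan (2005) code definitions.

    Conditions are ascertained with the two-outpatient/one-inpatient rule
    (set ``ascertainment=False`` to count any single diagnosis), the
    mild/severe hierarchies are applied, and the score is binned into the
    reporting categories 0 / 1 / 2 / 3+.
    """
    code_sets = quan_charlson_code_sets()
    present: set[str] = set()
    for name, cs in code_sets.items():
        if ascertainment:
            if comorbidity_present(patient, cs, window):
                present.add(name)
        else:
            if any(
                window.contains(d.date) and match_code(d.code, d.system, cs)
                for d in patient.diagnoses
            ):
                present.add(name)
    for mild, severe in CHARLSON_HIERARCHY.items():
        if severe in present:
            present.discard(mild)
    score = sum(CHARLSON_WEIGHTS[c] for c in present)
    return CharlsonResult(score=score, category=charlson_category(score), conditions=tuple(sorted(present)))


# ---------------------------------------------------------------------------
# Clopper-Pearson sample-size support
# ---------------------------------------------------------------------------


def clopper_pearson(x: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval via beta quantiles."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= x <= n:
        raise ValueError("x out of range")
    alpha = 1.0 - confidence
    lower = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    upper = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return lower, upper


def ppv_ci_width(ppv: float, n_positives: int, confidence: float = 0.95) -> float:
    """Width of the exact CI around a PPV estimated from ``n_positives`` calls.

    ``x`` is the half-up rounding of ``ppv * n_positives``. Used to reason
    about how many algorithm-positive patients must be chart-reviewed for a
    target PPV precision.
    """
    if not 0 < ppv < 1:
        raise ValueError("ppv must be strictly between 0 and 1")
    if n_positives <= 0:
        raise ValueError("n_positives must be positive")
    x = int(np.floor(ppv * n_positives + 0.5))
    lower, upper = clopper_pearson(x, n_positives, confidence)
    return upper - lower
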