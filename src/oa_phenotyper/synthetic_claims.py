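"""Labeled synthetic claims cohorts with the published archetype structure.

The validation study's raw data are restricted, so this module generates
synthetic longitudinal claims for three patient archetypes — patients without
hip/knee OA, OA "comparator" patients, and "case" patients (hip/knee OA that
is moderate-to-severe with inadequate response to at least two analgesic
classes) — whose per-concept event frequencies default to the published
clinical-characteristics table (claims subset; denominators 47/360/83).

Every patient receives an enrollment period covering the whole study window.
Events are placed inside the patient's 18-month extraction window (ending at
a generated arthroplasty when one occurs, otherwise at study end). Concepts
are sampled independently per patient — the published table reports marginal
frequencies only — with repeated-event counts drawn Poisson with rate
``-ln(1-p)`` so the presence probability equals the marginal ``p``. An
optional lift hook couples selected concept pairs for stress tests.

Step-1 structure is planted by construction: case patients always carry at
least two outpatient OA diagnoses 30+ days apart, comparators at least one
OA diagnosis, and non-OA patients none.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .cohort_builder import STUDY_WINDOW, DateInterval, _add_months
from .records_io import (
    CodeSystem,
    DiagnosisEvent,
    DrugClaim,
    DrugClass,
    EnrollmentPeriod,
    GoldLabel,
    PatientDB,
    PatientRecord,
    ProcedureEvent,
    Setting,
)
from .published import TABLE1_COUNTS

__all__ = [
    "SynthConfig",
    "default_config",
    "generate",
    "plant_edge_cases",
    "PANEL_EXPECTATIONS",
    "enriched_proxy_flags",
    "DX_CONCEPTS",
    "DRUG_CONCEPTS",
    "PROC_CONCEPTS",
]

ARCHETYPES = ("non_oa", "case", "comparator")

# concept -> (code, system) for generated diagnosis events
DX_CONCEPTS: dict[str, tuple[str, CodeSystem]] = {
    "obesity": ("E66.9", CodeSystem.ICD10CM),
    "joint_pain_hip": ("M25.551", CodeSystem.ICD10CM),
    "joint_pain_knee": ("M25.561", CodeSystem.ICD10CM),
    "joint_pain_other": ("M25.511", CodeSystem.ICD10CM),
    "back_pain": ("M54.5", CodeSystem.ICD10CM),
    "unspecified_pain": ("R52", CodeSystem.ICD10CM),
    "hypertension": ("I10", CodeSystem.ICD10CM),
    "diabetes": ("E11.9", CodeSystem.ICD10CM),
    "gerd": ("K21.9", CodeSystem.ICD10CM),
    "depression": ("F32.9", CodeSystem.ICD10CM),
    "anxiety": ("F41.1", CodeSystem.ICD10CM),
    "drug_alcohol_abuse": ("F10.20", CodeSystem.ICD10CM),
    "insomnia": ("G47.00", CodeSystem.ICD10CM),
}

DRUG_CONCEPTS: dict[str, DrugClass] = {
    "nsaid_nonsel": DrugClass.NSAID_NONSEL,
    "nsaid_cox2": DrugClass.NSAID_COX2,
    "nsaid_topical": DrugClass.NSAID_TOPICAL,
    "opioid_sa": DrugClass.OPIOID_SA,
    "opioid_la": DrugClass.OPIOID_LA,
    "opioid_mixed": DrugClass.OPIOID_MIXED,
    "oral_corticosteroid": DrugClass.ORAL_CORTICOSTEROID,
    "h2_blocker": DrugClass.H2_BLOCKER,
}

# concept -> (code, system, median cost)
PROC_CONCEPTS: dict[str, tuple[str, CodeSystem, float]] = {
    "ia_corticosteroid": ("20610", CodeSystem.CPT4, 300.0),
    "ha_injection": ("J7321", CodeSystem.HCPCS, 600.0),
    "hip_replacement": ("27130", CodeSystem.CPT4, 15000.0),
    "knee_replacement": ("27447", CodeSystem.CPT4, 15000.0),
    "nerve_block": ("64450", CodeSystem.CPT4, 800.0),
    "xray_hip_knee": ("73560", CodeSystem.CPT4, 150.0),
    "mri_hip_knee": ("73721", CodeSystem.CPT4, 900.0),
    "pt_ot": ("97110", CodeSystem.CPT4, 120.0),
    "mobility_aid": ("E0130", CodeSystem.HCPCS, 80.0),
}

_ARTHROPLASTY_CONCEPTS = ("hip_replacement", "knee_replacement")

#: Utilization concepts absent from the published table; curated rates.
_CURATED_RATES: dict[str, dict[str, float]] = {
    "xray_hip_knee": {"non_oa": 0.20, "case": 0.75, "comparator": 0.45},
    "mri_hip_knee": {"non_oa": 0.05, "case": 0.25, "comparator": 0.12},
    "pt_ot": {"non_oa": 0.10, "case": 0.40, "comparator": 0.20},
    "mobility_aid": {"non_oa": 0.02, "case": 0.15, "comparator": 0.05},
}


@dataclass(frozen=True)
class SynthConfig:
    n_non_oa: int = 47
    n_case: int = 360
    n_comparator: int = 83
    #: archetype -> concept -> presence probability
    rates: dict[str, dict[str, float]] = field(default_factory=dict)
    study_window: DateInterval = STUDY_WINDOW
    #: mean age (years) at the study anchor per archetype
    age_mean: dict[str, float] = field(
        default_factory=lambda: {"non_oa": 60.6, "case": 63.2, "comparator": 63.2}
    )
    age_sd: float = 10.0
    female_fraction: dict[str, float] = field(
        default_factory=lambda: {"non_oa": 0.638, "case": 0.644, "comparator": 0.644}
    )
    #: log-scale sigma of the log-normal cost draw
    cost_sigma: float = 0.5
    #: multiplicative shift of case patients' cost location parameter
    case_cost_multiplier: float = 1.5
    drug_fill_median_cost: float = 40.0
    #: comparator label mixture (claims subset: 53/83 and 3/83)
    comparator_moderate_rate: float = 53 / 83
    comparator_inadequate_rate: float = 3 / 83
    #: optional presence coupling: (concept_a, concept_b) -> lift on
    #: P(b | a present); the marginal of b is not preserved when used.
    couplings: dict[tuple[str, str], float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for arch, table in self.rates.items():
            for concept, p in table.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"rate {arch}.{concept}={p} outside [0,1]")

    def rate(self, archetype: str, concept: str) -> float:
        return self.rates[archetype][concept]


def default_config(**overrides) -> SynthConfig:
    """Config whose archetype rates are the published claims-subset
    frequencies (printed percentages / 100), plus curated utilization rates
    for concepts the publication does not tabulate."""
    rates: dict[str, dict[str, float]] = {a: {} for a in ARCHETYPES}
    event_concepts = (
        set(DX_CONCEPTS) | set(DRUG_CONCEPTS) | {
            "ia_corticosteroid", "ha_injection", "hip_replacement",
            "knee_replacement", "nerve_block",
        }
    )
    for concept, per_arch in TABLE1_COUNTS.items():
        if concept not in event_concepts:
            continue  # aggregates and Charlson categories are derived, not sampled
        for arch in ARCHETYPES:
            rates[arch][concept] = per_arch[arch][1] / 100.0
    for concept, per_arch in _CURATED_RATES.items():
        for arch in ARCHETYPES:
            rates[arch][concept] = per_arch[arch]
    return SynthConfig(rates=rates, **overrides)


def _poisson_count(rng: np.random.Generator, p: float) -> int:
    """Event count with P(count >= 1) == p (Poisson with rate -ln(1-p))."""
    if p <= 0.0:
        return 0
    if p >= 1.0:
        return 1 + int(rng.poisson(1.0))
    return int(rng.poisson(-math.log1p(-p)))


def _rand_date(rng: np.random.Generator, interval: DateInterval) -> dt.date:
    span = (interval.end - interval.start).days
    return interval.start + dt.timedelta(days=int(rng.integers(0, span + 1)))


def _lognormal_cost(rng: np.random.Generator, median: float, sigma: float) -> float:
    return float(median * math.exp(sigma * rng.standard_normal()))


def _dx_setting(rng: np.random.Generator) -> Setting:
    u = rng.random()
    if u < 0.70:
        return Setting.OUTPATIENT_OFFICE
    if u < 0.90:
        return Setting.OUTPATIENT_OTHER
    if u < 0.96:
        return Setting.ED
    return Setting.INPATIENT


def _draw_counts(
    rng: np.random.Generator, config: SynthConfig, archetype: str
) -> dict[str, int]:
    """Per-concept event counts; P(count >= 1) equals the archetype rate.

    Arthroplasty concepts are at most one event (the window terminus); all
    other concepts draw a Poisson count with rate ``-ln(1-p)``. Coupling
    lifts inflate a concept's rate when its partner is already present
    (concepts are processed in sorted order).
    """
    counts: dict[str, int] = {}
    for concept in sorted(config.rates[archetype]):
        p = config.rate(archetype, concept)
        for (a, b), lift in config.couplings.items():
            if b == concept and counts.get(a, 0) > 0:
                p = min(1.0, p * lift)
        if concept in _ARTHROPLASTY_CONCEPTS:
            counts[concept] = int(rng.random() < p)
        else:
            counts[concept] = _poisson_count(rng, p)
    return counts


def generate(config: SynthConfig | None = None) -> PatientDB:
    """Generate a labeled synthetic cohort; reproducible under ``config.seed``."""
    if config is None:
        config = default_config()
    rng = np.random.default_rng(config.seed)
    window = config.study_window
    # the most recent 18 months of the study window (the default extraction
    # period when no arthroplasty intervenes)
    extract_start = max(_add_months(window.end, -18) + dt.timedelta(days=1), window.start)

    db = PatientDB()
    counter = 0
    plan = (
        [("non_oa", None)] * config.n_non_oa
        + [("case", None)] * config.n_case
        + [("comparator", None)] * config.n_comparator
    )
    for archetype, _ in plan:
        counter += 1
        pid = f"P{counter:05d}"
        age = float(np.clip(config.age_mean[archetype] + config.age_sd * rng.standard_normal(), 19, 95))
        birth_year = window.start.year - int(round(age))
        sex = "F" if rng.random() < config.female_fraction[archetype] else "M"
        race = "White" if rng.random() < (0.70 if archetype != "non_oa" else 0.532) else "Other"
        rec = PatientRecord(
            patient_id=pid, birth_year=birth_year, sex=sex, race=race,
            enrollments=[EnrollmentPeriod(pid, window.start, window.end)],
        )

        counts = _draw_counts(rng, config, archetype)

        # arthroplasty, when present, terminates the extraction window: put it
        # late so the remaining events stay observable
        surgery_date: dt.date | None = None
        if any(counts.get(c, 0) > 0 for c in _ARTHROPLASTY_CONCEPTS):
            last = DateInterval(window.end - dt.timedelta(days=120), window.end)
            surgery_date = _rand_date(rng, last)
        event_interval = DateInterval(
            extract_start, surgery_date if surgery_date else window.end
        )

        cost_mult = config.case_cost_multiplier if archetype == "case" else 1.0

        # planted OA diagnoses (step-1 construction)
        if archetype == "case":
            first = _rand_date(
                rng, DateInterval(event_interval.start, event_interval.end - dt.timedelta(days=90))
            )
            gap = int(rng.integers(30, 91))
            rec.diagnoses.append(DiagnosisEvent(pid, first, "M17.11", CodeSystem.ICD10CM, Setting.OUTPATIENT_OFFICE))
            rec.diagnoses.append(DiagnosisEvent(pid, first + dt.timedelta(days=gap), "M17.11", CodeSystem.ICD10CM, Setting.OUTPATIENT_OFFICE))
            extra = int(rng.poisson(3.0))
        elif archetype == "comparator":
            rec.diagnoses.append(DiagnosisEvent(pid, _rand_date(rng, event_interval), "M16.11", CodeSystem.ICD10CM, Setting.OUTPATIENT_OFFICE))
            extra = int(rng.poisson(1.5))
        else:
            extra = 0
        for _ in range(extra):
            code = "M17.11" if rng.random() < 0.6 else "M16.11"
            rec.diagnoses.append(
                DiagnosisEvent(pid, _rand_date(rng, event_interval), code, CodeSystem.ICD10CM, _dx_setting(rng))
            )

        # comorbidity / pain diagnoses
        for concept, (code, system) in DX_CONCEPTS.items():
            for _ in range(counts.get(concept, 0)):
                rec.diagnoses.append(
                    DiagnosisEvent(pid, _rand_date(rng, event_interval), code, system, _dx_setting(rng))
                )

        # drug fills
        for concept, drug_class in DRUG_CONCEPTS.items():
            for _ in range(counts.get(concept, 0)):
                rec.drugs.append(
                    DrugClaim(
                        pid,
                        _rand_date(rng, event_interval),
                        drug_class,
                        cost=_lognormal_cost(rng, config.drug_fill_median_cost * cost_mult, config.cost_sigma),
                    )
                )

        # procedures
        for concept, (code, system, median) in PROC_CONCEPTS.items():
            n = counts.get(concept, 0)
            if n == 0:
                continue
            if concept in _ARTHROPLASTY_CONCEPTS:
                rec.procedures.append(
                    ProcedureEvent(pid, surgery_date, code, system, _lognormal_cost(rng, median * cost_mult, config.cost_sigma))
                )
                continue
            for _ in range(n):
                rec.procedures.append(
                    ProcedureEvent(pid, _rand_date(rng, event_interval), code, system, _lognormal_cost(rng, median * cost_mult, config.cost_sigma))
                )

        if archetype == "case":
            label = GoldLabel(pid, True, True, True)
        elif archetype == "comparator":
            moderate = rng.random() < config.comparator_moderate_rate
            inadequate = rng.random() < config.comparator_inadequate_rate
            if moderate and inadequate:
                inadequate = False  # all-three-true would make it a case
            label = GoldLabel(pid, True, moderate, inadequate)
        else:
            label = GoldLabel(pid, False, False, False)
        db.add(rec.sorted(), label)
    return db


def enriched_proxy_flags(db: PatientDB) -> dict[str, bool]:
    """Severity-proxy enrichment flags (stand-in for the study's criteria).

    A patient is "enriched" if they have any joint injection, nerve block, or
    arthroplasty procedure, or fills from two or more opioid classes.
    """
    proxy_codes = {"20610", "J7321", "J7323", "J7325", "J3301", "J1030",
                   "64450", "64640", "64635", "27130", "27447", "27446",
                   "27125", "27134", "27486", "27487"}
    flags: dict[str, bool] = {}
    opioid = {DrugClass.OPIOID_SA, DrugClass.OPIOID_LA, DrugClass.OPIOID_MIXED}
    for pid, rec in db.records.items():
        has_proc = any(p.code in proxy_codes for p in rec.procedures)
        n_opioid_classes = len({f.drug_class for f in rec.drugs if f.drug_class in opioid})
        flags[pid] = has_proc or n_opioid_classes >= 2
    return flags


# ---------------------------------------------------------------------------
# Hand-constructed boundary panel
# ---------------------------------------------------------------------------

_D = dt.date
_OFF = Setting.OUTPATIENT_OFFICE
_I10 = CodeSystem.ICD10CM
_CPT = CodeSystem.CPT4
_HCP = CodeSystem.HCPCS


def _panel_patients() -> list[tuple[PatientRecord, GoldLabel, dict[tuple[int, int], bool]]]:
    """The fixed boundary panel: (record, label, expected rule outcomes)."""

    def rec(pid: str) -> PatientRecord:
        return PatientRecord(
            patient_id=pid, birth_year=1955, sex="F", race="White",
            enrollments=[EnrollmentPeriod(pid, STUDY_WINDOW.start, STUDY_WINDOW.end)],
        )

    panel = []

    # two outpatient OA dx exactly 90 days apart: step-1 #2 inclusive boundary
    r = rec("edge-90d")
    r.diagnoses += [
        DiagnosisEvent(r.patient_id, _D(2019, 1, 1), "M17.11", _I10, _OFF),
        DiagnosisEvent(r.patient_id, _D(2019, 4, 1), "M17.11", _I10, _OFF),  # +90d
    ]
    panel.append((r, GoldLabel(r.patient_id, True, False, False),
                  {(1, 1): True, (1, 2): True, (1, 4): True, (1, 5): True, (1, 3): False}))

    # 91 days apart: #2 false, #1 (183d) still true
    r = rec("edge-91d")
    r.diagnoses += [
        DiagnosisEvent(r.patient_id, _D(2019, 1, 1), "M17.11", _I10, _OFF),
        DiagnosisEvent(r.patient_id, _D(2019, 4, 2), "M17.11", _I10, _OFF),  # +91d
    ]
    panel.append((r, GoldLabel(r.patient_id, True, False, False),
                  {(1, 2): False, (1, 1): True}))

    # 183 vs 184 days: step-1 #1 boundary
    r = rec("edge-183d")
    r.diagnoses += [
        DiagnosisEvent(r.patient_id, _D(2018, 8, 1), "M16.11", _I10, _OFF),
        DiagnosisEvent(r.patient_id, _D(2019, 1, 31), "M16.11", _I10, _OFF),  # +183d
    ]
    panel.append((r, GoldLabel(r.patient_id, True, False, False), {(1, 1): True}))

    r = rec("edge-184d")
    r.diagnoses += [
        DiagnosisEvent(r.patient_id, _D(2018, 8, 1), "M16.11", _I10, _OFF),
        DiagnosisEvent(r.patient_id, _D(2019, 2, 1), "M16.11", _I10, _OFF),  # +184d
    ]
    panel.append((r, GoldLabel(r.patient_id, True, False, False),
                  {(1, 1): False, (1, 13): True, (1, 14): True, (1, 5): False}))

    # adjacent dates across a calendar-year boundary: same-CY rules false
    r = rec("edge-cy")
    r.diagnoses += [
        DiagnosisEvent(r.patient_id, _D(2018, 12, 31), "M17.11", _I10, _OFF),
        DiagnosisEvent(r.patient_id, _D(2019, 1, 1), "M17.11", _I10, _OFF),
    ]
    panel.append((r, GoldLabel(r.patient_id, True, False, False),
                  {(1, 5): False, (1, 2): True, (1, 1): True}))

    # arthroplasty exactly 30 days after the OA dx: step-1 #19 boundary;
    # surgery terminates the window but is itself inside it
    r = rec("edge-arthro-30d")
    r.diagnoses.append(DiagnosisEvent(r.patient_id, _D(2019, 9, 1), "M17.11", _I10, _OFF))
    r.procedures.append(ProcedureEvent(r.patient_id, _D(2019, 10, 1), "27447", _CPT, 15000.0))  # +30d
    panel.append((r, GoldLabel(r.patient_id, True, True, True),
                  {(1, 19): True, (2, 1): True, (3, 3): True, (3, 4): False}))

    r = rec("edge-arthro-31d")
    r.diagnoses.append(DiagnosisEvent(r.patient_id, _D(2019, 9, 1), "M17.11", _I10, _OFF))
    r.procedures.append(ProcedureEvent(r.patient_id, _D(2019, 10, 2), "27447", _CPT, 15000.0))  # +31d
    panel.append((r, GoldLabel(r.patient_id, True, True, True),
                  {(1, 19): False, (2, 1): True, (3, 3): True}))

    # two IA injections exactly 90 days apart: step-2 #8 boundary
    r = rec("edge-ia-90d")
    r.diagnoses.append(DiagnosisEvent(r.patient_id, _D(2019, 1, 1), "M17.11", _I10, _OFF))
    r.procedures += [
        ProcedureEvent(r.patient_id, _D(2019, 2, 1), "20610", _CPT, 300.0),
        ProcedureEvent(r.patient_id, _D(2019, 5, 2), "20610", _CPT, 300.0),  # +90d
    ]
    panel.append((r, GoldLabel(r.patient_id, True, True, False),
                  {(2, 7): True, (2, 8): True, (1, 17): True}))

    r = rec("edge-ia-89d")
    r.diagnoses.append(DiagnosisEvent(r.patient_id, _D(2019, 1, 1), "M17.11", _I10, _OFF))
    r.procedures += [
        ProcedureEvent(r.patient_id, _D(2019, 2, 1), "20610", _CPT, 300.0),
        ProcedureEvent(r.patient_id, _D(2019, 5, 1), "20610", _CPT, 300.0),  # +89d
    ]
    panel.append((r, GoldLabel(r.patient_id, True, True, False),
                  {(2, 7): True, (2, 8): False}))

    # two opioid classes within exactly 90 days: step-3 #5 boundary
    r = rec("edge-opioid-90d")
    r.diagnoses.append(DiagnosisEvent(r.patient_id, _D(2019, 1, 1), "M17.11", _I10, _OFF))
    r.drugs += [
        DrugClaim(r.patient_id, _D(2019, 2, 1), DrugClass.OPIOID_SA, 25.0),
        DrugClaim(r.patient_id, _D(2019, 5, 2), DrugClass.OPIOID_MIXED, 25.0),  # +90d
    ]
    panel.append((r, GoldLabel(r.patient_id, True, False, True),
                  {(3, 5): True, (3, 2): False}))

    r = rec("edge-opioid-91d")
    r.diagnoses.append(DiagnosisEvent(r.patient_id, _D(2019, 1, 1), "M17.11", _I10, _OFF))
    r.drugs += [
        DrugClaim(r.patient_id, _D(2019, 2, 1), DrugClass.OPIOID_SA, 25.0),
        DrugClaim(r.patient_id, _D(2019, 5, 3), DrugClass.OPIOID_MIXED, 25.0),  # +91d
    ]
    panel.append((r, GoldLabel(r.patient_id, True, False, False), {(3, 5): False}))

    # mobility aid exactly 90 days after an opioid fill: step-3 #6 boundary;
    # aid before the fill must not fire
    r = rec("edge-aid-after")
    r.diagnoses.append(DiagnosisEvent(r.patient_id, _D(2019, 1, 1), "M17.11", _I10, _OFF))
    r.drugs.append(DrugClaim(r.patient_id, _D(2019, 2, 1), DrugClass.OPIOID_SA, 25.0))
    r.procedures.append(ProcedureEvent(r.patient_id, _D(2019, 5, 2), "E0130", _HCP, 80.0))  # +90d
    panel.append((r, GoldLabel(r.patient_id, True, False, False),
                  {(3, 6): True, (2, 10): False}))

    r = rec("edge-aid-before")
    r.diagnoses.append(DiagnosisEvent(r.patient_id, _D(2019, 6, 1), "M17.11", _I10, _OFF))
    r.drugs.append(DrugClaim(r.patient_id, _D(2019, 5, 1), DrugClass.OPIOID_SA, 25.0))
    r.procedures.append(ProcedureEvent(r.patient_id, _D(2019, 4, 1), "E0130", _HCP, 80.0))
    panel.append((r, GoldLabel(r.patient_id, True, False, False), {(3, 6): False}))

    # analgesic classes strictly before an injection: step-3 #1; same-day
    # fills do not count as "preceded by"
    r = rec("edge-preceded")
    r.diagnoses.append(DiagnosisEvent(r.patient_id, _D(2019, 1, 1), "M17.11", _I10, _OFF))
    r.drugs += [
        DrugClaim(r.patient_id, _D(2019, 2, 1), DrugClass.NSAID_NONSEL, 10.0),
        DrugClaim(r.patient_id, _D(2019, 3, 1), DrugClass.OPIOID_SA, 25.0),
    ]
    r.procedures.append(ProcedureEvent(r.patient_id, _D(2019, 4, 1), "20610", _CPT, 300.0))
    panel.append((r, GoldLabel(r.patient_id, True, True, True), {(3, 1): True}))

    r = rec("edge-preceded-sameday")
    r.diagnoses.append(DiagnosisEvent(r.patient_id, _D(2019, 1, 1), "M17.11", _I10, _OFF))
    r.drugs += [
        DrugClaim(r.patient_id, _D(2019, 2, 1), DrugClass.NSAID_NONSEL, 10.0),
        DrugClaim(r.patient_id, _D(2019, 4, 1), DrugClass.OPIOID_SA, 25.0),  # same day as proc
    ]
    r.procedures.append(ProcedureEvent(r.patient_id, _D(2019, 4, 1), "20610", _CPT, 300.0))
    panel.append((r, GoldLabel(r.patient_id, True, True, False), {(3, 1): False}))

    return [(r.sorted(), label, expect) for r, label, expect in panel]


#: patient id -> {(step, rule index): expected outcome}
PANEL_EXPECTATIONS: dict[str, dict[tuple[int, int], bool]] = {
    r.patient_id: expect for r, _, expect in _panel_patients()
}


def plant_edge_cases(db: PatientDB) -> PatientDB:
    """Append the fixed boundary panel to a copy of ``db``."""
    out = PatientDB(records=dict(db.records), labels=dict(db.labels))
    for r, label, _ in _panel_patients():
        out.add(r, label)
    return out
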