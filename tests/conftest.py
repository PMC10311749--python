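import datetime as dt

import pytest

from oa_phenotyper.cohort_builder import STUDY_WINDOW, determine_extraction_period
from oa_phenotyper.records_io import (
    CodeSystem,
    DiagnosisEvent,
    EnrollmentPeriod,
    PatientRecord,
    Setting,
    builtin_code_sets,
)
from oa_phenotyper.synthetic_claims import default_config, generate


@pytest.fixture(scope="session")
def code_sets():
    return builtin_code_sets()


@pytest.fixture(scope="session")
def synth_db():
    """Full-size synthetic cohort at the published archetype mix (490)."""
    return generate(default_config(seed=7))


@pytest.fixture(scope="session")
def synth_windows(synth_db, code_sets):
    return {
        pid: determine_extraction_period(
            synth_db.records[pid], STUDY_WINDOW, code_sets["ARTHROPLASTY"]
        )
        for pid in synth_db.records
    }


def make_patient(pid="pt1", birth_year=1955, diagnoses=(), procedures=(), drugs=()):
    """Minimal patient covering the whole study window."""
    rec = PatientRecord(
        patient_id=pid,
        birth_year=birth_year,
        sex="F",
        race="White",
        diagnoses=list(diagnoses),
        procedures=list(procedures),
        drugs=list(drugs),
        enrollments=[EnrollmentPeriod(pid, STUDY_WINDOW.start, STUDY_WINDOW.end)],
    )
    return rec.sorted()


def dx(pid, date, code="M17.11", system=CodeSystem.ICD10CM, setting=Setting.OUTPATIENT_OFFICE):
    return DiagnosisEvent(pid, date, code, system, setting)


@pytest.fixture
def patient_factory():
    return make_patient
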