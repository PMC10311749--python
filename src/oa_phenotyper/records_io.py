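"""Longitudinal claims data model, code-set registry, and delimited-table IO.

The package operates on a minimal, OMOP-flavoured event schema carried by five
comma-separated tables (plus optional gold labels):

``demographics.csv``
    ``patient_id, birth_year, sex, race``
``diagnoses.csv``
    ``patient_id, date, code, system, setting``
``procedures.csv``
    ``patient_id, date, code, system, cost``
``drugs.csv``
    ``patient_id, fill_date, drug_class, cost[, ndc]``
``enrollment.csv``
    ``patient_id, start, end``
``labels.csv``
    ``patient_id, has_oa_hip_knee, moderate_severe, inadequate_response``

Dates are ISO-8601. Drug events carry a pre-resolved therapeutic class (NDC to
class mapping tables are licensing-encumbered; an optional ``ndc`` column is
passed through opaquely). Clinical concepts are expressed as :class:`CodeSet`
objects — lists of exact codes or trailing-wildcard prefixes per coding system
— matched dot- and case-insensitively.
"""

from __future__ import annotations

import csv
import datetime as dt
import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "CodeSystem",
    "Setting",
    "DrugClass",
    "CodeSet",
    "DiagnosisEvent",
    "ProcedureEvent",
    "DrugClaim",
    "EnrollmentPeriod",
    "PatientRecord",
    "GoldLabel",
    "PatientDB",
    "SchemaError",
    "match_code",
    "builtin_code_sets",
    "load_event_tables",
    "write_event_tables",
    "validate_dir",
]

SCHEMA_VERSION = "1.0"


class SchemaError(ValueError):
    """Raised when an input table violates the documented schema."""


class CodeSystem(str, enum.Enum):
    ICD9CM = "ICD9CM"
    ICD10CM = "ICD10CM"
    CPT4 = "CPT4"
    HCPCS = "HCPCS"
    ICD9PROC = "ICD9PROC"
    ICD10PROC = "ICD10PROC"
    DRUGCLASS = "DRUGCLASS"


class Setting(str, enum.Enum):
    INPATIENT = "INPATIENT"
    OUTPATIENT_OFFICE = "OUTPATIENT_OFFICE"
    OUTPATIENT_OTHER = "OUTPATIENT_OTHER"
    ED = "ED"


#: Settings counted as "outpatient visits" by the rule vocabulary.
OUTPATIENT_SETTINGS = frozenset({Setting.OUTPATIENT_OFFICE, Setting.OUTPATIENT_OTHER})


class DrugClass(str, enum.Enum):
    NSAID_NONSEL = "NSAID_NONSEL"
    NSAID_COX2 = "NSAID_COX2"
    NSAID_TOPICAL = "NSAID_TOPICAL"
    OPIOID_SA = "OPIOID_SA"
    OPIOID_LA = "OPIOID_LA"
    # tramadol / tapentadol
    OPIOID_MIXED = "OPIOID_MIXED"
    ORAL_CORTICOSTEROID = "ORAL_CORTICOSTEROID"
    H2_BLOCKER = "H2_BLOCKER"
    OTHER = "OTHER"


ANALGESIC_NSAID_CLASSES = (
    DrugClass.NSAID_NONSEL,
    DrugClass.NSAID_COX2,
    DrugClass.NSAID_TOPICAL,
)
OPIOID_CLASSES = (DrugClass.OPIOID_SA, DrugClass.OPIOID_LA, DrugClass.OPIOID_MIXED)
ANALGESIC_CLASSES = ANALGESIC_NSAID_CLASSES + OPIOID_CLASSES


def _normalize_code(code: str) -> str:
    return code.replace(".", "").strip().upper()


@dataclass(frozen=True)
class CodeSet:
    """A named clinical concept: exact codes and prefix patterns per system.

    A trailing ``*`` in a pattern marks a prefix match; matching is performed
    on dot-stripped, upper-cased codes so both dotted ("M17.11") and undotted
    ("M1711") dialects are accepted.

    ``provenance`` records whether the code list is printed in the source
    publication ("paper") or curated by the implementers ("curated").
    """

    name: str
    patterns: tuple[tuple[CodeSystem, str], ...]  # (system, pattern-with-optional-*)
    provenance: str = "curated"

    def __post_init__(self) -> None:
        if not self.patterns:
            raise ValueError(f"CodeSet {self.name!r} has no patterns")
        for system, pat in self.patterns:
            if not isinstance(system, CodeSystem):
                raise ValueError(f"CodeSet {self.name!r}: bad system {system!r}")
            if not pat or pat == "*":
                raise ValueError(f"CodeSet {self.name!r}: empty pattern")
            if "*" in pat[:-1]:
                raise ValueError(
                    f"CodeSet {self.name!r}: wildcard only allowed at end: {pat!r}"
                )

    def systems(self) -> frozenset[CodeSystem]:
        return frozenset(system for system, _ in self.patterns)


def match_code(code: str, system: CodeSystem, code_set: CodeSet) -> bool:
    """True iff ``code`` (in ``system``) matches the concept ``code_set``.

    Exact patterns require equality after dot-stripping; ``X*`` patterns
    require a prefix match. Codes in systems absent from the set never match.
    """
    if not code:
        raise ValueError("empty code")
    if not isinstance(system, CodeSystem):
        raise SchemaError(f"unknown code system: {system!r}")
    norm = _normalize_code(code)
    for pat_system, pat in code_set.patterns:
        if pat_system is not system:
            continue
        if pat.endswith("*"):
            if norm.startswith(_normalize_code(pat[:-1])):
                return True
        elif norm == _normalize_code(pat):
            return True
    return False


# ---------------------------------------------------------------------------
# Event records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DiagnosisEvent:
    patient_id: str
    date: dt.date
    code: str
    system: CodeSystem
    setting: Setting


@dataclass(frozen=True)
class ProcedureEvent:
    patient_id: str
    date: dt.date
    code: str
    system: CodeSystem
    cost: float = 0.0

    def __post_init__(self) -> None:
        if self.cost < 0:
            raise ValueError("procedure cost must be non-negative")


@dataclass(frozen=True)
class DrugClaim:
    patient_id: str
    fill_date: dt.date
    drug_class: DrugClass
    cost: float = 0.0
    ndc: str = ""

    def __post_init__(self) -> None:
        if self.cost < 0:
            raise ValueError("drug cost must be non-negative")


@dataclass(frozen=True)
class EnrollmentPeriod:
    patient_id: str
    start: dt.date
    end: dt.date

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("enrollment start after end")


@dataclass
class PatientRecord:
    patient_id: str
    birth_year: int | None
    sex: str = ""
    race: str = ""
    diagnoses: list[DiagnosisEvent] = field(default_factory=list)
    procedures: list[ProcedureEvent] = field(default_factory=list)
    drugs: list[DrugClaim] = field(default_factory=list)
    enrollments: list[EnrollmentPeriod] = field(default_factory=list)

    def sorted(self) -> "PatientRecord":
        """Copy with all event lists in deterministic (date, code) order."""
        return replace(
            self,
            diagnoses=sorted(self.diagnoses, key=lambda e: (e.date, e.code, e.setting.value)),
            procedures=sorted(self.procedures, key=lambda e: (e.date, e.code)),
            drugs=sorted(self.drugs, key=lambda e: (e.fill_date, e.drug_class.value)),
            enrollments=sorted(self.enrollments, key=lambda e: (e.start, e.end)),
        )


@dataclass(frozen=True)
class GoldLabel:
    """Chart-adjudicated presence of the three OA characteristics.

    ``moderate_severe`` implies ``has_oa_hip_knee``; the composite "case"
    definition is all three true.
    """

    patient_id: str
    has_oa_hip_knee: bool
    moderate_severe: bool
    inadequate_response: bool

    def __post_init__(self) -> None:
        if self.moderate_severe and not self.has_oa_hip_knee:
            raise ValueError("moderate_severe requires has_oa_hip_knee")
        if self.inadequate_response and not self.has_oa_hip_knee:
            raise ValueError("inadequate_response recorded only for OA patients")

    @property
    def is_case(self) -> bool:
        return self.has_oa_hip_knee and self.moderate_severe and self.inadequate_response


@dataclass
class PatientDB:
    records: dict[str, PatientRecord] = field(default_factory=dict)
    labels: dict[str, GoldLabel] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, rec in self.records.items():
            if rec.patient_id != pid:
                raise ValueError(f"record keyed {pid!r} has patient_id {rec.patient_id!r}")
        for pid in self.labels:
            if pid not in self.records:
                raise ValueError(f"label for unknown patient {pid!r}")

    def add(self, record: PatientRecord, label: GoldLabel | None = None) -> None:
        if record.patient_id in self.records:
            raise ValueError(f"duplicate patient_id {record.patient_id!r}")
        self.records[record.patient_id] = record
        if label is not None:
            if label.patient_id != record.patient_id:
                raise ValueError("label/record patient_id mismatch")
            self.labels[record.patient_id] = label

    def patient_ids(self) -> list[str]:
        return sorted(self.records)

    def n_events(self) -> int:
        return sum(
            len(r.diagnoses) + len(r.procedures) + len(r.drugs) + len(r.enrollments)
            for r in self.records.values()
        )


# ---------------------------------------------------------------------------
# Built-in code sets
# ---------------------------------------------------------------------------

_I9 = CodeSystem.ICD9CM
_I10 = CodeSystem.ICD10CM
_CPT = CodeSystem.CPT4
_HCP = CodeSystem.HCPCS


def _cs(name: str, provenance: str, *patterns: tuple[CodeSystem, str]) -> CodeSet:
    return CodeSet(name=name, patterns=tuple(patterns), provenance=provenance)


def builtin_code_sets() -> dict[str, CodeSet]:
    """Registry of the clinical concepts the predefined rules reference.

    ``OA_HIP_KNEE`` is printed in the source publication (8 exact ICD-9-CM
    codes + the M16/M17 ICD-10-CM families). Every other set is curated from
    public code lists so the rules can execute; all are overridable via the
    config file. Quan's Charlson condition sets live in
    :mod:`oa_phenotyper.cohort_builder`.
    """
    sets = [
        _cs(
            "OA_HIP_KNEE",
            "paper",
            (_I9, "715.15"), (_I9, "715.25"), (_I9, "715.35"), (_I9, "715.95"),
            (_I9, "715.16"), (_I9, "715.26"), (_I9, "715.36"), (_I9, "715.96"),
            (_I10, "M16*"), (_I10, "M17*"),
        ),
        _cs(
            "JOINT_PAIN_HIP",
            "curated",
            (_I10, "M25.55*"), (_I9, "719.45"),
        ),
        _cs(
            "JOINT_PAIN_KNEE",
            "curated",
            (_I10, "M25.56*"), (_I9, "719.46"),
        ),
        _cs(
            "JOINT_PAIN_OTHER",
            "curated",
            (_I10, "M25.50"), (_I10, "M25.51*"), (_I10, "M25.52*"),
            (_I10, "M25.53*"), (_I10, "M25.57*"), (_I9, "719.40"),
            (_I9, "719.41"), (_I9, "719.42"), (_I9, "719.43"), (_I9, "719.44"),
            (_I9, "719.47"),
        ),
        _cs("BACK_PAIN", "curated", (_I10, "M54*"), (_I9, "724*")),
        _cs(
            "UNSPECIFIED_PAIN",
            "curated",
            (_I10, "R52"), (_I10, "G89.2*"), (_I10, "G89.4"), (_I9, "338.2*"),
            (_I9, "780.96"),
        ),
        _cs("DEPRESSION", "curated", (_I10, "F32*"), (_I10, "F33*"), (_I9, "311"), (_I9, "296.2*"), (_I9, "296.3*")),
        _cs("ANXIETY", "curated", (_I10, "F41*"), (_I9, "300.0*")),
        _cs("HYPERTENSION", "curated", (_I10, "I10"), (_I9, "401*")),
        _cs("DIABETES", "curated", (_I10, "E10*"), (_I10, "E11*"), (_I9, "250*")),
        _cs("GERD", "curated", (_I10, "K21*"), (_I9, "530.81")),
        _cs("OBESITY", "curated", (_I10, "E66*"), (_I9, "278.0*")),
        _cs(
            "DRUG_ALCOHOL_ABUSE",
            "curated",
            (_I10, "F10*"), (_I10, "F11*"), (_I10, "F19*"),
            (_I9, "303*"), (_I9, "304*"), (_I9, "305*"),
        ),
        _cs("INSOMNIA", "curated", (_I10, "G47.0*"), (_I9, "780.52")),
        # Psychiatric comorbidity per the severity rules = anxiety or depression.
        _cs(
            "PSYCHIATRIC",
            "curated",
            (_I10, "F32*"), (_I10, "F33*"), (_I10, "F41*"),
            (_I9, "311"), (_I9, "296.2*"), (_I9, "296.3*"), (_I9, "300.0*"),
        ),
        # Imaging of hip/knee: plain films + MRI (CPT).
        _cs(
            "XRAY_HIP_KNEE",
            "curated",
            (_CPT, "73560"), (_CPT, "73562"), (_CPT, "73564"), (_CPT, "73565"),
            (_CPT, "73501"), (_CPT, "73502"), (_CPT, "73510"), (_CPT, "73520"),
        ),
        _cs(
            "MRI_HIP_KNEE",
            "curated",
            (_CPT, "73721"), (_CPT, "73722"), (_CPT, "73723"),
        ),
        _cs(
            "IMAGING_HIP_KNEE",
            "curated",
            (_CPT, "73560"), (_CPT, "73562"), (_CPT, "73564"), (_CPT, "73565"),
            (_CPT, "73501"), (_CPT, "73502"), (_CPT, "73510"), (_CPT, "73520"),
            (_CPT, "73721"), (_CPT, "73722"), (_CPT, "73723"),
        ),
        _cs("HA_INJECTION", "curated", (_HCP, "J7321"), (_HCP, "J7323"), (_HCP, "J7325")),
        _cs("IA_CORTICOSTEROID", "curated", (_HCP, "J3301"), (_HCP, "J1030"), (_CPT, "20610")),
        _cs("NERVE_BLOCK", "curated", (_CPT, "64450"), (_CPT, "64640"), (_CPT, "64635")),
        _cs(
            "ARTHROPLASTY",
            "curated",
            (_CPT, "27447"), (_CPT, "27446"), (_CPT, "27486"), (_CPT, "27487"),
            (_CPT, "27130"), (_CPT, "27125"), (_CPT, "27134"),
            (CodeSystem.ICD9PROC, "81.51"), (CodeSystem.ICD9PROC, "81.53"),
            (CodeSystem.ICD9PROC, "81.54"), (CodeSystem.ICD9PROC, "81.55"),
            (CodeSystem.ICD10PROC, "0SR9*"), (CodeSystem.ICD10PROC, "0SRB*"),
            (CodeSystem.ICD10PROC, "0SRC*"), (CodeSystem.ICD10PROC, "0SRD*"),
        ),
        _cs(
            "KNEE_ARTHROPLASTY",
            "curated",
            (_CPT, "27447"), (_CPT, "27446"), (_CPT, "27486"), (_CPT, "27487"),
            (CodeSystem.ICD9PROC, "81.54"), (CodeSystem.ICD9PROC, "81.55"),
            (CodeSystem.ICD10PROC, "0SRC*"), (CodeSystem.ICD10PROC, "0SRD*"),
        ),
        _cs(
            "HIP_ARTHROPLASTY",
            "curated",
            (_CPT, "27130"), (_CPT, "27125"), (_CPT, "27134"),
            (CodeSystem.ICD9PROC, "81.51"), (CodeSystem.ICD9PROC, "81.53"),
            (CodeSystem.ICD10PROC, "0SR9*"), (CodeSystem.ICD10PROC, "0SRB*"),
        ),
        _cs(
            "MOBILITY_AID",
            "curated",
            (_HCP, "E0100"), (_HCP, "E0110"), (_HCP, "E0130"), (_HCP, "E0135"),
            (_HCP, "K0001"), (_HCP, "E1130"),
        ),
        _cs(
            "PT_OT",
            "curated",
            (_CPT, "97110"), (_CPT, "97112"), (_CPT, "97116"), (_CPT, "97530"),
            (_CPT, "97535"),
        ),
        # Cancer exclusion: malignant neoplasms + metastases, deliberately
        # excluding carcinoma in situ (D00-D09 / 230-234) and non-metastatic
        # melanoma (C43 / 172).
        _cs(
            "CANCER_EXCLUSION",
            "curated",
            (_I10, "C0*"), (_I10, "C1*"), (_I10, "C2*"), (_I10, "C30*"),
            (_I10, "C31*"), (_I10, "C32*"), (_I10, "C33*"), (_I10, "C34*"),
            (_I10, "C37*"), (_I10, "C38*"), (_I10, "C39*"), (_I10, "C40*"),
            (_I10, "C41*"), (_I10, "C44*"), (_I10, "C45*"), (_I10, "C46*"), (_I10, "C47*"),
            (_I10, "C48*"), (_I10, "C49*"), (_I10, "C5*"), (_I10, "C6*"),
            (_I10, "C7*"), (_I10, "C8*"), (_I10, "C9*"),
            (_I9, "14*"), (_I9, "15*"), (_I9, "16*"), (_I9, "170*"),
            (_I9, "171*"), (_I9, "174*"), (_I9, "175*"), (_I9, "176*"),
            (_I9, "179*"), (_I9, "18*"), (_I9, "19*"), (_I9, "20*"),
        ),
    ]
    return {s.name: s for s in sets}


# ---------------------------------------------------------------------------
# Delimited-table IO
# ---------------------------------------------------------------------------

TABLE_FILES = {
    "demographics": "demographics.csv",
    "diagnoses": "diagnoses.csv",
    "procedures": "procedures.csv",
    "drugs": "drugs.csv",
    "enrollment": "enrollment.csv",
    "labels": "labels.csv",
}

_HEADERS = {
    "demographics": ["patient_id", "birth_year", "sex", "race"],
    "diagnoses": ["patient_id", "date", "code", "system", "setting"],
    "procedures": ["patient_id", "date", "code", "system", "cost"],
    "drugs": ["patient_id", "fill_date", "drug_class", "cost", "ndc"],
    "enrollment": ["patient_id", "start", "end"],
    "labels": ["patient_id", "has_oa_hip_knee", "moderate_severe", "inadequate_response"],
}


def _parse_date(value: str, where: str) -> dt.date:
    try:
        return dt.date.fromisoformat(value)
    except ValueError as exc:
        raise SchemaError(f"{where}: unparseable date {value!r}") from exc


def _parse_enum(enum_cls, value: str, where: str):
    try:
        return enum_cls(value)
    except ValueError as exc:
        raise SchemaError(
            f"{where}: unknown {enum_cls.__name__} value {value!r}"
        ) from exc


def _parse_bool(value: str, where: str) -> bool:
    v = value.strip().lower()
    if v in {"true", "1", "yes"}:
        return True
    if v in {"false", "0", "no"}:
        return False
    raise SchemaError(f"{where}: unparseable boolean {value!r}")


def _read_rows(path: Path, table: str) -> Iterable[tuple[int, dict[str, str]]]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        required = [c for c in _HEADERS[table] if c != "ndc"]
        missing = [c for c in required if c not in header]
        if missing:
            raise SchemaError(f"{path.name}: missing columns {missing}")
        for lineno, row in enumerate(reader, start=2):
            yield lineno, row


def load_event_tables(
    data_dir: str | Path,
    schema_version: str = SCHEMA_VERSION,
) -> PatientDB:
    """Load a :class:`PatientDB` from a directory of delimited event tables.

    Every row becomes exactly one event; a malformed row raises
    :class:`SchemaError` naming the file, line and field (no silent drops).
    ``labels.csv`` is optional; every other table must exist.
    """
    if schema_version != SCHEMA_VERSION:
        raise SchemaError(f"unsupported schema version {schema_version!r}")
    data_dir = Path(data_dir)
    for table in ("demographics", "diagnoses", "procedures", "drugs", "enrollment"):
        if not (data_dir / TABLE_FILES[table]).exists():
            raise SchemaError(f"missing table file {TABLE_FILES[table]}")

    db = PatientDB()
    path = data_dir / TABLE_FILES["demographics"]
    for lineno, row in _read_rows(path, "demographics"):
        where = f"{path.name}:{lineno}"
        pid = row["patient_id"]
        if pid in db.records:
            raise SchemaError(f"{where}: duplicate patient_id {pid!r}")
        by = row["birth_year"].strip()
        if by:
            try:
                birth_year: int | None = int(by)
            except ValueError as exc:
                raise SchemaError(f"{where}: bad birth_year {by!r}") from exc
        else:
            birth_year = None
        db.records[pid] = PatientRecord(
            patient_id=pid, birth_year=birth_year, sex=row["sex"], race=row["race"]
        )

    def _record(pid: str, where: str) -> PatientRecord:
        if pid not in db.records:
            raise SchemaError(f"{where}: event for unknown patient {pid!r}")
        return db.records[pid]

    path = data_dir / TABLE_FILES["diagnoses"]
    for lineno, row in _read_rows(path, "diagnoses"):
        where = f"{path.name}:{lineno}"
        _record(row["patient_id"], where).diagnoses.append(
            DiagnosisEvent(
                patient_id=row["patient_id"],
                date=_parse_date(row["date"], where + " field=date"),
                code=row["code"],
                system=_parse_enum(CodeSystem, row["system"], where + " field=system"),
                setting=_parse_enum(Setting, row["setting"], where + " field=setting"),
            )
        )

    path = data_dir / TABLE_FILES["procedures"]
    for lineno, row in _read_rows(path, "procedures"):
        where = f"{path.name}:{lineno}"
        try:
            cost = float(row["cost"])
        except ValueError as exc:
            raise SchemaError(f"{where}: bad cost {row['cost']!r}") from exc
        _record(row["patient_id"], where).procedures.append(
            ProcedureEvent(
                patient_id=row["patient_id"],
                date=_parse_date(row["date"], where + " field=date"),
                code=row["code"],
                system=_parse_enum(CodeSystem, row["system"], where + " field=system"),
                cost=cost,
            )
        )

    path = data_dir / TABLE_FILES["drugs"]
    for lineno, row in _read_rows(path, "drugs"):
        where = f"{path.name}:{lineno}"
        try:
            cost = float(row["cost"])
        except ValueError as exc:
            raise SchemaError(f"{where}: bad cost {row['cost']!r}") from exc
        _record(row["patient_id"], where).drugs.append(
            DrugClaim(
                patient_id=row["patient_id"],
                fill_date=_parse_date(row["fill_date"], where + " field=fill_date"),
                drug_class=_parse_enum(DrugClass, row["drug_class"], where + " field=drug_class"),
                cost=cost,
                ndc=row.get("ndc", "") or "",
            )
        )

    path = data_dir / TABLE_FILES["enrollment"]
    for lineno, row in _read_rows(path, "enrollment"):
        where = f"{path.name}:{lineno}"
        start = _parse_date(row["start"], where + " field=start")
        end = _parse_date(row["end"], where + " field=end")
        if start > end:
            raise SchemaError(f"{where}: enrollment start after end")
        _record(row["patient_id"], where).enrollments.append(
            EnrollmentPeriod(patient_id=row["patient_id"], start=start, end=end)
        )

    labels_path = data_dir / TABLE_FILES["labels"]
    if labels_path.exists():
        for lineno, row in _read_rows(labels_path, "labels"):
            where = f"{labels_path.name}:{lineno}"
            pid = row["patient_id"]
            if pid not in db.records:
                raise SchemaError(f"{where}: label for unknown patient {pid!r}")
            try:
                db.labels[pid] = GoldLabel(
                    patient_id=pid,
                    has_oa_hip_knee=_parse_bool(row["has_oa_hip_knee"], where),
                    moderate_severe=_parse_bool(row["moderate_severe"], where),
                    inadequate_response=_parse_bool(row["inadequate_response"], where),
                )
            except ValueError as exc:
                raise SchemaError(f"{where}: {exc}") from exc

    db.records = {pid: rec.sorted() for pid, rec in db.records.items()}
    return db


def write_event_tables(db: PatientDB, out_dir: str | Path) -> dict[str, Path]:
    """Write ``db`` as the standard table files; deterministic row order."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def _open(table: str):
        path = out_dir / TABLE_FILES[table]
        paths[table] = path
        fh = open(path, "w", newline="", encoding="utf-8")
        writer = csv.writer(fh)
        writer.writerow(_HEADERS[table])
        return fh, writer

    pids = db.patient_ids()

    fh, w = _open("demographics")
    with fh:
        for pid in pids:
            r = db.records[pid]
            w.writerow([pid, "" if r.birth_year is None else r.birth_year, r.sex, r.race])

    fh, w = _open("diagnoses")
    with fh:
        for pid in pids:
            for e in sorted(db.records[pid].diagnoses, key=lambda e: (e.date, e.code, e.setting.value)):
                w.writerow([pid, e.date.isoformat(), e.code, e.system.value, e.setting.value])

    fh, w = _open("procedures")
    with fh:
        for pid in pids:
            for e in sorted(db.records[pid].procedures, key=lambda e: (e.date, e.code)):
                w.writerow([pid, e.date.isoformat(), e.code, e.system.value, f"{e.cost:.2f}"])

    fh, w = _open("drugs")
    with fh:
        for pid in pids:
            for e in sorted(db.records[pid].drugs, key=lambda e: (e.fill_date, e.drug_class.value)):
                w.writerow([pid, e.fill_date.isoformat(), e.drug_class.value, f"{e.cost:.2f}", e.ndc])

    fh, w = _open("enrollment")
    with fh:
        for pid in pids:
            for e in sorted(db.records[pid].enrollments, key=lambda e: (e.start, e.end)):
                w.writerow([pid, e.start.isoformat(), e.end.isoformat()])

    if db.labels:
        fh, w = _open("labels")
        with fh:
            for pid in pids:
                if pid in db.labels:
                    lab = db.labels[pid]
                    w.writerow([
                        pid,
                        str(lab.has_oa_hip_knee).lower(),
                        str(lab.moderate_severe).lower(),
                        str(lab.inadequate_response).lower(),
                    ])
    return paths


def validate_dir(data_dir: str | Path) -> dict[str, dict[str, int | str]]:
    """Per-table row/error report for ``phenotyper validate-data``."""
    data_dir = Path(data_dir)
    report: dict[str, dict[str, int | str]] = {}
    for table, fname in TABLE_FILES.items():
        path = data_dir / fname
        if not path.exists():
            report[table] = {"rows": 0, "status": "missing" if table != "labels" else "absent (optional)"}
            continue
        with open(path, newline="", encoding="utf-8") as fh:
            n = sum(1 for _ in fh) - 1
        report[table] = {"rows": max(n, 0), "status": "ok"}
    try:
        load_event_tables(data_dir)
    except SchemaError as exc:
        report["_load"] = {"rows": 0, "status": f"error: {exc}"}
    else:
        report["_load"] = {"rows": 0, "status": "ok"}
    return report
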