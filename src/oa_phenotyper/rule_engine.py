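"""Temporal rule engine: predicate vocabulary and the 40 predefined algorithms.

The predefined case-identification algorithms form three steps, each scored
independently against the chart-review gold standard:

* Step 1 (20 rules): presence of hip/knee osteoarthritis;
* Step 2 (14 rules): moderate-to-severe disease;
* Step 3 (6 rules): inadequate response to at least two analgesic classes.

Each rule is an AND/OR tree of temporal predicates over a patient's coded
events restricted to their extraction window. The vocabulary is negation-free,
so every predicate is monotone: adding events can only switch a rule from
unsatisfied to satisfied.

Counting conventions (applied uniformly here and in the test oracles):
diagnosis "encounters"/"visits" and procedure administrations are counted by
distinct service date; drug prescriptions are counted by fill event. All day
intervals are inclusive ("within d days" means a difference of at most d;
"at least d apart" at least d). "Within 6 months" is 183 days, "within 1/2/5
years" 365/731/1827 days; "same CY" compares calendar-year numbers.
"""

from __future__ import annotations

import datetime as dt
import enum
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

from .cohort_builder import DateInterval
from .records_io import (
    ANALGESIC_CLASSES,
    OPIOID_CLASSES,
    OUTPATIENT_SETTINGS,
    CodeSet,
    DrugClass,
    PatientDB,
    PatientRecord,
    Setting,
    match_code,
)

__all__ = [
    "Concept",
    "PredicateKind",
    "Predicate",
    "RuleSpec",
    "RuleOutcome",
    "CohortContext",
    "DAY_CONSTANTS",
    "evaluate_predicate",
    "evaluate_rule",
    "step1_registry",
    "step2_registry",
    "step3_registry",
    "all_rules",
    "combine_or",
    "composite_classify",
    "oa_related_cost",
    "build_context",
]

#: Day-count interpretations of the mixed phrasings in the rule texts.
DAY_CONSTANTS = {"6m": 183, "1y": 365, "2y": 731, "5y": 1827}


# ---------------------------------------------------------------------------
# Concepts: what events a predicate looks at
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Concept:
    """A stream of dated events: diagnoses or procedures matching named code
    sets, or drug fills of named therapeutic classes.

    ``domain="dx"`` with empty ``names`` means "any diagnosis" (used for the
    generic outpatient-visit requirement).
    """

    domain: str  # "dx" | "proc" | "drug"
    names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.domain not in {"dx", "proc", "drug"}:
            raise ValueError(f"unknown concept domain {self.domain!r}")
        if self.domain != "dx" and not self.names:
            raise ValueError("proc/drug concepts need at least one name")


def _concept_dates(
    patient: PatientRecord,
    concept: Concept,
    window: DateInterval,
    code_sets: Mapping[str, CodeSet],
    settings: frozenset[Setting] | None = None,
) -> list[dt.date]:
    """Event dates for a concept inside the window, in sorted order.

    Diagnoses and procedures are de-duplicated to distinct service dates;
    drug fills are kept one entry per fill.
    """
    if concept.domain == "dx":
        sets = [code_sets[n] for n in concept.names]
        dates = {
            d.date
            for d in patient.diagnoses
            if window.contains(d.date)
            and (settings is None or d.setting in settings)
            and (not sets or any(match_code(d.code, d.system, cs) for cs in sets))
        }
        return sorted(dates)
    if concept.domain == "proc":
        sets = [code_sets[n] for n in concept.names]
        dates = {
            p.date
            for p in patient.procedures
            if window.contains(p.date)
            and any(match_code(p.code, p.system, cs) for cs in sets)
        }
        return sorted(dates)
    classes = {DrugClass(n) for n in concept.names}
    return sorted(
        f.fill_date
        for f in patient.drugs
        if window.contains(f.fill_date) and f.drug_class in classes
    )


# ---------------------------------------------------------------------------
# Predicates
# ---------------------------------------------------------------------------


class PredicateKind(str, enum.Enum):
    COUNT_IN_WINDOW = "COUNT_IN_WINDOW"
    PAIR_APART_AT_LEAST = "PAIR_APART_AT_LEAST"
    WITHIN_SPAN = "WITHIN_SPAN"  # >= k events inside some span of <= d days
    SAME_CALENDAR_YEAR = "SAME_CALENDAR_YEAR"
    NEAR_ANCHOR = "NEAR_ANCHOR"  # >= k events each within +/- d days of an anchor
    AFTER_ANCHOR = "AFTER_ANCHOR"  # >= 1 event 0..d days after an anchor
    APART_FROM_ANCHOR_AT_LEAST = "APART_FROM_ANCHOR_AT_LEAST"
    COST_VS_COHORT_MEAN = "COST_VS_COHORT_MEAN"
    DISTINCT_CLASSES_AT_LEAST = "DISTINCT_CLASSES_AT_LEAST"
    PRECEDED_BY_CLASSES = "PRECEDED_BY_CLASSES"


@dataclass(frozen=True)
class Predicate:
    kind: PredicateKind
    concept: Concept | None = None
    anchor: Concept | None = None
    settings: frozenset[Setting] | None = None  # filter for dx concepts
    k: int = 1
    days: int | None = None
    multiplier: float | None = None
    classes: tuple[str, ...] = ()
    n_classes: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("count k must be >= 1")
        if self.days is not None and self.days < 0:
            raise ValueError("day offset must be >= 0")
        anchored = {
            PredicateKind.NEAR_ANCHOR,
            PredicateKind.AFTER_ANCHOR,
            PredicateKind.APART_FROM_ANCHOR_AT_LEAST,
        }
        if self.kind in anchored and self.anchor is None:
            raise ValueError(f"{self.kind.value} requires an anchor concept")
        if self.kind is PredicateKind.COST_VS_COHORT_MEAN and self.multiplier is None:
            raise ValueError("COST_VS_COHORT_MEAN requires a multiplier")
        if self.kind in {PredicateKind.DISTINCT_CLASSES_AT_LEAST, PredicateKind.PRECEDED_BY_CLASSES}:
            if not self.classes or self.n_classes < 1:
                raise ValueError(f"{self.kind.value} requires classes and n_classes >= 1")


@dataclass(frozen=True)
class CohortContext:
    """Cohort-level quantities some predicates need (OA-related costs)."""

    oa_cost: Mapping[str, float] = field(default_factory=dict)
    mean_oa_cost: float | None = None


def evaluate_predicate(
    patient: PatientRecord,
    pred: Predicate,
    window: DateInterval,
    code_sets: Mapping[str, CodeSet],
    ctx: CohortContext | None = None,
) -> bool:
    """Evaluate one predicate over the patient's events inside the window."""
    kind = pred.kind

    if kind is PredicateKind.COST_VS_COHORT_MEAN:
        if ctx is None or ctx.mean_oa_cost is None:
            raise ValueError("COST_VS_COHORT_MEAN requires a cohort context with mean cost")
        cost = ctx.oa_cost.get(patient.patient_id, 0.0)
        return cost > pred.multiplier * ctx.mean_oa_cost

    if kind is PredicateKind.DISTINCT_CLASSES_AT_LEAST:
        classes = {DrugClass(c) for c in pred.classes}
        fills = sorted(
            (f.fill_date, f.drug_class)
            for f in patient.drugs
            if window.contains(f.fill_date) and f.drug_class in classes
        )
        if pred.days is None:
            return len({c for _, c in fills}) >= pred.n_classes
        # sliding window of length <= days containing >= n distinct classes
        for i, (start, _) in enumerate(fills):
            seen = {c for d, c in fills[i:] if (d - start).days <= pred.days}
            if len(seen) >= pred.n_classes:
                return True
        return False

    if kind is PredicateKind.PRECEDED_BY_CLASSES:
        classes = {DrugClass(c) for c in pred.classes}
        proc_dates = _concept_dates(patient, pred.concept, window, code_sets)
        fills = [
            (f.fill_date, f.drug_class)
            for f in patient.drugs
            if window.contains(f.fill_date) and f.drug_class in classes
        ]
        for pdate in proc_dates:
            prior = {c for d, c in fills if d < pdate}
            if len(prior) >= pred.n_classes:
                return True
        return False

    dates = _concept_dates(patient, pred.concept, window, code_sets, pred.settings)

    if kind is PredicateKind.COUNT_IN_WINDOW:
        return len(dates) >= pred.k

    if kind is PredicateKind.PAIR_APART_AT_LEAST:
        return bool(dates) and (dates[-1] - dates[0]).days >= pred.days

    if kind is PredicateKind.WITHIN_SPAN:
        n = len(dates)
        if n < pred.k:
            return False
        # k events fitting in a span of <= days; dates sorted
        return any(
            (dates[i + pred.k - 1] - dates[i]).days <= pred.days
            for i in range(n - pred.k + 1)
        )

    if kind is PredicateKind.SAME_CALENDAR_YEAR:
        by_year: dict[int, int] = {}
        for d in dates:
            by_year[d.year] = by_year.get(d.year, 0) + 1
        years = {y for y, n in by_year.items() if n >= pred.k}
        if not years:
            return False
        if pred.anchor is None:
            return True
        companion = _concept_dates(patient, pred.anchor, window, code_sets)
        return any(d.year in years for d in companion)

    anchor_dates = _concept_dates(patient, pred.anchor, window, code_sets)

    if kind is PredicateKind.NEAR_ANCHOR:
        if not anchor_dates:
            return False
        near = [
            d for d in dates
            if any(abs((d - a).days) <= pred.days for a in anchor_dates)
        ]
        return len(near) >= pred.k

    if kind is PredicateKind.AFTER_ANCHOR:
        return any(
            0 <= (d - a).days <= pred.days for d in dates for a in anchor_dates
        )

    if kind is PredicateKind.APART_FROM_ANCHOR_AT_LEAST:
        return any(
            abs((d - a).days) >= pred.days for d in dates for a in anchor_dates
        )

    raise ValueError(f"unknown predicate kind {kind!r}")  # pragma: no cover


# ---------------------------------------------------------------------------
# Rule specifications
# ---------------------------------------------------------------------------

Node = Predicate | tuple  # ("and"|"or", [Node, ...])


@dataclass(frozen=True)
class RuleSpec:
    step: int  # 1 = OA, 2 = moderate-to-severe, 3 = inadequate response
    index: int
    description: str
    tree: Any  # Predicate or ("and"/"or", [subtrees])

    def to_dict(self) -> dict:
        return {
            "step": self.step,
            "index": self.index,
            "description": self.description,
            "tree": _tree_to_dict(self.tree),
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "RuleSpec":
        return cls(
            step=int(data["step"]),
            index=int(data["index"]),
            description=str(data["description"]),
            tree=_tree_from_dict(data["tree"]),
        )


@dataclass(frozen=True)
class RuleOutcome:
    patient_id: str
    step: int
    index: int
    satisfied: bool


def _concept_to_dict(c: Concept | None):
    return None if c is None else {"domain": c.domain, "names": list(c.names)}


def _concept_from_dict(d) -> Concept | None:
    return None if d is None else Concept(domain=d["domain"], names=tuple(d["names"]))


def _tree_to_dict(node: Any) -> dict:
    if isinstance(node, Predicate):
        return {
            "predicate": {
                "kind": node.kind.value,
                "concept": _concept_to_dict(node.concept),
                "anchor": _concept_to_dict(node.anchor),
                "settings": sorted(s.value for s in node.settings) if node.settings else None,
                "k": node.k,
                "days": node.days,
                "multiplier": node.multiplier,
                "classes": list(node.classes),
                "n_classes": node.n_classes,
            }
        }
    op, children = node
    return {"op": op, "children": [_tree_to_dict(c) for c in children]}


def _tree_from_dict(d: Mapping) -> Any:
    if "predicate" in d:
        p = d["predicate"]
        return Predicate(
            kind=PredicateKind(p["kind"]),
            concept=_concept_from_dict(p["concept"]),
            anchor=_concept_from_dict(p["anchor"]),
            settings=frozenset(Setting(s) for s in p["settings"]) if p["settings"] else None,
            k=p["k"],
            days=p["days"],
            multiplier=p["multiplier"],
            classes=tuple(p["classes"]),
            n_classes=p["n_classes"],
        )
    return (d["op"], [_tree_from_dict(c) for c in d["children"]])


def _eval_tree(
    node: Any,
    patient: PatientRecord,
    window: DateInterval,
    code_sets: Mapping[str, CodeSet],
    ctx: CohortContext | None,
) -> bool:
    if isinstance(node, Predicate):
        return evaluate_predicate(patient, node, window, code_sets, ctx)
    op, children = node
    results = (_eval_tree(c, patient, window, code_sets, ctx) for c in children)
    if op == "and":
        return all(results)
    if op == "or":
        return any(results)
    raise ValueError(f"unknown tree operator {op!r}")


def evaluate_rule(
    patient: PatientRecord,
    rule: RuleSpec,
    window: DateInterval,
    code_sets: Mapping[str, CodeSet],
    ctx: CohortContext | None = None,
) -> RuleOutcome:
    satisfied = _eval_tree(rule.tree, patient, window, code_sets, ctx)
    return RuleOutcome(
        patient_id=patient.patient_id, step=rule.step, index=rule.index, satisfied=satisfied
    )


# ---------------------------------------------------------------------------
# The registries
# ---------------------------------------------------------------------------

OA = Concept("dx", ("OA_HIP_KNEE",))
ANY_DX = Concept("dx", ())
JOINT_PAIN = Concept("dx", ("JOINT_PAIN_HIP", "JOINT_PAIN_KNEE", "JOINT_PAIN_OTHER"))
PSYCH = Concept("dx", ("PSYCHIATRIC",))
XRAY = Concept("proc", ("XRAY_HIP_KNEE",))
IMAGING = Concept("proc", ("IMAGING_HIP_KNEE",))
HA_IA = Concept("proc", ("HA_INJECTION", "IA_CORTICOSTEROID"))
HA_IA_NB = Concept("proc", ("HA_INJECTION", "IA_CORTICOSTEROID", "NERVE_BLOCK"))
NERVE_BLOCK = Concept("proc", ("NERVE_BLOCK",))
ARTHROPLASTY = Concept("proc", ("ARTHROPLASTY",))
MOBILITY_AID = Concept("proc", ("MOBILITY_AID",))
PT_OT = Concept("proc", ("PT_OT",))
OPIOIDS = Concept("drug", tuple(c.value for c in OPIOID_CLASSES))
ORAL_NSAIDS = Concept("drug", (DrugClass.NSAID_NONSEL.value, DrugClass.NSAID_COX2.value))
TOPICAL_NSAIDS = Concept("drug", (DrugClass.NSAID_TOPICAL.value,))

INPT = frozenset({Setting.INPATIENT})
OUTPT = frozenset(OUTPATIENT_SETTINGS)

_PK = PredicateKind


def _same_cy_with_xray(k: int) -> Predicate:
    return Predicate(
        kind=_PK.SAME_CALENDAR_YEAR, concept=OA, anchor=XRAY, settings=OUTPT, k=k
    )


def step1_registry() -> list[RuleSpec]:
    """The 20 predefined algorithms identifying OA of the hip and/or knee."""
    from .published import STEP1_ROWS

    desc = {r.index: r.description for r in STEP1_ROWS}
    rules = [
        RuleSpec(1, 1, desc[1], Predicate(_PK.WITHIN_SPAN, OA, k=2, days=DAY_CONSTANTS["6m"])),
        RuleSpec(1, 2, desc[2], Predicate(_PK.WITHIN_SPAN, OA, k=2, days=90)),
        RuleSpec(1, 3, desc[3], Predicate(_PK.COUNT_IN_WINDOW, OA, settings=INPT, k=1)),
        RuleSpec(1, 4, desc[4], Predicate(_PK.COUNT_IN_WINDOW, OA, settings=OUTPT, k=1)),
        RuleSpec(1, 5, desc[5], Predicate(_PK.SAME_CALENDAR_YEAR, OA, settings=OUTPT, k=2)),
        RuleSpec(1, 6, desc[6], Predicate(_PK.SAME_CALENDAR_YEAR, OA, settings=OUTPT, k=3)),
        RuleSpec(1, 7, desc[7], Predicate(_PK.SAME_CALENDAR_YEAR, OA, settings=OUTPT, k=4)),
        RuleSpec(1, 8, desc[8], _same_cy_with_xray(1)),
        RuleSpec(1, 9, desc[9], _same_cy_with_xray(2)),
        RuleSpec(1, 10, desc[10], _same_cy_with_xray(3)),
        RuleSpec(1, 11, desc[11], _same_cy_with_xray(4)),
        RuleSpec(
            1, 12, desc[12],
            ("and", [
                Predicate(_PK.COUNT_IN_WINDOW, ANY_DX, settings=OUTPT, k=1),
                Predicate(_PK.WITHIN_SPAN, OA, settings=OUTPT, k=2, days=DAY_CONSTANTS["5y"]),
            ]),
        ),
        RuleSpec(1, 13, desc[13], Predicate(_PK.WITHIN_SPAN, OA, settings=OUTPT, k=2, days=DAY_CONSTANTS["5y"])),
        RuleSpec(1, 14, desc[14], Predicate(_PK.WITHIN_SPAN, OA, settings=OUTPT, k=2, days=DAY_CONSTANTS["2y"])),
        RuleSpec(1, 15, desc[15], Predicate(_PK.COUNT_IN_WINDOW, OA, k=1)),
        RuleSpec(1, 16, desc[16], Predicate(_PK.APART_FROM_ANCHOR_AT_LEAST, JOINT_PAIN, anchor=OA, days=30)),
        RuleSpec(
            1, 17, desc[17],
            ("and", [
                Predicate(_PK.COUNT_IN_WINDOW, OA, k=1),
                Predicate(_PK.COUNT_IN_WINDOW, HA_IA, k=1),
            ]),
        ),
        RuleSpec(1, 18, desc[18], Predicate(_PK.NEAR_ANCHOR, IMAGING, anchor=OA, days=DAY_CONSTANTS["2y"], k=1)),
        RuleSpec(1, 19, desc[19], Predicate(_PK.AFTER_ANCHOR, ARTHROPLASTY, anchor=OA, days=30)),
        RuleSpec(1, 20, desc[20], Predicate(_PK.NEAR_ANCHOR, MOBILITY_AID, anchor=OA, days=30, k=1)),
    ]
    return rules


def step2_registry() -> list[RuleSpec]:
    """The 14 predefined algorithms identifying moderate-to-severe OA."""
    from .published import STEP2_ROWS

    desc = {r.index: r.description for r in STEP2_ROWS}
    return [
        RuleSpec(2, 1, desc[1], Predicate(_PK.COUNT_IN_WINDOW, ARTHROPLASTY, k=1)),
        RuleSpec(2, 2, desc[2], Predicate(_PK.NEAR_ANCHOR, PSYCH, anchor=OA, days=180, k=2)),
        RuleSpec(2, 3, desc[3], Predicate(_PK.NEAR_ANCHOR, PSYCH, anchor=OA, days=90, k=2)),
        RuleSpec(2, 4, desc[4], Predicate(_PK.NEAR_ANCHOR, OPIOIDS, anchor=OA, days=90, k=2)),
        RuleSpec(2, 5, desc[5], Predicate(_PK.NEAR_ANCHOR, ORAL_NSAIDS, anchor=OA, days=90, k=2)),
        RuleSpec(2, 6, desc[6], Predicate(_PK.NEAR_ANCHOR, TOPICAL_NSAIDS, anchor=OA, days=90, k=2)),
        RuleSpec(2, 7, desc[7], Predicate(_PK.COUNT_IN_WINDOW, HA_IA, k=1)),
        RuleSpec(2, 8, desc[8], Predicate(_PK.PAIR_APART_AT_LEAST, HA_IA, days=90)),
        RuleSpec(2, 9, desc[9], Predicate(_PK.NEAR_ANCHOR, NERVE_BLOCK, anchor=OA, days=30, k=1)),
        RuleSpec(2, 10, desc[10], Predicate(_PK.NEAR_ANCHOR, MOBILITY_AID, anchor=OA, days=30, k=1)),
        RuleSpec(2, 11, desc[11], Predicate(_PK.NEAR_ANCHOR, PT_OT, anchor=OA, days=30, k=1)),
        RuleSpec(2, 12, desc[12], Predicate(_PK.COST_VS_COHORT_MEAN, multiplier=1.30)),
        RuleSpec(2, 13, desc[13], Predicate(_PK.COST_VS_COHORT_MEAN, multiplier=1.50)),
        RuleSpec(2, 14, desc[14], Predicate(_PK.WITHIN_SPAN, XRAY, k=2, days=DAY_CONSTANTS["1y"])),
    ]


def step3_registry() -> list[RuleSpec]:
    """The 6 predefined algorithms identifying inadequate analgesic response."""
    from .published import STEP3_ROWS

    desc = {r.index: r.description for r in STEP3_ROWS}
    analgesics = tuple(c.value for c in ANALGESIC_CLASSES)
    opioids = tuple(c.value for c in OPIOID_CLASSES)
    return [
        RuleSpec(3, 1, desc[1], Predicate(_PK.PRECEDED_BY_CLASSES, HA_IA_NB, classes=analgesics, n_classes=2)),
        RuleSpec(3, 2, desc[2], Predicate(_PK.DISTINCT_CLASSES_AT_LEAST, classes=analgesics, n_classes=3)),
        RuleSpec(3, 3, desc[3], Predicate(_PK.COUNT_IN_WINDOW, ARTHROPLASTY, k=1)),
        RuleSpec(3, 4, desc[4], Predicate(_PK.COUNT_IN_WINDOW, NERVE_BLOCK, k=1)),
        RuleSpec(3, 5, desc[5], Predicate(_PK.DISTINCT_CLASSES_AT_LEAST, classes=opioids, n_classes=2, days=90)),
        RuleSpec(3, 6, desc[6], Predicate(_PK.AFTER_ANCHOR, MOBILITY_AID, anchor=OPIOIDS, days=90)),
    ]


def all_rules() -> list[RuleSpec]:
    return step1_registry() + step2_registry() + step3_registry()


# ---------------------------------------------------------------------------
# OR combination and the three-step composite classifier
# ---------------------------------------------------------------------------


def combine_or(outcomes: Mapping[int, bool], selected: set[int] | Sequence[int]) -> bool:
    """True iff any selected rule index is satisfied in ``outcomes``."""
    selected = set(selected)
    if not selected:
        raise ValueError("empty rule selection")
    missing = selected - set(outcomes)
    if missing:
        raise ValueError(f"no outcome for selected rules {sorted(missing)}")
    return any(outcomes[i] for i in selected)


def composite_classify(
    step_outcomes: tuple[Mapping[int, bool], Mapping[int, bool], Mapping[int, bool]],
    step_selections: tuple[Sequence[int], Sequence[int], Sequence[int]],
) -> bool:
    """Composite case call: the OR-combination must fire at all three steps."""
    return all(
        combine_or(outcomes, selection)
        for outcomes, selection in zip(step_outcomes, step_selections)
    )


# ---------------------------------------------------------------------------
# OA-related cost context
# ---------------------------------------------------------------------------

#: Procedure concepts whose reimbursed amounts count as OA-related cost.
OA_COST_PROC_SETS = (
    "HA_INJECTION", "IA_CORTICOSTEROID", "NERVE_BLOCK", "ARTHROPLASTY",
    "IMAGING_HIP_KNEE", "PT_OT", "MOBILITY_AID",
)


def oa_related_cost(
    patient: PatientRecord,
    window: DateInterval,
    code_sets: Mapping[str, CodeSet],
) -> float:
    """OA-related reimbursed cost inside the window.

    Sum of costs of OA-related procedures (injections, hip/knee imaging,
    arthroplasty, nerve block, therapy, mobility aids) plus analgesic drug
    fills.
    """
    sets = [code_sets[n] for n in OA_COST_PROC_SETS]
    total = sum(
        p.cost
        for p in patient.procedures
        if window.contains(p.date) and any(match_code(p.code, p.system, cs) for cs in sets)
    )
    analgesics = set(ANALGESIC_CLASSES)
    total += sum(
        f.cost
        for f in patient.drugs
        if window.contains(f.fill_date) and f.drug_class in analgesics
    )
    return float(total)


def build_context(
    db: PatientDB,
    windows: Mapping[str, DateInterval],
    code_sets: Mapping[str, CodeSet],
) -> CohortContext:
    """Per-patient OA-related costs and their cohort mean."""
    costs = {
        pid: oa_related_cost(db.records[pid], windows[pid], code_sets)
        for pid in windows
    }
    mean = float(sum(costs.values()) / len(costs)) if costs else 0.0
    return CohortContext(oa_cost=costs, mean_oa_cost=mean)
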