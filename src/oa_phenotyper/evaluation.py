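"""Diagnostic-accuracy evaluation against gold-standard labels.

Confusion counts and the five validation metrics (sensitivity, specificity,
NPV, PPV, accuracy), the F1 harmonic mean of PPV and sensitivity, rank-based
AUC, PPV-threshold selection of component algorithms, and the full per-step
report: per-rule rows followed by OR-combined rows at the five PPV
thresholds, plus the three-step composite classifier.

Metrics with a zero denominator are undefined and surface as ``None`` (the
reporting layer prints "N/A"), never as 0 or 1. Reported metrics are rounded
half-up to two decimals; raw proportions are retained on the objects.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_builder import DateInterval
from .records_io import CodeSet, PatientDB
from .rule_engine import (
    CohortContext,
    RuleSpec,
    build_context,
    combine_or,
    evaluate_rule,
    step1_registry,
    step2_registry,
    step3_registry,
)

__all__ = [
    "ConfusionMatrix",
    "MetricSet",
    "round2",
    "confusion",
    "metrics",
    "f1",
    "auc",
    "select_by_ppv",
    "rule_outcome_table",
    "evaluate_pipeline",
    "DEFAULT_THRESHOLDS",
]

DEFAULT_THRESHOLDS = (0.98, 0.95, 0.90, 0.85, 0.80)


def round2(value: float | None) -> float | None:
    """Half-up rounding to 2 decimals, as used for the printed tables."""
    if value is None:
        return None
    return float(Decimal(repr(value)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricSet:
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    accuracy: float | None
    f1: float | None = None
    auc: float | None = None

    def rounded(self) -> "MetricSet":
        return MetricSet(
            sensitivity=round2(self.sensitivity),
            specificity=round2(self.specificity),
            ppv=round2(self.ppv),
            npv=round2(self.npv),
            accuracy=round2(self.accuracy),
            f1=round2(self.f1),
            auc=round2(self.auc),
        )


def confusion(
    predicted: Mapping[str, bool],
    gold: Mapping[str, bool],
) -> ConfusionMatrix:
    """Tally TP/FP/TN/FN; the two id sets must coincide."""
    pred_ids, gold_ids = set(predicted), set(gold)
    if pred_ids != gold_ids:
        extra = sorted(pred_ids - gold_ids)[:5]
        missing = sorted(gold_ids - pred_ids)[:5]
        raise ValueError(
            f"id mismatch between predictions and gold labels "
            f"(extra={extra}, missing={missing})"
        )
    tp = fp = tn = fn = 0
    for pid, p in predicted.items():
        g = gold[pid]
        if p and g:
            tp += 1
        elif p and not g:
            fp += 1
        elif not p and not g:
            tn += 1
        else:
            fn += 1
    return ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def metrics(cm: ConfusionMatrix) -> MetricSet:
    """The five validation metrics; undefined (None) on zero denominators."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return MetricSet(
        sensitivity=_ratio(cm.tp, cm.tp + cm.fn),
        specificity=_ratio(cm.tn, cm.tn + cm.fp),
        ppv=_ratio(cm.tp, cm.tp + cm.fp),
        npv=_ratio(cm.tn, cm.tn + cm.fn),
        accuracy=(cm.tp + cm.tn) / cm.total,
    )


def f1(ppv: float, sensitivity: float) -> float:
    """Harmonic mean of PPV and sensitivity."""
    if ppv < 0 or sensitivity < 0:
        raise ValueError("ppv and sensitivity must be non-negative")
    if ppv + sensitivity == 0:
        raise ValueError("F1 undefined when PPV and sensitivity are both zero")
    return 2 * ppv * sensitivity / (ppv + sensitivity)


def auc(scores: Mapping[str, float], gold: Mapping[str, bool]) -> float:
    """Rank-based (Mann-Whitney) AUC with ties counted one half."""
    if set(scores) != set(gold):
        raise ValueError("id mismatch between scores and gold labels")
    ids = sorted(scores)
    y = np.array([gold[i] for i in ids], dtype=bool)
    s = np.array([scores[i] for i in ids], dtype=float)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = stats.rankdata(s)  # average ranks handle ties as 0.5
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def select_by_ppv(
    per_rule_metrics: Mapping[int, MetricSet],
    threshold: float,
) -> set[int]:
    """Rule indices whose (defined) PPV, rounded as printed, meets the bar."""
    selected = {
        idx
        for idx, m in per_rule_metrics.items()
        if m.ppv is not None and round2(m.ppv) >= threshold
    }
    if not selected:
        raise ValueError(
            f"no rule reaches PPV >= {threshold}; relax the threshold"
        )
    return selected


# ---------------------------------------------------------------------------
# Whole-cohort evaluation
# ---------------------------------------------------------------------------


def rule_outcome_table(
    db: PatientDB,
    windows: Mapping[str, DateInterval],
    rules: Sequence[RuleSpec],
    code_sets: Mapping[str, CodeSet],
    ctx: CohortContext | None = None,
) -> pd.DataFrame:
    """Boolean outcome per (patient, rule); columns are (step, index)."""
    if ctx is None:
        ctx = build_context(db, windows, code_sets)
    pids = sorted(windows)
    data = {
        (rule.step, rule.index): [
            evaluate_rule(db.records[pid], rule, windows[pid], code_sets, ctx).satisfied
            for pid in pids
        ]
        for rule in rules
    }
    return pd.DataFrame(data, index=pids)


_GOLD_FIELD = {1: "has_oa_hip_knee", 2: "moderate_severe", 3: "inadequate_response"}


def _gold_for_step(db: PatientDB, pids: Sequence[str], step: int) -> dict[str, bool]:
    field_name = _GOLD_FIELD[step]
    return {pid: getattr(db.labels[pid], field_name) for pid in pids}


def evaluate_pipeline(
    db: PatientDB,
    windows: Mapping[str, DateInterval],
    code_sets: Mapping[str, CodeSet],
    *,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    composite_thresholds: tuple[float, float, float] = (0.95, 0.95, 0.90),
) -> pd.DataFrame:
    """Per-rule and OR-combined validation report for all three steps.

    Returns a table shaped like the published validation tables: for each
    step, one row per rule with TP/FP/TN/FN and the five metrics (rounded,
    half-up, 2 decimals), followed by one combined row per PPV threshold,
    then a final three-step composite row at ``composite_thresholds``.
    Requires gold labels for every windowed patient.
    """
    pids = sorted(windows)
    missing = [pid for pid in pids if pid not in db.labels]
    if missing:
        raise ValueError(f"missing gold labels for patients {missing[:5]}")

    registries = {1: step1_registry(), 2: step2_registry(), 3: step3_registry()}
    ctx = build_context(db, windows, code_sets)
    rows: list[dict] = []
    step_combined_pred: dict[int, dict[str, bool]] = {}

    for step, registry in registries.items():
        gold = _gold_for_step(db, pids, step)
        outcomes = rule_outcome_table(db, windows, registry, code_sets, ctx)
        per_rule: dict[int, MetricSet] = {}
        per_rule_pred: dict[int, dict[str, bool]] = {}
        for rule in registry:
            pred = dict(outcomes[(rule.step, rule.index)])
            cm = confusion(pred, gold)
            m = metrics(cm)
            per_rule[rule.index] = m
            per_rule_pred[rule.index] = pred
            rows.append(_report_row(step, str(rule.index), rule.description, cm, m))
        for thr in thresholds:
            try:
                selected = select_by_ppv(per_rule, thr)
            except ValueError:
                continue
            pred = {
                pid: combine_or({i: per_rule_pred[i][pid] for i in selected}, selected)
                for pid in pids
            }
            cm = confusion(pred, gold)
            rows.append(
                _report_row(
                    step,
                    f"combined>={thr:.2f}",
                    f"Combinations of all algorithms with performance ≥ {thr:.2f} PPV",
                    cm,
                    metrics(cm),
                )
            )
            if abs(thr - composite_thresholds[step - 1]) < 1e-9:
                step_combined_pred[step] = pred

    if len(step_combined_pred) == 3:
        composite_pred = {
            pid: all(step_combined_pred[s][pid] for s in (1, 2, 3)) for pid in pids
        }
        gold_case = {pid: db.labels[pid].is_case for pid in pids}
        cm = confusion(composite_pred, gold_case)
        rows.append(
            _report_row(
                0,
                "composite",
                "Three-step composite (OA AND moderate-to-severe AND inadequate response)",
                cm,
                metrics(cm),
            )
        )
    return pd.DataFrame(rows)


def _report_row(step: int, rule: str, description: str, cm: ConfusionMatrix, m: MetricSet) -> dict:
    r = m.rounded()
    return {
        "step": step,
        "rule": rule,
        "description": description,
        "tp": cm.tp,
        "fp": cm.fp,
        "tn": cm.tn,
        "fn": cm.fn,
        "sensitivity": r.sensitivity,
        "specificity": r.specificity,
        "npv": r.npv,
        "ppv": r.ppv,
        "accuracy": r.accuracy,
    }
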