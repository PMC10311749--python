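"""Independent brute-force evaluator for the 40 predefined algorithms.

Each rule is re-implemented here as a literal nested-loop scan over event
pairs with no shared predicate machinery, serving as the oracle for
equivalence testing of the rule engine. Counting conventions match the
documented semantics: diagnosis/procedure events count by distinct service
date, drug fills by event; all day bounds are inclusive.
"""

from __future__ import annotations

import datetime as dt

NSAID_CLASSES = {"NSAID_NONSEL", "NSAID_COX2", "NSAID_TOPICAL"}
ORAL_NSAID_CLASSES = {"NSAID_NONSEL", "NSAID_COX2"}
OPIOID_CLASSES = {"OPIOID_SA", "OPIOID_LA", "OPIOID_MIXED"}
ANALGESIC_CLASSES = NSAID_CLASSES | OPIOID_CLASSES

OUTPT = {"OUTPATIENT_OFFICE", "OUTPATIENT_OTHER"}


def _norm(code: str) -> str:
    return code.replace(".", "").strip().upper()


def _matches(code: str, system: str, code_set) -> bool:
    c = _norm(code)
    for pat_system, pat in code_set.patterns:
        if pat_system.value != system:
            continue
        p = _norm(pat)
        if p.endswith("*"):
            if c.startswith(p[:-1]):
                return True
        elif c == p:
            return True
    return False


def _in(window, date: dt.date) -> bool:
    return window.start <= date <= window.end


def dx_dates(rec, window, code_sets, names, settings=None) -> list[dt.date]:
    out = set()
    for d in rec.diagnoses:
        if not _in(window, d.date):
            continue
        if settings is not None and d.setting.value not in settings:
            continue
        if names is None:
            out.add(d.date)
        elif any(_matches(d.code, d.system.value, code_sets[n]) for n in names):
            out.add(d.date)
    return sorted(out)


def proc_dates(rec, window, code_sets, names) -> list[dt.date]:
    out = set()
    for p in rec.procedures:
        if _in(window, p.date) and any(
            _matches(p.code, p.system.value, code_sets[n]) for n in names
        ):
            out.add(p.date)
    return sorted(out)


def drug_fills(rec, window, classes) -> list[tuple[dt.date, str]]:
    return sorted(
        (f.fill_date, f.drug_class.value)
        for f in rec.drugs
        if _in(window, f.fill_date) and f.drug_class.value in classes
    )


def _pair_at_most(dates, d):
    return any(
        0 <= (b - a).days <= d for i, a in enumerate(dates) for b in dates[i + 1:]
    )


def _year_counts(dates):
    out = {}
    for d in dates:
        out[d.year] = out.get(d.year, 0) + 1
    return out


def oracle_oa_cost(rec, window, code_sets) -> float:
    names = ("HA_INJECTION", "IA_CORTICOSTEROID", "NERVE_BLOCK", "ARTHROPLASTY",
             "IMAGING_HIP_KNEE", "PT_OT", "MOBILITY_AID")
    total = 0.0
    for p in rec.procedures:
        if _in(window, p.date) and any(
            _matches(p.code, p.system.value, code_sets[n]) for n in names
        ):
            total += p.cost
    for f in rec.drugs:
        if _in(window, f.fill_date) and f.drug_class.value in ANALGESIC_CLASSES:
            total += f.cost
    return total


JOINT_PAIN = ("JOINT_PAIN_HIP", "JOINT_PAIN_KNEE", "JOINT_PAIN_OTHER")


def evaluate_oracle(step: int, index: int, rec, window, code_sets, mean_cost=None) -> bool:
    oa_all = dx_dates(rec, window, code_sets, ("OA_HIP_KNEE",))
    oa_out = dx_dates(rec, window, code_sets, ("OA_HIP_KNEE",), OUTPT)

    if step == 1:
        if index == 1:
            return _pair_at_most(oa_all, 183)
        if index == 2:
            return _pair_at_most(oa_all, 90)
        if index == 3:
            return len(dx_dates(rec, window, code_sets, ("OA_HIP_KNEE",), {"INPATIENT"})) >= 1
        if index == 4:
            return len(oa_out) >= 1
        if index in (5, 6, 7):
            k = index - 3
            return any(n >= k for n in _year_counts(oa_out).values())
        if index in (8, 9, 10, 11):
            k = index - 7
            xray_years = {d.year for d in proc_dates(rec, window, code_sets, ("XRAY_HIP_KNEE",))}
            return any(n >= k and y in xray_years for y, n in _year_counts(oa_out).items())
        if index == 12:
            any_out = dx_dates(rec, window, code_sets, None, OUTPT)
            return len(any_out) >= 1 and _pair_at_most(oa_out, 1827)
        if index == 13:
            return _pair_at_most(oa_out, 1827)
        if index == 14:
            return _pair_at_most(oa_out, 731)
        if index == 15:
            return len(oa_all) >= 1
        if index == 16:
            jp = dx_dates(rec, window, code_sets, JOINT_PAIN)
            return any(abs((j - a).days) >= 30 for a in oa_all for j in jp)
        if index == 17:
            return len(oa_all) >= 1 and len(
                proc_dates(rec, window, code_sets, ("HA_INJECTION", "IA_CORTICOSTEROID"))
            ) >= 1
        if index == 18:
            scans = proc_dates(rec, window, code_sets, ("IMAGING_HIP_KNEE",))
            return any(abs((s - a).days) <= 731 for a in oa_all for s in scans)
        if index == 19:
            surg = proc_dates(rec, window, code_sets, ("ARTHROPLASTY",))
            return any(0 <= (s - a).days <= 30 for a in oa_all for s in surg)
        if index == 20:
            aids = proc_dates(rec, window, code_sets, ("MOBILITY_AID",))
            return any(abs((m - a).days) <= 30 for a in oa_all for m in aids)

    if step == 2:
        if index == 1:
            return len(proc_dates(rec, window, code_sets, ("ARTHROPLASTY",))) >= 1
        if index in (2, 3):
            d = 180 if index == 2 else 90
            psych = dx_dates(rec, window, code_sets, ("PSYCHIATRIC",))
            near = [e for e in psych if any(abs((e - a).days) <= d for a in oa_all)]
            return len(near) >= 2
        if index in (4, 5, 6):
            classes = {4: OPIOID_CLASSES, 5: ORAL_NSAID_CLASSES, 6: {"NSAID_TOPICAL"}}[index]
            fills = drug_fills(rec, window, classes)
            near = [f for f, _ in fills if any(abs((f - a).days) <= 90 for a in oa_all)]
            return len(near) >= 2
        if index == 7:
            return len(proc_dates(rec, window, code_sets, ("HA_INJECTION", "IA_CORTICOSTEROID"))) >= 1
        if index == 8:
            inj = proc_dates(rec, window, code_sets, ("HA_INJECTION", "IA_CORTICOSTEROID"))
            return any((b - a).days >= 90 for i, a in enumerate(inj) for b in inj[i + 1:])
        if index in (9, 10, 11):
            names = {9: ("NERVE_BLOCK",), 10: ("MOBILITY_AID",), 11: ("PT_OT",)}[index]
            dates = proc_dates(rec, window, code_sets, names)
            return any(abs((e - a).days) <= 30 for a in oa_all for e in dates)
        if index in (12, 13):
            m = 1.30 if index == 12 else 1.50
            if mean_cost is None:
                raise ValueError("cost rules need the cohort mean")
            return oracle_oa_cost(rec, window, code_sets) > m * mean_cost
        if index == 14:
            return _pair_at_most(proc_dates(rec, window, code_sets, ("XRAY_HIP_KNEE",)), 365)

    if step == 3:
        if index == 1:
            procs = proc_dates(rec, window, code_sets, ("HA_INJECTION", "IA_CORTICOSTEROID", "NERVE_BLOCK"))
            fills = drug_fills(rec, window, ANALGESIC_CLASSES)
            return any(
                len({c for f, c in fills if f < p}) >= 2 for p in procs
            )
        if index == 2:
            return len({c for _, c in drug_fills(rec, window, ANALGESIC_CLASSES)}) >= 3
        if index == 3:
            return len(proc_dates(rec, window, code_sets, ("ARTHROPLASTY",))) >= 1
        if index == 4:
            return len(proc_dates(rec, window, code_sets, ("NERVE_BLOCK",))) >= 1
        if index == 5:
            fills = drug_fills(rec, window, OPIOID_CLASSES)
            return any(
                c1 != c2 and abs((d1 - d2).days) <= 90
                for d1, c1 in fills
                for d2, c2 in fills
            )
        if index == 6:
            aids = proc_dates(rec, window, code_sets, ("MOBILITY_AID",))
            opioids = [f for f, _ in drug_fills(rec, window, OPIOID_CLASSES)]
            return any(0 <= (m - o).days <= 90 for o in opioids for m in aids)

    raise ValueError(f"unknown rule ({step}, {index})")
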