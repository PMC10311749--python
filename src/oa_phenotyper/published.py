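"""Published validation-study results, transcribed as machine-readable data.

The source study validated the predefined algorithms against chart-review
gold-standard labels on the 490 patients with claims data, and printed the
raw confusion counts (TP/FP/TN/FN) next to five rounded metrics per
algorithm. Those printed counts and cells are transcribed here so the
evaluation code can be checked against them; they are inputs, not outputs,
of this package.

Structures
----------
``STEP1_ROWS`` / ``STEP2_ROWS`` / ``STEP3_ROWS``
    One entry per predefined algorithm: row index, description, the four
    confusion counts, and the five printed metrics (``None`` where the table
    prints N/A).
``STEP1_COMBINED`` / ``STEP2_COMBINED`` / ``STEP3_COMBINED``
    The OR-combined rows, keyed by PPV threshold.
``TABLE1_COUNTS``
    Clinical characteristic counts by patient archetype with the printed
    percentages (denominators 47 / 360 / 83).
``ML_PERFORMANCE``
    Printed metrics of the three ML model families, including PPV,
    sensitivity and the F1 derived from them.
"""

from __future__ import annotations

from dataclasses import dataclass

CLAIMS_N = 490


@dataclass(frozen=True)
class PublishedRow:
    step: int
    index: int  # 1-based row number within its table; 0 for combined rows
    description: str
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float | None
    specificity: float | None
    npv: float | None
    ppv: float | None
    accuracy: float | None

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _row(step, index, desc, tp, fp, tn, fn, sens, spec, npv, ppv, acc) -> PublishedRow:
    return PublishedRow(step, index, desc, tp, fp, tn, fn, sens, spec, npv, ppv, acc)


# Step 1: identify OA of hip and/or knee (N = 490).
STEP1_ROWS: list[PublishedRow] = [
    _row(1, 1, "≥ 2 medical (inpatient and/or outpatient [both physicians' office visits and all other outpatient settings]) encounters resulting in diagnoses OA of the hip and/or knee within 6 months",
         350, 7, 40, 93, 0.79, 0.85, 0.30, 0.98, 0.80),
    _row(1, 2, "≥ 2 medical encounters resulting in diagnoses of OA of the hip and/or knee ≤ 90 days apart",
         335, 6, 41, 108, 0.76, 0.87, 0.28, 0.98, 0.77),
    _row(1, 3, "1 inpatient admission resulting in a diagnosis of OA of the hip and/or knee",
         239, 2, 45, 204, 0.54, 0.96, 0.18, 0.99, 0.58),
    _row(1, 4, "A diagnosis of OA of the hip and/or knee from ≥ 1 outpatient visit",
         401, 21, 26, 42, 0.91, 0.55, 0.38, 0.95, 0.87),
    _row(1, 5, "A diagnosis of OA of the hip and/or knee from ≥ 2 outpatient visits in the same CY",
         345, 6, 41, 98, 0.78, 0.87, 0.29, 0.98, 0.79),
    _row(1, 6, "A diagnosis of OA of the hip and/or knee from ≥ 3 outpatient visits in the same CY",
         294, 6, 41, 149, 0.66, 0.87, 0.22, 0.98, 0.68),
    _row(1, 7, "A diagnosis of OA of the hip and/or knee from ≥ 4 outpatient visits in the same CY",
         263, 2, 45, 180, 0.59, 0.96, 0.20, 0.99, 0.63),
    _row(1, 8, "A diagnosis of OA of the hip and/or knee from ≥ 1 outpatient visit; and ≥ 1 X-rays of the hip and/or knee in the same CY",
         351, 10, 37, 92, 0.79, 0.79, 0.29, 0.97, 0.79),
    _row(1, 9, "A diagnosis of OA of the hip and/or knee from ≥ 2 outpatient visits; and ≥ 1 X-rays of the hip and/or knee in the same CY",
         318, 3, 44, 125, 0.72, 0.94, 0.26, 0.99, 0.74),
    _row(1, 10, "A diagnosis of OA of the hip and/or knee from ≥ 3 outpatient visits; and ≥ 1 X-rays of the hip and/or knee in the same CY",
         270, 3, 44, 173, 0.61, 0.94, 0.20, 0.99, 0.64),
    _row(1, 11, "A diagnosis of OA of the hip and/or knee from ≥ 4 outpatient visits; and ≥ 1 X-rays of the hip and/or knee in the same CY",
         244, 1, 46, 199, 0.55, 0.98, 0.19, 1.00, 0.59),
    _row(1, 12, "1 outpatient visit and ≥ 2 diagnoses of OA of the hip and/or knee from outpatient visits within 5 years",
         274, 5, 42, 169, 0.62, 0.89, 0.20, 0.98, 0.64),
    _row(1, 13, "≥ 2 outpatient visits resulting in diagnoses of OA of the hip and/or knee within 5 years",
         351, 6, 41, 92, 0.79, 0.87, 0.31, 0.98, 0.80),
    _row(1, 14, "≥ 2 outpatient visits resulting in diagnoses of OA of the hip and/or knee within 2 years",
         351, 6, 41, 92, 0.79, 0.87, 0.31, 0.98, 0.80),
    _row(1, 15, "≥ 1 medical encounter resulting in a diagnosis of OA of the hip and/or knee",
         401, 21, 26, 42, 0.91, 0.55, 0.38, 0.95, 0.87),
    _row(1, 16, "≥ 1 medical encounter resulting in a diagnosis of OA of the hip or knee plus ≥ 1 medical encounter resulting in a diagnosis of joint pain ≥ 30 days apart",
         325, 4, 43, 118, 0.73, 0.91, 0.27, 0.99, 0.75),
    _row(1, 17, "≥ 1 medical encounter resulting in a diagnosis of OA of the hip or knee plus ≥ 1 administration of either HA or IA corticosteroids",
         316, 8, 39, 127, 0.71, 0.83, 0.23, 0.98, 0.72),
    _row(1, 18, "≥ 1 medical encounter resulting in a diagnosis of OA of the hip or knee plus ≥ 1 relevant scans (i.e., X-ray, MRI) of knee or hip ± 2 years of the OA diagnosis",
         358, 7, 40, 85, 0.81, 0.85, 0.32, 0.98, 0.81),
    _row(1, 19, "≥ 1 medical encounter resulting in a diagnosis of OA of the hip or knee plus ≥ 1 procedure codes for knee or hip arthroplasty (partial or full; initial or revision) within 30 days after OA diagnosis",
         231, 0, 47, 212, 0.52, 1.00, 0.18, 1.00, 0.57),
    _row(1, 20, "≥ 1 medical encounter resulting in a diagnosis of OA of the hip or knee plus ≥ 1 mobility aid (e.g., cane, walker, wheelchair) ± 30 days of OA diagnosis",
         79, 2, 45, 364, 0.18, 0.96, 0.11, 0.98, 0.25),
]

STEP1_COMBINED: dict[float, PublishedRow] = {
    0.98: _row(1, 0, "Combinations of all algorithms with performance ≥ 0.98 PPV",
               382, 11, 36, 61, 0.86, 0.77, 0.37, 0.97, 0.85),
    0.95: _row(1, 0, "Combinations of all algorithms with performance ≥ 0.95 PPV",
               403, 21, 26, 40, 0.91, 0.55, 0.39, 0.95, 0.88),
    0.90: _row(1, 0, "Combinations of all algorithms with performance ≥ 0.90 PPV",
               403, 21, 26, 40, 0.91, 0.55, 0.39, 0.95, 0.88),
    0.85: _row(1, 0, "Combinations of all algorithms with performance ≥ 0.85 PPV",
               403, 21, 26, 40, 0.91, 0.55, 0.39, 0.95, 0.88),
    0.80: _row(1, 0, "Combinations of all algorithms with performance ≥ 0.80 PPV",
               403, 21, 26, 40, 0.91, 0.55, 0.39, 0.95, 0.88),
}

# Step 2: identify moderate-to-severe OA (N = 490).
STEP2_ROWS: list[PublishedRow] = [
    _row(2, 1, "≥ 1 code for any OA-related surgical procedures",
         263, 0, 77, 150, 0.64, 1.00, 0.34, 1.00, 0.69),
    _row(2, 2, "≥ 2 medical encounters on different days resulting in diagnosis of a relevant psychiatric comorbidity (i.e., anxiety, depression), with at least two encounters for psychiatric comorbidities both occurring within 180 days of any OA diagnosis",
         87, 14, 63, 326, 0.21, 0.82, 0.16, 0.86, 0.31),
    _row(2, 3, "≥ 2 medical encounters resulting in diagnosis of relevant psychiatric comorbidities, with at least two encounters for the psychiatric comorbidities within 90 days of any OA diagnosis",
         83, 12, 65, 330, 0.20, 0.84, 0.16, 0.87, 0.30),
    _row(2, 4, "≥ 2 prescriptions for opioids within 90 days of any OA diagnosis",
         66, 5, 72, 347, 0.16, 0.94, 0.17, 0.93, 0.28),
    _row(2, 5, "≥ 2 prescriptions for oral NSAIDs (including COX-2 inhibitors) within 90 days of any OA diagnosis",
         1, 0, 77, 412, 0.00, 1.00, 0.16, 1.00, 0.16),
    _row(2, 6, "≥ 2 prescriptions for topical NSAIDs (including COX-2 inhibitors) within 90 days of any OA diagnosis",
         10, 2, 75, 403, 0.02, 0.97, 0.16, 0.83, 0.17),
    _row(2, 7, "≥ 1 administration of HA or IA corticosteroids",
         331, 3, 74, 82, 0.80, 0.96, 0.47, 0.99, 0.83),
    _row(2, 8, "≥ 2 administrations of HA or IA corticosteroids at least 90 days apart",
         191, 1, 76, 222, 0.46, 0.99, 0.26, 0.99, 0.54),
    _row(2, 9, "≥ 1 administration of a nerve block ± 30 days of any OA diagnosis",
         191, 3, 74, 222, 0.46, 0.96, 0.25, 0.98, 0.54),
    _row(2, 10, "≥ 1 claim for a mobility aid including walking cane, walker, and wheelchair, or crutch ± 30 days of any OA diagnosis",
         79, 5, 72, 334, 0.19, 0.94, 0.18, 0.94, 0.31),
    _row(2, 11, "≥ 1 code for physical and/or occupational therapy ± 30 days of any OA diagnosis",
         175, 12, 65, 238, 0.42, 0.84, 0.21, 0.94, 0.49),
    _row(2, 12, "OA-related costs > 30% mean OA-related costs for the cohort",
         147, 0, 77, 266, 0.36, 1.00, 0.22, 1.00, 0.46),
    _row(2, 13, "OA-related costs > 50% mean OA-related costs for the cohort",
         0, 0, 77, 413, 0.00, 1.00, 0.16, None, 0.16),
    _row(2, 14, "≥ 2 codes for X-ray examinations in a 1-year period",
         295, 10, 67, 118, 0.71, 0.87, 0.36, 0.97, 0.74),
]

STEP2_COMBINED: dict[float, PublishedRow] = {
    0.98: _row(2, 0, "Combinations of all algorithms with performance ≥ 0.98 PPV",
               360, 6, 71, 53, 0.87, 0.92, 0.57, 0.98, 0.88),
    0.95: _row(2, 0, "Combinations of all algorithms with performance ≥ 0.95 PPV",
               372, 13, 64, 41, 0.90, 0.83, 0.61, 0.97, 0.89),
    0.90: _row(2, 0, "Combinations of all algorithms with performance ≥ 0.90 PPV",
               378, 21, 56, 35, 0.92, 0.73, 0.62, 0.95, 0.89),
    0.85: _row(2, 0, "Combinations of all algorithms with performance ≥ 0.85 PPV",
               378, 25, 52, 35, 0.92, 0.68, 0.60, 0.94, 0.88),
    0.80: _row(2, 0, "Combinations of all algorithms with performance ≥ 0.80 PPV",
               378, 26, 51, 35, 0.92, 0.66, 0.59, 0.94, 0.88),
}

# Step 3: identify inadequate response to ≥2 pain-related medications (N = 490).
STEP3_ROWS: list[PublishedRow] = [
    _row(3, 1, "Receipt of HA, IA corticosteroid, and/or nerve block preceded by receipt of 2 different classes of analgesics (i.e., NSAIDs [including COX-2 inhibitors], opioids)",
         10, 0, 127, 353, 0.03, 1.00, 0.26, 1.00, 0.28),
    _row(3, 2, "Receipt of ≥ 3 analgesic classes",
         44, 1, 126, 319, 0.12, 0.99, 0.28, 0.98, 0.35),
    _row(3, 3, "Receipt of knee or hip arthroplasty (partial or complete; original or revision)",
         258, 6, 121, 105, 0.71, 0.95, 0.54, 0.98, 0.77),
    _row(3, 4, "Receipt of nerve block",
         210, 19, 108, 153, 0.58, 0.85, 0.41, 0.92, 0.65),
    _row(3, 5, "Receipt of ≥ 2 different opioids within a 90-day period",
         24, 4, 123, 339, 0.07, 0.97, 0.27, 0.86, 0.30),
    _row(3, 6, "Receipt of a mobility aid (as described above) within 90-day period subsequent to receipt of an opioid",
         12, 0, 127, 351, 0.03, 1.00, 0.27, 1.00, 0.28),
]

STEP3_COMBINED: dict[float, PublishedRow] = {
    0.98: _row(3, 0, "Combinations of all algorithms with performance ≥ 0.98 PPV",
               21, 0, 127, 342, 0.06, 1.00, 0.27, 1.00, 0.30),
    0.95: _row(3, 0, "Combinations of all algorithms with performance ≥ 0.95 PPV",
               262, 6, 121, 101, 0.72, 0.95, 0.55, 0.98, 0.78),
    0.90: _row(3, 0, "Combinations of all algorithms with performance ≥ 0.90 PPV",
               290, 23, 104, 73, 0.80, 0.82, 0.59, 0.93, 0.80),
    0.85: _row(3, 0, "Combinations of all algorithms with performance ≥ 0.85 PPV",
               291, 25, 102, 72, 0.80, 0.80, 0.59, 0.92, 0.80),
    0.80: _row(3, 0, "Combinations of all algorithms with performance ≥ 0.80 PPV",
               291, 25, 102, 72, 0.80, 0.80, 0.59, 0.92, 0.80),
}

ALL_ROWS: list[PublishedRow] = (
    STEP1_ROWS + list(STEP1_COMBINED.values())
    + STEP2_ROWS + list(STEP2_COMBINED.values())
    + STEP3_ROWS + list(STEP3_COMBINED.values())
)

# ---------------------------------------------------------------------------
# Clinical characteristics by patient archetype (claims subset):
# concept -> (count and printed %, per archetype) with denominators
# non-OA N=47, case N=360, comparator N=83.
# ---------------------------------------------------------------------------

TABLE1_DENOMS = {"non_oa": 47, "case": 360, "comparator": 83}

#: concept -> {archetype: (count, printed_percent)}
TABLE1_COUNTS: dict[str, dict[str, tuple[int, float]]] = {
    "obesity": {"non_oa": (4, 8.5), "case": (101, 28.1), "comparator": (16, 19.3)},
    "joint_pain_hip": {"non_oa": (2, 4.3), "case": (46, 12.8), "comparator": (5, 6.0)},
    "joint_pain_knee": {"non_oa": (0, 0.0), "case": (83, 23.1), "comparator": (13, 15.7)},
    "joint_pain_other": {"non_oa": (15, 31.9), "case": (148, 41.1), "comparator": (29, 34.9)},
    "back_pain": {"non_oa": (0, 0.0), "case": (10, 2.8), "comparator": (2, 2.4)},
    "unspecified_pain": {"non_oa": (12, 25.5), "case": (168, 46.7), "comparator": (19, 22.9)},
    "hypertension": {"non_oa": (11, 23.4), "case": (153, 42.5), "comparator": (27, 32.5)},
    "diabetes": {"non_oa": (12, 25.5), "case": (47, 13.1), "comparator": (12, 14.5)},
    "gerd": {"non_oa": (4, 8.5), "case": (90, 25.0), "comparator": (9, 10.8)},
    "depression": {"non_oa": (3, 6.4), "case": (56, 15.6), "comparator": (8, 9.6)},
    "anxiety": {"non_oa": (4, 8.5), "case": (47, 13.1), "comparator": (8, 9.6)},
    "drug_alcohol_abuse": {"non_oa": (0, 0.0), "case": (16, 4.4), "comparator": (3, 3.6)},
    "insomnia": {"non_oa": (0, 0.0), "case": (14, 3.9), "comparator": (4, 4.8)},
    "charlson_cat_0": {"non_oa": (32, 68.1), "case": (230, 63.9), "comparator": (58, 69.9)},
    "charlson_cat_1": {"non_oa": (9, 19.1), "case": (64, 17.8), "comparator": (14, 16.9)},
    "charlson_cat_2": {"non_oa": (1, 2.1), "case": (26, 7.2), "comparator": (4, 4.8)},
    "charlson_cat_3plus": {"non_oa": (5, 10.6), "case": (40, 11.1), "comparator": (7, 8.4)},
    "any_nsaid": {"non_oa": (7, 14.9), "case": (148, 41.1), "comparator": (22, 26.5)},
    "nsaid_topical": {"non_oa": (0, 0.0), "case": (37, 10.3), "comparator": (7, 8.4)},
    "nsaid_cox2": {"non_oa": (0, 0.0), "case": (37, 10.3), "comparator": (7, 8.4)},
    "nsaid_nonsel": {"non_oa": (7, 14.9), "case": (117, 32.5), "comparator": (17, 20.5)},
    "any_opioid": {"non_oa": (13, 27.7), "case": (178, 49.4), "comparator": (20, 24.1)},
    "opioid_sa": {"non_oa": (7, 14.9), "case": (145, 40.3), "comparator": (15, 18.1)},
    "opioid_la": {"non_oa": (0, 0.0), "case": (4, 1.1), "comparator": (1, 1.2)},
    "opioid_mixed": {"non_oa": (7, 14.9), "case": (66, 18.3), "comparator": (7, 8.4)},
    "oral_corticosteroid": {"non_oa": (0, 0.0), "case": (1, 0.3), "comparator": (0, 0.0)},
    "h2_blocker": {"non_oa": (3, 6.4), "case": (33, 9.2), "comparator": (9, 10.8)},
    "ia_corticosteroid": {"non_oa": (10, 21.3), "case": (288, 80.0), "comparator": (21, 25.3)},
    "ha_injection": {"non_oa": (1, 2.1), "case": (89, 24.7), "comparator": (3, 3.6)},
    "hip_replacement": {"non_oa": (0, 0.0), "case": (80, 22.2), "comparator": (2, 2.4)},
    "knee_replacement": {"non_oa": (1, 2.1), "case": (134, 37.2), "comparator": (4, 4.8)},
    "nerve_block": {"non_oa": (7, 14.9), "case": (208, 57.8), "comparator": (14, 16.9)},
}

# ---------------------------------------------------------------------------
# ML model performance on claims data (case vs comparator, n=443).
# ---------------------------------------------------------------------------

ML_PERFORMANCE: dict[str, dict[str, float]] = {
    "logistic_regression": {
        "ppv": 0.88, "ppv_sd": 0.02, "npv": 0.47, "sensitivity": 0.77,
        "specificity": 0.66, "accuracy": 0.75, "auc": 0.72, "f1": 0.82,
    },
    "cart": {
        "ppv": 0.89, "ppv_sd": 0.03, "npv": 0.48, "sensitivity": 0.78,
        "specificity": 0.67, "accuracy": 0.75, "auc": 0.73, "f1": 0.83,
    },
    "random_forest": {
        "ppv": 0.92, "ppv_sd": 0.02, "npv": 0.62, "sensitivity": 0.86,
        "specificity": 0.75, "accuracy": 0.83, "auc": 0.81, "f1": 0.89,
    },
}

# Composite three-step classifier on the claims subset (step thresholds
# 0.95 / 0.95 / 0.90), printed in the running text.
COMPOSITE_HEADLINE = {
    "sensitivity": 0.95, "specificity": 0.26, "npv": 0.65, "ppv": 0.78,
    "accuracy": 0.77,
}
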