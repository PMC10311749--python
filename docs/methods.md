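# Methods

This note documents the modelling choices behind `oa_phenotyper`: what each
component computes, the parameters that matter, what the synthetic data do
and do not emulate, and the numerical conventions. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Data model and code matching

Patients are longitudinal event records — diagnoses (with care setting),
procedures (with reimbursed cost), drug fills (with a pre-resolved
therapeutic class), and enrollment periods — carried in five delimited
tables plus optional gold labels. Clinical concepts are `CodeSet`s of exact
codes and trailing-wildcard prefixes per coding system; matching strips dots
and upper-cases both sides, so dotted and undotted code dialects are
interchangeable. The hip/knee OA concept (8 exact ICD-9-CM codes plus the
M16/M17 ICD-10-CM families) is taken from the validation publication; every
other concept set (imaging, injections, nerve block, arthroplasty, mobility
aids, therapy, psychiatric comorbidity, cancer exclusion) is curated from
public code lists, flagged `provenance="curated"`, and overridable — the
publication does not print them. Drug identification is at therapeutic-class
level: NDC→class mapping tables are licensing-encumbered, and every rule and
feature that touches medication operates on classes; an optional `ndc`
column passes through opaquely.

Loading never silently drops rows: any malformed row aborts with the file,
line and field named.

## Cohort construction

**Selection.** Adults (≥ 18 years at 2015-01-01, computed from birth year
only, as claims extracts rarely carry full birth dates) with ≥ 1 hip/knee OA
diagnosis during the 2015-01-01..2019-12-31 study window and no excluding
cancer diagnosis (the exclusion set deliberately omits carcinoma in situ and
non-metastatic melanoma).

**Extraction window.** Per patient, the most recent 18 months ending at the
earliest of first qualifying arthroplasty in the window, enrollment end, or
study end. "18 months" means subtracting 18 calendar months and adding one
day (closed interval); a fixed 548-day alternative is available via
`fixed_days`. The terminating arthroplasty date is *inside* the window, so
surgery-based severity/response rules can see it.

**Enriched sampling.** Chart-review samples are drawn disproportionately —
by default 75% from an "enriched" stratum of severity proxies — via exact
stratum quotas (`round(target_n × fraction)`) without replacement; an
infeasible quota is an error, never a silent top-up. The original study's
enrichment criteria are unpublished; `enriched_proxy_flags` provides a
documented proxy (any joint injection, nerve block or arthroplasty, or ≥ 2
opioid classes).

**Comorbidity ascertainment.** A condition counts when coded at ≥ 2
outpatient encounters on distinct dates ≥ 30 days apart, or at ≥ 1 inpatient
encounter, inside the window. The "two encounters" requirement is read as
distinct service dates (the source is ambiguous between distinct claims and
distinct days).

**Charlson index.** Quan's (2005) ICD-9/ICD-10 condition definitions with
the original Charlson weights — the study cites Quan for coding, not for
reweighting. Hierarchies (complicated diabetes over uncomplicated, severe
liver over mild, metastatic over any malignancy) are applied before summing;
scores are binned 0 / 1 / 2 / 3+.

**Sample-size support.** `ppv_ci_width(ppv, n, conf)` returns the width of
the exact Clopper-Pearson interval at `x = round(ppv·n)` successes of `n`.
A direct computation at PPV 0.80 with 480/600 gives a width near 0.066, not
the 8.1% the source text attributes to n = 600; scanning `n` shows a
0.081-wide interval corresponds to roughly 400 positive calls. The function
is implemented faithfully and the discrepancy is left standing — the
published figure appears to assume a smaller positive-call denominator.

## Rule engine

The 40 predefined algorithms are encoded as AND/OR trees over a small,
negation-free predicate vocabulary; monotonicity (adding events never turns
a rule off) is property-tested. Counting conventions, applied uniformly and
mirrored by the brute-force test oracle:

- diagnosis "encounters"/"visits" and procedure administrations count by
  **distinct service date**; drug "prescriptions" count by **fill event**;
- "medical encounter" means any setting; "outpatient visit" means the
  physician-office or other-outpatient settings;
- all day bounds are inclusive: "within *d* days" is a difference ≤ *d*,
  "at least *d* apart" is ≥ *d*; "within *k* days after" requires
  0 ≤ difference ≤ *k*;
- "within 6 months" is 183 days; 1/2/5 years are 365/731/1827 days; "same
  CY" compares calendar-year numbers (the constants are centralized in
  `DAY_CONSTANTS`).

Interpretation calls where the published row text is ambiguous or garbled:

- Step-1 rows 8–11 pair *k* outpatient OA visits with "≥ X-rays … in the
  same CY", with the count truncated in the available text; read as **≥ 1
  X-ray in the same calendar year**.
- Step-1 row 12 ("1 outpatient visit and ≥ 2 diagnoses … within 5 years") is
  encoded as the conjunction of ≥ 1 outpatient visit of any kind and ≥ 2
  outpatient OA diagnoses within 5 years; no negation ("exactly one") is
  intended by the vocabulary.
- Step-2 rows 12–13, "OA-related costs > 30% (50%) mean OA-related costs for
  the cohort", are read as patient cost > **1.30× (1.50×)** the cohort mean
  (multipliers configurable): the published zero-true-positive result for
  row 13 is consistent with a high multiplier, not with 0.3×/0.5× of the
  mean. OA-related cost sums OA-related procedures (injections, hip/knee
  imaging, arthroplasty, nerve block, therapy, mobility aids) plus analgesic
  fills inside the window; the cohort mean is taken over the analysis
  cohort.
- Step-3 row 1 requires both analgesic classes to have a fill **strictly
  before** the procedure date.

The OR combination declares a patient positive when any component rule with
(rounded) PPV ≥ the threshold fires; the three-step composite requires the
combined rule to fire at all three steps (default thresholds
0.95/0.95/0.90). A consequence worth stating: the combined row dominates the
sensitivity of its *selected* components only — a low-PPV component excluded
from the combination may individually be more sensitive.

## Evaluation

TP/FP/TN/FN are tallied against the gold labels per step (step 1: any OA;
step 2: moderate-to-severe; step 3: inadequate response; composite: all
three), over the full labeled cohort. Metrics with zero denominators are an
explicit undefined sentinel (`None`, printed "N/A"), never 0 or 1. Reported
values are rounded **half-up to two decimals** — this convention reproduces
all 275 published metric cells from the published counts — while raw
proportions are retained internally. AUC is the rank-based (Mann-Whitney)
statistic with ties counted ½; F1 is the harmonic mean of PPV and
sensitivity.

## Synthetic cohorts

The generator emulates three archetypes — non-OA (label F/F/F), comparator
(OA, mixed severity/response), case (T/T/T) — with per-concept event
probabilities defaulting to the published claims-subset frequencies
(denominators 47/360/83). Design choices:

- Concepts are sampled **independently** per patient because only marginal
  frequencies are published; an optional lift hook couples chosen pairs for
  stress tests (it does not preserve the lifted concept's marginal).
- Repeated events draw a Poisson count with rate `-ln(1-p)` so the presence
  probability equals the marginal `p` exactly.
- Every patient is enrolled for the whole study window; events are placed
  inside the extraction window, and a generated arthroplasty is placed in
  the window's final 120 days with all other events before it, so the
  surgery terminus does not hide events from the rules.
- Step-1 structure is planted: cases always carry ≥ 2 outpatient OA
  diagnoses 30–90 days apart, comparators ≥ 1 OA diagnosis, non-OA patients
  none. Comparator labels mix moderate-to-severe at 53/83 and inadequate
  response at 3/83 (the claims-subset rates); when both would be true the
  response label is forced false, since all-three-true defines a case.
- Costs are log-normal (σ = 0.5) around per-procedure medians, with a 1.5×
  location shift for cases so cost rules and the daily-cost feature carry
  signal. Ages are normal (means 63.2 / 60.6 OA vs non-OA, SD 10, clipped to
  19–95); the utilization concepts the publication does not tabulate
  (imaging, therapy, mobility aids) use curated rates.

What passing tests on these cohorts show — and what they do not: the rules,
the evaluation harness and the ML pipeline behave correctly on data with
known structure. Because concepts are sampled independently at the published
marginal gaps (e.g., injections at 0.80 vs 0.25), the synthetic
case/comparator contrast is stronger than in real claims, where events
correlate within patients and coding is noisy. ML metrics on synthetic data
are therefore upper bounds in spirit; the published real-cohort values
(e.g., RF accuracy 0.83) are not reproducible without the restricted data
and are not targets of this package.

A fixed hand-built boundary panel (`plant_edge_cases`) exercises every rule
boundary — 30/90/183-day gaps, calendar-year edges, the arthroplasty
terminus, same-day "preceded by" — each with a documented expected outcome.

## ML pipeline

Features (per OA-positive patient): one flag + one count per diagnosis and
procedure concept, one flag + count per drug class, distinct-date visit
counts per care setting, age at the extraction-window start, daily
health-care cost (total reimbursed cost / window days), and the Charlson
score — 73 columns on the default cohort; column order is fixed.

- **SMOTE** (in-package): synthetic minority rows `x + u·(nn − x)`,
  `u ~ U(0,1)`, `nn` among the k = 5 nearest minority neighbours by
  Euclidean distance on z-scored columns; the interpolation itself is done
  in raw space (affine-equivalent). Applied strictly inside training
  partitions; the default target ratio is 1:1. The source's phrase
  "stratified random sampling with replacement … using SMOTE" is read as
  SMOTE interpolation, not a plain bootstrap.
- **RF-RFE**: iterative elimination of the least-important ~20% of surviving
  features (at least one) per refit of a 100-tree forest, down to the
  threshold; importance ties drop the lexicographically-last name for
  determinism. Inside nested CV one elimination *path* is computed per
  training fold and thresholds index into it.
- **Nested CV**: stratified 5 outer × 3 inner folds (the source does not
  state its fold counts; these are standard for n ≈ 500). The inner loop
  grid-searches hyperparameters × RFE thresholds (default {20, 35, 50},
  within the stated 20–50 range) by mean inner-validation AUC; the winner is
  refit on the SMOTE'd outer-training set and scored once on the untouched
  outer test fold. Means and SDs are over outer folds only. Default grids
  (the source's grids are unpublished): logistic C ∈ {0.01, 0.1, 1, 10} on
  z-scored features; tree depth 2–8 with min leaf {5, 10, 20}; forest
  {200, 500} trees × depth {∞, 4, 8}. Trees consume raw features.
- **SHAP**: Monte-Carlo permutation estimation for all model families
  (default 128 draws). Each draw samples one background row and one feature
  permutation and accumulates telescoping marginal contributions, so
  per-sample attributions sum *exactly* to `f(x) − mean(f(background
  draws))`; the dummy and symmetry axioms are property-tested. An exact
  tree-path method would reduce variance for the tree families but is not
  required for the mean-|SHAP| ranking use here.

## Numerical conventions and degenerate inputs

Half-up decimal rounding for all reported metrics; undefined metrics are
sentinels, never imputed. Empty rule selections, zero-length windows,
single-class training labels, SMOTE with minority ≤ k, and RFE thresholds
outside the column range are errors, not silent fallbacks. All randomness
flows through explicit integer seeds (`numpy.random.default_rng`);
regeneration with the same seed is byte-identical on disk.

## Problem sizes used in the checks

The shipped tests and the acceptance script run the full pipeline on the
published archetype mix (490 patients, 443 OA-positive for ML), the
law-of-large-numbers generator check at n = 5000, the rule-engine/brute-force
equivalence on the full cohort plus the boundary panel (≈ 20,000 rule
evaluations), and nested CV for all three families plus a permuted-label
control at n = 443.

## Known limitations

- Curated (non-published) code sets are plausible but not the study's; real
  deployments should override them via the registry.
- Independence of concepts in the generator understates real-world
  correlation; the lift hook is a stress-test device, not a copula.
- The comorbidity ascertainment rule and encounter-counting conventions
  resolve ambiguities the source text leaves open; both are centralized and
  documented above.
- EMR-dialect feature extraction, NDC dictionaries, chart-abstraction
  tooling and bootstrap CIs are out of scope.
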