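"""Frozen numerical and schema choices shared across the pipeline.

Everything here is a deliberate, documented constant: aggregation conventions,
the putative-case flagging rules, leakage-code ranges, and the reference CBC
parameter table (per-group medians and observed ranges) that calibrates the
synthetic cohort generator.
"""

from __future__ import annotations

import math

# --- aggregation conventions -------------------------------------------------
# Percentiles use linear interpolation; variance is the sample variance (n-1),
# defined as 0 for a single measurement; monotonicity ties (last == first)
# resolve to False; bin assignment is strictly-below (a value equal to an edge
# falls in the lower interval).
AGGREGATE_NAMES = (
    "p25",
    "p50",
    "p75",
    "min",
    "max",
    "variance",
    "first_last_absdiff",
    "monotonic_increase",
)
N_BINS = 10
PREVALENCE_THRESHOLD = 0.05

# --- putative-case flagging --------------------------------------------------
# Word-boundary match on the Polish stem for myelofibrosis, plus the ICD-10
# codes used for case ascertainment. A bare root (e.g. "C94") also matches all
# of its subcodes.
CASE_TEXT_PATTERN = r"\b[mM]ielofibroz"
CASE_ICD_CODES = ("C94", "C94.4", "D47", "D47.1", "D47.4")

# --- leakage exclusion -------------------------------------------------------
# ICD-10 roots highly indicative of hematologic malignancy are removed from the
# feature set so that the model cannot read the label off a diagnosis code.
LEAKAGE_ROOTS = frozenset(
    {"D45", "D46", "D47"}
    | {f"D{i}" for i in range(70, 78)}
    | {f"C{i}" for i in range(81, 97)}
)

# --- decision thresholds -----------------------------------------------------
DEFAULT_DECISION_THRESHOLD = 0.5
FDR_ALPHA = 0.05
VOLCANO_LOG2_OR_THRESHOLD = math.log2(1.5)  # 0.585: OR 1.5 / 0.67 effect band

# --- study-scale constants ---------------------------------------------------
# Cohort sizes of the reference screening study: 67 confirmed cases against
# 110,000 controls drawn 11,000 from each of 10 centers.
STUDY_N_POSITIVE = 67
STUDY_N_UNLABELED = 110_000
STUDY_N_CENTERS = 10

# Review workload convention: minutes of physician time to triage one flagged
# patient, matching a standard outpatient visit.
REVIEW_MINUTES_PER_PATIENT = 15.0

# --- CBC reference table -----------------------------------------------------
# name, unit, control median, (control min, control max), case median,
# (case min, case max), optional (subject to missingness).
# Medians/ranges are per-patient medians summarized within each group.
CBC_REFERENCE = (
    ("RBC_blood_t_l", "T/l", 4.41, (2.88, 5.51), 3.67, (2.29, 6.55), False),
    ("HGB_blood_g_dl", "g/dl", 13.30, (8.60, 16.60), 10.20, (7.38, 15.12), False),
    ("HCT_blood_percentage", "%", 39.50, (26.20, 48.70), 33.60, (23.05, 47.88), True),
    ("MCV_blood_fl", "fl", 89.50, (77.10, 102.00), 91.55, (74.00, 116.14), True),
    ("MCH_blood_pg", "pg", 30.20, (24.40, 34.50), 29.02, (22.08, 38.11), True),
    ("MCHC_blood_g_dl", "g/dl", 33.60, (30.80, 35.90), 31.65, (28.50, 34.00), True),
    ("RDW_CV_blood_percentage", "%", 13.60, (11.90, 19.90), 19.45, (13.38, 26.37), True),
    ("WBC_blood_g_l", "G/l", 7.67, (3.55, 19.33), 8.00, (2.75, 72.95), False),
    ("NEUT_blood_g_l", "G/l", 4.68, (1.58, 15.48), 5.53, (1.14, 65.16), False),
    ("LYMPH_blood_g_l", "G/l", 1.67, (0.50, 3.82), 1.46, (0.70, 5.03), False),
    ("MONO_blood_g_l", "G/l", 0.60, (0.22, 1.55), 0.72, (0.22, 2.88), False),
    ("BASO_blood_g_l", "G/l", 0.03, (0.00, 0.10), 0.08, (0.00, 0.76), False),
    ("EO_blood_g_l", "G/l", 0.11, (0.00, 0.54), 0.12, (0.00, 2.75), False),
    ("NEUT_blood_percentage", "%", 64.30, (35.01, 89.00), 64.90, (41.18, 86.91), False),
    ("LYMPH_blood_percentage", "%", 23.60, (4.90, 49.15), 16.75, (3.26, 41.29), False),
    ("MONO_blood_percentage", "%", 8.10, (3.00, 15.40), 7.60, (2.40, 19.14), False),
    ("EO_blood_percentage", "%", 1.50, (0.00, 6.90), 1.80, (0.06, 5.28), False),
    ("BASO_blood_percentage", "%", 0.40, (0.00, 1.30), 1.00, (0.00, 2.49), False),
    ("PLT_blood_g_l", "G/l", 233.00, (73.50, 468.00), 416.00, (33.00, 1418.00), False),
    ("PDW_blood_fl", "fl", 12.30, (9.10, 18.40), 13.30, (9.68, 25.40), True),
    ("MPV_blood_fl", "fl", 10.25, (7.40, 12.65), 11.05, (8.95, 13.04), True),
    ("PLCR_blood_percentage", "%", 28.80, (15.70, 46.60), 33.60, (19.45, 48.71), True),
)

CBC_PARAMETER_NAMES = tuple(row[0] for row in CBC_REFERENCE)
OPTIONAL_CBC_PARAMETERS = frozenset(row[0] for row in CBC_REFERENCE if row[6])

# Default ICD-10 code emission model for the synthetic cohort: (code,
# control-group per-window emission probability, case odds multiplier). D64.8
# (other anemias) and Z03 (observation for suspected disease) carry the
# characteristic ~8-fold odds increase in cases; the rest are common
# comorbidity codes with neutral odds that exercise the prevalence filter.
DEFAULT_CODE_SPECS = (
    ("D64.8", 0.15, 8.0),
    ("Z03", 0.15, 8.0),
    ("I10", 0.30, 1.0),
    ("E11", 0.25, 1.0),
    ("J06", 0.20, 1.0),
    ("M54", 0.25, 1.0),
    ("K21", 0.20, 1.0),
)

# Default ICD-10 -> higher-level phenotype mapping shipped with the simulator
# (5 phenotype groups; two codes deliberately unmapped).
DEFAULT_PHENOTYPE_MAPPING = (
    ("D64.8", "anemias"),
    ("Z03", "diagnostic_observation"),
    ("I10", "hypertension"),
    ("E11", "type2_diabetes"),
    ("J06", "upper_respiratory_infection"),
)
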