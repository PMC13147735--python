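"""Reference values of the 908-patient ASMD development cohort.

The suspicion index was developed on a retrospective chart review of
48 confirmed ASMD cases, 52 controls (phenotypically similar lysosomal
disease: NPD-C, Gaucher type I) and 808 non-cases. The per-group symptom
counts and the demographic summaries below are the published cohort margins;
they parameterise the default synthetic-cohort generator and provide the
contingency tables for the exact-test screening checks.
"""

from __future__ import annotations

GROUPS = ("case", "control", "non_case")

GROUP_SIZES = {"case": 48, "control": 52, "non_case": 808}

# symptom_id -> (n present among cases, among controls, among non-cases)
SYMPTOM_COUNTS: dict[str, tuple[int, int, int]] = {
    "learning_disability": (19, 13, 0),
    "muscular_hypotonia": (10, 15, 0),
    "peripheral_neuropathy": (10, 3, 1),
    "loss_of_deep_tendon_reflexes": (9, 5, 0),
    "macular_halo": (9, 0, 0),
    "loss_of_skills": (8, 17, 0),
    "cherry_red_spot": (8, 0, 0),
    "ataxia": (7, 26, 0),
    "psychiatric_symptoms": (7, 10, 0),
    "dysphagia": (5, 26, 1),
    "splenomegaly": (48, 37, 3),
    "hepatomegaly": (44, 29, 3),
    "interstitial_lung_disease": (32, 3, 0),
    "thrombocytopenia_bleeding": (27, 2, 4),
    "mixed_dyslipidemia_low_hdl": (24, 6, 806),
    "recurrent_respiratory_infections": (18, 0, 0),
    "abnormal_liver_function_test": (15, 0, 0),
    "diarrhea": (15, 5, 0),
    "cholestatic_jaundice": (14, 2, 0),
    "portal_hypertension": (12, 0, 0),
    "aspiration_pneumonia": (11, 1, 0),
    "liver_fibrosis": (11, 1, 1),
    "feeding_difficulties": (6, 24, 0),
    "cardiac_valve_disease": (3, 2, 0),
    "growth_retardation": (24, 9, 0),
    "reduced_bone_density": (13, 2, 0),
    "bone_and_joint_pain": (10, 3, 4),
    "family_history_asmd": (10, 0, 0),
}

# printed screening columns of the development cohort: symptom -> (p category, odds ratio)
# p category is either the string "<=0.001" or the printed two-decimal value.
# Odds ratios are conditional-MLE values oriented comparator-odds / case-odds.
PUBLISHED_SCREENING: dict[str, tuple[str, float]] = {
    "learning_disability": ("0.14", 0.51),
    "muscular_hypotonia": ("0.49", 1.50),
    "peripheral_neuropathy": ("0.04", 0.24),
    "loss_of_deep_tendon_reflexes": ("0.25", 0.46),
    "macular_halo": ("<=0.001", 0.01),
    "loss_of_skills": ("0.07", 2.41),
    "cherry_red_spot": ("0.01", 0.01),
    "ataxia": ("<=0.001", 5.75),
    "psychiatric_symptoms": ("0.60", 1.39),
    "dysphagia": ("<=0.001", 8.41),
    "splenomegaly": ("<=0.001", 0.01),
    "hepatomegaly": ("<=0.001", 0.12),
    "interstitial_lung_disease": ("0.03", 0.01),  # inconsistent with its own counts
    "thrombocytopenia_bleeding": ("<=0.001", 0.03),
    "mixed_dyslipidemia_low_hdl": ("<=0.001", 0.13),
    "recurrent_respiratory_infections": ("<=0.001", 0.01),
    "abnormal_liver_function_test": ("<=0.001", 0.01),
    "diarrhea": ("0.01", 0.24),
    "cholestatic_jaundice": ("<=0.001", 0.10),
    "portal_hypertension": ("<=0.001", 0.01),
    "aspiration_pneumonia": ("<=0.001", 0.07),
    "liver_fibrosis": ("<=0.001", 0.07),
    "feeding_difficulties": ("<=0.001", 5.89),
    "cardiac_valve_disease": ("0.67", 0.60),
    "growth_retardation": ("<=0.001", 0.21),
    "reduced_bone_density": ("<=0.001", 0.11),
    "bone_and_joint_pain": ("0.04", 0.24),
}

# The interstitial lung disease row prints p=0.03 / OR=0.01, which is
# irreconcilable with its own counts (32/48 vs 3/52 gives p << 0.001,
# conditional-MLE OR 0.032) -- a suspected typesetting error, excluded from
# reproduction checks.
INCONSISTENT_SCREENING_ROWS = ("interstitial_lung_disease",)

# The non-boundary rows whose printed odds ratios serve as exact
# reproduction checks (no zero cell in the cases-vs-controls table).
NONBOUNDARY_OR_ROWS = (
    "ataxia",
    "dysphagia",
    "feeding_difficulties",
    "loss_of_skills",
    "learning_disability",
    "muscular_hypotonia",
    "psychiatric_symptoms",
    "peripheral_neuropathy",
    "growth_retardation",
    "hepatomegaly",
    "thrombocytopenia_bleeding",
)

# group -> (onset mean, onset SD, current-age mean, current-age SD), years
AGE_PARAMS = {
    "case": (8.6, 12.7, 20.4, 15.9),
    "control": (11.6, 10.9, 22.9, 14.8),
    "non_case": (34.9, 19.3, 14.0, 5.4),
}

# group -> number of male patients
MALE_COUNTS = {"case": 26, "control": 24, "non_case": 520}

# group -> number with positive ASMD family history
FAMILY_HISTORY_COUNTS = {"case": 10, "control": 0, "non_case": 0}

# ASMD subtype composition of the case group (30 type B, 16 type A/B, 2 type A)
CASE_SUBTYPE_COUNTS = {"B": 30, "AB": 16, "A": 2}

# Final published tool variables: prerequisite + three score inputs
SIT_PREREQUISITE = "hepatosplenomegaly"
SIT_INPUTS = (
    "thrombocytopenia_bleeding",
    "interstitial_lung_disease",
    "mixed_dyslipidemia_low_hdl",
)


def prevalence(symptom_id: str, group: str) -> float:
    """Observed prevalence of a symptom in a development-cohort group."""
    gi = GROUPS.index(group)
    return SYMPTOM_COUNTS[symptom_id][gi] / GROUP_SIZES[group]
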