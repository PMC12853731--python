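"""Published reference values from a national-registry TJA audit.

These are the printed summary statistics of a published interpretability
audit of 30-day complication models on a proprietary national surgical
registry (ACS-NSQIP, 2019-2023 total-joint-arthroplasty extract).  The raw
data are not publicly available, so the package uses these printed values
two ways: as the marginals the synthetic generator emulates (see
:mod:`riskaudit.specs`) and as inputs to self-contained arithmetic checks —
cohort-exclusion accounting, the directional-agreement proportion, the
influence decomposition and the AUC deltas — that the audit code must
reproduce exactly from the printed tables.
"""

from __future__ import annotations

# ---------------------------------------------------------------------------
# Cohort accounting (cases)
# ---------------------------------------------------------------------------

INITIAL_COHORT = 557_307
COHORT_COMPONENTS = {
    "primary_tha": 210_484,
    "primary_tka": 307_342,
    "hip_revisions": 15_531,
    "knee_revisions": 15_750,
    "unicompartmental_tka": 8_200,
}
REVISIONS_EXCLUDED = 31_281  # hip + knee revisions
UNICOMPARTMENTAL_EXCLUDED = 8_200
FINAL_COHORT = 517_826


def final_cohort_size() -> int:
    """Initial cohort minus the printed exclusions."""
    return INITIAL_COHORT - REVISIONS_EXCLUDED - UNICOMPARTMENTAL_EXCLUDED


# ---------------------------------------------------------------------------
# Directional concordance table (per predictor):
# (feature, PDP trend sign, Spearman rho of values vs attributions, agrees)
# ---------------------------------------------------------------------------

CONCORDANCE_TABLE = [
    ("asa_class", +1, +0.879, True),
    ("preop_hematocrit", -1, -0.862, True),
    ("age", +1, +0.905, True),
    ("operative_time", +1, +0.838, True),
    ("procedure_tha", +1, +0.852, True),
    ("preop_albumin", -1, -0.874, True),
    ("hypertension", +1, +0.850, True),
    ("preop_creatinine", +1, +0.470, True),
    ("sex_female", -1, -0.845, True),
    ("weight_loss", -1, -0.827, True),
    ("elective", -1, +0.645, False),
    ("bmi", +1, +0.472, True),
    ("smoker", +1, +0.468, True),
    ("diabetes", -1, -0.405, True),
    ("steroid_use", +1, +0.327, True),
    ("copd", +1, +0.304, True),
    ("chf", +1, +0.257, True),
    ("bleeding_disorder", +1, +0.256, True),
    ("functional_status_dependent", -1, +0.229, False),
    ("hemoglobin_a1c", -1, -0.048, True),
]

REPORTED_UNWEIGHTED_AGREEMENT = 90.0  # percent (18 of 20)
REPORTED_WEIGHTED_AGREEMENT = 97.8  # percent

# ---------------------------------------------------------------------------
# Influence decomposition: the seven features above the 5% relative-influence
# threshold (percent of total model influence), with the remaining 30.5%
# spread over 37 below-threshold features.
# ---------------------------------------------------------------------------

SELECTED_INFLUENCES_PCT = {
    "age_x_asa_class": 19.10,
    "operative_time_x_asa_class": 10.10,
    "operative_time_x_age": 7.90,
    "preop_hematocrit_x_asa_class": 6.45,
    "preop_hematocrit_x_diabetes": 6.37,
    "operative_time": 7.37,
    "preop_hematocrit": 12.16,
}
N_FEATURES_TOTAL = 44
N_BELOW_THRESHOLD = 37

REPORTED_SHARE_INTERACTION_TOTAL = 49.9
REPORTED_SHARE_MAIN_TOTAL = 19.5
REPORTED_SHARE_SELECTED_TOTAL = 69.5
REPORTED_SHARE_INTERACTION_WITHIN = 71.9
REPORTED_SHARE_MAIN_WITHIN = 28.1

# ---------------------------------------------------------------------------
# Model discrimination (registry-dependent; used only for delta arithmetic)
# ---------------------------------------------------------------------------

AUC_FULL_20_FEATURES = 0.6777
AUC_REDUCED_16_FEATURES = 0.6484
REPORTED_DELTA_AUC = 0.0293

N_PREDICTORS = 20
FAMILY_ALPHA = 0.05
REPORTED_BONFERRONI_ALPHA = 0.0025
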