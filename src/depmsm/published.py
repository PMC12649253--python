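"""Reference coefficient estimates from the published CHARLS multi-state
analysis of depressive-symptom transitions.

These printed estimates serve two purposes: they are the default "true"
coefficients of the synthetic-cohort generator (so demo runs resemble the
published cohort) and they are the inputs for arithmetic cross-checks of the
effect-reporting layer (TRR = exp(Est), Wald confidence limits).

The underlying survey microdata are restricted; nothing here re-derives the
estimates, they are transcribed published numbers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: model-matrix term order: 13 main effects then 5 interaction products.
MAIN_TERMS = (
    "residence",
    "sex",
    "age",
    "education",
    "marital_status",
    "retired",
    "income",
    "n_conditions",
    "pain",
    "badl_disability",
    "social_engagement",
    "child_interaction",
    "child_support",
)
INTERACTION_PAIRS = (
    ("education", "income"),
    ("n_conditions", "income"),
    ("n_conditions", "sex"),
    ("sex", "age"),
    ("age", "education"),
)
INTERACTION_TERMS = tuple(f"{a}_x_{b}" for a, b in INTERACTION_PAIRS)
MODEL_TERMS = MAIN_TERMS + INTERACTION_TERMS

#: coefficient blocks: one per transition group; "24+34" is the shared
#: remission block (episode/persistence -> remission).
COEFFICIENT_GROUPS = ("12", "23", "24+34", "45")

# (group, term, est, se, trr, cl_low, cl_high, sig); zero-coefficient rows
# carry None in the inference columns, as printed.
REPORTED_EFFECTS: list[tuple] = [
    # (1) no symptom -> new symptom episode
    ("12", "residence", -0.1660, 0.0812, 0.8471, 0.7224, 0.9932, "*"),
    ("12", "sex", 0.4026, 0.0568, 1.4957, 1.3382, 1.6717, "**"),
    ("12", "age", 0.0, None, None, None, None, ""),
    ("12", "education", 0.0, None, None, None, None, ""),
    ("12", "marital_status", -0.0500, 0.0683, 0.9512, 0.8321, 1.0874, ""),
    ("12", "retired", -0.2354, 0.1050, 0.7903, 0.6432, 0.9709, "*"),
    ("12", "income", -0.6536, 0.2866, 0.5201, 0.2966, 0.9122, "*"),
    ("12", "n_conditions", 0.0, None, None, None, None, ""),
    ("12", "pain", 0.3875, 0.0606, 1.4733, 1.3083, 1.6590, "**"),
    ("12", "badl_disability", 0.4671, 0.1537, 1.5954, 1.1805, 2.1561, "*"),
    ("12", "social_engagement", -0.1310, 0.0543, 0.8772, 0.7886, 0.9757, "*"),
    ("12", "child_interaction", 0.0, None, None, None, None, ""),
    ("12", "child_support", 0.0, None, None, None, None, ""),
    ("12", "education_x_income", -0.5862, 0.1144, 0.5564, 0.4446, 0.6963, "**"),
    ("12", "n_conditions_x_income", 1.4512, 0.3113, 4.2681, 2.3188, 7.8560, "**"),
    ("12", "n_conditions_x_sex", 0.0, None, None, None, None, ""),
    ("12", "sex_x_age", 0.0, None, None, None, None, ""),
    ("12", "age_x_education", 0.0, None, None, None, None, ""),
    # (2) new symptom episode -> symptom persistence
    ("23", "residence", -0.0723, 0.1490, 0.9302, 0.6946, 1.2457, ""),
    ("23", "sex", 0.0, None, None, None, None, ""),
    ("23", "age", -0.4992, 0.3999, 0.6070, 0.2772, 1.3292, ""),
    ("23", "education", 0.0, None, None, None, None, ""),
    ("23", "marital_status", -0.0514, 0.1238, 0.9499, 0.7453, 1.2106, ""),
    ("23", "retired", 0.0, None, None, None, None, ""),
    ("23", "income", 0.6114, 0.5605, 1.8430, 0.6143, 5.5291, ""),
    ("23", "n_conditions", 0.2197, 0.7518, 1.2457, 0.2854, 5.4364, ""),
    ("23", "pain", 0.0, None, None, None, None, ""),
    ("23", "badl_disability", 0.0, None, None, None, None, ""),
    ("23", "social_engagement", 0.0, None, None, None, None, ""),
    ("23", "child_interaction", 0.0, None, None, None, None, ""),
    ("23", "child_support", -0.0811, 0.1157, 0.9221, 0.7350, 1.1569, ""),
    ("23", "education_x_income", -0.3622, 0.2571, 0.6962, 0.4206, 1.1523, ""),
    ("23", "n_conditions_x_income", 0.0, None, None, None, None, ""),
    ("23", "n_conditions_x_sex", -0.0814, 0.5722, 0.9218, 0.3003, 2.8294, ""),
    ("23", "sex_x_age", 0.5098, 0.4215, 1.6649, 0.7288, 3.8037, ""),
    ("23", "age_x_education", 0.0, None, None, None, None, ""),
    # (3) new symptom episode / symptom persistence -> symptom remission
    ("24+34", "residence", 0.0, None, None, None, None, ""),
    ("24+34", "sex", 0.0, None, None, None, None, ""),
    ("24+34", "age", 0.4673, 0.2986, 1.5956, 0.8887, 2.8648, ""),
    ("24+34", "education", 0.0, None, None, None, None, ""),
    ("24+34", "marital_status", 0.0821, 0.1038, 1.0855, 0.8857, 1.3303, ""),
    ("24+34", "retired", 0.0, None, None, None, None, ""),
    ("24+34", "income", -0.1472, 0.7786, 0.8631, 0.1876, 3.9703, ""),
    ("24+34", "n_conditions", -0.1212, 1.0128, 0.8859, 0.1217, 6.4490, ""),
    ("24+34", "pain", 0.0, None, None, None, None, ""),
    ("24+34", "badl_disability", 0.0, None, None, None, None, ""),
    ("24+34", "social_engagement", 0.0415, 0.0811, 1.0424, 0.8892, 1.2220, ""),
    ("24+34", "child_interaction", 0.0, None, None, None, None, ""),
    ("24+34", "child_support", 0.0, None, None, None, None, ""),
    ("24+34", "education_x_income", 0.1478, 0.5211, 1.1593, 0.4175, 3.2194, ""),
    ("24+34", "n_conditions_x_income", 0.0, None, None, None, None, ""),
    ("24+34", "n_conditions_x_sex", -0.2723, 0.5577, 0.7616, 0.2553, 2.2720, ""),
    ("24+34", "sex_x_age", -0.3908, 0.3525, 0.6765, 0.3390, 1.3501, ""),
    ("24+34", "age_x_education", 0.0, None, None, None, None, ""),
    # (4) symptom remission -> symptom relapse
    ("45", "residence", -0.3314, 0.3035, 0.7179, 0.3961, 1.3014, ""),
    ("45", "sex", 0.0, None, None, None, None, ""),
    ("45", "age", -1.0178, 0.6924, 0.3614, 0.0930, 1.4039, ""),
    ("45", "education", 0.0, None, None, None, None, ""),
    ("45", "marital_status", 0.0, None, None, None, None, ""),
    ("45", "retired", -0.4200, 0.4482, 0.6570, 0.2729, 1.5817, ""),
    ("45", "income", 0.0, None, None, None, None, ""),
    ("45", "n_conditions", 0.0, None, None, None, None, ""),
    ("45", "pain", 0.0, None, None, None, None, ""),
    ("45", "badl_disability", -0.2841, 0.5022, 0.7527, 0.2813, 2.0144, ""),
    ("45", "social_engagement", -0.0987, 0.1900, 0.9061, 0.6244, 1.3148, ""),
    ("45", "child_interaction", 0.0, None, None, None, None, ""),
    ("45", "child_support", 0.0, None, None, None, None, ""),
    ("45", "education_x_income", 0.0, None, None, None, None, ""),
    ("45", "n_conditions_x_income", 0.0, None, None, None, None, ""),
    ("45", "n_conditions_x_sex", 0.0, None, None, None, None, ""),
    ("45", "sex_x_age", 1.5215, 0.6106, 4.5790, 1.3835, 15.1549, "*"),
    ("45", "age_x_education", 0.0, None, None, None, None, ""),
]

#: published baseline cohort characteristics: binary proportions and
#: continuous mean/sd on the raw scale.
COVARIATE_MARGINALS: dict[str, dict] = {
    "residence": {"kind": "binary", "proportion": 0.2187},
    "sex": {"kind": "binary", "proportion": 0.4662},
    "age": {"kind": "continuous", "mean": 57.88, "sd": 8.50, "bounds": (18.0, 100.0)},
    "education": {"kind": "binary", "proportion": 0.6417},
    "marital_status": {"kind": "binary", "proportion": 0.8116},
    "retired": {"kind": "binary", "proportion": 0.1341},
    "income": {"kind": "continuous", "mean": 10783.51, "sd": 11056.88, "bounds": (0.0, float("inf"))},
    "n_conditions": {"kind": "continuous", "mean": 1.1, "sd": 1.17, "bounds": (0.0, 8.0)},
    "pain": {"kind": "binary", "proportion": 0.2356},
    "badl_disability": {"kind": "binary", "proportion": 0.0205},
    "social_engagement": {"kind": "binary", "proportion": 0.5131},
    "child_interaction": {"kind": "binary", "proportion": 0.6513},
    "child_support": {"kind": "binary", "proportion": 0.3124},
}


def reported_effect_frame() -> pd.DataFrame:
    """The published effect table as a tidy DataFrame."""
    return pd.DataFrame(
        REPORTED_EFFECTS,
        columns=["group", "term", "est", "se", "trr", "cl_low", "cl_high", "sig"],
    )


def default_true_betas() -> dict[str, np.ndarray]:
    """Published estimates arranged as per-group coefficient vectors over
    MODEL_TERMS — the generator's default effects."""
    frame = reported_effect_frame().set_index(["group", "term"])
    return {
        group: np.array([frame.loc[(group, term), "est"] for term in MODEL_TERMS])
        for group in COEFFICIENT_GROUPS
    }
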