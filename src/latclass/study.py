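"""Reference-study constants: the printed summary tables of a 2016
cross-sectional latrine-use survey in rural Esmeraldas, Ecuador (251
individuals aged >=13 in 98 households across 20 communities).

The raw individual-level data were never deposited; what survives are the
published marginal tables. This module records those numbers verbatim so the
synthetic-data generator (:mod:`latclass.simulate`) can rebuild a generative
model with the study's structure. Printed rows occasionally sum to 0.99 or
1.01 from rounding; consumers renormalize at use.

Category convention everywhere: ``agree=0, disagree=1, dont_know=2``.
Class convention: class 0 = "consistent latrine use" (the larger class),
class 1 = "inconsistent latrine use".
"""

from __future__ import annotations

N_INDIVIDUALS = 251
N_HOUSEHOLDS = 98

#: Marginal class weights of the final 2-class measurement model.
CLASS_WEIGHTS = (0.78, 0.22)

#: Printed relative entropy of the final 5-indicator, 2-class model.
FINAL_MODEL_ENTROPY = 0.86

CATEGORIES = ("agree", "disagree", "dont_know")

#: (indicator id, survey statement, (P agree, P disagree, P don't know)).
INDICATOR_TABLE = [
    ("anxious",
     "When I use the latrine, it causes me to feel anxious.",
     (0.19, 0.82, 0.00)),
    ("daily_use",
     "I use the latrine every day.",
     (0.91, 0.09, 0.00)),
    ("rain_no_use",
     "I do not use the latrine when it is raining because I do not want to get wet.",
     (0.81, 0.19, 0.00)),
    ("men_dry",
     "During the dry season, I think that most of the men in my village regularly use a latrine.",
     (0.68, 0.14, 0.18)),
    ("neighbors_rainy",
     "During the rainy season, I think all of my neighbors regularly use a latrine.",
     (0.80, 0.07, 0.14)),
    ("children_rainy",
     "During the rainy season, I think that most of the children in my village regularly use a latrine.",
     (0.87, 0.08, 0.04)),
    ("too_many_people",
     "There are too many people in this household for one latrine.",
     (0.43, 0.56, 0.01)),
    ("neighbors_latrine",
     "If my household did not have its own latrine, I would use my neighbor's latrine.",
     (0.86, 0.14, 0.00)),
    ("cabin_small",
     "The cabin of the latrine is too small for me to use.",
     (0.26, 0.73, 0.01)),
    ("pleased_looks",
     "I am pleased with how the latrine looks.",
     (0.64, 0.35, 0.01)),
    ("basin_strong",
     "The latrine's basin is strong enough to hold my weight.",
     (0.92, 0.06, 0.01)),
    ("clean_enough",
     "The latrine is clean enough to use.",
     (0.87, 0.10, 0.03)),
    ("convenient_outside",
     "It is more convenient to defecate outside than to return home to use the latrine.",
     (0.44, 0.55, 0.00)),
    ("morning_routine",
     "My morning routine is not suited for using the latrine to defecate.",
     (0.33, 0.66, 0.01)),
    ("night_convenient",
     "It is more convenient to use the latrine at night than to defecate in a container within my household.",
     (0.85, 0.15, 0.01)),
    ("night_danger",
     "It is dangerous to use the latrine at night.",
     (0.36, 0.64, 0.00)),
]

INDICATOR_IDS = [row[0] for row in INDICATOR_TABLE]
INDICATOR_MARGINALS = {row[0]: row[2] for row in INDICATOR_TABLE}

#: The five indicators retained by the published CI-overlap pruning step.
FINAL_INDICATORS = [
    "men_dry",
    "neighbors_rainy",
    "children_rainy",
    "too_many_people",
    "neighbors_latrine",
]

#: Printed class-conditional item probabilities of the final model:
#: indicator id -> {class index: (category, probability, SE)}.  Only the
#: modal response per class was printed; the rest of each row is
#: reconstructed from the mixture constraints (see simulate.reconstruct_item_probs).
FINAL_MODEL_CONDITIONALS = {
    "men_dry": {0: ("agree", 0.85, 0.03), 1: ("dont_know", 0.53, 0.11)},
    "neighbors_rainy": {0: ("agree", 1.00, 0.00), 1: ("dont_know", 0.57, 0.11)},
    "children_rainy": {0: ("agree", 0.96, 0.02), 1: ("agree", 0.60, 0.08)},
    "too_many_people": {0: ("disagree", 0.52, 0.03), 1: ("disagree", 0.70, 0.07)},
    "neighbors_latrine": {0: ("agree", 0.90, 0.02), 1: ("agree", 0.71, 0.07)},
}

#: Covariate marginal distributions of the study sample (proportions as
#: printed; "missing" is a substantive row in the published table).
COVARIATE_MARGINALS = {
    "sex": {"female": 0.65, "male": 0.35},
    "ethnicity": {"afro_ecuadorian": 0.63, "mestizo_other": 0.13, "chachi": 0.24},
    "education": {
        "less_than_primary": 0.25,
        "primary": 0.20,
        "less_than_secondary": 0.36,
        "secondary": 0.17,
        "missing": 0.02,
    },
    "payment_type": {
        "cash": 0.47,
        "cash_and_kind": 0.06,
        "not_paid": 0.16,
        "not_employed": 0.30,
    },
    "cement_walls": {"yes": 0.45, "no": 0.51, "missing": 0.03},
    "asset_deprived": {"yes": 0.61, "no": 0.39, "missing": 0.004},
    "sanitation": {
        "basic": 0.53,
        "shared": 0.33,
        "unimproved": 0.05,
        "none": 0.09,
        "missing": 0.01,
    },
}

#: Age summary: median 23 y, SD 14 y, eligibility floor 13 y.
AGE_MEDIAN = 23.0
AGE_SD = 14.0
AGE_MIN = 13.0

#: Mean household size implied by the study (251 individuals / 98 households).
MEAN_HOUSEHOLD_SIZE = N_INDIVIDUALS / N_HOUSEHOLDS
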