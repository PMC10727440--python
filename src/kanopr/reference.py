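"""Published summary data of the reference COPD cohort (N = 237).

The package is calibrated against a cross-sectional survey of 237 COPD
patients from eight health-care facilities in Hangzhou and Quzhou (Zhejiang,
China) who rated 18 pulmonary-rehabilitation services on the paired Kano
scale.  The study released only summary tables, not row-level data; this
module holds those printed summaries verbatim:

* per-attribute Kano category tallies with the published final categories,
* the fitted linear model of participation intention (1-5) on its six
  retained predictors,
* cohort covariate margins and subgroup sizes,
* the awareness-subgroup satisfaction-coefficient patterns used to emulate
  subgroup demand shifts.

These serve as worked-example inputs and as calibration targets for
:mod:`kanopr.simulate`.
"""

from __future__ import annotations

from types import MappingProxyType

from .kano import CategoryCounts, KanoCategory

# Per-attribute tallies (A, O, M, I, R, Q); every row sums to 237.
_TALLY_ROWS: dict[int, tuple[int, int, int, int, int, int]] = {
    1: (6, 56, 1, 173, 1, 0),
    2: (31, 143, 2, 60, 1, 0),
    3: (7, 85, 1, 143, 1, 0),
    4: (34, 97, 5, 101, 0, 0),
    5: (35, 97, 4, 101, 0, 0),
    6: (35, 97, 5, 100, 0, 0),
    7: (4, 204, 6, 23, 0, 0),
    8: (5, 204, 6, 22, 0, 0),
    9: (21, 161, 7, 47, 1, 0),
    10: (23, 162, 7, 43, 1, 1),
    11: (4, 170, 39, 24, 0, 0),
    12: (2, 171, 40, 24, 0, 0),
    13: (10, 183, 18, 26, 0, 0),
    14: (21, 88, 13, 115, 0, 0),
    15: (21, 88, 13, 115, 0, 0),
    16: (13, 126, 14, 84, 0, 0),
    17: (15, 38, 4, 179, 1, 0),
    18: (15, 38, 3, 180, 1, 0),
}

#: Published category tallies, ``attribute id -> CategoryCounts``.
REFERENCE_TALLIES: MappingProxyType[int, CategoryCounts] = MappingProxyType(
    {aid: CategoryCounts(*row) for aid, row in _TALLY_ROWS.items()}
)

#: Published final category per attribute (9 one-dimensional, 9 indifferent).
REFERENCE_FINAL_CATEGORIES: MappingProxyType[int, KanoCategory] = MappingProxyType(
    {
        aid: KanoCategory("O" if aid in {2, 7, 8, 9, 10, 11, 12, 13, 16} else "I")
        for aid in _TALLY_ROWS
    }
)

#: Cohort size of the reference study.
REFERENCE_N: int = 237

#: Published multiple-linear-regression model of intention (1-5 scale):
#: intercept plus coefficient per retained predictor.  Binary predictors
#: (awareness, no-drinking) are 0/1; perceived-influence items are 1-5 scores.
INTENTION_MODEL = MappingProxyType(
    {
        "const": 2.13,
        "awareness": 0.43,
        "no_drinking": 0.14,
        "influence_staff_skills": 0.44,
        "influence_knowledge_promotion": -0.17,
        "influence_transportation": -0.10,
        "influence_family_support": 0.17,
    }
)

#: Published standard errors of the intention model (same key order).
INTENTION_MODEL_SE = MappingProxyType(
    {
        "const": 0.76,
        "awareness": 0.10,
        "no_drinking": 0.04,
        "influence_staff_skills": 0.09,
        "influence_knowledge_promotion": 0.04,
        "influence_transportation": 0.04,
        "influence_family_support": 0.05,
    }
)

#: Covariate margins of the reference cohort (counts out of 237).
COHORT_MARGINS = MappingProxyType(
    {
        "region": MappingProxyType({"Hangzhou": 156, "Quzhou": 81}),
        "gender": MappingProxyType({"male": 186, "female": 51}),
        "education": MappingProxyType(
            {
                "primary-or-below": 92,
                "junior-secondary": 94,
                "senior-secondary-or-above": 51,
            }
        ),
        "income": MappingProxyType({"<=3999": 48, "4000-6999": 122, ">=7000": 67}),
        "copd_stage": MappingProxyType({"stable": 142, "acute": 95}),
        "awareness": MappingProxyType({"yes": 149, "no": 88}),
        "mmrc_0_1": 43,
        "mmrc_2_4": 194,
        "age_lt_75": 104,
        "age_ge_75": 133,
        "willingness": 178,  # intention level 4-5
        "unwillingness": 59,  # intention level 1-3
    }
)

#: Awareness-subgroup coefficient patterns: the six attributes whose final
#: category flips between aware (one-dimensional) and unaware (indifferent)
#: respondents, with the published per-group (category, SI, DSI) triples.
AWARENESS_SUBGROUP_PATTERNS = MappingProxyType(
    {
        2: {"yes": ("O", 0.87, -0.74), "no": ("I", 0.51, -0.40)},
        3: {"yes": ("O", 0.54, -0.50), "no": ("I", 0.13, -0.13)},
        4: {"yes": ("O", 0.66, -0.54), "no": ("I", 0.36, -0.25)},
        5: {"yes": ("O", 0.67, -0.54), "no": ("I", 0.36, -0.24)},
        6: {"yes": ("O", 0.67, -0.54), "no": ("I", 0.36, -0.25)},
        16: {"yes": ("O", 0.72, -0.71), "no": ("I", 0.35, -0.39)},
    }
)
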