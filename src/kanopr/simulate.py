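"""Synthetic respondent cohorts with the structure the analyses assume.

The generator emulates the reference COPD survey: per-attribute multinomial
Kano-category propensities (calibrated by default to the published tallies),
independent covariate margins matching the published cohort, a linear
intention model with the published coefficient vector, and optional
subgroup-specific propensity shifts that reproduce the category-flip
patterns seen between, e.g., aware and unaware patients.

Design notes
------------
* Categories, not raw answer pairs, are calibrated: published tallies only
  constrain the category distribution, so a drawn category is spread
  uniformly over its preimage in the 5x5 evaluation grid.
* Attributes are sampled independently of one another (the true inter-item
  dependence of the survey is unidentifiable from published summaries).
* Intention is generated as round-and-clip to 1..5 of a Gaussian linear
  score, matching the linear-model treatment of the outcome; the latent
  continuous score is always emitted as ``intention_latent`` (round-and-clip
  censoring biases least squares, so parameter-recovery checks regress on
  the latent scale).  An ordinal-logit generator is available for checking
  the proportional-odds model.
* A fixed seed yields a byte-identical cohort.
"""

from __future__ import annotations

from typing import Literal, Mapping, Sequence

import numpy as np
from pydantic import BaseModel, Field, field_validator

from .io import Respondent
from .kano import CATEGORY_PREIMAGE, CategoryCounts, KanoCategory
from .reference import (
    AWARENESS_SUBGROUP_PATTERNS,
    COHORT_MARGINS,
    INTENTION_MODEL,
    REFERENCE_N,
    REFERENCE_TALLIES,
)
from .registry import ATTRIBUTE_IDS
from .subgroups import SUBGROUP_SPECS

_CATEGORY_ORDER = tuple(c.value for c in KanoCategory)


def _check_propensity(vec: Mapping[str, float]) -> dict[str, float]:
    unknown = set(vec) - set(_CATEGORY_ORDER)
    if unknown:
        raise ValueError(f"unknown Kano categories in propensity vector: {sorted(unknown)}")
    full = {c: float(vec.get(c, 0.0)) for c in _CATEGORY_ORDER}
    total = sum(full.values())
    if any(v < 0 for v in full.values()) or not np.isclose(total, 1.0, atol=1e-8):
        raise ValueError(f"propensities must be non-negative and sum to 1 (got {total})")
    return full


class IntentionModelConfig(BaseModel):
    """Linear (round-and-clip Gaussian) or ordinal-logit intention generator."""

    kind: Literal["linear", "ordinal"] = "linear"
    const: float = INTENTION_MODEL["const"]
    coefficients: dict[str, float] = Field(
        default_factory=lambda: {k: v for k, v in INTENTION_MODEL.items() if k != "const"}
    )
    noise_sd: float = 0.8
    thresholds: list[float] = Field(default_factory=lambda: [2.0, 3.0, 3.7, 5.0])

    @field_validator("noise_sd")
    @classmethod
    def _positive_sd(cls, v):
        if v <= 0:
            raise ValueError("noise_sd must be positive")
        return v


class CovariateConfig(BaseModel):
    """Marginal covariate distributions (independent across covariates)."""

    categorical: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {
            "region": {"Hangzhou": 156 / REFERENCE_N, "Quzhou": 81 / REFERENCE_N},
            "gender": {"male": 186 / REFERENCE_N, "female": 51 / REFERENCE_N},
            "education": {
                "primary-or-below": 92 / REFERENCE_N,
                "junior-secondary": 94 / REFERENCE_N,
                "senior-secondary-or-above": 51 / REFERENCE_N,
            },
            "income": {
                "<=3999": 48 / REFERENCE_N,
                "4000-6999": 122 / REFERENCE_N,
                ">=7000": 67 / REFERENCE_N,
            },
            "copd_stage": {"stable": 142 / REFERENCE_N, "acute": 95 / REFERENCE_N},
            "awareness": {"yes": 149 / REFERENCE_N, "no": 88 / REFERENCE_N},
            "no_drinking": {"yes": 0.6, "no": 0.4},
        }
    )
    age_mean: float = 76.6
    age_sd: float = 10.0
    age_min: int = 45
    age_max: int = 97
    mmrc_probs: list[float] = Field(
        default_factory=lambda: [0.04, 0.14, 0.595, 0.17, 0.055]
    )
    # Perceived-influence items on the 1-5 scale.  Facilitator items (staff
    # skills, family support) are rated high; barrier items (lack of
    # community knowledge promotion, transportation concerns) mid-scale.
    influence_probs: dict[str, list[float]] = Field(
        default_factory=lambda: {
            "influence_staff_skills": [0.02, 0.04, 0.10, 0.30, 0.54],
            "influence_knowledge_promotion": [0.05, 0.12, 0.30, 0.34, 0.19],
            "influence_transportation": [0.05, 0.12, 0.30, 0.34, 0.19],
            "influence_family_support": [0.02, 0.04, 0.10, 0.30, 0.54],
        }
    )


class GeneratorConfig(BaseModel):
    """Full specification of a synthetic cohort."""

    n_respondents: int = REFERENCE_N
    seed: int = 0
    attribute_propensities: dict[int, dict[str, float]] = Field(
        default_factory=lambda: calibrate_from_table3(REFERENCE_TALLIES)
    )
    covariates: CovariateConfig = Field(default_factory=CovariateConfig)
    intention_model: IntentionModelConfig = Field(default_factory=IntentionModelConfig)
    #: ``{spec name: {level: {attribute id: propensity vector}}}`` overrides,
    #: applied to respondents whose subgroup label matches.
    subgroup_shifts: dict[str, dict[str, dict[int, dict[str, float]]]] = Field(
        default_factory=dict
    )

    @field_validator("n_respondents")
    @classmethod
    def _at_least_one(cls, v):
        if v < 1:
            raise ValueError("n_respondents must be >= 1")
        return v

    @field_validator("attribute_propensities")
    @classmethod
    def _valid_propensities(cls, v):
        return {int(aid): _check_propensity(vec) for aid, vec in v.items()}

    @field_validator("subgroup_shifts")
    @classmethod
    def _valid_shifts(cls, v):
        out = {}
        for spec_name, levels in v.items():
            if spec_name not in SUBGROUP_SPECS:
                raise ValueError(f"unknown subgroup spec {spec_name!r}")
            out[spec_name] = {
                level: {int(aid): _check_propensity(vec) for aid, vec in attrs.items()}
                for level, attrs in levels.items()
            }
        return out


def calibrate_from_table3(
    counts_by_attribute: Mapping[int, CategoryCounts],
) -> dict[int, dict[str, float]]:
    """Category propensities equal to observed tally proportions."""
    out: dict[int, dict[str, float]] = {}
    for aid, counts in counts_by_attribute.items():
        n = counts.n_total
        if n == 0:
            raise ValueError(f"attribute {aid} has a zero-total tally")
        out[int(aid)] = {c.value: counts[c] / n for c in KanoCategory}
    return out


def propensities_from_coefficients(
    si: float, dsi: float, m_share: float = 0.03
) -> dict[str, float]:
    """A/O/M/I propensity vector consistent with target SI and DSI values.

    Solves ``(A+O) = si``, ``(O+M) = |dsi|``, ``A+O+M+I = 1`` (no reverse or
    questionable mass); the remaining degree of freedom (the must-be share)
    defaults to ``m_share``, clipped into its feasible interval.
    """
    adsi = abs(dsi)
    if not (0 <= si <= 1 and 0 <= adsi <= 1):
        raise ValueError("si and |dsi| must lie in [0, 1]")
    lo, hi = max(0.0, adsi - si), min(1.0 - si, adsi)
    if lo > hi:
        raise ValueError(f"no A/O/M/I vector attains si={si}, dsi={dsi}")
    m = float(np.clip(m_share, lo, hi))
    o = adsi - m
    a = max(0.0, si - o)  # clamp float dust at the feasibility boundary
    i = max(0.0, 1.0 - si - m)
    total = a + o + m + i
    vec = {"A": a / total, "O": o / total, "M": m / total, "I": i / total,
           "R": 0.0, "Q": 0.0}
    return _check_propensity(vec)


def awareness_shift_config() -> dict[str, dict[str, dict[int, dict[str, float]]]]:
    """Subgroup-shift fragment reproducing the published aware/unaware
    category flips (six attributes one-dimensional for aware respondents but
    indifferent for unaware ones)."""
    return {
        "awareness": {
            level: {
                aid: propensities_from_coefficients(si, dsi)
                for aid, pattern in AWARENESS_SUBGROUP_PATTERNS.items()
                for (_, si, dsi) in [pattern[level]]
            }
            for level in ("yes", "no")
        }
    }


def _sample_categorical(rng, labels: Sequence[str], probs: Sequence[float], n: int):
    p = np.asarray(probs, dtype=float)
    if (p < 0).any() or not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise ValueError(f"invalid probability vector {list(p)}")
    return rng.choice(np.asarray(labels, dtype=object), size=n, p=p / p.sum())


def _predictor_value(record: dict, name: str) -> float:
    v = record.get(name)
    if v is None:
        raise KeyError(f"intention-model predictor {name!r} not generated")
    if isinstance(v, str):
        if v in ("yes", "no"):
            return 1.0 if v == "yes" else 0.0
        raise ValueError(f"predictor {name!r} has non-numeric value {v!r}")
    return float(v)


def simulate_cohort(config: GeneratorConfig | None = None, **overrides) -> list[Respondent]:
    """Draw a synthetic cohort; deterministic under a fixed seed.

    Keyword overrides are applied on top of ``config`` (or the default
    configuration), e.g. ``simulate_cohort(n_respondents=500, seed=7)``.
    """
    if config is None:
        config = GeneratorConfig(**overrides)
    elif overrides:
        config = config.model_copy(update=overrides)
    rng = np.random.default_rng(config.seed)
    n = config.n_respondents
    cov = config.covariates

    columns: dict[str, np.ndarray] = {}
    for name, dist in cov.categorical.items():
        labels = list(dist)
        columns[name] = _sample_categorical(rng, labels, [dist[k] for k in labels], n)
    age = np.rint(rng.normal(cov.age_mean, cov.age_sd, size=n))
    columns["age"] = np.clip(age, cov.age_min, cov.age_max).astype(int)
    columns["mmrc"] = rng.choice(5, size=n, p=np.asarray(cov.mmrc_probs))
    for name, probs in cov.influence_probs.items():
        columns[name] = rng.choice(np.arange(1, 6), size=n, p=np.asarray(probs))

    records = [
        {name: values[idx] for name, values in columns.items()} for idx in range(n)
    ]

    im = config.intention_model
    xb = np.full(n, im.const if im.kind == "linear" else 0.0)
    for name, beta in im.coefficients.items():
        xb += beta * np.array([_predictor_value(r, name) for r in records])
    if im.kind == "linear":
        latent = xb + rng.normal(0.0, im.noise_sd, size=n)
        intention = np.clip(np.rint(latent), 1, 5).astype(int)
    else:
        latent = xb + rng.logistic(0.0, 1.0, size=n)
        intention = 1 + (latent[:, None] > np.asarray(im.thresholds)[None, :]).sum(axis=1)
    for idx, record in enumerate(records):
        record["intention"] = int(intention[idx])
        record["intention_latent"] = float(latent[idx])

    # Per attribute: pick each respondent's propensity row (base or shifted),
    # draw a category, then spread uniformly over the category's preimage.
    shift_masks: list[tuple[np.ndarray, dict[int, dict[str, float]]]] = []
    for spec_name, levels in config.subgroup_shifts.items():
        spec = SUBGROUP_SPECS[spec_name]
        labels = np.array([spec.label(r) for r in records], dtype=object)
        for level, attr_vecs in levels.items():
            shift_masks.append((labels == level, attr_vecs))

    pair_columns: dict[int, list[tuple[str, str]]] = {}
    for aid in ATTRIBUTE_IDS:
        base = config.attribute_propensities.get(aid)
        if base is None:
            raise ValueError(f"no propensity vector for attribute {aid}")
        prop = np.tile([base[c] for c in _CATEGORY_ORDER], (n, 1))
        for mask, attr_vecs in shift_masks:
            if aid in attr_vecs:
                prop[mask] = [attr_vecs[aid][c] for c in _CATEGORY_ORDER]
        u = rng.random(n)
        cat_idx = (u[:, None] > np.cumsum(prop, axis=1)).sum(axis=1)
        preimages = [CATEGORY_PREIMAGE[KanoCategory(c)] for c in _CATEGORY_ORDER]
        sizes = np.array([len(p) for p in preimages])
        within = np.floor(rng.random(n) * sizes[cat_idx]).astype(int)
        pair_columns[aid] = [
            (preimages[c][w][0].value, preimages[c][w][1].value)
            for c, w in zip(cat_idx, within)
        ]

    respondents = []
    for idx, record in enumerate(records):
        core = {
            "respondent_id": f"S{idx + 1:04d}",
            "region": str(record["region"]),
            "gender": str(record["gender"]),
            "age": int(record["age"]),
            "education": str(record["education"]),
            "income": str(record["income"]),
            "mmrc": int(record["mmrc"]),
            "copd_stage": str(record["copd_stage"]),
            "awareness": str(record["awareness"]),
            "intention": int(record["intention"]),
        }
        extras = {
            "no_drinking": str(record["no_drinking"]),
            "intention_latent": record["intention_latent"],
            **{name: int(record[name]) for name in cov.influence_probs},
        }
        resp = Respondent(
            pairs={aid: pair_columns[aid][idx] for aid in ATTRIBUTE_IDS},
            extras=extras,
            **core,
        )
        resp.validate()
        respondents.append(resp)
    return respondents


def simulate_frame(config: GeneratorConfig | None = None, **overrides):
    """Synthetic cohort as the canonical wide DataFrame."""
    from .io import respondents_to_frame

    return respondents_to_frame(simulate_cohort(config, **overrides))
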