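"""Kano-model classification of paired functional/dysfunctional responses.

Each service attribute is probed with two questions — "if the service were
provided, how would you feel?" (functional) and "if it were not provided, how
would you feel?" (dysfunctional) — each answered on the five-level scale
*Like it / Must-be / Neutral / Accept it / Dislike*.  The 5x5 answer grid maps
every pair onto one of six Kano categories:

====  ==================  =========================================================
code  name                meaning
====  ==================  =========================================================
A     attractive          delights when present, no penalty when absent
O     one-dimensional     satisfaction rises with provision, falls with absence
M     must-be             taken for granted when present, dissatisfies when absent
I     indifferent         presence/absence does not move satisfaction
R     reverse             provision decreases satisfaction
Q     questionable        contradictory answer pair
====  ==================  =========================================================

Per attribute the assigned categories are tallied over respondents, the final
category is the modal one, and the satisfaction / dissatisfaction coefficients

    SI  = (A + O) / (A + O + M + I)          ("better",  0 <= SI <= 1)
    DSI = -(O + M) / (A + O + M + I)         ("worse",  -1 <= DSI <= 0)

summarise how strongly provision (SI) or withdrawal (|DSI|) of the service
moves satisfaction.  Reverse and questionable answers are excluded from the
coefficient denominator.  Attributes are then placed on a quadrant matrix of
SI (y) against |DSI| (x): quadrant 1 (both high) holds the top-priority
services.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .registry import ATTRIBUTE_IDS, ATTRIBUTES, AttributeDef, get_attribute


class AnswerLevel(str, Enum):
    """Five-level answer scale, in canonical serialization order."""

    LIKE = "Like it"
    MUST_BE = "Must-be"
    NEUTRAL = "Neutral"
    ACCEPT = "Accept it"
    DISLIKE = "Dislike"


#: Canonical serialization order of the answer levels.
ANSWER_LEVELS: tuple[AnswerLevel, ...] = tuple(AnswerLevel)


class KanoCategory(str, Enum):
    ATTRACTIVE = "A"
    ONE_DIMENSIONAL = "O"
    MUST_BE = "M"
    INDIFFERENT = "I"
    REVERSE = "R"
    QUESTIONABLE = "Q"


CATEGORIES: tuple[KanoCategory, ...] = tuple(KanoCategory)

# Evaluation grid: rows = functional answer, columns = dysfunctional answer,
# both in canonical level order (Like it, Must-be, Neutral, Accept it, Dislike).
_GRID = (
    ("Q", "A", "A", "A", "O"),
    ("R", "I", "I", "I", "M"),
    ("R", "I", "I", "I", "M"),
    ("R", "I", "I", "I", "M"),
    ("R", "R", "R", "R", "Q"),
)

#: Total mapping over all 25 (functional, dysfunctional) combinations.
EVALUATION_TABLE: Mapping[tuple[AnswerLevel, AnswerLevel], KanoCategory] = {
    (f, d): KanoCategory(_GRID[i][j])
    for i, f in enumerate(ANSWER_LEVELS)
    for j, d in enumerate(ANSWER_LEVELS)
}

#: Preimage of each category under the evaluation grid.
CATEGORY_PREIMAGE: Mapping[KanoCategory, tuple[tuple[AnswerLevel, AnswerLevel], ...]] = {
    cat: tuple(pair for pair, c in EVALUATION_TABLE.items() if c is cat)
    for cat in CATEGORIES
}

#: Modal-category tie-break: must-be first, then one-dimensional, attractive,
#: indifferent, reverse, questionable — the Kano provision-priority order.
DEFAULT_TIE_BREAK: tuple[KanoCategory, ...] = (
    KanoCategory.MUST_BE,
    KanoCategory.ONE_DIMENSIONAL,
    KanoCategory.ATTRACTIVE,
    KanoCategory.INDIFFERENT,
    KanoCategory.REVERSE,
    KanoCategory.QUESTIONABLE,
)


def _coerce_level(value: str | AnswerLevel, side: str) -> AnswerLevel:
    try:
        return AnswerLevel(value)
    except ValueError:
        raise ValueError(
            f"non-canonical {side} answer level {value!r}; "
            f"expected one of {[lvl.value for lvl in ANSWER_LEVELS]}"
        ) from None


def classify_response_pair(
    functional: str | AnswerLevel, dysfunctional: str | AnswerLevel
) -> KanoCategory:
    """Map one (functional, dysfunctional) answer pair to its Kano category."""
    f = _coerce_level(functional, "functional")
    d = _coerce_level(dysfunctional, "dysfunctional")
    return EVALUATION_TABLE[(f, d)]


@dataclass(frozen=True)
class CategoryCounts:
    """Per-attribute tally over the six Kano categories."""

    a: int = 0
    o: int = 0
    m: int = 0
    i: int = 0
    r: int = 0
    q: int = 0

    def __post_init__(self) -> None:
        for name in "aomirq":
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"count {name!r} must be a non-negative integer, got {v!r}")

    @property
    def n_total(self) -> int:
        return self.a + self.o + self.m + self.i + self.r + self.q

    @property
    def n_classifiable(self) -> int:
        """Denominator of the satisfaction coefficients (R and Q excluded)."""
        return self.a + self.o + self.m + self.i

    def __getitem__(self, category: KanoCategory | str) -> int:
        return getattr(self, KanoCategory(category).value.lower())

    def __add__(self, other: "CategoryCounts") -> "CategoryCounts":
        return CategoryCounts(*(self[c] + other[c] for c in CATEGORIES))

    def as_series(self) -> pd.Series:
        return pd.Series({c.value: self[c] for c in CATEGORIES}, dtype=int)

    def percentages(self) -> pd.Series:
        """Category shares in percent (NaN for an empty tally)."""
        n = self.n_total
        if n == 0:
            return pd.Series({c.value: math.nan for c in CATEGORIES})
        return self.as_series() / n * 100.0


def tally_categories(
    pairs: Iterable[tuple[str | AnswerLevel | None, str | AnswerLevel | None]],
) -> CategoryCounts:
    """Tally Kano categories over one attribute's response pairs.

    Pairs with a missing half (``None`` on either side) are skipped, so the
    tally sums to the number of complete pairs.
    """
    counts = {c: 0 for c in CATEGORIES}
    for functional, dysfunctional in pairs:
        if functional is None or dysfunctional is None:
            continue
        counts[classify_response_pair(functional, dysfunctional)] += 1
    return CategoryCounts(*(counts[c] for c in CATEGORIES))


def assign_final_category(
    counts: CategoryCounts,
    tie_break: Sequence[KanoCategory] = DEFAULT_TIE_BREAK,
) -> KanoCategory:
    """Modal category of a tally; ties resolved by the fixed priority order."""
    if counts.n_total == 0:
        raise ValueError("cannot assign a final category to an empty tally")
    order = [KanoCategory(c) for c in tie_break]
    if sorted(order, key=lambda c: c.value) != sorted(CATEGORIES, key=lambda c: c.value):
        raise ValueError("tie_break must be a permutation of the six categories")
    return max(order, key=lambda c: (counts[c], -order.index(c)))


@dataclass(frozen=True)
class CoefficientPair:
    """Satisfaction (better, SI) and dissatisfaction (worse, DSI) coefficients.

    ``defined`` is False when the attribute has no A/O/M/I answers at all, in
    which case ``si`` and ``dsi`` are NaN.
    """

    si: float
    dsi: float
    defined: bool = True

    def __post_init__(self) -> None:
        if self.defined and not (0.0 <= self.si <= 1.0 and -1.0 <= self.dsi <= 0.0):
            raise ValueError(f"coefficients out of range: si={self.si}, dsi={self.dsi}")


def satisfaction_coefficients(counts: CategoryCounts) -> CoefficientPair:
    """SI = (A+O)/(A+O+M+I), DSI = -(O+M)/(A+O+M+I); R/Q excluded."""
    denom = counts.n_classifiable
    if denom == 0:
        return CoefficientPair(math.nan, math.nan, defined=False)
    return CoefficientPair(
        si=(counts.a + counts.o) / denom,
        dsi=-(counts.o + counts.m) / denom,
    )


def assign_quadrant(
    coefficients: CoefficientPair, split: float | tuple[float, float] = 0.5
) -> int:
    """Quadrant of the SI (y) versus |DSI| (x) matrix for a given axis split.

    ``split`` is either one threshold for both axes (default 0.5, the
    conventional importance cut-off) or a ``(si_split, dsi_split)`` pair,
    e.g. the cohort means of SI and |DSI|.

    1 = upper right (both above the split: provide with top priority),
    2 = upper left (high SI only), 4 = lower right (high |DSI| only),
    3 = lower left (neither).
    """
    if not coefficients.defined:
        raise ValueError("cannot place undefined coefficients on the matrix")
    si_split, dsi_split = split if isinstance(split, tuple) else (split, split)
    hi_si = coefficients.si > si_split
    hi_dsi = abs(coefficients.dsi) > dsi_split
    if hi_si:
        return 1 if hi_dsi else 2
    return 4 if hi_dsi else 3


@dataclass(frozen=True)
class AttributeResult:
    """Full Kano result for one attribute."""

    attribute: AttributeDef
    counts: CategoryCounts
    final_category: KanoCategory
    coefficients: CoefficientPair
    quadrant: int | None = field(default=None)

    @property
    def flagged(self) -> bool:
        """True when the attribute cannot be placed on the quadrant matrix."""
        return self.quadrant is None


def _pairs_by_attribute(respondents) -> dict[int, list[tuple]]:
    """Extract per-attribute pair lists from a DataFrame or Respondent sequence.

    DataFrames use the canonical wide layout with columns ``F01..F18`` and
    ``D01..D18``; anything else must be an iterable of objects exposing a
    ``pairs`` mapping ``attribute id -> (functional, dysfunctional)``.
    """
    out: dict[int, list[tuple]] = {aid: [] for aid in ATTRIBUTE_IDS}
    if isinstance(respondents, pd.DataFrame):
        for aid in ATTRIBUTE_IDS:
            fcol, dcol = f"F{aid:02d}", f"D{aid:02d}"
            if fcol not in respondents.columns or dcol not in respondents.columns:
                raise KeyError(f"survey frame is missing columns {fcol!r}/{dcol!r}")
            f = respondents[fcol].where(respondents[fcol].notna(), None)
            d = respondents[dcol].where(respondents[dcol].notna(), None)
            out[aid] = list(zip(f, d))
        return out
    for resp in respondents:
        pairs = resp.pairs
        for aid in ATTRIBUTE_IDS:
            if aid not in pairs:
                raise KeyError(
                    f"respondent {getattr(resp, 'respondent_id', '?')!r} lacks "
                    f"attribute {aid}"
                )
            out[aid].append(pairs[aid])
        unknown = set(pairs) - set(ATTRIBUTE_IDS)
        if unknown:
            raise KeyError(f"unknown attribute ids in respondent pairs: {sorted(unknown)}")
    return out


def run_kano(
    respondents,
    attributes: Sequence[int] | None = None,
    split: float = 0.5,
    tie_break: Sequence[KanoCategory] = DEFAULT_TIE_BREAK,
) -> list[AttributeResult]:
    """Run the full Kano procedure and return one result per attribute.

    ``respondents`` is either the canonical wide survey DataFrame or an
    iterable of :class:`kanopr.io.Respondent`.  Deterministic given its input.
    """
    by_attr = _pairs_by_attribute(respondents)
    ids = list(attributes) if attributes is not None else list(ATTRIBUTE_IDS)
    results = []
    for aid in ids:
        attr = get_attribute(aid)
        counts = tally_categories(by_attr[aid])
        if counts.n_total == 0:
            raise ValueError(f"attribute {aid} has no complete response pairs")
        final = assign_final_category(counts, tie_break)
        coeffs = satisfaction_coefficients(counts)
        placeable = coeffs.defined and final not in (
            KanoCategory.REVERSE,
            KanoCategory.QUESTIONABLE,
        )
        quadrant = assign_quadrant(coeffs, split) if placeable else None
        results.append(AttributeResult(attr, counts, final, coeffs, quadrant))
    return results


def results_from_counts(
    counts_by_attribute: Mapping[int, CategoryCounts],
    split: float = 0.5,
    tie_break: Sequence[KanoCategory] = DEFAULT_TIE_BREAK,
) -> list[AttributeResult]:
    """Kano results straight from pre-tallied category counts."""
    results = []
    for aid in sorted(counts_by_attribute):
        attr = get_attribute(aid)
        counts = counts_by_attribute[aid]
        final = assign_final_category(counts, tie_break)
        coeffs = satisfaction_coefficients(counts)
        placeable = coeffs.defined and final not in (
            KanoCategory.REVERSE,
            KanoCategory.QUESTIONABLE,
        )
        quadrant = assign_quadrant(coeffs, split) if placeable else None
        results.append(AttributeResult(attr, counts, final, coeffs, quadrant))
    return results


def results_to_frame(results: Sequence[AttributeResult]) -> pd.DataFrame:
    """Tabulate attribute results (one row per attribute)."""
    rows = []
    for res in results:
        row = {
            "attribute_id": res.attribute.id,
            "dimension": res.attribute.dimension,
            "label": res.attribute.label,
        }
        pct = res.counts.percentages()
        for c in CATEGORIES:
            row[c.value] = res.counts[c]
            row[f"{c.value}_pct"] = round(float(pct[c.value]), 1)
        row["final_category"] = res.final_category.value
        row["si"] = round(res.coefficients.si, 2) if res.coefficients.defined else np.nan
        row["dsi"] = round(res.coefficients.dsi, 2) if res.coefficients.defined else np.nan
        row["quadrant"] = res.quadrant if res.quadrant is not None else pd.NA
        rows.append(row)
    return pd.DataFrame(rows).set_index("attribute_id")


class KanoAnalyzer(BaseEstimator):
    """Kano demand analysis as a fit-style estimator.

    Parameters
    ----------
    split : float, default 0.5
        Axis split of the SI versus |DSI| quadrant matrix.  0.5 is the
        conventional importance threshold; pass ``split="mean"`` to use the
        cohort means of SI and |DSI| instead.
    tie_break : sequence of KanoCategory
        Priority order used when two categories tie for the mode.

    Attributes
    ----------
    results_ : list of AttributeResult
    counts_ : dict mapping attribute id to CategoryCounts
    summary_ : pandas.DataFrame
        One row per attribute with counts, percentages, final category,
        SI/DSI and quadrant.
    """

    def __init__(self, split: float | str = 0.5, tie_break=DEFAULT_TIE_BREAK):
        self.split = split
        self.tie_break = tie_break

    def fit(self, X, y=None):
        by_attr = _pairs_by_attribute(X)
        counts = {aid: tally_categories(by_attr[aid]) for aid in ATTRIBUTE_IDS}
        if all(c.n_total == 0 for c in counts.values()):
            raise ValueError("survey contains no complete response pairs")
        if self.split == "mean":
            coeffs = [satisfaction_coefficients(c) for c in counts.values()]
            defined = [c for c in coeffs if c.defined]
            split: float | tuple[float, float] = (
                float(np.mean([c.si for c in defined])),
                float(np.mean([abs(c.dsi) for c in defined])),
            )
        elif isinstance(self.split, tuple):
            split = (float(self.split[0]), float(self.split[1]))
        else:
            split = float(self.split)
        self.split_ = split
        self.counts_ = counts
        self.results_ = results_from_counts(counts, split=split, tie_break=self.tie_break)
        self.summary_ = results_to_frame(self.results_)
        return self

    def transform(self, X=None) -> pd.DataFrame:
        """Return the per-attribute summary table of the fitted analysis."""
        if not hasattr(self, "results_"):
            raise AttributeError("KanoAnalyzer is not fitted yet; call fit first")
        return self.summary_.copy()
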