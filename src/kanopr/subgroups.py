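"""Subgroup demand comparison.

The Kano analysis is re-run within patient subgroups (by intention,
awareness, dyspnea burden, age, income, education or region) and the
per-attribute category distributions are compared between subgroups with a
Pearson chi-square test on the groups-by-categories contingency table.  The
sparse reverse/questionable columns are dropped before testing (they hold at
most one answer per attribute in cohorts like the reference study); when the
asymptotic test is unreliable (any expected cell below 5) the p-value falls
back to Fisher's exact test (2x2) or a seeded Monte-Carlo resampling of
tables with fixed margins.

An attribute is *divergent* when its final Kano category differs across the
subgroup levels — the pattern of interest being a service that is
one-dimensional (high demand) in one subgroup but indifferent in another.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .kano import (
    AttributeResult,
    CategoryCounts,
    KanoCategory,
    run_kano,
)
from .registry import ATTRIBUTE_IDS, AttributeDef, get_attribute


@dataclass(frozen=True)
class SubgroupSpec:
    """Named partition of the cohort on one covariate."""

    name: str
    levels: tuple[str, ...]
    labeler: Callable[[Mapping], str | None]

    def label(self, record: Mapping) -> str | None:
        """Subgroup level of one respondent record; None when unassignable."""
        return self.labeler(record)


def _field(record, name):
    if isinstance(record, Mapping) or isinstance(record, pd.Series):
        return record.get(name)
    return getattr(record, name, None)


def _binary(field: str, cut: Callable, lo: str, hi: str) -> Callable:
    def labeler(record):
        v = _field(record, field)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return None
        return lo if cut(v) else hi

    return labeler


def _categorical(field: str) -> Callable:
    def labeler(record):
        v = _field(record, field)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return None
        return str(v)

    return labeler


#: Built-in subgroup specifications, keyed by covariate name.
SUBGROUP_SPECS: dict[str, SubgroupSpec] = {
    "intention": SubgroupSpec(
        "intention",
        ("willingness", "unwillingness"),
        _binary("intention", lambda v: int(v) >= 4, "willingness", "unwillingness"),
    ),
    "awareness": SubgroupSpec("awareness", ("yes", "no"), _categorical("awareness")),
    "mmrc": SubgroupSpec(
        "mmrc", ("0-1", "2-4"), _binary("mmrc", lambda v: int(v) <= 1, "0-1", "2-4")
    ),
    "age": SubgroupSpec(
        "age", ("<75", ">=75"), _binary("age", lambda v: int(v) < 75, "<75", ">=75")
    ),
    "income": SubgroupSpec(
        "income", ("<=3999", "4000-6999", ">=7000"), _categorical("income")
    ),
    "education": SubgroupSpec(
        "education",
        ("primary-or-below", "junior-secondary", "senior-secondary-or-above"),
        _categorical("education"),
    ),
    "region": SubgroupSpec("region", ("Hangzhou", "Quzhou"), _categorical("region")),
}


def split_cohort(respondents, spec: SubgroupSpec | str):
    """Partition respondents by a subgroup spec.

    Returns an ordered ``{level: sub-cohort}`` dict of the same container
    flavour as the input (DataFrame in, DataFrame slices out).  Respondents
    whose covariate is missing are excluded (logged sizes always sum to the
    non-missing cohort size).
    """
    if isinstance(spec, str):
        try:
            spec = SUBGROUP_SPECS[spec]
        except KeyError:
            raise KeyError(
                f"unknown subgroup spec {spec!r}; known: {sorted(SUBGROUP_SPECS)}"
            ) from None
    if isinstance(respondents, pd.DataFrame):
        labels = respondents.apply(spec.label, axis=1)
        out = {
            level: respondents.loc[labels == level] for level in spec.levels
        }
        stray = set(labels.dropna()) - set(spec.levels)
    else:
        out = {level: [] for level in spec.levels}
        stray = set()
        for resp in respondents:
            level = spec.label(resp)
            if level is None:
                continue
            if level not in out:
                stray.add(level)
                continue
            out[level].append(resp)
    if stray:
        raise ValueError(f"labels outside spec levels for {spec.name!r}: {sorted(stray)}")
    return out


_POOLED = (
    KanoCategory.ATTRACTIVE,
    KanoCategory.ONE_DIMENSIONAL,
    KanoCategory.MUST_BE,
    KanoCategory.INDIFFERENT,
)


def _contingency(counts: Sequence[CategoryCounts], pooling: str) -> np.ndarray:
    if pooling == "drop_rq":
        cats = _POOLED
    elif pooling == "none":
        cats = tuple(KanoCategory)
    else:
        raise ValueError(f"unknown pooling rule {pooling!r}")
    table = np.array([[c[cat] for cat in cats] for c in counts], dtype=float)
    table = table[:, table.sum(axis=0) > 0]
    return table


def compare_category_distributions(
    *counts: CategoryCounts,
    pooling: str = "drop_rq",
    mc_samples: int = 2000,
    seed: int | None = 0,
) -> tuple[float, float, str]:
    """Pearson chi-square comparison of category tallies across groups.

    Returns ``(statistic, p_value, method)`` where ``method`` is
    ``"chi2"`` for the asymptotic test, ``"fisher"`` for the 2x2 exact
    fallback, or ``"monte-carlo"`` for the fixed-margins resampling fallback
    (both fallbacks keep the Pearson statistic and trigger when any expected
    cell is below 5).
    """
    if len(counts) == 1 and isinstance(counts[0], (list, tuple)):
        counts = tuple(counts[0])
    if len(counts) < 2:
        raise ValueError("need at least two group tallies")
    if any(c.n_total == 0 for c in counts):
        raise ValueError("all group tallies must be non-empty")
    table = _contingency(counts, pooling)
    if table.shape[1] < 2:
        raise ValueError("degenerate table: fewer than two non-empty categories")
    res = stats.chi2_contingency(table, correction=False)
    statistic, p_value = float(res.statistic), float(res.pvalue)
    expected = res.expected_freq
    if (expected >= 5).all():
        return statistic, p_value, "chi2"
    if table.shape == (2, 2):
        _, p_exact = stats.fisher_exact(table.astype(int))
        return statistic, float(p_exact), "fisher"
    rng = np.random.default_rng(seed)
    sampler = stats.random_table(table.sum(axis=1), table.sum(axis=0))
    sims = sampler.rvs(mc_samples, random_state=rng)
    colsums = table.sum(axis=0)
    exp = np.outer(table.sum(axis=1), colsums) / table.sum()
    sim_stats = ((sims - exp) ** 2 / exp).sum(axis=(1, 2))
    p_mc = (1.0 + float((sim_stats >= statistic - 1e-12).sum())) / (mc_samples + 1.0)
    return statistic, float(p_mc), "monte-carlo"


@dataclass(frozen=True)
class SubgroupComparison:
    """Per-attribute cross-subgroup comparison result."""

    spec: str
    attribute: AttributeDef
    per_level: dict[str, AttributeResult]
    statistic: float
    p_value: float
    method: str
    flagged_divergent: bool

    @property
    def significant(self) -> bool:
        return bool(self.p_value < 0.05)


def demand_difference_table(
    respondents,
    specs: Sequence[SubgroupSpec | str],
    alpha: float = 0.05,
    split: float = 0.5,
    pooling: str = "drop_rq",
    seed: int | None = 0,
) -> list[SubgroupComparison]:
    """Compare Kano category distributions across subgroups.

    One :class:`SubgroupComparison` per (spec, attribute); an attribute is
    flagged divergent when its final categories differ across levels.  Each
    subgroup level needs at least two respondents.
    """
    comparisons: list[SubgroupComparison] = []
    for spec in specs:
        parts = split_cohort(respondents, spec)
        spec_name = spec if isinstance(spec, str) else spec.name
        sizes = {lvl: len(part) for lvl, part in parts.items()}
        if any(n < 2 for n in sizes.values()):
            raise ValueError(
                f"subgroup {spec_name!r} has a level with <2 respondents: {sizes}"
            )
        per_level_results = {
            lvl: {res.attribute.id: res for res in run_kano(part, split=split)}
            for lvl, part in parts.items()
        }
        for aid in ATTRIBUTE_IDS:
            results = {lvl: per_level_results[lvl][aid] for lvl in parts}
            tallies = [results[lvl].counts for lvl in parts]
            statistic, p_value, method = compare_category_distributions(
                *tallies, pooling=pooling, seed=seed
            )
            categories = {res.final_category for res in results.values()}
            comparisons.append(
                SubgroupComparison(
                    spec=spec_name,
                    attribute=get_attribute(aid),
                    per_level=results,
                    statistic=statistic,
                    p_value=p_value,
                    method=method,
                    flagged_divergent=len(categories) > 1,
                )
            )
    return comparisons


def comparisons_to_frame(comparisons: Sequence[SubgroupComparison]) -> pd.DataFrame:
    """Tabulate subgroup comparisons, one row per (spec, attribute)."""
    rows = []
    for comp in comparisons:
        row = {
            "spec": comp.spec,
            "attribute_id": comp.attribute.id,
            "label": comp.attribute.label,
            "statistic": round(comp.statistic, 2),
            "p_value": comp.p_value,
            "method": comp.method,
            "divergent": comp.flagged_divergent,
            "significant": comp.significant,
        }
        for lvl, res in comp.per_level.items():
            row[f"kano[{lvl}]"] = res.final_category.value
            row[f"better[{lvl}]"] = round(res.coefficients.si, 2)
            row[f"worse[{lvl}]"] = round(res.coefficients.dsi, 2)
        rows.append(row)
    return pd.DataFrame(rows)
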