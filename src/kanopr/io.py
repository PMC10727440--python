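"""Survey table input/output.

Canonical on-disk format is a wide table, one row per respondent: covariate
columns, a 1-5 ``intention`` score, and answer columns ``F01..F18`` /
``D01..D18`` holding the functional / dysfunctional answer for each of the
18 service attributes.  CSV is the native dialect; XLSX is read through the
same schema mapping.  A :class:`SurveySchema` absorbs foreign layouts by
renaming columns and translating localized answer-level spellings onto the
five canonical levels.

Rows violating the respondent invariants (intention outside 1-5, mMRC outside
0-4, unknown category labels, ...) are rejected individually with row-level
diagnostics; missing answer cells become explicit ``None`` halves so that the
Kano tally can exclude incomplete pairs per attribute.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterator, Sequence

import pandas as pd
from pydantic import BaseModel, Field

from .kano import ANSWER_LEVELS, AttributeResult, CategoryCounts, results_from_counts
from .registry import ATTRIBUTE_IDS, ATTRIBUTES

logger = logging.getLogger(__name__)

REGIONS = ("Hangzhou", "Quzhou")
GENDERS = ("male", "female")
EDUCATION_LEVELS = ("primary-or-below", "junior-secondary", "senior-secondary-or-above")
INCOME_BRACKETS = ("<=3999", "4000-6999", ">=7000")
COPD_STAGES = ("stable", "acute")
YES_NO = ("yes", "no")

_CANONICAL_LEVELS = tuple(lvl.value for lvl in ANSWER_LEVELS)


@dataclass
class Respondent:
    """One surveyed COPD patient.

    ``pairs`` maps every attribute id 1..18 to a (functional, dysfunctional)
    answer tuple; a missing half is ``None`` (never an absent key).
    ``extras`` carries additional configured covariates (health behaviours,
    perceived-influence scores, ...) by name.
    """

    respondent_id: str
    region: str
    gender: str
    age: int
    education: str
    income: str
    mmrc: int
    copd_stage: str
    awareness: str
    intention: int
    pairs: dict[int, tuple[str | None, str | None]]
    extras: dict[str, Any] = field(default_factory=dict)

    def validate(self) -> None:
        """Raise ``ValueError`` naming the offending field on any violation."""
        checks = (
            ("region", self.region in REGIONS),
            ("gender", self.gender in GENDERS),
            ("age", isinstance(self.age, int) and self.age >= 40),
            ("education", self.education in EDUCATION_LEVELS),
            ("income", self.income in INCOME_BRACKETS),
            ("mmrc", isinstance(self.mmrc, int) and 0 <= self.mmrc <= 4),
            ("copd_stage", self.copd_stage in COPD_STAGES),
            ("awareness", self.awareness in YES_NO),
            ("intention", isinstance(self.intention, int) and 1 <= self.intention <= 5),
        )
        for name, ok in checks:
            if not ok:
                raise ValueError(f"invalid value for field {name!r}: {getattr(self, name)!r}")
        if set(self.pairs) != set(ATTRIBUTE_IDS):
            raise ValueError(
                f"pairs must cover attribute ids 1..{len(ATTRIBUTE_IDS)}; "
                f"got {sorted(self.pairs)}"
            )
        for aid, (f, d) in self.pairs.items():
            for side, ans in (("functional", f), ("dysfunctional", d)):
                if ans is not None and ans not in _CANONICAL_LEVELS:
                    raise ValueError(
                        f"attribute {aid} {side} answer {ans!r} is not a canonical level"
                    )


class SurveySchema(BaseModel):
    """Mapping between a concrete file layout and the canonical one.

    ``column_map`` renames file columns to canonical names (canonical name ->
    file column); unmapped canonical columns are looked up under their own
    name.  ``level_map`` translates answer spellings (e.g. localized labels)
    to the canonical five; canonical spellings always pass through.
    ``value_maps`` optionally recodes covariate labels per field.  Columns not
    consumed by the canonical fields are carried into ``Respondent.extras``.
    """

    column_map: dict[str, str] = Field(default_factory=dict)
    level_map: dict[str, str] = Field(default_factory=dict)
    value_maps: dict[str, dict[str, str]] = Field(default_factory=dict)
    missing_values: list[str] = Field(default_factory=lambda: ["", "NA", "NaN", "nan"])

    def source_column(self, canonical: str) -> str:
        return self.column_map.get(canonical, canonical)

    def canonical_level(self, raw: Any) -> str | None:
        if raw is None or (isinstance(raw, float) and pd.isna(raw)):
            return None
        text = str(raw).strip()
        if text in self.missing_values:
            return None
        text = self.level_map.get(text, text)
        if text not in _CANONICAL_LEVELS:
            raise ValueError(f"unknown answer level {raw!r}")
        return text

    def canonical_value(self, fieldname: str, raw: Any) -> Any:
        mapping = self.value_maps.get(fieldname)
        if mapping is not None and str(raw) in mapping:
            return mapping[str(raw)]
        return raw


_COVARIATE_COLUMNS = (
    "respondent_id",
    "region",
    "gender",
    "age",
    "education",
    "income",
    "mmrc",
    "copd_stage",
    "awareness",
    "intention",
)


def _answer_columns() -> list[str]:
    return [f"F{aid:02d}" for aid in ATTRIBUTE_IDS] + [
        f"D{aid:02d}" for aid in ATTRIBUTE_IDS
    ]


@dataclass
class SurveyReadResult:
    """Respondents accepted from a file plus row-level rejection diagnostics."""

    respondents: list[Respondent]
    rejected: list[tuple[int, str]] = field(default_factory=list)

    def __iter__(self) -> Iterator[Respondent]:
        return iter(self.respondents)

    def __len__(self) -> int:
        return len(self.respondents)


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".xlsx", ".xlsm"):
        return pd.read_excel(path, dtype=object)
    return pd.read_csv(path, dtype=object, keep_default_na=False)


def read_survey(
    path: str | Path,
    schema: SurveySchema | None = None,
    errors: str = "drop",
) -> SurveyReadResult:
    """Read a wide survey table into validated :class:`Respondent` records.

    Parameters
    ----------
    path : CSV or XLSX file.
    schema : layout/spelling mapping; defaults to the canonical layout.
    errors : ``"drop"`` rejects invalid rows with diagnostics (logged and
        returned); ``"raise"`` raises on the first invalid row.
    """
    schema = schema or SurveySchema()
    if errors not in ("drop", "raise"):
        raise ValueError("errors must be 'drop' or 'raise'")
    df = _read_table(path)
    respondents: list[Respondent] = []
    rejected: list[tuple[int, str]] = []
    seen_ids: set[str] = set()
    for idx, row in df.iterrows():
        try:
            resp = _row_to_respondent(row, schema)
            if resp.respondent_id in seen_ids:
                raise ValueError(f"duplicate respondent_id {resp.respondent_id!r}")
            seen_ids.add(resp.respondent_id)
            respondents.append(resp)
        except (ValueError, KeyError) as exc:
            if errors == "raise":
                raise ValueError(f"row {idx}: {exc}") from exc
            logger.warning("rejecting row %s: %s", idx, exc)
            rejected.append((int(idx), str(exc)))
    return SurveyReadResult(respondents, rejected)


def _missing(schema: SurveySchema, raw: Any) -> bool:
    return (
        raw is None
        or (isinstance(raw, float) and pd.isna(raw))
        or str(raw).strip() in schema.missing_values
    )


def _row_to_respondent(row: pd.Series, schema: SurveySchema) -> Respondent:
    values: dict[str, Any] = {}
    consumed: set[str] = set()
    for name in _COVARIATE_COLUMNS:
        col = schema.source_column(name)
        if col not in row.index:
            raise KeyError(f"missing column {col!r} for field {name!r}")
        consumed.add(col)
        raw = schema.canonical_value(name, row[col])
        if _missing(schema, raw):
            raise ValueError(f"field {name!r} is missing")
        if name in ("age", "mmrc", "intention"):
            try:
                raw = int(float(str(raw)))
            except ValueError:
                raise ValueError(f"field {name!r} is not an integer: {row[col]!r}")
        values[name] = str(raw) if name not in ("age", "mmrc", "intention") else raw
    pairs: dict[int, tuple[str | None, str | None]] = {}
    for aid in ATTRIBUTE_IDS:
        half = []
        for prefix in ("F", "D"):
            col = schema.source_column(f"{prefix}{aid:02d}")
            if col not in row.index:
                raise KeyError(f"missing answer column {col!r}")
            consumed.add(col)
            half.append(schema.canonical_level(row[col]))
        pairs[aid] = (half[0], half[1])
    extras = {
        col: row[col] for col in row.index if col not in consumed and not pd.isna(row[col])
    }
    resp = Respondent(pairs=pairs, extras=extras, **values)
    resp.validate()
    return resp


def respondents_to_frame(respondents: Sequence[Respondent]) -> pd.DataFrame:
    """Serialize respondents to the canonical wide DataFrame."""
    rows = []
    extra_names: list[str] = []
    for resp in respondents:
        row: dict[str, Any] = {name: getattr(resp, name) for name in _COVARIATE_COLUMNS}
        for name, value in resp.extras.items():
            if name not in extra_names:
                extra_names.append(name)
            row[name] = value
        for aid in ATTRIBUTE_IDS:
            f, d = resp.pairs[aid]
            row[f"F{aid:02d}"] = f
            row[f"D{aid:02d}"] = d
        rows.append(row)
    columns = list(_COVARIATE_COLUMNS) + extra_names + _answer_columns()
    return pd.DataFrame(rows, columns=columns)


def write_survey(respondents: Sequence[Respondent], path: str | Path) -> Path:
    """Write respondents as the canonical wide CSV (or XLSX by extension)."""
    path = Path(path)
    frame = respondents_to_frame(respondents)
    if path.suffix.lower() in (".xlsx", ".xlsm"):
        frame.to_excel(path, index=False)
    else:
        frame.to_csv(path, index=False)
    return path


RESULT_COLUMNS = (
    ["dimension", "attribute_id", "label"]
    + [c for cat in "AOMIRQ" for c in (cat, f"{cat}_pct")]
    + ["final_category", "si", "dsi", "quadrant"]
)


def write_results(results: Sequence[AttributeResult], path: str | Path) -> Path:
    """Write attribute results as a TSV.

    Layout mirrors the published demand table: per attribute the six category
    counts with percentages to one decimal and the final category, plus SI and
    DSI to two decimals and the assigned quadrant.
    """
    if not results:
        raise ValueError("results collection is empty")
    path = Path(path)
    rows = []
    for res in results:
        pct = res.counts.percentages()
        row: dict[str, Any] = {
            "dimension": res.attribute.dimension,
            "attribute_id": res.attribute.id,
            "label": res.attribute.label,
        }
        for cat in "AOMIRQ":
            row[cat] = res.counts[cat]
            row[f"{cat}_pct"] = f"{pct[cat]:.1f}"
        row["final_category"] = res.final_category.value
        row["si"] = f"{res.coefficients.si:.2f}" if res.coefficients.defined else ""
        row["dsi"] = f"{res.coefficients.dsi:.2f}" if res.coefficients.defined else ""
        row["quadrant"] = "" if res.quadrant is None else res.quadrant
        rows.append(row)
    pd.DataFrame(rows, columns=RESULT_COLUMNS).to_csv(path, sep="\t", index=False)
    return path


def read_results(path: str | Path) -> list[AttributeResult]:
    """Read back a results TSV written by :func:`write_results`.

    Counts and the quadrant split are re-derived from the stored tallies, so
    ``read_results(write_results(x))`` reproduces ``x`` for the default split.
    """
    df = pd.read_csv(path, sep="\t")
    counts = {
        int(row["attribute_id"]): CategoryCounts(
            *(int(row[cat]) for cat in "AOMIRQ")
        )
        for _, row in df.iterrows()
    }
    unknown = set(counts) - set(ATTRIBUTES)
    if unknown:
        raise KeyError(f"results file references unknown attribute ids {sorted(unknown)}")
    return results_from_counts(counts)
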