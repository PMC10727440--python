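"""Fixed registry of the 18 pulmonary-rehabilitation service attributes.

The demand questionnaire asks one functional / dysfunctional question pair
per attribute.  Attributes are grouped into eight intervention dimensions
(exercise, respiratory muscle training, diet, psychological interventions,
education, oxygen therapy, expectoration, TCM-based non-pharmacological
therapy).  The registry is immutable: analyses referencing an unknown
attribute id fail loudly.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import MappingProxyType


@dataclass(frozen=True)
class AttributeDef:
    """One service attribute of the demand questionnaire."""

    id: int
    label: str
    dimension: str


DIMENSIONS: tuple[str, ...] = (
    "Exercise",
    "Respiratory muscle training",
    "Diet",
    "Psychological interventions",
    "Education",
    "Oxygen therapy",
    "Expectoration",
    "TCM-based non-pharmacological therapy",
)

_ATTRIBUTE_ROWS: tuple[tuple[int, str, str], ...] = (
    (1, "Provide upper limb exercise interventions", "Exercise"),
    (2, "Provide lower limb exercise interventions", "Exercise"),
    (3, "Provide systemic exercise interventions", "Exercise"),
    (4, "Provide chest breathing training", "Respiratory muscle training"),
    (5, "Provide pursed lip breathing training", "Respiratory muscle training"),
    (6, "Provide abdominal breathing training", "Respiratory muscle training"),
    (7, "Inform about prohibited foods", "Diet"),
    (8, "Inform about how to properly arrange diet", "Diet"),
    (9, "Regular psychological assessment", "Psychological interventions"),
    (
        10,
        "Regularly communicate with patients and their family to motivate "
        "patients for rehabilitation",
        "Psychological interventions",
    ),
    (
        11,
        "Popularize the pathophysiology and clinical basic knowledge of COPD",
        "Education",
    ),
    (12, "Medication guidance", "Education"),
    (13, "Personalized guidance on daily life", "Education"),
    (14, "Provide long-term oxygen therapy interventions", "Oxygen therapy"),
    (15, "Provide non-invasive ventilation interventions", "Oxygen therapy"),
    (16, "Provide expectoration guidance", "Expectoration"),
    (
        17,
        "Dietary guidance according to TCM syndrome differentiation theory",
        "TCM-based non-pharmacological therapy",
    ),
    (18, "Provide TCM non-drug therapy", "TCM-based non-pharmacological therapy"),
)

#: Immutable mapping ``attribute id -> AttributeDef`` covering ids 1..18.
ATTRIBUTES: MappingProxyType[int, AttributeDef] = MappingProxyType(
    {i: AttributeDef(i, label, dim) for i, label, dim in _ATTRIBUTE_ROWS}
)

ATTRIBUTE_IDS: tuple[int, ...] = tuple(sorted(ATTRIBUTES))
N_ATTRIBUTES: int = len(ATTRIBUTE_IDS)


def get_attribute(attribute_id: int) -> AttributeDef:
    """Look up an attribute definition; unknown ids raise ``KeyError``."""
    try:
        return ATTRIBUTES[attribute_id]
    except KeyError:
        raise KeyError(
            f"unknown attribute id {attribute_id!r}; valid ids are 1..{N_ATTRIBUTES}"
        ) from None
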