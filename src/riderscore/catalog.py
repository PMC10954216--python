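"""The canonical six-trait diagnostic catalog.

The horsemanship syndrome is diagnosed from six skeletal trait categories,
each carrying an integer weight expressing its relative diagnostic
specificity. The weights sum to 12, the maximum attainable score.
"""

from __future__ import annotations

from dataclasses import dataclass

CATALOG_VERSION = "1.0"

#: Maximum weighted score attainable when every trait is present.
MAX_SCORE = 12


@dataclass(frozen=True)
class TraitDefinition:
    """One diagnostic trait category.

    Parameters
    ----------
    trait_id
        Short machine identifier, used as the column name in trait tables.
    name
        Human-readable label.
    weight
        Integer diagnostic weight in {1, 2, 3}; higher means the trait is
        more specific to habitual riding.
    description
        What the trait is and why it indicates riding.
    """

    trait_id: str
    name: str
    weight: int
    description: str = ""

    def __post_init__(self) -> None:
        if self.weight not in (1, 2, 3):
            raise ValueError(
                f"trait {self.trait_id!r}: weight must be 1, 2 or 3, got {self.weight}"
            )


_CANONICAL = (
    TraitDefinition(
        "entheses",
        "Femoral/pelvic entheses",
        3,
        "Pronounced entheseal stress reactions at the attachment sites of "
        "the hip adductors and gluteal muscles on pelvis and femur, from "
        "continuous balancing contractions when riding astride.",
    ),
    TraitDefinition(
        "ovalization",
        "Ovalization of acetabulum",
        3,
        "Anterosuperior extension and thickening of the acetabular rim, a "
        "response to pressure from frequent hip flexion with updrawn legs.",
    ),
    TraitDefinition(
        "fa_lesion",
        "Femoroacetabular lesion",
        2,
        "Impression dent with dense raised margin on the anterosuperior "
        "femoral neck from repeated femoroacetabular contact in a sitting "
        "position with spread, drawn-up legs.",
    ),
    TraitDefinition(
        "platymeric",
        "Platymeric femur",
        2,
        "Anteroposterior flattening of the subtrochanteric femoral shaft "
        "(platymeric index below 85), an adaptation to mediolateral bending "
        "stress on the proximal femur.",
    ),
    TraitDefinition(
        "vertebral",
        "Specific vertebral degeneration",
        1,
        "Symmetric spondylosis of the lower thoracic and lumbar spine with "
        "concave endplates and Schmorl's nodes, from repetitive vertical "
        "impact stress in an upright riding posture.",
    ),
    TraitDefinition(
        "trauma",
        "Specific trauma",
        1,
        "Healed trauma consistent with falls from horseback or other "
        "injuries typical of handling horses.",
    ),
)


def canonical_catalog() -> list[TraitDefinition]:
    """Return the six canonical traits in fixed order.

    Weights are (3, 3, 2, 2, 1, 1) and sum to :data:`MAX_SCORE`.
    """
    return list(_CANONICAL)


def canonical_trait_ids() -> list[str]:
    """Trait identifiers in canonical order."""
    return [t.trait_id for t in _CANONICAL]
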