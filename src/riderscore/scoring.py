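"""The dual-threshold weighted scoring rule.

An individual is classified as a probable habitual rider when it passes
both thresholds of the published rule:

* **trait threshold** — at least ``min_traits`` of the 6 diagnostic
  traits present (default 4, i.e. more than half), and
* **point threshold** — a weighted score of at least ``min_points`` of
  the maximum 12 (default 7, again more than half).

Traits that are not preserved contribute zero points (missing is never
imputed), but the engine reports score *bounds*: the minimum assumes
every unpreserved trait absent, the maximum assumes every unpreserved
trait present. When the bounds straddle a threshold the classification
is flagged as preservation-capped — advisory only; positivity always
uses the observed score.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .catalog import MAX_SCORE, TraitDefinition, canonical_catalog
from .records import Assemblage, SkeletonRecord, TraitState


class ScoreSource(enum.Enum):
    """Which score the point threshold is applied to."""

    BASE = "base"          # recomputed weighted sum of present traits
    REPORTED = "reported"  # transcribed published score (may embed a
                           # severity-of-expression adjustment)
    ADJUSTED = "adjusted"  # base score minus explicit severity deductions
    AUTO = "auto"          # reported when available, else base


@dataclass(frozen=True)
class Thresholds:
    """The dual classification thresholds (defaults are the published rule)."""

    min_traits: int = 4
    min_points: int = 7

    def __post_init__(self) -> None:
        if not 0 <= self.min_traits <= 6:
            raise ValueError(f"min_traits {self.min_traits} outside [0, 6]")
        if not 0 <= self.min_points <= MAX_SCORE:
            raise ValueError(f"min_points {self.min_points} outside [0, {MAX_SCORE}]")


@dataclass(frozen=True)
class SeverityAdjustment:
    """Explicit per-trait point deductions for weak trait expression.

    The published scores embed severity-of-expression deductions whose
    rules are not public; this type lets a user supply them explicitly.
    Each deduction applies to a PRESENT trait and cannot exceed the
    trait's weight.
    """

    deductions: dict[tuple[str, str], int] = field(default_factory=dict)

    def total_for(self, record: SkeletonRecord, catalog: list[TraitDefinition]) -> int:
        weights = {t.trait_id: t.weight for t in catalog}
        total = 0
        for (ind, trait_id), d in self.deductions.items():
            if ind != record.individual_id:
                continue
            if d < 0:
                raise ValueError(f"negative deduction for {ind}/{trait_id}")
            if trait_id not in weights:
                raise ValueError(f"deduction on unknown trait {trait_id!r}")
            if record.state_of(trait_id) is not TraitState.PRESENT:
                raise ValueError(
                    f"individual {ind}: deduction on trait {trait_id!r} "
                    f"which is not PRESENT"
                )
            if d > weights[trait_id]:
                raise ValueError(
                    f"individual {ind}: deduction {d} exceeds weight "
                    f"{weights[trait_id]} of trait {trait_id!r}"
                )
            total += d
        return total


@dataclass(frozen=True)
class ScoreResult:
    """Scoring and classification outcome for one individual."""

    individual_id: str
    trait_count: int
    base_score: int
    score_min: int
    score_max: int
    max_attainable: int
    selected_score: int
    score_source: ScoreSource
    adjusted_score: int | None
    meets_trait_threshold: bool
    meets_point_threshold: bool
    positive: bool
    preservation_capped: bool


def _weights(catalog: list[TraitDefinition], record: SkeletonRecord) -> dict[str, int]:
    weights = {t.trait_id: t.weight for t in catalog}
    missing = set(record.observations) - set(weights)
    if missing:
        raise ValueError(
            f"individual {record.individual_id!r}: traits {sorted(missing)} "
            f"not in catalog"
        )
    return weights


def trait_count(record: SkeletonRecord) -> int:
    """Number of diagnostic traits in PRESENT state."""
    return sum(1 for o in record.observations.values() if o.state is TraitState.PRESENT)


def base_score(
    record: SkeletonRecord, catalog: list[TraitDefinition] | None = None
) -> int:
    """Weighted sum over PRESENT traits; ABSENT and UNOBSERVABLE score 0."""
    weights = _weights(catalog or canonical_catalog(), record)
    return sum(
        weights[tid]
        for tid, o in record.observations.items()
        if o.state is TraitState.PRESENT
    )


def score_bounds(
    record: SkeletonRecord, catalog: list[TraitDefinition] | None = None
) -> tuple[int, int]:
    """(min, max) score over all completions of unpreserved traits.

    The minimum treats every UNOBSERVABLE trait as absent (this equals
    the base score); the maximum treats every UNOBSERVABLE trait as
    present.
    """
    weights = _weights(catalog or canonical_catalog(), record)
    lo = base_score(record, catalog)
    hidden = sum(
        weights[tid]
        for tid, o in record.observations.items()
        if o.state is TraitState.UNOBSERVABLE
    )
    return lo, lo + hidden


def max_attainable(
    record: SkeletonRecord, catalog: list[TraitDefinition] | None = None
) -> int:
    """Weighted sum over observable (PRESENT or ABSENT) traits.

    The highest score this skeleton could show given its preservation.
    """
    weights = _weights(catalog or canonical_catalog(), record)
    return sum(
        weights[tid]
        for tid, o in record.observations.items()
        if o.state is not TraitState.UNOBSERVABLE
    )


def apply_adjustment(
    base: int,
    record: SkeletonRecord,
    adjustment: SeverityAdjustment,
    catalog: list[TraitDefinition] | None = None,
) -> int:
    """Deduct explicit severity-of-expression points from a base score."""
    total = adjustment.total_for(record, catalog or canonical_catalog())
    return max(base - total, 0)


def classify(
    record: SkeletonRecord,
    thresholds: Thresholds | None = None,
    score_source: ScoreSource = ScoreSource.AUTO,
    adjustment: SeverityAdjustment | None = None,
    catalog: list[TraitDefinition] | None = None,
) -> ScoreResult:
    """Score one individual and apply the dual-threshold rule.

    ``score_source`` selects which score the point threshold is applied
    to: the recomputed base score, the transcribed published score, an
    explicitly adjusted score, or (default) the published score when
    present falling back to the base score.
    """
    thresholds = thresholds or Thresholds()
    catalog = catalog or canonical_catalog()

    count = trait_count(record)
    base = base_score(record, catalog)
    lo, hi = score_bounds(record, catalog)
    attainable = max_attainable(record, catalog)

    adjusted = None
    if adjustment is not None:
        adjusted = apply_adjustment(base, record, adjustment, catalog)

    source = score_source
    if source is ScoreSource.AUTO:
        source = (
            ScoreSource.REPORTED if record.reported_score is not None else ScoreSource.BASE
        )
    if source is ScoreSource.BASE:
        selected = base
    elif source is ScoreSource.REPORTED:
        if record.reported_score is None:
            raise ValueError(
                f"individual {record.individual_id!r}: no reported score to classify on"
            )
        selected = record.reported_score
    elif source is ScoreSource.ADJUSTED:
        if adjusted is None:
            raise ValueError(
                f"individual {record.individual_id!r}: no adjustment supplied"
            )
        selected = adjusted
    else:  # pragma: no cover - enum is exhaustive
        raise ValueError(f"unknown score source {score_source}")

    n_unobservable = sum(
        1 for o in record.observations.values() if o.state is TraitState.UNOBSERVABLE
    )
    meets_traits = count >= thresholds.min_traits
    meets_points = selected >= thresholds.min_points
    # preservation limits the verdict: the score band straddles the point
    # cut, the hidden traits straddle the trait cut, or the thresholds are
    # unreachable no matter what the unpreserved regions held
    n_observable = len(record.observations) - n_unobservable
    capped = (
        (lo < thresholds.min_points <= hi)
        or (count < thresholds.min_traits <= count + n_unobservable)
        or attainable < thresholds.min_points
        or n_observable < thresholds.min_traits
    )

    return ScoreResult(
        individual_id=record.individual_id,
        trait_count=count,
        base_score=base,
        score_min=lo,
        score_max=hi,
        max_attainable=attainable,
        selected_score=selected,
        score_source=source,
        adjusted_score=adjusted,
        meets_trait_threshold=meets_traits,
        meets_point_threshold=meets_points,
        positive=meets_traits and meets_points,
        preservation_capped=capped,
    )


def score_assemblage(
    assemblage: Assemblage,
    thresholds: Thresholds | None = None,
    score_source: ScoreSource = ScoreSource.AUTO,
    adjustment: SeverityAdjustment | None = None,
    catalog: list[TraitDefinition] | None = None,
) -> list[ScoreResult]:
    """Classify every record, preserving input order."""
    results = []
    for record in assemblage:
        try:
            results.append(
                classify(record, thresholds, score_source, adjustment, catalog)
            )
        except ValueError as e:
            raise ValueError(f"individual {record.individual_id!r}: {e}") from None
    return results


class FemurShape(enum.Enum):
    """Subtrochanteric femoral shaft shape classes of the platymeric index."""

    PLATYMERIC = "platymeric"    # index < 85: anteroposteriorly flattened
    EURYMERIC = "eurymeric"      # 85 <= index < 100
    STENOMERIC = "stenomeric"    # index >= 100: mediolaterally flattened


def platymeric_index(
    ap_diameter: float, ml_diameter: float
) -> tuple[float, FemurShape]:
    """Platymeric index and shape class of a femoral shaft.

    ``100 * anteroposterior / mediolateral`` subtrochanteric diameter;
    indices below 85 indicate the anteroposterior flattening seen in the
    diagnostic trait catalog. Boundary values fall in the upper class.
    """
    if ap_diameter <= 0 or ml_diameter <= 0:
        raise ValueError("femoral diameters must be positive")
    index = 100.0 * ap_diameter / ml_diameter
    if index < 85.0:
        shape = FemurShape.PLATYMERIC
    elif index < 100.0:
        shape = FemurShape.EURYMERIC
    else:
        shape = FemurShape.STENOMERIC
    return index, shape
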