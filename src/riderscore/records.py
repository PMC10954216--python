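"""Per-individual records: trait observations, metadata and assemblages."""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

from .catalog import canonical_trait_ids


class TraitState(enum.Enum):
    """Observation state of one diagnostic trait on one skeleton."""

    PRESENT = "+"
    ABSENT = "-"
    UNOBSERVABLE = "?"


class Sex(enum.Enum):
    MALE = "m"
    PROBABLE_MALE = "(m)"
    FEMALE = "f"
    PROBABLE_FEMALE = "(f)"
    UNDETERMINED = "u"


class Culture(enum.Enum):
    YAMNAYA = "Yamnaya"
    PRE_YAMNAYA = "Pre-Yamnaya"
    POST_YAMNAYA = "Post-Yamnaya"
    CORDED_WARE = "Corded Ware"
    COPPER_AGE = "Copper Age"
    MIDDLE_BRONZE_AGE = "Middle Bronze Age"
    OTHER = "Other"


@dataclass(frozen=True)
class TraitObservation:
    """State of one trait, optionally annotated with an expression note."""

    state: TraitState
    expression_note: str | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.state, TraitState):
            raise TypeError(f"state must be a TraitState, got {self.state!r}")


@dataclass(frozen=True)
class SkeletonRecord:
    """One individual: metadata plus the six trait observations.

    ``completeness`` is the estimated preserved percentage of the skeleton
    (0-100); ``age_range`` is the estimated age-at-death interval in years.
    ``reported_score`` is a transcribed published score, never recomputed:
    published scores may embed a severity-of-expression adjustment, so the
    scoring engine compares transcribed and recomputed values explicitly.
    """

    individual_id: str
    observations: dict[str, TraitObservation]
    country: str = ""
    site_label: str = ""
    completeness: float = 100.0
    sex: Sex = Sex.UNDETERMINED
    age_range: tuple[int, int] = (0, 0)
    culture: Culture = Culture.OTHER
    culture_note: str | None = None
    radiocarbon: str | None = None
    reported_score: int | None = None

    def __post_init__(self) -> None:
        expected = canonical_trait_ids()
        got = list(self.observations)
        if sorted(got) != sorted(expected):
            missing = set(expected) - set(got)
            extra = set(got) - set(expected)
            raise ValueError(
                f"individual {self.individual_id!r}: observations must cover "
                f"exactly the canonical traits (missing={sorted(missing)}, "
                f"unexpected={sorted(extra)})"
            )
        if not 0 <= self.completeness <= 100:
            raise ValueError(
                f"individual {self.individual_id!r}: completeness "
                f"{self.completeness} outside [0, 100]"
            )
        lo, hi = self.age_range
        if lo < 0 or lo > hi:
            raise ValueError(
                f"individual {self.individual_id!r}: invalid age range {self.age_range}"
            )
        if self.reported_score is not None and not 0 <= self.reported_score <= 12:
            raise ValueError(
                f"individual {self.individual_id!r}: reported_score "
                f"{self.reported_score} outside [0, 12]"
            )

    def state_of(self, trait_id: str) -> TraitState:
        return self.observations[trait_id].state

    def with_observation(self, trait_id: str, state: TraitState) -> "SkeletonRecord":
        """Copy of this record with one trait set to ``state``."""
        obs = dict(self.observations)
        obs[trait_id] = TraitObservation(state)
        return replace(self, observations=obs)


@dataclass
class Assemblage:
    """An ordered collection of skeleton records with provenance."""

    records: list[SkeletonRecord]
    label: str = ""
    provenance: str = ""
    # hidden ground truth, parallel to records; only set by the synthetic
    # generator (True = rider); never written to trait tables
    true_rider: list[bool] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        ids = [r.individual_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate individual_id values: {dupes}")
        if self.true_rider is not None and len(self.true_rider) != len(self.records):
            raise ValueError("true_rider must align one-to-one with records")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, individual_id: str) -> SkeletonRecord:
        for r in self.records:
            if r.individual_id == individual_id:
                return r
        raise KeyError(individual_id)
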