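"""Assemblage-level demographic and classification summaries."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .records import Assemblage, Culture, Sex
from .scoring import ScoreResult


@dataclass(frozen=True)
class SexCounts:
    """Sex composition of a cohort.

    ``males`` includes probable males and ``females`` probable females,
    following the usual "male or probably male" convention of skeletal
    demography.
    """

    males: int
    females: int
    undetermined: int = 0

    def __post_init__(self) -> None:
        if min(self.males, self.females, self.undetermined) < 0:
            raise ValueError("sex counts must be non-negative")

    @property
    def total(self) -> int:
        return self.males + self.females + self.undetermined


class UndefinedIndexError(ZeroDivisionError):
    """The masculinity index is undefined when there are no females."""


def masculinity_index(counts: SexCounts) -> int:
    """Males per 1000 females, rounded to the nearest integer.

    Rounding is half-away-from-zero (so 2030.77 males-per-1000-females
    reports as 2031). Raises :class:`UndefinedIndexError` when the cohort
    contains no females.
    """
    if counts.females == 0:
        raise UndefinedIndexError(
            "masculinity index undefined: no females in cohort"
        )
    return math.floor(1000 * counts.males / counts.females + 0.5)


def subadult_fraction(n_subadult: int, n_total: int) -> float:
    """Percentage of the cohort that died at subadult age, to one decimal."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_subadult <= n_total:
        raise ValueError("n_subadult must lie in [0, n_total]")
    return round(100.0 * n_subadult / n_total, 1)


@dataclass(frozen=True)
class CohortSummary:
    """Demographic and classification roll-up of a scored assemblage."""

    n_individuals: int
    sex_counts: SexCounts
    masculinity_index: int | None
    subadult_count: int
    subadult_fraction: float | None
    completeness_mean: float | None
    n_positive: int
    positives_by_culture: dict[Culture, int] = field(default_factory=dict)
    trait_count_histogram: dict[int, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_individuals": self.n_individuals,
            "males": self.sex_counts.males,
            "females": self.sex_counts.females,
            "sex_undetermined": self.sex_counts.undetermined,
            "masculinity_index": self.masculinity_index,
            "subadult_count": self.subadult_count,
            "subadult_fraction_pct": self.subadult_fraction,
            "completeness_mean_pct": self.completeness_mean,
            "n_positive": self.n_positive,
            "positives_by_culture": {
                c.value: n for c, n in self.positives_by_culture.items()
            },
            "trait_count_histogram": dict(sorted(self.trait_count_histogram.items())),
        }


_MALE = (Sex.MALE, Sex.PROBABLE_MALE)
_FEMALE = (Sex.FEMALE, Sex.PROBABLE_FEMALE)


def summarize(
    assemblage: Assemblage,
    results: list[ScoreResult],
    subadult_age_cutoff: int = 18,
) -> CohortSummary:
    """Summarize a scored assemblage.

    ``results`` must align one-to-one with the assemblage records. An
    individual counts as subadult when the upper bound of its age
    estimate is below ``subadult_age_cutoff`` years.
    """
    records = assemblage.records
    if len(results) != len(records) or any(
        r.individual_id != s.individual_id for r, s in zip(records, results)
    ):
        raise ValueError("results do not align one-to-one with assemblage records")

    sex_counts = SexCounts(
        males=sum(1 for r in records if r.sex in _MALE),
        females=sum(1 for r in records if r.sex in _FEMALE),
        undetermined=sum(1 for r in records if r.sex is Sex.UNDETERMINED),
    )
    try:
        mi = masculinity_index(sex_counts)
    except UndefinedIndexError:
        mi = None

    n = len(records)
    n_subadult = sum(1 for r in records if r.age_range[1] < subadult_age_cutoff)
    positives_by_culture: dict[Culture, int] = {}
    histogram = {k: 0 for k in range(7)}
    n_positive = 0
    for record, result in zip(records, results):
        histogram[result.trait_count] += 1
        if result.positive:
            n_positive += 1
            positives_by_culture[record.culture] = (
                positives_by_culture.get(record.culture, 0) + 1
            )

    return CohortSummary(
        n_individuals=n,
        sex_counts=sex_counts,
        masculinity_index=mi,
        subadult_count=n_subadult,
        subadult_fraction=subadult_fraction(n_subadult, n) if n else None,
        completeness_mean=round(sum(r.completeness for r in records) / n, 1)
        if n
        else None,
        n_positive=n_positive,
        positives_by_culture=positives_by_culture,
        trait_count_histogram=histogram,
    )
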