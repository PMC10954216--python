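"""Reading and writing trait-observation tables, and the packaged fixture.

The on-disk format is a delimited UTF-8 text table (TSV by default, CSV
accepted) with one header row and one row per skeleton:

    individual_id, country, site_label, completeness, sex, age_low,
    age_high, culture, <six trait columns in canonical order>,
    [reported_score]

Trait cells use the field's conventional symbols: ``+`` present, ``-``
absent (the Unicode minus ``−`` is accepted on input), ``?`` not
preserved. Unknown symbols are reported as errors with the offending row
and column, never silently coerced.
"""

from __future__ import annotations

import re
from importlib import resources
from pathlib import Path

import pandas as pd

from .catalog import canonical_trait_ids
from .records import (
    Assemblage,
    Culture,
    Sex,
    SkeletonRecord,
    TraitObservation,
    TraitState,
)


class TraitTableError(ValueError):
    """Base class for trait-table reading problems."""


class SchemaError(TraitTableError):
    """A required column is missing or the header is malformed."""


class ParseError(TraitTableError):
    """A cell value could not be interpreted; names the row and column."""


_STATE_SYMBOLS = {
    "+": TraitState.PRESENT,
    "-": TraitState.ABSENT,
    "−": TraitState.ABSENT,  # Unicode minus, as printed in typeset tables
    "?": TraitState.UNOBSERVABLE,
}

_SEX_SYMBOLS = {
    "m": Sex.MALE,
    "(m)": Sex.PROBABLE_MALE,
    "f": Sex.FEMALE,
    "(f)": Sex.PROBABLE_FEMALE,
    "u": Sex.UNDETERMINED,
    "": Sex.UNDETERMINED,
}


def parse_state(symbol: str) -> TraitState:
    """Map a trait-cell symbol to a :class:`TraitState`."""
    sym = str(symbol).strip()
    try:
        return _STATE_SYMBOLS[sym]
    except KeyError:
        raise ParseError(f"unknown trait state symbol {symbol!r}") from None


def parse_sex(value: str) -> Sex:
    v = str(value).strip()
    if v in _SEX_SYMBOLS:
        return _SEX_SYMBOLS[v]
    try:
        return Sex[v.upper()]
    except KeyError:
        raise ParseError(f"unknown sex value {value!r}") from None


def parse_culture(value: str) -> tuple[Culture, str | None]:
    """Normalize a cultural-assignment string.

    Parenthetical doubts (e.g. ``"Pre-Yamnaya (early Yamnaya?)"``) are
    preserved as a free-text note; classification counts use the
    normalized value.
    """
    v = str(value).strip()
    note = None
    m = re.match(r"^(.*?)\s*\((.*)\)\s*$", v)
    if m:
        v, note = m.group(1).strip(), m.group(2).strip()
    for culture in Culture:
        if v.lower() == culture.value.lower() or v.upper() == culture.name:
            return culture, note
    raise ParseError(f"unknown culture value {value!r}")


def parse_age_range(value: str) -> tuple[int, int]:
    """Parse ``"25-35"`` / ``"25–35 years"`` style age intervals."""
    v = str(value).strip()
    m = re.match(r"^(\d+)\s*[-–]\s*(\d+)(?:\s*years?)?$", v)
    if m:
        return int(m.group(1)), int(m.group(2))
    m = re.match(r"^(\d+)(?:\s*years?)?$", v)
    if m:
        return int(m.group(1)), int(m.group(1))
    raise ParseError(f"cannot parse age range {value!r}")


_META_COLUMNS = [
    "individual_id",
    "country",
    "site_label",
    "completeness",
    "sex",
    "age_low",
    "age_high",
    "culture",
]


def _sniff_sep(path: Path, dialect: str | None) -> str:
    if dialect in ("tsv", "\t"):
        return "\t"
    if dialect in ("csv", ","):
        return ","
    if dialect is not None:
        raise ValueError(f"unknown dialect {dialect!r}; use 'tsv' or 'csv'")
    return "\t" if path.suffix.lower() != ".csv" else ","


def read_trait_table(path: str | Path, dialect: str | None = None) -> Assemblage:
    """Read a trait-observation table into an :class:`Assemblage`.

    Parameters
    ----------
    path
        Delimited text file. The separator follows ``dialect`` (``"tsv"``
        or ``"csv"``); by default it is inferred from the file suffix.
    """
    path = Path(path)
    sep = _sniff_sep(path, dialect)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)

    trait_ids = canonical_trait_ids()
    missing = [c for c in _META_COLUMNS + trait_ids if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns: {missing}")
    has_score = "reported_score" in df.columns

    records = []
    for idx, row in df.iterrows():
        ind = str(row["individual_id"]).strip()
        observations = {}
        for tid in trait_ids:
            try:
                observations[tid] = TraitObservation(parse_state(row[tid]))
            except ParseError as e:
                raise ParseError(
                    f"{path}: row {idx + 2} (individual {ind!r}), column {tid!r}: {e}"
                ) from None
        try:
            culture, note = parse_culture(row["culture"])
            score_raw = str(row["reported_score"]).strip() if has_score else ""
            records.append(
                SkeletonRecord(
                    individual_id=ind,
                    observations=observations,
                    country=str(row["country"]).strip(),
                    site_label=str(row["site_label"]).strip(),
                    completeness=float(row["completeness"]),
                    sex=parse_sex(row["sex"]),
                    age_range=(int(row["age_low"]), int(row["age_high"])),
                    culture=culture,
                    culture_note=note,
                    radiocarbon=(str(row["radiocarbon"]).strip() or None)
                    if "radiocarbon" in df.columns
                    else None,
                    reported_score=int(score_raw) if score_raw else None,
                )
            )
        except (ParseError, ValueError) as e:
            raise ParseError(f"{path}: row {idx + 2} (individual {ind!r}): {e}") from None

    return Assemblage(records=records, label=path.stem, provenance=f"file:{path}")


def write_trait_table(
    assemblage: Assemblage, path: str | Path, dialect: str | None = None
) -> None:
    """Write an assemblage as a delimited trait table.

    The output round-trips through :func:`read_trait_table` losslessly;
    absent traits are written with the ASCII hyphen.
    """
    path = Path(path)
    sep = _sniff_sep(path, dialect)
    trait_ids = canonical_trait_ids()
    rows = []
    for r in assemblage:
        row = {
            "individual_id": r.individual_id,
            "country": r.country,
            "site_label": r.site_label,
            "completeness": r.completeness,
            "sex": r.sex.value,
            "age_low": r.age_range[0],
            "age_high": r.age_range[1],
            "culture": r.culture.value
            if r.culture_note is None
            else f"{r.culture.value} ({r.culture_note})",
            "radiocarbon": r.radiocarbon or "",
        }
        for tid in trait_ids:
            row[tid] = r.state_of(tid).value
        row["reported_score"] = "" if r.reported_score is None else r.reported_score
        rows.append(row)
    columns = _META_COLUMNS + ["radiocarbon"] + trait_ids + ["reported_score"]
    pd.DataFrame(rows, columns=columns).to_csv(path, sep=sep, index=False)


def load_fixture() -> Assemblage:
    """Load the packaged reference assemblage.

    Returns the 24 published individuals (ids 032-215) that display at
    least three of the six diagnostic traits, with their trait
    observations, published scores, and burial metadata. The loader
    cross-checks each individual's recomputed trait count against the
    published per-individual count and fails hard on any mismatch.
    """
    data = resources.files("riderscore.data")
    with resources.as_file(data / "trait_observations.tsv") as p:
        obs_df = pd.read_csv(p, sep="\t", dtype=str)
    with resources.as_file(data / "individual_metadata.tsv") as p:
        meta_df = pd.read_csv(p, sep="\t", dtype=str, keep_default_na=False)

    meta = meta_df.set_index("individual_id")
    trait_ids = canonical_trait_ids()
    records = []
    for _, row in obs_df.iterrows():
        ind = row["individual_id"]
        if ind not in meta.index:
            raise TraitTableError(f"fixture: individual {ind!r} missing from metadata")
        observations = {}
        for tid in trait_ids:
            try:
                observations[tid] = TraitObservation(parse_state(row[tid]))
            except ParseError as e:
                raise TraitTableError(
                    f"fixture: individual {ind!r}, column {tid!r}: {e}"
                ) from None
        n_present = sum(
            1 for o in observations.values() if o.state is TraitState.PRESENT
        )
        if n_present != int(row["n_traits"]):
            raise TraitTableError(
                f"fixture: individual {ind!r}: recomputed trait count {n_present} "
                f"!= published count {row['n_traits']}"
            )
        m = meta.loc[ind]
        culture, note = parse_culture(m["culture"])
        records.append(
            SkeletonRecord(
                individual_id=ind,
                observations=observations,
                country=m["country"],
                site_label=m["site_label"],
                completeness=float(m["completeness"]),
                sex=parse_sex(m["sex"]),
                age_range=parse_age_range(m["age"]),
                culture=culture,
                culture_note=note,
                radiocarbon=m["radiocarbon"] or None,
                reported_score=int(m["reported_score"]),
            )
        )
    if len(records) != 24:
        raise TraitTableError(f"fixture: expected 24 individuals, found {len(records)}")
    return Assemblage(records=records, label="published-24", provenance="fixture")
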