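"""Interaction-record data model, CSV input/output and per-individual summaries.

One row of the record table is one communicative act: an immature signaller
(with fixed attributes: species, research setting, group, sex, age) directs
one non-vocal signal type at one partner class (mother, peer, or older
non-mother conspecific), with a presumed social goal coded by the observer.

The canonical in-memory container is a :class:`pandas.DataFrame` with the
columns of :data:`RECORD_COLUMNS`; :class:`InteractionRecord` is the
row-level view used for single-record construction and round-tripping.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

SPECIES_LEVELS = ("bornean", "sumatran")
SETTING_LEVELS = ("wild", "captive")
SEX_LEVELS = ("female", "male")
PARTNER_CLASSES = ("mother", "peer", "older")
#: partner scopes accepted by downstream analyses; "other" = peer + older
PARTNER_SCOPES = ("mother", "other", "peer", "older")
SOCIAL_GOALS = (
    "co_locomote",
    "share_food_object",
    "groom",
    "play_affiliate",
    "move_away",
    "sexual_contact",
    "stop_action",
)

RECORD_COLUMNS = (
    "record_id",
    "individual_id",
    "species",
    "setting",
    "group_id",
    "sex",
    "age_years",
    "partner_class",
    "signal_type",
    "social_goal",
)

#: attributes that must be constant within an individual
_INDIVIDUAL_ATTRS = ("species", "setting", "group_id", "sex")

_ENUM_FIELDS = {
    "species": SPECIES_LEVELS,
    "setting": SETTING_LEVELS,
    "sex": SEX_LEVELS,
    "partner_class": PARTNER_CLASSES,
    "social_goal": SOCIAL_GOALS,
}


class RecordValidationError(ValueError):
    """A record table violated the schema; the message names row and field."""


@dataclass(frozen=True)
class InteractionRecord:
    """A single communicative act."""

    record_id: str
    individual_id: str
    species: str
    setting: str
    group_id: str
    sex: str
    age_years: float
    partner_class: str
    signal_type: str
    social_goal: str

    def __post_init__(self) -> None:
        for field, levels in _ENUM_FIELDS.items():
            value = getattr(self, field)
            if value not in levels:
                raise RecordValidationError(
                    f"field {field!r}: {value!r} not in {levels}"
                )
        if self.age_years < 0:
            raise RecordValidationError(
                f"field 'age_years': {self.age_years} is negative"
            )
        if not self.signal_type:
            raise RecordValidationError("field 'signal_type': empty label")


@dataclass(frozen=True)
class IndividualProfile:
    """One immature subject with its fixed attributes and observation effort.

    ``effort_by_partner_class`` counts signal instances separately for the
    mother / peer / older partner classes; the "other" scope (peer + older)
    is always derived, never stored.
    """

    individual_id: str
    species: str
    setting: str
    group_id: str
    sex: str
    age_years: float
    effort_by_partner_class: Mapping[str, int]

    def effort(self, scope: str) -> int:
        """Signal instances contributed within a partner scope."""
        if scope == "other":
            return self.effort_by_partner_class.get("peer", 0) + (
                self.effort_by_partner_class.get("older", 0)
            )
        if scope not in PARTNER_CLASSES:
            raise ValueError(f"unknown partner scope {scope!r}")
        return self.effort_by_partner_class.get(scope, 0)


def validate_records(frame: pd.DataFrame) -> pd.DataFrame:
    """Validate a record table against the schema.

    Checks column presence, enum levels, age parseability/sign, non-empty
    signal types, record-id uniqueness, and constancy of individual
    attributes across repeated ``individual_id``.  Errors carry the 1-based
    data-row number (header excluded).  If an individual appears with more
    than one age, ages are averaged with a warning (one age per immature is
    assumed for the study period).

    Returns the validated frame (a copy with ``age_years`` as float).
    """
    missing = [c for c in RECORD_COLUMNS if c not in frame.columns]
    if missing:
        raise RecordValidationError(f"missing column(s): {', '.join(missing)}")
    frame = frame.loc[:, list(RECORD_COLUMNS)].copy()
    frame.index = pd.RangeIndex(1, len(frame) + 1)

    for field, levels in _ENUM_FIELDS.items():
        bad = ~frame[field].isin(levels)
        if bad.any():
            row = int(frame.index[bad][0])
            raise RecordValidationError(
                f"row {row}, field {field!r}: {frame[field][row]!r} "
                f"not in {levels}"
            )
    age = pd.to_numeric(frame["age_years"], errors="coerce")
    bad = age.isna()
    if bad.any():
        row = int(frame.index[bad][0])
        raise RecordValidationError(
            f"row {row}, field 'age_years': {frame['age_years'][row]!r} "
            "is not a number"
        )
    if (age < 0).any():
        row = int(frame.index[age < 0][0])
        raise RecordValidationError(
            f"row {row}, field 'age_years': negative age {age[row]}"
        )
    frame["age_years"] = age.astype(float)

    empty = frame["signal_type"].astype(str).str.len() == 0
    if empty.any():
        row = int(frame.index[empty][0])
        raise RecordValidationError(f"row {row}, field 'signal_type': empty label")

    dup = frame["record_id"].duplicated()
    if dup.any():
        row = int(frame.index[dup][0])
        raise RecordValidationError(
            f"row {row}, field 'record_id': duplicate id "
            f"{frame['record_id'][row]!r}"
        )

    for attr in _INDIVIDUAL_ATTRS:
        per_ind = frame.groupby("individual_id")[attr].nunique()
        if (per_ind > 1).any():
            ind = per_ind.index[per_ind > 1][0]
            rows = frame.index[frame["individual_id"] == ind]
            raise RecordValidationError(
                f"row {int(rows[1])}, field {attr!r}: individual {ind!r} has "
                "inconsistent values across records"
            )
    multi_age = frame.groupby("individual_id")["age_years"].nunique()
    if (multi_age > 1).any():
        inds = list(multi_age.index[multi_age > 1])
        warnings.warn(
            f"multiple ages for individual(s) {inds}; using the mean age",
            stacklevel=2,
        )
        mean_age = frame.groupby("individual_id")["age_years"].transform("mean")
        frame["age_years"] = mean_age
    frame.index = pd.RangeIndex(len(frame))
    return frame


def read_records(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Read and validate a record CSV (UTF-8, comma-separated, header row).

    ``column_map`` renames foreign column names to the canonical schema
    (``{"their_name": "canonical_name"}``), the adaptation point for
    externally deposited tables.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    if column_map:
        frame = frame.rename(columns=dict(column_map))
    return validate_records(frame)


def write_records(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a validated record table to CSV (round-trips with read_records)."""
    frame.loc[:, list(RECORD_COLUMNS)].to_csv(path, index=False)


def records_to_frame(records: Iterable[InteractionRecord]) -> pd.DataFrame:
    """Build a validated record table from row objects."""
    rows = [asdict(r) for r in records]
    frame = pd.DataFrame(rows, columns=list(RECORD_COLUMNS))
    return validate_records(frame)


def frame_to_records(frame: pd.DataFrame) -> list[InteractionRecord]:
    """Row-object view of a validated record table (file order preserved)."""
    return [
        InteractionRecord(**{k: row[k] for k in RECORD_COLUMNS})
        for row in frame.to_dict("records")
    ]


def profile_individuals(frame: pd.DataFrame) -> list[IndividualProfile]:
    """Summarise a validated record table into one profile per individual.

    Effort counts are partitioned by stored partner class (mother / peer /
    older); their sum over all individuals equals the total record count.
    Profiles are ordered by first appearance in the table.
    """
    if len(frame) == 0:
        return []
    profiles = []
    for ind, sub in frame.groupby("individual_id", sort=False):
        counts = sub["partner_class"].value_counts().to_dict()
        first = sub.iloc[0]
        profiles.append(
            IndividualProfile(
                individual_id=str(ind),
                species=first["species"],
                setting=first["setting"],
                group_id=first["group_id"],
                sex=first["sex"],
                age_years=float(first["age_years"]),
                effort_by_partner_class={
                    cls: int(counts.get(cls, 0)) for cls in PARTNER_CLASSES
                },
            )
        )
    return profiles


def write_profiles(profiles: Sequence[IndividualProfile], path: str | Path) -> None:
    """Serialise profiles to JSON."""
    payload = [asdict(p) for p in profiles]
    Path(path).write_text(json.dumps(payload, indent=2))


def read_profiles(path: str | Path) -> list[IndividualProfile]:
    payload = json.loads(Path(path).read_text())
    return [IndividualProfile(**p) for p in payload]
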