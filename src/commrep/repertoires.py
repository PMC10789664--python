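"""Customary-repertoire construction: eligibility and usage filters.

Two filters turn raw interaction records into conservative, "customarily
used" repertoires:

* **eligibility** — an individual enters the analysis for a partner scope
  only if it contributed strictly more than ``min_interactions`` (default
  30) signal instances within that scope;
* **customary use** — a signal type belongs to the repertoire only if the
  individual used it at least ``min_uses`` (default 2) times within the
  scope.

A partner scope is one of ``mother``, ``other`` (= peer + older), ``peer``
or ``older``; mother- and other-scope repertoires are computed from
disjoint record subsets.  Social-goal diversity (the number of distinct
presumed goals) is filtered with the same occurrence threshold by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from commrep.records import IndividualProfile, PARTNER_SCOPES

DEFAULT_MIN_INTERACTIONS = 30
DEFAULT_MIN_USES = 2


@dataclass(frozen=True)
class Repertoire:
    """Per (individual, partner scope) customary signal repertoire.

    ``size`` is the response of the repertoire-size models; ``goal_count``
    (number of distinct presumed social goals pursued at least
    ``goal_min_uses`` times in scope) is the response of the social-goal
    models.  ``effort`` is the number of signal instances in scope, the
    observation-effort control covariate.
    """

    individual_id: str
    partner_class_scope: str
    signal_types: frozenset[str]
    effort: int
    goal_set: frozenset[str] = field(default_factory=frozenset)

    @property
    def size(self) -> int:
        return len(self.signal_types)

    @property
    def goal_count(self) -> int:
        return len(self.goal_set)


def _scope_mask(frame: pd.DataFrame, scope: str) -> pd.Series:
    if scope == "other":
        return frame["partner_class"].isin(("peer", "older"))
    if scope not in PARTNER_SCOPES:
        raise ValueError(f"unknown partner scope {scope!r}")
    return frame["partner_class"] == scope


def select_eligible(
    profiles: Sequence[IndividualProfile],
    scope: str,
    min_interactions: int = DEFAULT_MIN_INTERACTIONS,
) -> set[str]:
    """Individuals with strictly more than ``min_interactions`` instances in scope.

    The threshold is strict (effort 30 is excluded, 31 included); an
    individual may be eligible for one scope and not another.
    """
    if scope not in PARTNER_SCOPES:
        raise ValueError(f"unknown partner scope {scope!r}")
    return {
        p.individual_id for p in profiles if p.effort(scope) > min_interactions
    }


def build_repertoire(
    frame: pd.DataFrame,
    individual_id: str,
    scope: str,
    min_uses: int = DEFAULT_MIN_USES,
    goal_min_uses: int | None = None,
) -> Repertoire:
    """Customary repertoire of one individual within one partner scope.

    ``goal_min_uses`` defaults to ``min_uses`` so goals and signal types are
    filtered consistently; pass 1 to count every observed goal.
    """
    if goal_min_uses is None:
        goal_min_uses = min_uses
    sub = frame[(frame["individual_id"] == individual_id) & _scope_mask(frame, scope)]
    type_counts = sub["signal_type"].value_counts()
    goal_counts = sub["social_goal"].value_counts()
    return Repertoire(
        individual_id=individual_id,
        partner_class_scope=scope,
        signal_types=frozenset(type_counts.index[type_counts >= min_uses]),
        effort=int(len(sub)),
        goal_set=frozenset(goal_counts.index[goal_counts >= goal_min_uses]),
    )


def build_repertoires(
    frame: pd.DataFrame,
    profiles: Sequence[IndividualProfile],
    scope: str,
    min_interactions: int = DEFAULT_MIN_INTERACTIONS,
    min_uses: int = DEFAULT_MIN_USES,
    goal_min_uses: int | None = None,
) -> list[Repertoire]:
    """Repertoires of all scope-eligible individuals, in profile order."""
    eligible = select_eligible(profiles, scope, min_interactions)
    return [
        build_repertoire(frame, p.individual_id, scope, min_uses, goal_min_uses)
        for p in profiles
        if p.individual_id in eligible
    ]


def inventory_counts(
    repertoires: Iterable[Repertoire],
    profiles: Sequence[IndividualProfile],
) -> pd.DataFrame:
    """Population-level inventory: distinct customary signal types per cell.

    Each cell of the returned table is the size of the union of individual
    customary repertoires for one (setting x species) population, with
    pooled ``all`` margins, one row per partner scope present in the input.
    Columns are a (setting, species) MultiIndex including margins.
    """
    reps = list(repertoires)
    if not reps:
        raise ValueError("empty repertoire collection")
    attrs = {p.individual_id: p for p in profiles}
    rows: dict[str, dict[tuple[str, str], set[str]]] = {}
    for rep in reps:
        prof = attrs[rep.individual_id]
        cell_keys = [
            (prof.setting, prof.species),
            (prof.setting, "all"),
            ("all", "all"),
        ]
        scope_row = rows.setdefault(rep.partner_class_scope, {})
        for key in cell_keys:
            scope_row.setdefault(key, set()).update(rep.signal_types)
    columns = sorted({key for row in rows.values() for key in row})
    table = pd.DataFrame(
        {
            col: {scope: len(rows[scope].get(col, set())) for scope in rows}
            for col in columns
        }
    )
    table.columns = pd.MultiIndex.from_tuples(columns, names=["setting", "species"])
    table.index.name = "scope"
    return table


def raw_inventory_counts(
    frame: pd.DataFrame, scope: str
) -> pd.DataFrame:
    """Unfiltered variant: distinct observed signal types per cell.

    Counts every observed type in scope regardless of the per-individual
    customary-use filter, for comparison with the filtered inventory.
    """
    sub = frame[_scope_mask(frame, scope)]
    if len(sub) == 0:
        raise ValueError(f"no records in scope {scope!r}")
    cells: dict[tuple[str, str], int] = {}
    for (setting, species), grp in sub.groupby(["setting", "species"]):
        cells[(setting, species)] = grp["signal_type"].nunique()
    for setting, grp in sub.groupby("setting"):
        cells[(setting, "all")] = grp["signal_type"].nunique()
    cells[("all", "all")] = sub["signal_type"].nunique()
    table = pd.DataFrame({col: {scope: n} for col, n in sorted(cells.items())})
    table.columns = pd.MultiIndex.from_tuples(
        sorted(cells), names=["setting", "species"]
    )
    table.index.name = "scope"
    return table


def write_repertoires(reps: Sequence[Repertoire], path: str | Path) -> None:
    payload = []
    for rep in reps:
        d = asdict(rep)
        d["signal_types"] = sorted(rep.signal_types)
        d["goal_set"] = sorted(rep.goal_set)
        d["size"] = rep.size
        d["goal_count"] = rep.goal_count
        payload.append(d)
    Path(path).write_text(json.dumps(payload, indent=2))


def read_repertoires(path: str | Path) -> list[Repertoire]:
    payload = json.loads(Path(path).read_text())
    return [
        Repertoire(
            individual_id=d["individual_id"],
            partner_class_scope=d["partner_class_scope"],
            signal_types=frozenset(d["signal_types"]),
            effort=int(d["effort"]),
            goal_set=frozenset(d["goal_set"]),
        )
        for d in payload
    ]
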