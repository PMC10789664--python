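"""Dyadic Dice similarity and matrix-permutation inference.

Repertoire overlap between two individuals A and B is the Dice coefficient

    D_C = 2 * C_AB / (R_A + R_B),

where ``C_AB`` is the number of signal types shared by A and B and ``R_A``,
``R_B`` are their repertoire sizes.  Because every individual contributes to
many dyads, the pairwise values in a Dice matrix are non-independent row-
and column-wise; inference therefore permutes the per-individual setting
labels (jointly over rows and columns, the matrix values held fixed) and
rebuilds the contrast statistic under each relabelling.

Two contrasts are supported:

* ``within_vs_between`` — mean Dice of same-setting dyads (wild-wild and
  captive-captive pooled) minus mean Dice of contrasting-setting dyads;
* ``captive_within_vs_wild_within`` — mean captive-captive minus mean
  wild-wild Dice.

P values are upper-tail positions of the observed statistic in the null
distribution with an add-one correction, and the decision rule uses the
asymmetric thresholds P <= 0.025 (observed significantly high) and
P >= 0.975 (observed significantly low), i.e. 2.5% per tail.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

COMPARISONS = ("within_vs_between", "captive_within_vs_wild_within")

#: asymmetric two-tailed decision thresholds (2.5% per tail)
P_LOW_THRESHOLD = 0.025
P_HIGH_THRESHOLD = 0.975

DEFAULT_N_PERM = 1000
DEFAULT_SEED = 20180101


def dice_coefficient(rep_a: Iterable[str], rep_b: Iterable[str]) -> float:
    """Dice set-overlap similarity 2|A∩B|/(|A|+|B|) in [0, 1].

    Equals 1 iff the repertoires are equal and non-empty, 0 iff disjoint.
    Undefined (raises) when both are empty.
    """
    a, b = set(rep_a), set(rep_b)
    if not a and not b:
        raise ValueError("Dice coefficient undefined for two empty repertoires")
    return 2.0 * len(a & b) / (len(a) + len(b))


@dataclass(frozen=True)
class DiceMatrix:
    """Symmetric dyadic similarity matrix for one species x partner scope.

    The diagonal is fixed at 1 by convention and excluded from every
    statistic; the n(n-1)/2 upper-triangle entries are the informative
    dyads.  ``settings`` holds the per-individual setting labels used by
    the permutation tests.
    """

    individual_ids: tuple[str, ...]
    values: np.ndarray
    settings: tuple[str, ...]
    species: str = ""
    scope: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.individual_ids)
        if v.shape != (n, n):
            raise ValueError("matrix shape does not match individual count")
        if len(self.settings) != n:
            raise ValueError("one setting label per individual required")
        if not np.allclose(v, v.T):
            raise ValueError("Dice matrix must be symmetric")
        off = v[~np.eye(n, dtype=bool)]
        if off.size and (off.min() < 0 or off.max() > 1):
            raise ValueError("Dice values must lie in [0, 1]")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return len(self.individual_ids)

    def pair_table(self) -> pd.DataFrame:
        """Long form: one row per unordered dyad with its pair category."""
        i, j = np.triu_indices(self.n, k=1)
        s = np.asarray(self.settings)
        same = s[i] == s[j]
        category = np.where(
            same, np.char.add(np.char.add(s[i], "-"), s[j]), "between"
        )
        return pd.DataFrame(
            {
                "id_a": np.asarray(self.individual_ids)[i],
                "id_b": np.asarray(self.individual_ids)[j],
                "dice": self.values[i, j],
                "within": same,
                "category": category,
            }
        )

    def to_csv(self, path) -> None:
        frame = pd.DataFrame(
            self.values, index=self.individual_ids, columns=self.individual_ids
        )
        frame.insert(0, "setting", self.settings)
        frame.to_csv(path, index_label="individual_id")


def dice_matrix_from_csv(path, species: str = "", scope: str = "") -> DiceMatrix:
    frame = pd.read_csv(path, index_col="individual_id")
    settings = tuple(frame.pop("setting"))
    return DiceMatrix(
        individual_ids=tuple(frame.index.astype(str)),
        values=frame.to_numpy(dtype=float),
        settings=settings,
        species=species,
        scope=scope,
    )


def build_dice_matrix(
    repertoires: Sequence, settings_by_id: Mapping[str, str],
    species: str = "", scope: str = ""
) -> DiceMatrix:
    """Pairwise Dice matrix over the repertoires of one species x scope.

    Cross-species dyads are never formed: the caller passes repertoires of
    a single species, and the tests are run separately per species.
    """
    if len(repertoires) < 2:
        raise ValueError("need at least 2 individuals for a Dice matrix")
    ids = tuple(r.individual_id for r in repertoires)
    sets = [r.signal_types for r in repertoires]
    n = len(ids)
    values = np.eye(n)
    for i, j in itertools.combinations(range(n), 2):
        values[i, j] = values[j, i] = dice_coefficient(sets[i], sets[j])
    return DiceMatrix(
        individual_ids=ids,
        values=values,
        settings=tuple(settings_by_id[i] for i in ids),
        species=species,
        scope=scope,
    )


def _pair_arrays(matrix: DiceMatrix):
    i, j = np.triu_indices(matrix.n, k=1)
    return i, j, matrix.values[i, j]


def _stat_from_labels(
    labels: np.ndarray, i: np.ndarray, j: np.ndarray, vals: np.ndarray,
    comparison: str,
) -> np.ndarray:
    """Contrast statistic for one (1-D) or many (2-D) label vectors."""
    labels = np.atleast_2d(labels)
    captive = labels == "captive"
    li, lj = captive[:, i], captive[:, j]
    if comparison == "within_vs_between":
        mask_a = li == lj          # within (either setting)
        mask_b = ~mask_a           # between
    elif comparison == "captive_within_vs_wild_within":
        mask_a = li & lj           # captive-captive
        mask_b = ~li & ~lj         # wild-wild
    else:
        raise ValueError(f"unknown comparison {comparison!r}")
    na, nb = mask_a.sum(axis=1), mask_b.sum(axis=1)
    if (na == 0).any() or (nb == 0).any():
        raise ValueError(
            f"comparison {comparison!r}: a contrasted pair category is empty"
        )
    mean_a = (vals * mask_a).sum(axis=1) / na
    mean_b = (vals * mask_b).sum(axis=1) / nb
    return mean_a - mean_b


def overlap_statistic(matrix: DiceMatrix, comparison: str) -> float:
    """Observed contrast of mean Dice between the two pair categories."""
    i, j, vals = _pair_arrays(matrix)
    return float(
        _stat_from_labels(np.asarray(matrix.settings), i, j, vals, comparison)[0]
    )


@dataclass(frozen=True)
class PermutationResult:
    """Outcome of a matrix-permutation (or exact enumeration) test."""

    comparison: str
    observed_stat: float
    null_stats: np.ndarray = field(repr=False)
    p_value: float
    n_perm: int
    seed: int | None
    decision: str
    #: raw tail proportion #{null >= observed} / n_perm (no add-one)
    p_raw: float
    #: lower-tail counterpart (#{null <= observed} + 1) / (n_perm + 1)
    p_lower: float
    exact: bool = False

    def to_dict(self) -> dict:
        d = {
            "comparison": self.comparison,
            "observed_stat": self.observed_stat,
            "p_value": self.p_value,
            "p_raw": self.p_raw,
            "p_lower": self.p_lower,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "decision": self.decision,
            "exact": self.exact,
            "null_stats": np.asarray(self.null_stats).tolist(),
        }
        return d


def _decide(p_value: float) -> str:
    if p_value <= P_LOW_THRESHOLD:
        return "significant_high"
    if p_value >= P_HIGH_THRESHOLD:
        return "significant_low"
    return "ns"


def _check_labels(settings: Sequence[str]) -> None:
    levels = set(settings)
    if not levels <= {"wild", "captive"}:
        raise ValueError(f"setting labels must be wild/captive, got {levels}")
    if len(levels) < 2:
        raise ValueError("degenerate label vector: all individuals in one setting")


def matrix_permutation_test(
    matrix: DiceMatrix,
    comparison: str,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = DEFAULT_SEED,
) -> PermutationResult:
    """Monte-Carlo matrix-permutation test of a setting contrast.

    The null distribution is built by randomly permuting the per-individual
    setting labels (equivalently, jointly permuting rows and columns of the
    fixed Dice matrix) and recomputing the contrast statistic; group sizes
    are preserved by construction.  ``p_value`` is the upper-tail position
    (#{null >= observed} + 1) / (n_perm + 1), so ties count as at least as
    extreme and p is never 0.  Reproducible given ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    _check_labels(matrix.settings)
    i, j, vals = _pair_arrays(matrix)
    labels = np.asarray(matrix.settings)
    observed = float(_stat_from_labels(labels, i, j, vals, comparison)[0])
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(labels) for _ in range(n_perm)])
    null = _stat_from_labels(perms, i, j, vals, comparison)
    n_ge = int((null >= observed).sum())
    n_le = int((null <= observed).sum())
    p_value = (n_ge + 1) / (n_perm + 1)
    return PermutationResult(
        comparison=comparison,
        observed_stat=observed,
        null_stats=null,
        p_value=p_value,
        n_perm=n_perm,
        seed=seed,
        decision=_decide(p_value),
        p_raw=n_ge / n_perm,
        p_lower=(n_le + 1) / (n_perm + 1),
        exact=False,
    )


def exact_permutation_test(
    matrix: DiceMatrix, comparison: str, max_assignments: int = 100_000
) -> PermutationResult:
    """Exact test by complete enumeration of setting-label assignments.

    Enumerates every assignment of the observed numbers of wild and captive
    labels to individuals (the observed labelling included), so the p value
    is exact: p = #{assignments with statistic >= observed} / #assignments.
    Usable as an oracle for the Monte-Carlo test when C(n, n_captive) is
    below ``max_assignments``.
    """
    _check_labels(matrix.settings)
    labels = np.asarray(matrix.settings)
    n = matrix.n
    n_captive = int((labels == "captive").sum())
    total = comb(n, n_captive)
    if total > max_assignments:
        raise ValueError(
            f"{total} label assignments exceed the cap of {max_assignments}"
        )
    i, j, vals = _pair_arrays(matrix)
    observed = float(_stat_from_labels(labels, i, j, vals, comparison)[0])
    assignments = np.full((total, n), "wild", dtype=labels.dtype)
    for row, captive_idx in enumerate(
        itertools.combinations(range(n), n_captive)
    ):
        assignments[row, list(captive_idx)] = "captive"
    null = _stat_from_labels(assignments, i, j, vals, comparison)
    n_ge = int((null >= observed).sum())
    n_le = int((null <= observed).sum())
    p_value = n_ge / total
    return PermutationResult(
        comparison=comparison,
        observed_stat=observed,
        null_stats=null,
        p_value=p_value,
        n_perm=total,
        seed=None,
        decision=_decide(p_value),
        p_raw=n_ge / total,
        p_lower=n_le / total,
        exact=True,
    )


def mean_dice_table(matrices: Mapping[tuple[str, str], DiceMatrix]) -> pd.DataFrame:
    """Mean Dice per pair category, one column per (species, scope).

    Rows: within settings (pooled), between settings, within captive only,
    within wild only.  Categories with no dyads are reported as missing.
    Values are arithmetic means at full precision; display rounding (2
    decimals) is left to the renderer.
    """
    rows = (
        "within_settings",
        "between_settings",
        "within_captive_only",
        "within_wild_only",
    )
    out = {}
    for key, matrix in matrices.items():
        pairs = matrix.pair_table()
        cat = pairs["category"]
        means = {
            "within_settings": pairs.loc[pairs["within"], "dice"].mean(),
            "between_settings": pairs.loc[~pairs["within"], "dice"].mean(),
            "within_captive_only": pairs.loc[cat == "captive-captive", "dice"].mean(),
            "within_wild_only": pairs.loc[cat == "wild-wild", "dice"].mean(),
        }
        out[key] = {r: means[r] for r in rows}
    table = pd.DataFrame(out)
    table.columns = pd.MultiIndex.from_tuples(
        table.columns, names=["species", "scope"]
    )
    table.index.name = "pair_category"
    return table.loc[list(rows)]
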