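"""Synthetic interaction-record generator with known ground truth.

The generator emulates the statistical structure the downstream analyses
assume, at the scale of the study population it mirrors: two orangutan
species crossed with two research settings (one field site per species,
several zoos), a global inventory of 41 non-vocal signal types, seven
presumed social goals, and per-individual observation effort between 32 and
776 signal instances per partner scope (with an optional sub-threshold
fraction to exercise the eligibility filter).

Latent model, per individual i in group g (zoo or field site):

* **repertoire size** — the other-directed latent repertoire size is
  Poisson with mean ``base_size_other * exp(beta_setting * captive_i +
  beta_species * sumatran_i + b_g)`` where ``b_g ~ N(0, sigma_group^2)``;
  mother-directed sizes use ``base_size_mother`` with no setting or
  species effect, matching the study's finding that wild-captive contrasts
  arise in interactions beyond the mother-offspring bond;
* **repertoire composition** — each (species, setting, scope) cell owns a
  "setting core" of signal types sampled from the global inventory with a
  Zipf-like weight (common types in every core); an individual takes the
  commonest ``min(k_i, core size)`` core types plus individually private
  types, so within-setting overlap exceeds between-setting overlap, with
  the contrast tuned by ``core_fraction``;
* **records** — effort draws per scope, then multinomial draws of signal
  types from the latent repertoire with a Zipf-like frequency skew (so
  singleton uses occur and the >=2 customary-use filter is non-trivial),
  and categorical social-goal draws identical across settings.

``null_scenario`` switches off the setting/species effects and the core
structure, giving a fully exchangeable null for type-I-error studies.
All randomness flows from a single integer seed; per-cell and
per-individual sub-streams are derived deterministically so edits to one
part of the configuration leave unrelated draws unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from commrep.records import (
    RECORD_COLUMNS,
    SOCIAL_GOALS,
    IndividualProfile,
    validate_records,
)


@dataclass(frozen=True)
class CellDesign:
    """One (species, setting, group) population cell."""

    species: str
    setting: str
    group_id: str
    n_individuals: int


#: study-like default design: 13 Bornean (8 wild / 5 captive across three
#: zoos) and 14 Sumatran immatures (7 wild / 7 captive across two zoos)
DEFAULT_DESIGN: tuple[CellDesign, ...] = (
    CellDesign("bornean", "wild", "field_b", 8),
    CellDesign("bornean", "captive", "zoo_b1", 2),
    CellDesign("bornean", "captive", "zoo_b2", 2),
    CellDesign("bornean", "captive", "zoo_b3", 1),
    CellDesign("sumatran", "wild", "field_s", 7),
    CellDesign("sumatran", "captive", "zoo_s1", 4),
    CellDesign("sumatran", "captive", "zoo_s2", 3),
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Tunable parameters of the generator (defaults are the study conditions)."""

    global_inventory_size: int = 41
    n_goals: int = 7
    design: tuple[CellDesign, ...] = DEFAULT_DESIGN
    age_range: tuple[float, float] = (1.0, 9.0)
    effort_range: tuple[int, int] = (32, 776)
    #: probability an individual's scope effort falls below the eligibility
    #: threshold (several wild infants yielded too little other-directed data)
    p_subthreshold: float = 0.1
    subthreshold_range: tuple[int, int] = (5, 30)
    base_size_mother: float = 14.0
    base_size_other: float = 8.0        # wild Bornean reference cell
    beta_setting_captive: float = 0.42  # log-scale captive effect, other scope
    beta_species_sumatran: float = 0.52  # log-scale Sumatran effect, other scope
    sigma_group: float = 0.15           # SD of the group random intercept
    core_fraction: float = 0.8          # fraction of a cell's expected size shared
    zipf_exponent: float = 1.0          # rank-frequency skew of signal use
    size_poisson: bool = True           # Poisson latent sizes (False: deterministic)
    p_peer: float = 0.5                 # peer share of other-directed effort
    #: probability each goal category is available to an individual x scope
    #: (identical across settings, so goal diversity carries no setting effect)
    p_goal: float = 0.8

    def validate(self) -> None:
        if self.global_inventory_size < 1 or self.n_goals < 1:
            raise ValueError("inventory and goal counts must be positive")
        if self.n_goals > len(SOCIAL_GOALS):
            raise ValueError(f"at most {len(SOCIAL_GOALS)} goal categories")
        if not 0 <= self.core_fraction <= 1:
            raise ValueError("core_fraction must lie in [0, 1]")
        if not 0 <= self.p_subthreshold <= 1:
            raise ValueError("p_subthreshold must lie in [0, 1]")
        if not 0 <= self.p_peer <= 1:
            raise ValueError("p_peer must lie in [0, 1]")
        if not 0 < self.p_goal <= 1:
            raise ValueError("p_goal must lie in (0, 1]")
        if self.effort_range[0] < 1 or self.effort_range[0] > self.effort_range[1]:
            raise ValueError("invalid effort range")
        if self.sigma_group < 0:
            raise ValueError("sigma_group must be non-negative")
        for cell in self.design:
            if cell.n_individuals < 0:
                raise ValueError("cell sizes must be non-negative")


@dataclass
class GroundTruth:
    """Latent state behind a generated population."""

    latent_repertoires: dict          # (individual_id, scope) -> tuple of types
    latent_goals: dict                # (individual_id, scope) -> tuple of goals
    beta: dict                        # true log-scale effects, other scope
    sigma2: float
    group_effects: dict               # group_id -> realised random intercept
    dice_gap: dict                    # (species, scope) -> within - between mean
    config: SyntheticConfig


def null_scenario(config: SyntheticConfig) -> SyntheticConfig:
    """Exchangeable-null copy: no setting/species effects, no setting core."""
    return replace(
        config,
        beta_setting_captive=0.0,
        beta_species_sumatran=0.0,
        core_fraction=0.0,
    )


def _zipf_weights(n: int, exponent: float) -> np.ndarray:
    w = 1.0 / np.arange(1, n + 1, dtype=float) ** exponent
    return w / w.sum()


def _cell_core(cell_idx, scope, mu_cell, config, seed):
    """Ordered (commonest-first) shared core of one cell x scope."""
    m = int(round(config.core_fraction * mu_cell))
    m = min(m, config.global_inventory_size)
    if m == 0:
        return np.empty(0, dtype=int)
    rng = np.random.default_rng([seed, 7001, cell_idx, scope == "mother"])
    w = _zipf_weights(config.global_inventory_size, config.zipf_exponent)
    core = rng.choice(config.global_inventory_size, size=m, replace=False, p=w)
    return np.sort(core)  # global rank order = commonest first


def _latent_repertoire(k, core, config, rng):
    """Individual latent repertoire: core prefix + private periphery draws."""
    n_core = min(k, len(core))
    types = list(core[:n_core])
    n_private = k - n_core
    if n_private > 0:
        pool = np.setdiff1d(
            np.arange(config.global_inventory_size), core, assume_unique=False
        )
        w = _zipf_weights(config.global_inventory_size, config.zipf_exponent)[pool]
        w = w / w.sum()
        n_private = min(n_private, len(pool))
        types.extend(rng.choice(pool, size=n_private, replace=False, p=w))
    return np.sort(np.array(types, dtype=int))


def _signal_label(idx: int) -> str:
    return f"sig{idx + 1:02d}"


def generate_population(
    config: SyntheticConfig, seed: int
) -> tuple[list[IndividualProfile], GroundTruth]:
    """Draw individuals, efforts and latent repertoires; deterministic per seed.

    The returned profiles carry the exact per-partner-class effort counts
    that :func:`generate_records` will emit, so generator bookkeeping and
    record-table summaries agree by construction.
    """
    config.validate()
    master = np.random.default_rng([seed, 1])
    group_ids = sorted({c.group_id for c in config.design})
    b_g = {
        g: float(master.normal(0.0, config.sigma_group)) for g in group_ids
    }

    goals = np.array(SOCIAL_GOALS[: config.n_goals])
    profiles: list[IndividualProfile] = []
    latents: dict[tuple[str, str], tuple[str, ...]] = {}
    latent_goals: dict[tuple[str, str], tuple[str, ...]] = {}
    cell_of: dict[str, CellDesign] = {}
    idx = 0
    for cell_idx, cell in enumerate(config.design):
        mu_other_cell = config.base_size_other * np.exp(
            config.beta_setting_captive * (cell.setting == "captive")
            + config.beta_species_sumatran * (cell.species == "sumatran")
        )
        cores = {
            "mother": _cell_core(
                _setting_species_index(cell), "mother",
                config.base_size_mother, config, seed,
            ),
            "other": _cell_core(
                _setting_species_index(cell), "other", mu_other_cell, config, seed
            ),
        }
        for _ in range(cell.n_individuals):
            ind_id = f"ind{idx + 1:03d}"
            rng = np.random.default_rng([seed, 2, idx])
            age = float(rng.uniform(*config.age_range))
            sex = "male" if rng.random() < 0.5 else "female"
            efforts = {}
            for cls_seed, scope in ((0, "mother"), (1, "other")):
                r = np.random.default_rng([seed, 3, idx, cls_seed])
                if r.random() < config.p_subthreshold:
                    lo, hi = config.subthreshold_range
                else:
                    lo, hi = config.effort_range
                efforts[scope] = int(r.integers(lo, hi + 1))
            peer = int(
                np.random.default_rng([seed, 4, idx]).binomial(
                    efforts["other"], config.p_peer
                )
            )
            effort_by_class = {
                "mother": efforts["mother"],
                "peer": peer,
                "older": efforts["other"] - peer,
            }
            for scope, mu_base in (
                ("mother", config.base_size_mother),
                ("other", mu_other_cell),
            ):
                mu_i = mu_base * np.exp(b_g[cell.group_id])
                if config.size_poisson:
                    k = int(rng.poisson(mu_i))
                else:
                    k = int(round(mu_i))
                k = int(np.clip(k, 1, config.global_inventory_size))
                rep = _latent_repertoire(k, cores[scope], config, rng)
                latents[(ind_id, scope)] = tuple(_signal_label(t) for t in rep)
                avail = rng.random(len(goals)) < config.p_goal
                if not avail.any():
                    avail[0] = True
                latent_goals[(ind_id, scope)] = tuple(goals[avail])
            profiles.append(
                IndividualProfile(
                    individual_id=ind_id,
                    species=cell.species,
                    setting=cell.setting,
                    group_id=cell.group_id,
                    sex=sex,
                    age_years=round(age, 2),
                    effort_by_partner_class=effort_by_class,
                )
            )
            cell_of[ind_id] = cell
            idx += 1

    truth = GroundTruth(
        latent_repertoires=latents,
        latent_goals=latent_goals,
        beta={
            "intercept": float(np.log(config.base_size_other)),
            "setting_captive": config.beta_setting_captive,
            "species_sumatran": config.beta_species_sumatran,
        },
        sigma2=config.sigma_group**2,
        group_effects=b_g,
        dice_gap=_latent_dice_gaps(profiles, latents),
        config=config,
    )
    return profiles, truth


def _setting_species_index(cell: CellDesign) -> int:
    # cores are shared across groups of the same (species, setting)
    return (cell.species == "sumatran") * 2 + (cell.setting == "captive")


def _dice(a: Sequence[str], b: Sequence[str]) -> float:
    sa, sb = set(a), set(b)
    return 2.0 * len(sa & sb) / (len(sa) + len(sb))


def _latent_dice_gaps(profiles, latents):
    gaps = {}
    for scope in ("mother", "other"):
        for species in sorted({p.species for p in profiles}):
            subset = [p for p in profiles if p.species == species]
            within, between = [], []
            for i in range(len(subset)):
                for j in range(i + 1, len(subset)):
                    a, b = subset[i], subset[j]
                    d = _dice(
                        latents[(a.individual_id, scope)],
                        latents[(b.individual_id, scope)],
                    )
                    (within if a.setting == b.setting else between).append(d)
            if within and between:
                gaps[(species, scope)] = float(
                    np.mean(within) - np.mean(between)
                )
    return gaps


def generate_records(
    population: Sequence[IndividualProfile],
    truth: GroundTruth,
    seed: int,
    validate: bool = True,
) -> pd.DataFrame:
    """Emit the interaction-record table implied by a generated population.

    For each individual and partner class, exactly the profiled number of
    signal instances is drawn: signal types multinomially from the latent
    repertoire with Zipf-skewed frequencies, social goals categorically
    with a common mild skew.  Total records equal total profiled effort.
    """
    config = truth.config
    cols: dict[str, list] = {c: [] for c in RECORD_COLUMNS}
    counter = 0
    for idx, prof in enumerate(population):
        for cls_seed, cls in ((0, "mother"), (1, "peer"), (2, "older")):
            n = prof.effort_by_partner_class.get(cls, 0)
            if n == 0:
                continue
            scope = "mother" if cls == "mother" else "other"
            rep = np.array(truth.latent_repertoires[(prof.individual_id, scope)])
            w = _zipf_weights(len(rep), config.zipf_exponent)
            rng = np.random.default_rng([seed, 5, idx, cls_seed])
            sig = rng.choice(rep, size=n, p=w)
            avail = np.array(truth.latent_goals[(prof.individual_id, scope)])
            goal = rng.choice(avail, size=n, p=_zipf_weights(len(avail), 0.5))
            cols["record_id"].extend(
                f"r{counter + k:07d}" for k in range(n)
            )
            counter += n
            cols["individual_id"].extend([prof.individual_id] * n)
            cols["species"].extend([prof.species] * n)
            cols["setting"].extend([prof.setting] * n)
            cols["group_id"].extend([prof.group_id] * n)
            cols["sex"].extend([prof.sex] * n)
            cols["age_years"].extend([prof.age_years] * n)
            cols["partner_class"].extend([cls] * n)
            cols["signal_type"].extend(sig.tolist())
            cols["social_goal"].extend(goal.tolist())
    frame = pd.DataFrame(cols, columns=list(RECORD_COLUMNS))
    if validate:
        frame = validate_records(frame)
    else:
        frame["age_years"] = frame["age_years"].astype(float)
    return frame


def generate_dataset(
    config: SyntheticConfig, seed: int, validate: bool = True
) -> tuple[pd.DataFrame, list[IndividualProfile], GroundTruth]:
    """Population + records in one call (the common entry point)."""
    population, truth = generate_population(config, seed)
    records = generate_records(population, truth, seed, validate=validate)
    return records, population, truth


# ---------------------------------------------------------------------------
# direct GLMM-scenario simulation (parameter-recovery and coverage studies)

DEFAULT_GLMM_BETA: Mapping[str, float] = {
    "intercept": 2.3,
    "age": 0.0,
    "age_squared": 0.0,
    "setting_wild": -0.42,
    "species_sumatran": 0.52,
    "sex_male": 0.0,
    "log_z_effort": 0.35,
}


def simulate_glmm_counts(
    beta: Mapping[str, float] | None = None,
    sigma: float = 0.15,
    n: int = 200,
    n_groups: int = 10,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Counts drawn directly from the Poisson random-intercept model.

    Bypasses the record layer: covariates follow the study design (group
    determines setting and species; age, sex and effort individual-level),
    and y_i ~ Poisson(exp(x_i' beta + b_g)).  Returns a model frame ready
    for :func:`commrep.glmm.fit_poisson_glmm` plus the simulation truth.
    """
    beta = dict(DEFAULT_GLMM_BETA if beta is None else beta)
    rng = np.random.default_rng(seed)
    group = rng.integers(0, n_groups, size=n)
    group_setting = (np.arange(n_groups) % 2).astype(float)      # wild indicator
    group_species = ((np.arange(n_groups) // 2) % 2).astype(float)
    b_g = rng.normal(0.0, sigma, size=n_groups)
    age = rng.uniform(1.0, 9.0, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    effort = rng.integers(32, 777, size=n)
    log_z = np.log(effort)
    log_z = (log_z - log_z.mean()) / log_z.std(ddof=1)
    frame = pd.DataFrame(
        {
            "age": age,
            "age_squared": age**2,
            "setting_wild": group_setting[group],
            "species_sumatran": group_species[group],
            "sex_male": sex,
            "log_z_effort": log_z,
            "group_id": [f"g{g}" for g in group],
        }
    )
    eta = np.full(n, beta["intercept"]) + b_g[group]
    for term in (
        "age", "age_squared", "setting_wild", "species_sumatran",
        "sex_male", "log_z_effort",
    ):
        eta += beta.get(term, 0.0) * frame[term].to_numpy()
    frame["repertoire_size"] = rng.poisson(np.exp(eta))
    frame["goal_count"] = frame["repertoire_size"]
    truth = {"beta": beta, "sigma": sigma, "group_effects": b_g.tolist()}
    return frame, truth


def config_to_dict(config: SyntheticConfig) -> dict:
    d = asdict(config)
    d["design"] = [asdict(c) for c in config.design]
    return d


def config_from_dict(payload: Mapping) -> SyntheticConfig:
    payload = dict(payload)
    if "design" in payload:
        payload["design"] = tuple(
            CellDesign(**c) for c in payload["design"]
        )
    for key in ("age_range", "effort_range", "subthreshold_range"):
        if key in payload:
            payload[key] = tuple(payload[key])
    return SyntheticConfig(**payload)
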