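"""Registry-like cohort simulator with known ground truth.

Generates categorical covariates from configurable distributions and draws
discrete annual survival times from an additive hazard: general-population
mortality (Gompertz life table) plus a stage- and adherence-specific excess
hazard.  Censoring combines an annual dropout hazard with administrative
censoring at 10 years.  Everything is seeded and reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .cohort_io import (
    AGE_GROUPS,
    ADHERENCE_LEVELS,
    HER2_LEVELS,
    STAGES,
    LifeTable,
    PatientRecord,
)

__all__ = ["RegistryConfig", "generate_lifetable", "generate_cohort"]

#: Exact-age span of each age group (inclusive).
AGE_RANGES = ((26, 49), (50, 59), (60, 74))

HORIZON = 10


def _asarray(x, shape, name):
    arr = np.asarray(x, dtype=float)
    if arr.shape != shape:
        raise ValueError(f"{name} must have shape {shape}, got {arr.shape}")
    return arr


@dataclass
class RegistryConfig:
    """Ground-truth parameters of the synthetic registry.

    Probability matrices are indexed in the canonical level orders of
    :data:`synsurv.cohort_io.VARIABLE_LEVELS`; ``excess_hazard`` is indexed
    [stage, adherence] with adherence order (yes, no).
    """

    n_patients: int = 2000
    seed: int = 0
    age_group_probs: tuple = (0.327, 0.296, 0.377)
    her2_pos_prob: float = 0.244
    # rows: her2 level (pos, neg); columns: stage I, II, III
    stage_probs_given_her2: tuple = (
        (0.347, 0.459, 0.194),
        (0.443, 0.369, 0.188),
    )
    # rows: age group; columns: stage
    adherence_prob: tuple = (
        (0.78, 0.75, 0.72),
        (0.76, 0.75, 0.74),
        (0.73, 0.74, 0.70),
    )
    # rows: stage; columns: adherence (yes, no); annual excess hazard
    excess_hazard: tuple = (
        (0.003, 0.012),
        (0.010, 0.035),
        (0.035, 0.080),
    )
    dropout_hazard: float = 0.0
    missing_adherence_prob: float = 0.459
    gompertz_a: float = 0.00004
    gompertz_b: float = 0.085
    year_min: int = 2005
    year_max: int = 2009
    horizon: int = HORIZON
    lifetable_min_age: int = 25
    lifetable_max_age: int = 85

    def validate(self) -> None:
        probs = _asarray(self.age_group_probs, (3,), "age_group_probs")
        if abs(probs.sum() - 1.0) > 1e-12:
            raise ValueError("age_group_probs must sum to 1")
        stage = _asarray(self.stage_probs_given_her2, (2, 3), "stage_probs_given_her2")
        if np.max(np.abs(stage.sum(axis=1) - 1.0)) > 1e-12:
            raise ValueError("stage_probs_given_her2 rows must sum to 1")
        adh = _asarray(self.adherence_prob, (3, 3), "adherence_prob")
        if np.any((adh < 0) | (adh > 1)):
            raise ValueError("adherence_prob entries must be in [0, 1]")
        excess = _asarray(self.excess_hazard, (3, 2), "excess_hazard")
        if np.any(excess < 0):
            raise ValueError("excess_hazard must be non-negative")
        if self.dropout_hazard < 0:
            raise ValueError("dropout_hazard must be non-negative")
        if not 0 <= self.missing_adherence_prob <= 1:
            raise ValueError("missing_adherence_prob must be in [0, 1]")
        if not 0 <= self.her2_pos_prob <= 1:
            raise ValueError("her2_pos_prob must be in [0, 1]")
        if self.gompertz_a < 0:
            raise ValueError("gompertz_a must be non-negative")
        if self.horizon != HORIZON:
            raise ValueError(f"horizon is fixed at {HORIZON} years")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RegistryConfig":
        with open(path) as handle:
            payload = yaml.safe_load(handle) or {}
        config = cls(**payload)
        config.validate()
        return config

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(dataclasses.asdict(self), handle, sort_keys=False)


def population_rate(config: RegistryConfig, age: int) -> float:
    """Gompertz annual mortality hazard a * exp(b * age)."""
    return config.gompertz_a * np.exp(config.gompertz_b * age)


def generate_lifetable(config: RegistryConfig) -> LifeTable:
    """Deterministic Gompertz life table covering every reachable (age, year)."""
    config.validate()
    rates = {}
    years = range(config.year_min, config.year_max + config.horizon + 1)
    for age in range(config.lifetable_min_age, config.lifetable_max_age + 1):
        rate = population_rate(config, age)
        for year in years:
            rates[(age, year)] = rate
    return LifeTable(rates)


def generate_cohort(config: RegistryConfig) -> list[PatientRecord]:
    """Draw a cohort of ``n_patients`` records from the configured registry.

    Death and dropout compete on the annual grid: within each follow-up year
    the per-year death probability is ``1 - exp(-(lambda_P + lambda_X))`` at
    the attained age, dropout is ``1 - exp(-dropout_hazard)``, and a death
    in the same year as a dropout wins.  Follow-up is the exit year
    (capped at 10); administrative censoring at 10 years.
    """
    config.validate()
    n = config.n_patients
    if n == 0:
        return []
    rng = np.random.default_rng(config.seed)

    group_idx = rng.choice(3, size=n, p=np.asarray(config.age_group_probs, dtype=float))
    lo = np.array([AGE_RANGES[g][0] for g in group_idx])
    hi = np.array([AGE_RANGES[g][1] for g in group_idx])
    age_dx = rng.integers(lo, hi + 1)
    year_dx = rng.integers(config.year_min, config.year_max + 1, size=n)

    her2_idx = (rng.random(n) >= config.her2_pos_prob).astype(int)  # 0=pos, 1=neg
    stage_matrix = np.asarray(config.stage_probs_given_her2, dtype=float)
    stage_cum = stage_matrix.cumsum(axis=1)
    stage_idx = (rng.random(n)[:, None] >= stage_cum[her2_idx]).sum(axis=1)

    adh_matrix = np.asarray(config.adherence_prob, dtype=float)
    adherent = rng.random(n) < adh_matrix[group_idx, stage_idx]
    adh_idx = np.where(adherent, 0, 1)  # (yes, no)

    excess = np.asarray(config.excess_hazard, dtype=float)
    lam_x = excess[stage_idx, adh_idx]

    horizon = config.horizon
    # attained age per interval t: age_dx + t - 1
    ages = age_dx[:, None] + np.arange(horizon)[None, :]
    lam_p = config.gompertz_a * np.exp(
        config.gompertz_b * np.minimum(ages, config.lifetable_max_age)
    )
    p_die = 1.0 - np.exp(-(lam_p + lam_x[:, None]))
    die_draw = rng.random((n, horizon)) < p_die
    death_year = np.where(die_draw.any(axis=1), die_draw.argmax(axis=1) + 1, horizon + 1)

    if config.dropout_hazard > 0:
        p_drop = 1.0 - np.exp(-config.dropout_hazard)
        drop_draw = rng.random((n, horizon)) < p_drop
        drop_year = np.where(drop_draw.any(axis=1), drop_draw.argmax(axis=1) + 1, horizon + 1)
    else:
        drop_year = np.full(n, horizon + 1)

    died = (death_year <= drop_year) & (death_year <= horizon)
    followup = np.minimum(np.minimum(death_year, drop_year), horizon)

    missing = rng.random(n) < config.missing_adherence_prob

    width = len(str(n))
    records = []
    for i in range(n):
        records.append(
            PatientRecord(
                id=f"S{i + 1:0{width}d}",
                age_dx=int(age_dx[i]),
                stage=STAGES[stage_idx[i]],
                her2=HER2_LEVELS[her2_idx[i]],
                adherence=None if missing[i] else ADHERENCE_LEVELS[adh_idx[i]],
                followup=int(followup[i]),
                exitus="died" if died[i] else "survived",
                year_dx=int(year_dx[i]),
            )
        )
    return records
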