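"""Synthetic stand-ins for the restricted linked data the analysis consumes.

Two generators are provided.  ``generate_cohort`` emulates the person-level
post-MI follow-up table (one row per person per follow-up year, with annual
chronic-management cost and person-year exposure weights) on which the cost
GLM is estimated.  ``generate_projection_inputs`` emulates the population,
rate, prevalence, migration and cost tables feeding the dynamic Markov
projection.

Default parameter values mirror a linked Australian MI cohort followed for up
to six years: ~59k people, two-thirds male, three-quarters NSTEMI, high
hypertension and moderate diabetes prevalence, costs highest in the first
follow-up year and declining ~12%/year thereafter, and individual annual
costs gamma-distributed (heavy right skew) around a multiplicative
(log-linear) mean surface so that GLM recovery targets are well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .grids import AGES, CostSurface, N_AGES, N_SEXES, SEXES, validate_age_sex_grid
from .markov import TransitionRates
from .errors import ValidationError

__all__ = [
    "AGE_BANDS",
    "CostMeanSurface",
    "SyntheticCohortConfig",
    "ProjectionInputs",
    "generate_cohort",
    "generate_projection_inputs",
]

# 5-year age bands 30-34 .. 95-99 and their midpoints
AGE_BANDS = tuple(f"{lo}-{lo + 4}" for lo in range(30, 100, 5))
AGE_BAND_MIDPOINTS = tuple(lo + 2.0 for lo in range(30, 100, 5))

#: default band distribution (heavier at older ages, as in hospital MI cohorts)
_DEFAULT_AGE_BAND_PROBS = (
    0.0075, 0.0091,  # 30s
    0.0350, 0.0427,  # 40s
    0.0785, 0.0958,  # 50s
    0.1046, 0.1278,  # 60s
    0.1163, 0.1162,  # 70s
    0.1066, 0.0800, 0.0533, 0.0266,  # 80+
)


@dataclass(frozen=True)
class CostMeanSurface:
    """Multiplicative mean model for individual annual chronic costs.

    The mean for a person-year is

    ``base_mean * exp(age_slope * (age_mid - age_ref)) * decay^(fy - 1)``

    times the covariate multipliers for their sex, MI subtype, comorbidities
    and IRSD quintile.  ``base_mean`` is the year-1 cost of the reference
    person: male, NSTEMI, no diabetes, no hypertension, IRSD quintile 3,
    age ``age_ref``.
    """

    base_mean: float = 9350.0
    age_ref: float = 65.0
    age_slope: float = 0.009  # log-cost per year of age
    follow_up_decay: float = 0.88  # multiplicative per follow-up year
    female_mult: float = 0.95
    stemi_mult: float = 0.80
    diabetes_mult: float = 1.55
    hypertension_mult: float = 1.50
    irsd_mults: tuple = (1.02, 1.01, 1.00, 0.99, 0.98)

    def mean(self, age_mid, female, stemi, diabetes, hypertension, irsd, follow_up_year):
        age_mid = np.asarray(age_mid, dtype=float)
        irsd = np.asarray(irsd, dtype=int)
        m = (
            self.base_mean
            * np.exp(self.age_slope * (age_mid - self.age_ref))
            * self.follow_up_decay ** (np.asarray(follow_up_year) - 1)
            * np.where(np.asarray(female, bool), self.female_mult, 1.0)
            * np.where(np.asarray(stemi, bool), self.stemi_mult, 1.0)
            * np.where(np.asarray(diabetes, bool), self.diabetes_mult, 1.0)
            * np.where(np.asarray(hypertension, bool), self.hypertension_mult, 1.0)
            * np.asarray(self.irsd_mults)[irsd - 1]
        )
        return m


@dataclass(frozen=True)
class SyntheticCohortConfig:
    n_people: int = 59_260
    seed: int = 0
    max_follow_up: int = 6
    age_band_probs: tuple = _DEFAULT_AGE_BAND_PROBS
    male_fraction: float = 0.670
    nstemi_fraction: float = 0.743
    diabetes_fraction: float = 0.306
    hypertension_fraction: float = 0.931
    irsd_probs: tuple = (0.213, 0.200, 0.199, 0.216, 0.172)
    cost_mean_surface: CostMeanSurface = field(default_factory=CostMeanSurface)
    cost_shape: float = 0.7  # gamma shape; CV = 1/sqrt(shape)
    annual_dropout_prob: float = 0.33

    def validate(self) -> None:
        if self.n_people < 0:
            raise ConfigurationError("n_people must be >= 0")
        if self.max_follow_up < 1:
            raise ConfigurationError("max_follow_up must be >= 1")
        for name in (
            "male_fraction",
            "nstemi_fraction",
            "diabetes_fraction",
            "hypertension_fraction",
            "annual_dropout_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        for name, probs, k in (
            ("age_band_probs", self.age_band_probs, len(AGE_BANDS)),
            ("irsd_probs", self.irsd_probs, 5),
        ):
            p = np.asarray(probs, dtype=float)
            if p.size != k:
                raise ConfigurationError(f"{name} must have {k} entries, got {p.size}")
            if np.any(p < 0):
                raise ConfigurationError(f"{name} contains negative probabilities")
            if abs(p.sum() - 1.0) > 1e-9:
                raise ConfigurationError(f"{name} must sum to 1 (got {p.sum():.12f})")
        if self.cost_shape <= 0:
            raise ConfigurationError("cost_shape must be > 0")
        s = self.cost_mean_surface
        if s.base_mean <= 0 or s.follow_up_decay <= 0:
            raise ConfigurationError("cost means must be strictly positive")


def generate_cohort(config: SyntheticCohortConfig) -> pd.DataFrame:
    """Generate a person-year cohort table.

    Each person receives covariates from the configured marginal
    distributions and a follow-up length from a geometric dropout process
    truncated at ``max_follow_up``; every follow-up year yields one row with
    a gamma-distributed annual cost around the configured mean surface.
    The final follow-up year carries a partial person-year exposure drawn
    uniform on (0, 1]; earlier years are full years.

    Deterministic given ``config.seed``.
    """
    config.validate()
    cols = [
        "person_id", "age_band", "age_mid", "sex", "mi_type", "diabetes",
        "hypertension", "irsd_quintile", "follow_up_year", "annual_cost",
        "person_years",
    ]
    if config.n_people == 0:
        return pd.DataFrame({c: pd.Series(dtype=float) for c in cols})

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    n = config.n_people
    band_idx = rng.choice(len(AGE_BANDS), size=n, p=np.asarray(config.age_band_probs))
    male = rng.random(n) < config.male_fraction
    nstemi = rng.random(n) < config.nstemi_fraction
    diabetes = rng.random(n) < config.diabetes_fraction
    hypertension = rng.random(n) < config.hypertension_fraction
    irsd = rng.choice(np.arange(1, 6), size=n, p=np.asarray(config.irsd_probs))

    # follow-up length: survive each further year w.p. (1 - dropout)
    if config.annual_dropout_prob > 0:
        k = rng.geometric(config.annual_dropout_prob, size=n)
    else:
        k = np.full(n, np.iinfo(np.int64).max)
    k = np.minimum(k, config.max_follow_up)

    person_id = np.repeat(np.arange(n), k)
    fy = _ragged_arange(k)
    last = fy == np.repeat(k, k)
    person_years = np.ones(person_id.size)
    person_years[last] = 1.0 - rng.random(int(last.sum()))  # uniform (0, 1]

    age_mid = np.asarray(AGE_BAND_MIDPOINTS)[band_idx][person_id]
    female_r = ~male[person_id]
    stemi_r = ~nstemi[person_id]
    dm_r = diabetes[person_id]
    htn_r = hypertension[person_id]
    irsd_r = irsd[person_id]
    mean = config.cost_mean_surface.mean(
        age_mid, female_r, stemi_r, dm_r, htn_r, irsd_r, fy
    )
    shape = config.cost_shape
    cost = rng.gamma(shape, mean / shape)

    return pd.DataFrame(
        {
            "person_id": person_id,
            "age_band": np.asarray(AGE_BANDS)[band_idx][person_id],
            "age_mid": age_mid,
            "sex": np.where(male[person_id], "male", "female"),
            "mi_type": np.where(nstemi[person_id], "NSTEMI", "STEMI"),
            "diabetes": dm_r.astype(int),
            "hypertension": htn_r.astype(int),
            "irsd_quintile": irsd_r,
            "follow_up_year": fy,
            "annual_cost": cost,
            "person_years": person_years,
        }
    )


def _ragged_arange(lengths: np.ndarray) -> np.ndarray:
    """[3, 2] -> [1, 2, 3, 1, 2]."""
    total = int(lengths.sum())
    out = np.ones(total, dtype=int)
    starts = np.cumsum(lengths)[:-1]
    out[0] = 1
    if starts.size:
        out[starts] -= lengths[:-1]
    return np.cumsum(out)


@dataclass
class ProjectionInputs:
    """Complete input set for the dynamic Markov projection.

    All grids are ``(sex, age)`` over ages 30..99.  ``entry_cohort`` is the
    number of new 30-year-olds entering per cycle, by sex;
    ``net_migration`` is added to every age each cycle.
    """

    initial_population: np.ndarray
    mi_prevalence: np.ndarray
    rates: TransitionRates
    net_migration: np.ndarray
    entry_cohort: np.ndarray  # (sex,)
    acute_unit_cost: float
    chronic_surface: CostSurface
    meta: dict = field(default_factory=dict)

    def validate(self) -> None:
        self.initial_population = validate_age_sex_grid(
            self.initial_population, "initial_population"
        )
        self.mi_prevalence = validate_age_sex_grid(self.mi_prevalence, "mi_prevalence")
        self.net_migration = validate_age_sex_grid(self.net_migration, "net_migration")
        if np.any(self.initial_population < 0):
            raise ValidationError("initial_population must be >= 0")
        if np.any((self.mi_prevalence < 0) | (self.mi_prevalence > 1)):
            raise ValidationError("mi_prevalence must lie in [0, 1]")
        if np.any(self.net_migration < 0):
            raise ValidationError("net_migration must be >= 0")
        self.entry_cohort = np.asarray(self.entry_cohort, dtype=float)
        if self.entry_cohort.shape != (N_SEXES,) or np.any(self.entry_cohort < 0):
            raise ValidationError("entry_cohort must be a nonnegative per-sex pair")
        if not self.acute_unit_cost > 0:
            raise ValidationError("acute_unit_cost must be > 0")


def generate_projection_inputs(seed: int = 0, scale_options: dict | None = None) -> ProjectionInputs:
    """Generate a complete, internally consistent projection input set.

    Shapes follow the epidemiology of MI: incidence and mortality rise
    roughly exponentially with age, case fatality rises with age, males have
    higher incidence than females, and chronic costs decline with follow-up
    year.  ``scale_options`` maps table names (``incidence``,
    ``mortality_other``, ``mortality_post_mi``, ``p_fatal``, ``prevalence``,
    ``migration``, ``entry``, ``population``, ``acute_unit_cost``,
    ``chronic_cost``) to multiplicative factors; proportions are clipped
    back to [0, 1].
    """
    scale = dict(scale_options or {})

    def s(name):
        return float(scale.pop(name, 1.0))

    x = (AGES - 30).astype(float)  # years past 30
    male, female = 0, 1

    population = np.zeros((N_SEXES, N_AGES))
    population[male] = 165_000.0 / (1.0 + np.exp((AGES - 72.0) / 7.0))
    population[female] = 165_000.0 / (1.0 + np.exp((AGES - 74.0) / 7.0))
    population *= s("population")

    prevalence = np.zeros((N_SEXES, N_AGES))
    prevalence[male] = 0.45 / (1.0 + np.exp(-(AGES - 76.0) / 9.0))
    prevalence[female] = 0.28 / (1.0 + np.exp(-(AGES - 78.0) / 9.0))
    prevalence = np.clip(prevalence * s("prevalence"), 0.0, 1.0)

    incidence = np.zeros((N_SEXES, N_AGES))
    incidence[male] = 4.0e-4 * np.exp(0.075 * x)
    incidence[female] = 2.2e-4 * np.exp(0.075 * x)
    incidence *= s("incidence")

    mortality_other = np.zeros((N_SEXES, N_AGES))
    mortality_other[male] = 6.0e-4 * np.exp(0.087 * x)
    mortality_other[female] = 4.8e-4 * np.exp(0.087 * x)
    mortality_other *= s("mortality_other")

    # post-MI mortality: excess hazard on top of a multiple of background mortality
    mortality_post_mi = (0.010 + 2.5 * mortality_other) * s("mortality_post_mi")

    p_fatal = np.zeros((N_SEXES, N_AGES))
    p_fatal[male] = 0.03 + 0.45 / (1.0 + np.exp(-(AGES - 80.0) / 8.0))
    p_fatal[female] = 0.03 + 0.50 / (1.0 + np.exp(-(AGES - 80.0) / 8.0))
    p_fatal = np.clip(p_fatal * s("p_fatal"), 0.0, 1.0)

    migration = np.zeros((N_SEXES, N_AGES))
    migration[male] = 3_500.0 * np.exp(-x / 8.0)
    migration[female] = 3_500.0 * np.exp(-x / 8.0)
    migration *= s("migration")

    entry_cohort = np.array([160_000.0, 160_000.0]) * s("entry")

    acute_unit_cost = 10_000.0 * s("acute_unit_cost")

    K = 6
    fy = np.arange(1, K + 1)
    base = 15_500.0 * np.exp(0.008 * (AGES - 65.0))
    surf = np.zeros((N_SEXES, N_AGES, K))
    surf[male] = base[:, None] * 0.88 ** (fy - 1)[None, :]
    surf[female] = 0.95 * base[:, None] * 0.88 ** (fy - 1)[None, :]
    surf *= s("chronic_cost")

    if scale:
        raise ConfigurationError(f"unknown scale_options key(s): {sorted(scale)}")

    rates = TransitionRates(
        incidence=incidence,
        mortality_other=mortality_other,
        mortality_post_mi=mortality_post_mi,
        p_fatal=p_fatal,
    )
    return ProjectionInputs(
        initial_population=population,
        mi_prevalence=prevalence,
        rates=rates,
        net_migration=migration,
        entry_cohort=entry_cohort,
        acute_unit_cost=acute_unit_cost,
        chronic_surface=CostSurface(values=np.maximum(surf, 1e-9)),
        meta={"seed": int(seed), "scale_options": dict(scale_options or {})},
    )
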