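"""Probabilistic sensitivity analysis (Monte-Carlo uncertainty intervals).

Each uncertain input table receives a parameter distribution specified by a
(mean multiplier, SE) pair and a family appropriate to its support: gamma
for nonnegative rates, lognormal for positive unit costs, beta for
proportions, ``fixed`` for inputs held at their means (population counts in
the base configuration).  One draw per iteration scales the whole table
(a shared age-profile multiplier), preserving the age gradient; proportions
are scaled on their mean level and clipped back to [0, 1].

An iteration redraws every parameter, reruns the full projection and
costing pipeline, and records the headline outputs; the 95% uncertainty
interval is the 2.5th-97.5th percentile band over iterations, while the
point estimate always comes from the deterministic all-means run (so it is
invariant to the iteration count and seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .grids import CostSurface
from .markov import TransitionRates, run_projection
from .costing import CostingAssumptions, DiscountSpec, project_costs
from .synthetic import ProjectionInputs

__all__ = [
    "ParameterDistribution",
    "PSAResult",
    "default_distributions",
    "draw_parameters",
    "run_psa",
]

#: input tables a distribution may target
TARGETS = (
    "incidence",
    "mortality_other",
    "mortality_post_mi",
    "p_fatal",
    "mi_prevalence",
    "acute_unit_cost",
    "chronic_surface",
    "initial_population",
    "net_migration",
    "entry_cohort",
)

_PROPORTION_TARGETS = {"p_fatal", "mi_prevalence"}


@dataclass(frozen=True)
class ParameterDistribution:
    """Sampling distribution for one input table's shared multiplier.

    ``mean`` is the central multiplier (1.0 leaves the table at its input
    values); ``se`` is its standard error.  Families: ``gamma`` and
    ``lognormal`` for positive parameters, ``beta`` for [0, 1] proportions
    (applied on the proportion scale, see :func:`draw_parameters`),
    ``fixed`` for no uncertainty.
    """

    target: str
    family: str = "fixed"
    mean: float = 1.0
    se: float = 0.0

    def __post_init__(self):
        if self.target not in TARGETS:
            raise ConfigurationError(
                f"unknown distribution target {self.target!r}; expected one of {TARGETS}"
            )
        if self.family not in ("beta", "gamma", "lognormal", "fixed"):
            raise ConfigurationError(f"unknown family {self.family!r}")
        if self.family == "beta" and self.target not in _PROPORTION_TARGETS:
            raise ConfigurationError(
                f"beta family is only valid for proportion targets {sorted(_PROPORTION_TARGETS)}"
            )
        if self.family in ("gamma", "lognormal") and self.target in _PROPORTION_TARGETS:
            raise ConfigurationError(
                f"{self.family} family is for positive parameters, not proportion "
                f"target {self.target!r}"
            )
        if self.se < 0:
            raise ConfigurationError("se must be >= 0")
        if self.family != "fixed" and self.mean <= 0:
            raise ConfigurationError("mean must be > 0 for stochastic families")

    def draw(self, rng: np.random.Generator) -> float:
        """Draw one multiplier solving the (mean, se) moments exactly."""
        if self.family == "fixed" or self.se == 0.0:
            return self.mean
        m, s = self.mean, self.se
        if self.family == "gamma":
            shape = (m / s) ** 2
            return float(rng.gamma(shape, s**2 / m))
        if self.family == "lognormal":
            sigma2 = np.log1p((s / m) ** 2)
            mu = np.log(m) - sigma2 / 2.0
            return float(rng.lognormal(mu, np.sqrt(sigma2)))
        # beta on the proportion scale
        if not 0.0 < m < 1.0:
            raise ConfigurationError("beta mean must lie strictly inside (0, 1)")
        v = s**2
        if v >= m * (1.0 - m):
            raise ConfigurationError(
                f"beta SE {s} incompatible with mean {m} (variance >= m(1-m))"
            )
        nu = m * (1.0 - m) / v - 1.0
        return float(rng.beta(m * nu, (1.0 - m) * nu))


def default_distributions(inputs: ProjectionInputs) -> list[ParameterDistribution]:
    """Default PSA specification: ~5% SEs on rates and costs, beta on proportions.

    Proportion targets are parameterized at the table's population-weighted
    mean level; population counts are fixed.
    """
    w = inputs.initial_population
    dists = [
        ParameterDistribution("incidence", "gamma", 1.0, 0.05),
        ParameterDistribution("mortality_other", "gamma", 1.0, 0.03),
        ParameterDistribution("mortality_post_mi", "gamma", 1.0, 0.05),
        ParameterDistribution("acute_unit_cost", "lognormal", 1.0, 0.05),
        ParameterDistribution("chronic_surface", "lognormal", 1.0, 0.03),
        ParameterDistribution("initial_population", "fixed"),
        ParameterDistribution("net_migration", "fixed"),
        ParameterDistribution("entry_cohort", "fixed"),
    ]
    for target, table in (("p_fatal", inputs.rates.p_fatal), ("mi_prevalence", inputs.mi_prevalence)):
        mean_level = float(np.average(table, weights=np.maximum(w, 1e-12)))
        dists.append(
            ParameterDistribution(target, "beta", mean_level, 0.05 * mean_level)
        )
    return dists


def draw_parameters(
    inputs: ProjectionInputs,
    distributions,
    seed,
) -> ProjectionInputs:
    """Realize one coherent input set from the parameter distributions.

    Positive-parameter draws are multipliers on the whole table; beta draws
    are levels, converted to the multiplier ``draw / mean`` and clipped back
    to [0, 1] cellwise.  Reproducible given ``seed``.
    """
    rng = np.random.default_rng(seed)
    mult = {}
    for dist in distributions:
        if dist.target in mult:
            raise ConfigurationError(f"duplicate distribution for target {dist.target!r}")
        d = dist.draw(rng)
        mult[dist.target] = d / dist.mean if dist.family == "beta" else d

    def m(target):
        return mult.get(target, 1.0)

    rates = TransitionRates(
        incidence=inputs.rates.incidence * m("incidence"),
        mortality_other=inputs.rates.mortality_other * m("mortality_other"),
        mortality_post_mi=inputs.rates.mortality_post_mi * m("mortality_post_mi"),
        p_fatal=np.clip(inputs.rates.p_fatal * m("p_fatal"), 0.0, 1.0),
        cycle_length=inputs.rates.cycle_length,
    )
    return ProjectionInputs(
        initial_population=inputs.initial_population * m("initial_population"),
        mi_prevalence=np.clip(inputs.mi_prevalence * m("mi_prevalence"), 0.0, 1.0),
        rates=rates,
        net_migration=inputs.net_migration * m("net_migration"),
        entry_cohort=inputs.entry_cohort * m("entry_cohort"),
        acute_unit_cost=inputs.acute_unit_cost * m("acute_unit_cost"),
        chronic_surface=CostSurface(values=inputs.chronic_surface.values * m("chronic_surface")),
        meta=dict(inputs.meta),
    )


@dataclass
class PSAResult:
    """Point estimates and percentile uncertainty intervals per output quantity."""

    quantities: pd.DataFrame  # columns: quantity, point, ui_lb, ui_ub
    n_iterations: int
    master_seed: int
    draws: pd.DataFrame | None = None

    def interval(self, quantity: str) -> tuple[float, float, float]:
        row = self.quantities.set_index("quantity").loc[quantity]
        return float(row["point"]), float(row["ui_lb"]), float(row["ui_ub"])


def _headline_quantities(result) -> dict:
    g = result.grand_totals()
    out = {
        "acute_cost": g["acute"],
        "chronic_cost": g["chronic"],
        "total_cost": g["total"],
        "acute_n": g["acute_n"],
        "chronic_n": g["chronic_n"],
    }
    for si, sex in enumerate(("male", "female")):
        out[f"acute_cost_{sex}"] = float(result.acute[:, si].sum())
        out[f"chronic_cost_{sex}"] = float(result.chronic[:, si].sum())
        out[f"total_cost_{sex}"] = float(result.total[:, si].sum())
    for row in result.by_age_group().itertuples(index=False):
        for component in ("acute", "chronic", "total"):
            out[f"{component}_cost_{row.sex}_{row.age_group}"] = getattr(row, component)
    return out


def run_psa(
    inputs: ProjectionInputs,
    distributions=None,
    n_iter: int = 1000,
    seed: int = 0,
    horizon: int = 20,
    discount: DiscountSpec | None = None,
    fatal_acute_fraction: float = 0.5,
    keep_draws: bool = False,
) -> PSAResult:
    """Monte-Carlo PSA of the full projection + costing pipeline.

    Runs ``n_iter`` projections on drawn input realizations and returns
    percentile (2.5, 97.5) intervals around the deterministic all-means
    point estimate.  Iteration seeds are spawned from ``seed`` so the point
    estimate never depends on ``n_iter`` or ``seed``.
    """
    if n_iter < 2:
        raise ConfigurationError("n_iter must be >= 2")
    if distributions is None:
        distributions = default_distributions(inputs)
    discount = discount or DiscountSpec()

    def evaluate(realized: ProjectionInputs) -> dict:
        trace = run_projection(realized, horizon=horizon, start_year=discount.reference_year)
        assumptions = CostingAssumptions(
            acute_unit_cost=realized.acute_unit_cost,
            chronic_surface=realized.chronic_surface,
            fatal_acute_fraction=fatal_acute_fraction,
        )
        return _headline_quantities(project_costs(trace, assumptions, discount))

    point = evaluate(inputs)

    rows = []
    root = np.random.SeedSequence([int(seed), 555])
    for i, child in enumerate(root.spawn(n_iter)):
        try:
            realized = draw_parameters(inputs, distributions, child)
            rows.append(evaluate(realized))
        except ConfigurationError:
            raise
        except Exception as exc:  # noqa: BLE001 - annotate failing iteration
            raise RuntimeError(f"PSA iteration {i} (seed {seed}) failed: {exc}") from exc
    draws = pd.DataFrame(rows)

    records = []
    for q, p in point.items():
        lo, hi = np.percentile(draws[q].to_numpy(), [2.5, 97.5])
        records.append({"quantity": q, "point": p, "ui_lb": float(lo), "ui_ub": float(hi)})
    return PSAResult(
        quantities=pd.DataFrame(records),
        n_iterations=n_iter,
        master_seed=int(seed),
        draws=draws if keep_draws else None,
    )
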