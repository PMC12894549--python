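"""Scenario engine and comparison statistics.

The base case discounts at 5% per year, costs half of fatal MIs for the
acute event, and projects 20 years (2019-2038).  Scenarios vary the
discount rate (0%, 3%), cost all fatal MIs ("all fatal MI"), or shorten the
horizon to 10 years; everything else is shared.  Comparison statistics are
the exact absolute difference and percent change, rendered at one decimal
(percent) and 0.1-billion granularity (headline AUD) as in published
cost-of-illness tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DomainError
from .costing import CostingAssumptions, DiscountSpec, ProjectionCostResult, project_costs
from .markov import run_projection
from .synthetic import ProjectionInputs

__all__ = [
    "ScenarioConfig",
    "ScenarioComparison",
    "BASE_CASE",
    "STANDARD_SCENARIOS",
    "run_scenario",
    "compare_scenarios",
    "cost_share",
]


@dataclass(frozen=True)
class ScenarioConfig:
    name: str = "base"
    discount_rate: float = 0.05
    fatal_acute_fraction: float = 0.5
    horizon: int = 20
    start_year: int = 2019

    def __post_init__(self):
        if self.discount_rate < 0:
            raise ConfigurationError("discount_rate must be >= 0")
        if not 0.0 <= self.fatal_acute_fraction <= 1.0:
            raise ConfigurationError("fatal_acute_fraction must lie in [0, 1]")
        if self.horizon < 1:
            raise ConfigurationError("horizon must be >= 1")

    @property
    def is_base_case(self) -> bool:
        return (
            self.discount_rate == 0.05
            and self.fatal_acute_fraction == 0.5
            and self.horizon == 20
        )


BASE_CASE = ScenarioConfig()
STANDARD_SCENARIOS = (
    BASE_CASE,
    ScenarioConfig(name="discount_3pct", discount_rate=0.03),
    ScenarioConfig(name="discount_0pct", discount_rate=0.0),
    ScenarioConfig(name="all_fatal_mi", fatal_acute_fraction=1.0),
    ScenarioConfig(name="horizon_10yr", horizon=10),
)


def run_scenario(inputs: ProjectionInputs, config: ScenarioConfig) -> ProjectionCostResult:
    """Full pipeline (projection + costing) under one scenario's settings."""
    trace = run_projection(inputs, horizon=config.horizon, start_year=config.start_year)
    assumptions = CostingAssumptions(
        acute_unit_cost=inputs.acute_unit_cost,
        chronic_surface=inputs.chronic_surface,
        fatal_acute_fraction=config.fatal_acute_fraction,
    )
    spec = DiscountSpec(annual_rate=config.discount_rate, reference_year=config.start_year)
    return project_costs(trace, assumptions, spec)


@dataclass(frozen=True)
class ScenarioComparison:
    base: float
    scenario: float

    @property
    def difference(self) -> float:
        return self.scenario - self.base

    @property
    def percent_change(self) -> float:
        return 100.0 * self.difference / self.base

    @property
    def percent_change_rendered(self) -> float:
        """Percent change at one decimal."""
        return round(self.percent_change, 1)

    @property
    def difference_billions_rendered(self) -> float:
        """Absolute difference at 0.1-billion AUD granularity."""
        return round(self.difference / 1e9, 1)


def compare_scenarios(base: float, scenario: float) -> ScenarioComparison:
    """Exact difference and percent change of a scenario against the base case."""
    if not base > 0:
        raise DomainError(f"base value must be > 0, got {base}")
    return ScenarioComparison(base=float(base), scenario=float(scenario))


def cost_share(components) -> list[tuple[str, float]]:
    """Percent share of each (label, AUD) component, rendered at one decimal."""
    labels = [label for label, _ in components]
    values = np.array([float(v) for _, v in components])
    if np.any(values < 0):
        raise DomainError("cost components must be >= 0")
    total = values.sum()
    if not total > 0:
        raise DomainError("total of components must be > 0")
    return [(label, round(100.0 * v / total, 1)) for label, v in zip(labels, values)]
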