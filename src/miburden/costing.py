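"""Discounted acute, chronic and total cost projection from a state trace.

Acute event costs attach to incident MIs: every non-fatal MI and a
configurable fraction of fatal MIs (base case one half, reflecting the
assumption that half of fatal MIs occur in hospital) incur the uniform acute
unit cost.  Chronic management costs attach to person-years lived with MI:
each end-of-cycle person-year in the new-MI or post-MI states is costed at
the chronic surface value for that sex, current age and follow-up year
(the K+ tunnel maps to the year-K cost).  Person-years themselves are
undiscounted; discounting applies to the monetary flow of each calendar
year, with the first projection year undiscounted (costs are discounted
beyond the first year, per Australian pharmacoeconomic convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, ValidationError
from .grids import AGE_GROUPS, AGES, N_AGES, N_SEXES, SEXES, age_group_label, CostSurface
from .markov import StateTrace

__all__ = [
    "DiscountSpec",
    "CostingAssumptions",
    "ProjectionCostResult",
    "discount_factor",
    "project_acute_costs",
    "project_chronic_costs",
    "aggregate_results",
    "project_costs",
]


@dataclass(frozen=True)
class DiscountSpec:
    """Annual discounting: year k after the reference year gets (1+r)^-k."""

    annual_rate: float = 0.05
    reference_year: int = 2019

    def __post_init__(self):
        if self.annual_rate < 0:
            raise DomainError("discount rate must be >= 0")


def discount_factor(spec: DiscountSpec, calendar_year) -> float | np.ndarray:
    """Discount factor for a calendar year (1.0 in the reference year)."""
    year = np.asarray(calendar_year)
    if np.any(year < spec.reference_year):
        raise DomainError(
            f"calendar year {year.min()} precedes reference year {spec.reference_year}"
        )
    out = (1.0 + spec.annual_rate) ** (-(year - spec.reference_year).astype(float))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class CostingAssumptions:
    acute_unit_cost: float
    chronic_surface: CostSurface
    fatal_acute_fraction: float = 0.5

    def __post_init__(self):
        if not self.acute_unit_cost > 0:
            raise ValidationError("acute_unit_cost must be > 0")
        if not 0.0 <= self.fatal_acute_fraction <= 1.0:
            raise ValidationError("fatal_acute_fraction must lie in [0, 1]")


@dataclass
class ProjectionCostResult:
    """Discounted costs and event counts by (year, sex, age).

    ``acute_n`` counts acute-costed events (non-fatal + fraction x fatal,
    undiscounted); ``chronic_n`` counts prevalent MI person-years.
    ``total`` is exactly ``acute + chronic`` cellwise.
    """

    years: np.ndarray
    acute: np.ndarray
    chronic: np.ndarray
    acute_n: np.ndarray
    chronic_n: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.acute + self.chronic

    def grand_totals(self) -> dict:
        return {
            "acute": float(self.acute.sum()),
            "chronic": float(self.chronic.sum()),
            "total": float(self.total.sum()),
            "acute_n": float(self.acute_n.sum()),
            "chronic_n": float(self.chronic_n.sum()),
        }

    def by_age_group(self) -> pd.DataFrame:
        """Decade-band x sex rollup (plus per-sex and overall totals)."""
        rows = []
        for si, sex in enumerate(SEXES + ("total",)):
            sel = slice(None) if sex == "total" else slice(si, si + 1)
            for lo, hi in AGE_GROUPS:
                a = slice(lo - 30, hi - 30 + 1)
                rows.append(
                    {
                        "sex": sex,
                        "age_group": age_group_label(lo, hi),
                        "acute_n": float(self.acute_n[:, sel, a].sum()),
                        "chronic_n": float(self.chronic_n[:, sel, a].sum()),
                        "acute": float(self.acute[:, sel, a].sum()),
                        "chronic": float(self.chronic[:, sel, a].sum()),
                        "total": float(self.total[:, sel, a].sum()),
                    }
                )
            rows.append(
                {
                    "sex": sex,
                    "age_group": "Total",
                    "acute_n": float(self.acute_n[:, sel].sum()),
                    "chronic_n": float(self.chronic_n[:, sel].sum()),
                    "acute": float(self.acute[:, sel].sum()),
                    "chronic": float(self.chronic[:, sel].sum()),
                    "total": float(self.total[:, sel].sum()),
                }
            )
        return pd.DataFrame(rows)

    def by_year(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.years,
                "acute": self.acute.sum(axis=(1, 2)),
                "chronic": self.chronic.sum(axis=(1, 2)),
                "total": self.total.sum(axis=(1, 2)),
            }
        )


def _check_axes(trace: StateTrace, spec: DiscountSpec) -> np.ndarray:
    factors = discount_factor(spec, trace.years)
    return np.asarray(factors)


def project_acute_costs(
    trace: StateTrace, assumptions: CostingAssumptions, spec: DiscountSpec
) -> ProjectionCostResult:
    """Acute component: (non-fatal + fraction x fatal events) x unit cost, discounted."""
    factors = _check_axes(trace, spec)
    n = trace.new_mi_nonfatal + assumptions.fatal_acute_fraction * trace.new_mi_fatal
    acute = n * assumptions.acute_unit_cost * factors[:, None, None]
    zero = np.zeros_like(acute)
    return ProjectionCostResult(
        years=trace.years, acute=acute, chronic=zero, acute_n=n, chronic_n=zero
    )


def project_chronic_costs(
    trace: StateTrace, assumptions: CostingAssumptions, spec: DiscountSpec
) -> ProjectionCostResult:
    """Chronic component: undiscounted MI person-years x cost surface, discounted flows."""
    factors = _check_axes(trace, spec)
    surface = assumptions.chronic_surface
    if surface.n_follow_up < trace.n_follow_up:
        raise ValidationError(
            f"chronic surface covers {surface.n_follow_up} follow-up years but the "
            f"trace occupies {trace.n_follow_up}"
        )
    py = trace.mi_person_years_by_follow_up()  # (year, sex, age, fy 1..K)
    costed = py * surface.values[None, :, :, : py.shape[3]]
    chronic = costed.sum(axis=3) * factors[:, None, None]
    zero = np.zeros_like(chronic)
    return ProjectionCostResult(
        years=trace.years,
        acute=zero,
        chronic=chronic,
        acute_n=zero,
        chronic_n=py.sum(axis=3),
    )


def aggregate_results(
    acute: ProjectionCostResult, chronic: ProjectionCostResult
) -> ProjectionCostResult:
    """Combine the components; total = acute + chronic exactly, cellwise."""
    if not np.array_equal(acute.years, chronic.years):
        raise ValidationError("acute and chronic components cover different years")
    return ProjectionCostResult(
        years=acute.years,
        acute=acute.acute,
        chronic=chronic.chronic,
        acute_n=acute.acute_n,
        chronic_n=chronic.chronic_n,
    )


def project_costs(
    trace: StateTrace, assumptions: CostingAssumptions, spec: DiscountSpec
) -> ProjectionCostResult:
    """Acute + chronic costing of a trace in one call."""
    return aggregate_results(
        project_acute_costs(trace, assumptions, spec),
        project_chronic_costs(trace, assumptions, spec),
    )
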