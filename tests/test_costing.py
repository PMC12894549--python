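"""Discounting and cost aggregation."""

import numpy as np
import pytest

from miburden import (
    CostingAssumptions,
    DiscountSpec,
    discount_factor,
    project_acute_costs,
    project_chronic_costs,
    project_costs,
    aggregate_results,
)
from miburden.errors import DomainError, ValidationError
from miburden.grids import CostSurface
from miburden.markov import StateTrace


def make_trace(nonfatal=0.0, fatal=0.0, post_py=0.0, years=(2019,)):
    """Minimal hand-built trace with events/occupancy in one age-sex cell."""
    T = len(years)
    shape = (T, 2, 70)
    trace = StateTrace(
        years=np.asarray(years),
        alive_no_mi=np.zeros(shape),
        alive_new_mi=np.zeros(shape),
        alive_post_mi=np.zeros(shape + (5,)),
        new_mi_nonfatal=np.zeros(shape),
        new_mi_fatal=np.zeros(shape),
        deaths_other=np.zeros(shape),
        deaths_post_mi=np.zeros(shape),
        exited_alive=np.zeros((T, 2)),
    )
    trace.new_mi_nonfatal[0, 0, 30] = nonfatal
    trace.new_mi_fatal[0, 0, 30] = fatal
    trace.alive_post_mi[0, 0, 30, 0] = post_py
    return trace


def flat_surface(cost):
    return CostSurface(values=np.full((2, 70, 6), float(cost)))


class TestDiscountFactor:
    def test_zero_rate_is_unity(self):
        assert discount_factor(DiscountSpec(annual_rate=0.0), 2035) == 1.0

    def test_reference_year_undiscounted(self):
        assert discount_factor(DiscountSpec(), 2019) == 1.0

    def test_closed_form_value(self):
        assert discount_factor(DiscountSpec(), 2020) == pytest.approx(0.9523810, abs=5e-8)

    def test_twenty_year_annuity_sum(self):
        total = sum(discount_factor(DiscountSpec(), y) for y in range(2019, 2039))
        assert total == pytest.approx(13.08532, abs=1e-5)

    def test_year_before_reference_rejected(self):
        with pytest.raises(DomainError):
            discount_factor(DiscountSpec(), 2018)


class TestAcuteCosting:
    def test_arithmetic_half_fatal(self):
        trace = make_trace(nonfatal=100, fatal=10)
        assumptions = CostingAssumptions(10_000.0, flat_surface(1.0), fatal_acute_fraction=0.5)
        result = project_acute_costs(trace, assumptions, DiscountSpec(annual_rate=0.0))
        assert result.acute.sum() == pytest.approx(1_050_000.0)

    def test_arithmetic_all_fatal(self):
        trace = make_trace(nonfatal=100, fatal=10)
        assumptions = CostingAssumptions(10_000.0, flat_surface(1.0), fatal_acute_fraction=1.0)
        result = project_acute_costs(trace, assumptions, DiscountSpec(annual_rate=0.0))
        assert result.acute.sum() == pytest.approx(1_100_000.0)

    def test_zero_events_zero_cost(self):
        result = project_acute_costs(
            make_trace(), CostingAssumptions(10_000.0, flat_surface(1.0)), DiscountSpec()
        )
        assert result.acute.sum() == 0.0


class TestChronicCosting:
    def test_person_years_times_unit_cost(self):
        trace = make_trace(post_py=10)
        result = project_chronic_costs(
            trace, CostingAssumptions(1.0, flat_surface(14_412.0)), DiscountSpec(annual_rate=0.0)
        )
        assert result.chronic.sum() == pytest.approx(144_120.0)

    def test_zero_occupancy_zero_cost(self):
        result = project_chronic_costs(
            make_trace(), CostingAssumptions(1.0, flat_surface(14_412.0)), DiscountSpec()
        )
        assert result.chronic.sum() == 0.0

    def test_flat_surface_factorizes(self, inputs_default, base_trace):
        c = 9_000.0
        result = project_chronic_costs(
            base_trace,
            CostingAssumptions(1.0, flat_surface(c)),
            DiscountSpec(annual_rate=0.0),
        )
        assert result.chronic.sum() == pytest.approx(c * base_trace.mi_person_years().sum(), rel=1e-12)

    def test_short_surface_rejected(self, base_trace):
        short = CostSurface(values=np.full((2, 70, 2), 100.0))
        with pytest.raises(ValidationError, match="follow-up"):
            project_chronic_costs(base_trace, CostingAssumptions(1.0, short), DiscountSpec())


class TestAggregation:
    def test_total_is_exact_sum(self, inputs_default, base_trace):
        assumptions = CostingAssumptions(
            inputs_default.acute_unit_cost, inputs_default.chronic_surface
        )
        spec = DiscountSpec()
        acute = project_acute_costs(base_trace, assumptions, spec)
        chronic = project_chronic_costs(base_trace, assumptions, spec)
        combined = aggregate_results(acute, chronic)
        np.testing.assert_array_equal(combined.total, combined.acute + combined.chronic)

    def test_band_rollup_conserves_grand_total(self, inputs_default, base_trace):
        result = project_costs(
            base_trace,
            CostingAssumptions(inputs_default.acute_unit_cost, inputs_default.chronic_surface),
            DiscountSpec(),
        )
        groups = result.by_age_group()
        total_row = groups[(groups["sex"] == "total") & (groups["age_group"] == "Total")]
        bands = groups[(groups["sex"] == "total") & (groups["age_group"] != "Total")]
        assert total_row["total"].iloc[0] == pytest.approx(bands["total"].sum(), rel=1e-6)
        assert total_row["total"].iloc[0] == pytest.approx(result.total.sum(), rel=1e-12)

    def test_scale_equivariance(self, inputs_default, base_trace):
        spec = DiscountSpec()
        base = project_costs(
            base_trace,
            CostingAssumptions(inputs_default.acute_unit_cost, inputs_default.chronic_surface),
            spec,
        )
        scaled = project_costs(
            base_trace,
            CostingAssumptions(
                3.0 * inputs_default.acute_unit_cost,
                CostSurface(values=3.0 * inputs_default.chronic_surface.values),
            ),
            spec,
        )
        np.testing.assert_allclose(scaled.total, 3.0 * base.total, rtol=1e-12)

    def test_discount_monotonicity(self, inputs_default, base_trace):
        totals = []
        for r in (0.0, 0.03, 0.05):
            result = project_costs(
                base_trace,
                CostingAssumptions(inputs_default.acute_unit_cost, inputs_default.chronic_surface),
                DiscountSpec(annual_rate=r),
            )
            totals.append(result.total.sum())
        assert totals[0] > totals[1] > totals[2]

    def test_horizon_nesting(self, inputs_default, base_trace):
        from miburden import run_projection

        assumptions = CostingAssumptions(
            inputs_default.acute_unit_cost, inputs_default.chronic_surface
        )
        spec = DiscountSpec()
        full = project_costs(base_trace, assumptions, spec)
        short_trace = run_projection(inputs_default, horizon=10)
        short = project_costs(short_trace, assumptions, spec)
        partial = full.total[np.isin(full.years, short.years)].sum()
        assert short.total.sum() == pytest.approx(partial, rel=1e-12)
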