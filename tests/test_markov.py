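"""Markov engine: probability conversion, competing risks, projection bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from miburden import (
    TransitionRates,
    build_transition_probabilities,
    competing_split,
    generate_projection_inputs,
    microsim_oracle,
    rate_to_prob,
    run_projection,
)
from miburden.errors import DomainError, ValidationError


class TestRateToProb:
    def test_zero_rate(self):
        assert rate_to_prob(0.0, 1.0) == 0.0

    def test_known_value(self):
        assert rate_to_prob(0.04, 1.0) == pytest.approx(0.0392106, abs=5e-8)

    def test_saturation(self):
        # strictly below 1 while the gap is representable; at rate 1e3 the
        # probability saturates to 1.0 within double precision
        assert rate_to_prob(30.0, 1.0) < 1.0
        assert 1 - 1e-9 <= rate_to_prob(1e3, 1.0) <= 1.0

    def test_negative_rate_rejected(self):
        with pytest.raises(DomainError):
            rate_to_prob(-0.1, 1.0)

    @given(st.floats(min_value=0.0, max_value=1e-4))
    @settings(max_examples=50, deadline=None)
    def test_small_rate_limit(self, rate):
        # 1 - exp(-r) = r - r^2/2 + ...: error below r^2
        assert abs(rate_to_prob(rate, 1.0) - rate) <= rate**2


class TestCompetingSplit:
    def test_closed_form(self):
        tp_mi, tp_other = competing_split(0.01, 0.03, 1.0)
        assert tp_mi == pytest.approx(0.0098026, abs=5e-8)
        assert tp_other == pytest.approx(0.0294079, abs=5e-8)
        assert tp_mi + tp_other == pytest.approx(1 - np.exp(-0.04), rel=1e-12)

    def test_single_risk_reduction(self):
        tp_mi, tp_other = competing_split(0.0, 0.2, 1.0)
        assert tp_mi == 0.0
        assert tp_other == pytest.approx(1 - np.exp(-0.2), rel=1e-12)

    def test_degenerate_zero_rates(self):
        assert competing_split(0.0, 0.0, 1.0) == (0.0, 0.0)

    @given(
        st.floats(min_value=0.0, max_value=5.0),
        st.floats(min_value=0.0, max_value=5.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_split_sums_to_tpsum(self, lam, mu):
        tp_mi, tp_other = competing_split(lam, mu, 1.0)
        tpsum = rate_to_prob(lam + mu, 1.0)
        assert 0.0 <= tp_mi <= 1.0 and 0.0 <= tp_other <= 1.0
        assert abs(tp_mi + tp_other - tpsum) <= 1e-12


class TestBuildTransitionProbabilities:
    def test_all_zero_rates(self):
        zeros = np.zeros((2, 70))
        tp = build_transition_probabilities(
            TransitionRates(zeros, zeros, zeros, zeros)
        )
        assert np.all(tp.tpsum == 0)
        assert np.all(tp.tp_death_post == 0)

    def test_all_fatal(self, inputs_default):
        rates = inputs_default.rates
        tp = build_transition_probabilities(
            TransitionRates(
                rates.incidence, rates.mortality_other,
                rates.mortality_post_mi, np.ones((2, 70)),
            )
        )
        assert np.all(tp.tp_mi_nonfatal == 0)
        np.testing.assert_allclose(tp.tp_mi_fatal, tp.tp_mi)

    def test_identity_holds_on_default_grid(self, inputs_default):
        tp = build_transition_probabilities(inputs_default.rates)
        expected = rate_to_prob(
            inputs_default.rates.incidence + inputs_default.rates.mortality_other
        )
        assert np.max(np.abs(tp.tp_mi + tp.tp_death_other - expected)) <= 1e-12

    def test_incomplete_grid_rejected(self):
        with pytest.raises(ValidationError):
            TransitionRates(
                np.zeros((2, 69)), np.zeros((2, 70)), np.zeros((2, 70)), np.zeros((2, 70))
            )


class TestRunProjection:
    def test_zero_rates_conserve_population(self):
        inputs = generate_projection_inputs(
            seed=0,
            scale_options={
                "incidence": 0.0, "mortality_other": 0.0, "mortality_post_mi": 0.0,
                "migration": 0.0, "entry": 0.0,
            },
        )
        trace = run_projection(inputs, horizon=20)
        # no deaths; alive + cumulative alive-exits equals initial stock
        assert trace.deaths().sum() == 0
        initial = inputs.initial_population.sum()
        for t in range(20):
            # census at t still includes that cycle's 99-year-olds; earlier
            # cycles' alive-exits left the model
            total = trace.alive()[t].sum() + trace.exited_alive[:t].sum()
            assert total == pytest.approx(initial, rel=1e-12)

    def test_all_fatal_empties_new_mi_state(self, inputs_default):
        inputs = generate_projection_inputs(seed=0, scale_options={"p_fatal": 100.0})
        assert np.all(inputs.rates.p_fatal == 1.0)  # clipped to 1
        trace = run_projection(inputs, horizon=10)
        assert trace.alive_new_mi.sum() == 0
        assert trace.new_mi_nonfatal.sum() == 0
        # prevalent pool still contributes MI person-years
        assert trace.mi_person_years().sum() > 0

    def test_accounting_identity_each_cycle(self, inputs_default, base_trace):
        trace = base_trace
        inflow = inputs_default.entry_cohort.sum() + inputs_default.net_migration.sum()
        initial = inputs_default.initial_population.sum()
        for t in range(len(trace.years)):
            lhs = trace.alive()[t].sum()
            rhs = (
                initial
                + (t + 1) * inflow
                - trace.deaths()[: t + 1].sum()
                - trace.exited_alive[: t].sum()
            )
            assert abs(lhs - rhs) / rhs < 1e-9

    def test_occupancies_nonnegative_and_deaths_monotone(self, base_trace):
        assert np.all(base_trace.alive_no_mi >= 0)
        assert np.all(base_trace.alive_new_mi >= 0)
        assert np.all(base_trace.alive_post_mi >= 0)
        cum = np.cumsum(base_trace.deaths().sum(axis=(1, 2)))
        assert np.all(np.diff(cum) >= 0)

    def test_doubling_mortality_never_increases_mi_person_years(self, base_trace):
        doubled = generate_projection_inputs(
            seed=1, scale_options={"mortality_other": 2.0, "mortality_post_mi": 2.0}
        )
        trace2 = run_projection(doubled)
        assert trace2.mi_person_years().sum() <= base_trace.mi_person_years().sum()

    def test_small_rate_limit_matches_linearized_hand_calculation(self):
        eps = 1e-5
        inputs = generate_projection_inputs(
            seed=0,
            scale_options={
                "incidence": 0.0, "mortality_other": 0.0, "mortality_post_mi": 0.0,
                "migration": 0.0, "entry": 0.0, "prevalence": 0.0,
            },
        )
        from dataclasses import replace

        zeros = np.zeros((2, 70))
        inputs = replace(
            inputs,
            rates=TransitionRates(np.full((2, 70), eps), zeros, zeros, inputs.rates.p_fatal),
        )
        trace = run_projection(inputs, horizon=1)
        # expected new MIs ~= population * eps * (1 - p_fatal applied after)
        expected = (inputs.initial_population * eps).sum()
        observed = (trace.new_mi_nonfatal + trace.new_mi_fatal).sum()
        assert abs(observed - expected) / expected < eps

    def test_bad_horizon_rejected(self, inputs_default):
        with pytest.raises(ValidationError):
            run_projection(inputs_default, horizon=0)


class TestMicrosimOracle:
    def test_zero_rates_produce_no_events(self):
        inputs = generate_projection_inputs(
            seed=0,
            scale_options={"incidence": 0.0, "mortality_other": 0.0, "mortality_post_mi": 0.0},
        )
        trace = microsim_oracle(inputs, n_individuals=20_000, seed=4, horizon=5)
        assert trace.new_mi_nonfatal.sum() == 0
        assert trace.deaths().sum() == 0

    def test_fixed_seed_reproducible(self, inputs_default):
        a = microsim_oracle(inputs_default, n_individuals=10_000, seed=8, horizon=5)
        b = microsim_oracle(inputs_default, n_individuals=10_000, seed=8, horizon=5)
        np.testing.assert_array_equal(a.alive(), b.alive())

    def test_years_with_mi_agree_with_deterministic_engine(self, inputs_default, base_trace):
        oracle = microsim_oracle(inputs_default, n_individuals=100_000, seed=12)
        det = base_trace.mi_person_years().sum()
        assert abs(oracle.mi_person_years().sum() - det) / det < 0.02
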