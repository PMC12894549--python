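"""Stochastic individual-level oracle for the cohort projection engine.

Simulates an integer population whose members each draw their annual
transition from the same transition probabilities the deterministic engine
uses, then rescales to population totals.  Draws are made cell-by-cell
(multinomial per age x sex x state cell), which is distributionally
identical to looping over individuals.  The initial population is an exact
multinomial allocation of ``n_individuals`` across cells; per-cycle entry
cohorts and migrants arrive as Poisson counts at the scaled means.

This is a validation tool: its expectation equals the deterministic
:func:`~miburden.markov.run_projection` trace, so agreement within sampling
error is evidence the cohort engine's bookkeeping is right.
"""

from __future__ import annotations

import numpy as np

from .errors import ValidationError
from .grids import N_AGES, N_SEXES
from .markov import StateTrace, _age_shift, _allocate_trace, build_transition_probabilities

__all__ = ["microsim_oracle"]


def microsim_oracle(
    inputs,
    n_individuals: int,
    seed: int,
    horizon: int = 20,
    start_year: int = 2019,
) -> StateTrace:
    """Run the stochastic microsimulation and return a population-scaled trace."""
    if n_individuals < 1:
        raise ValidationError("n_individuals must be >= 1")
    inputs.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 977]))
    tp = build_transition_probabilities(inputs.rates)
    n_tunnels = inputs.chronic_surface.n_follow_up - 1

    total_pop = float(inputs.initial_population.sum())
    if total_pop <= 0:
        raise ValidationError("initial population is empty")
    scale = n_individuals / total_pop

    # exact multinomial allocation of individuals over (sex, age, state) cells
    pop_weights = inputs.initial_population.ravel() / total_pop
    counts = rng.multinomial(n_individuals, pop_weights).reshape(N_SEXES, N_AGES)
    prevalent = rng.binomial(counts, inputs.mi_prevalence)
    no_mi = (counts - prevalent).astype(np.int64)
    new_mi = np.zeros((N_SEXES, N_AGES), dtype=np.int64)
    post_mi = np.zeros((N_SEXES, N_AGES, n_tunnels), dtype=np.int64)
    post_mi[:, :, -1] = prevalent

    trace = _allocate_trace(horizon, n_tunnels)
    years = np.arange(start_year, start_year + horizon)

    p_no_mi = np.stack(
        [
            tp.tp_mi_nonfatal,
            tp.tp_mi_fatal,
            tp.tp_death_other,
            1.0 - tp.tp_mi_nonfatal - tp.tp_mi_fatal - tp.tp_death_other,
        ],
        axis=-1,
    )
    p_no_mi = np.clip(p_no_mi, 0.0, 1.0)
    p_no_mi /= p_no_mi.sum(axis=-1, keepdims=True)

    for t in range(horizon):
        # inflow (Poisson at the scaled means, prevalence-split)
        entry = rng.poisson(inputs.entry_cohort * scale)
        entry_prev = rng.binomial(entry, inputs.mi_prevalence[:, 0])
        no_mi[:, 0] += entry - entry_prev
        post_mi[:, 0, -1] += entry_prev
        mig = rng.poisson(inputs.net_migration * scale)
        mig_prev = rng.binomial(mig, inputs.mi_prevalence)
        no_mi += mig - mig_prev
        post_mi[:, :, -1] += mig_prev

        # transitions
        draws = rng.multinomial(no_mi, p_no_mi)
        mi_nonfatal, mi_fatal, d_other = draws[..., 0], draws[..., 1], draws[..., 2]
        no_mi = draws[..., 3]
        d_new = rng.binomial(new_mi, tp.tp_death_post)
        to_first = new_mi - d_new
        d_post = rng.binomial(post_mi, tp.tp_death_post[:, :, None])
        surv = post_mi - d_post
        post_next = np.zeros_like(post_mi)
        post_next[:, :, 0] = to_first
        post_next[:, :, 1:] = surv[:, :, :-1]
        post_next[:, :, -1] += surv[:, :, -1]
        post_mi = post_next
        new_mi = mi_nonfatal

        trace["alive_no_mi"][t] = no_mi
        trace["alive_new_mi"][t] = new_mi
        trace["alive_post_mi"][t] = post_mi
        trace["new_mi_nonfatal"][t] = mi_nonfatal
        trace["new_mi_fatal"][t] = mi_fatal
        trace["deaths_other"][t] = d_other
        trace["deaths_post_mi"][t] = d_new + d_post.sum(axis=2)
        trace["exited_alive"][t] = (
            no_mi[:, -1] + new_mi[:, -1] + post_mi[:, -1, :].sum(axis=1)
        )

        no_mi = _age_shift(no_mi)
        new_mi = _age_shift(new_mi)
        post_mi = _age_shift(post_mi)

    for key in trace:
        trace[key] = trace[key] / scale
    return StateTrace(
        years=years,
        start_population=counts / scale,
        **trace,
    )
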