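"""Dynamic multistate Markov engine for projecting the burden of myocardial infarction.

The model follows the Australian population aged 30-99 in annual cycles.
Health states:

* ``ALIVE_NO_MI`` -- never had an MI;
* ``ALIVE_NEW_MI`` -- non-fatal MI this cycle (occupied for exactly one cycle,
  follow-up year 1);
* ``ALIVE_POST_MI`` -- survivors of an earlier MI, tracked through follow-up
  year tunnels 2..K with the last tunnel a "K+" cap so time-varying chronic
  costs can be attached;
* three absorbing death states: other-cause death, fatal MI (death at the
  event, governed by ``p_fatal``), and post-MI death.

Transitions are driven by age- and sex-specific rates converted to annual
probabilities via ``1 - exp(-rate)``; the exit probability from the no-MI
state is split between MI and other-cause death in proportion to their rates
(exponential competing risks).  The model is dynamic: a new cohort of
30-year-olds and net migrants enter at the start of every cycle, split
between the no-MI and post-MI states by MI prevalence.  Individuals who age
past 99 exit alive.  Rates are held constant over calendar time.

Each cycle performs, in order: (1) demographic inflow, (2) transitions
(which also advance the post-MI tunnels), (3) ageing.  The recorded state
occupancy is the end-of-cycle census at the age at which the cycle was
lived; occupancy of the two MI states summed over cycles is the model's
"years of life lived with MI", the quantity the chronic costing consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, ValidationError
from .grids import AGES, N_AGES, N_SEXES, SEXES, validate_age_sex_grid

__all__ = [
    "HealthState",
    "TransitionRates",
    "TransitionProbabilities",
    "StateTrace",
    "rate_to_prob",
    "competing_split",
    "build_transition_probabilities",
    "run_projection",
]

DEFAULT_START_YEAR = 2019
DEFAULT_HORIZON = 20


class HealthState:
    """State labels used in serialized traces."""

    ALIVE_NO_MI = "alive_no_mi"
    ALIVE_NEW_MI = "alive_new_mi"
    ALIVE_POST_MI = "alive_post_mi"
    DEATH_OTHER = "death_other"
    DEATH_FATAL_MI = "death_fatal_mi"
    DEATH_POST_MI = "death_post_mi"


@dataclass(frozen=True)
class TransitionRates:
    """Age- and sex-specific annual rates and the fatal-MI proportion.

    ``incidence`` (events/person-year) and ``mortality_other``
    (deaths/person-year) govern exits from the no-MI state;
    ``mortality_post_mi`` is the all-cause death rate applied to both MI
    states; ``p_fatal`` is the proportion of incident MIs fatal at the event.
    All arrays are ``(sex, age)`` over the complete 30..99 grid.
    """

    incidence: np.ndarray
    mortality_other: np.ndarray
    mortality_post_mi: np.ndarray
    p_fatal: np.ndarray
    cycle_length: float = 1.0

    def __post_init__(self):
        for name in ("incidence", "mortality_other", "mortality_post_mi", "p_fatal"):
            arr = validate_age_sex_grid(getattr(self, name), name)
            if np.any(arr < 0.0):
                raise ValidationError(f"{name} contains negative cells")
            object.__setattr__(self, name, arr)
        if np.any(self.p_fatal > 1.0):
            raise ValidationError("p_fatal must lie in [0, 1]")
        if not self.cycle_length > 0:
            raise DomainError("cycle_length must be > 0")


@dataclass(frozen=True)
class TransitionProbabilities:
    """Per-cycle transition probabilities derived from :class:`TransitionRates`."""

    tp_mi: np.ndarray
    tp_death_other: np.ndarray
    tp_mi_fatal: np.ndarray
    tp_mi_nonfatal: np.ndarray
    tp_death_post: np.ndarray

    @property
    def tpsum(self) -> np.ndarray:
        return self.tp_mi + self.tp_death_other


def rate_to_prob(rate, cycle_length: float = 1.0):
    """Convert an event rate (events/person-year) to a per-cycle probability.

    Uses the constant-rate exponential relation ``1 - exp(-rate * l)``.
    """
    rate = np.asarray(rate, dtype=float)
    if np.any(rate < 0):
        raise DomainError("rate must be >= 0")
    if not cycle_length > 0:
        raise DomainError("cycle_length must be > 0")
    out = -np.expm1(-rate * cycle_length)
    return out if out.ndim else float(out)


def competing_split(incidence, mortality_other, cycle_length: float = 1.0):
    """Split the combined exit probability from the no-MI state by cause.

    The total exit probability ``tpsum = 1 - exp(-(lambda + mu_other) * l)``
    is allocated to MI and other-cause death in proportion to their rates;
    a zero rate sum yields (0, 0).
    """
    lam = np.asarray(incidence, dtype=float)
    mu = np.asarray(mortality_other, dtype=float)
    if np.any(lam < 0) or np.any(mu < 0):
        raise DomainError("rates must be >= 0")
    ratesum = lam + mu
    tpsum = rate_to_prob(ratesum, cycle_length)
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(ratesum > 0, lam / np.where(ratesum > 0, ratesum, 1.0), 0.0)
    tp_mi = np.asarray(tpsum) * share
    tp_death_other = np.asarray(tpsum) - tp_mi
    if tp_mi.ndim:
        return tp_mi, tp_death_other
    return float(tp_mi), float(tp_death_other)


def build_transition_probabilities(rates: TransitionRates) -> TransitionProbabilities:
    """Convert a complete rate grid into per-cycle transition probabilities."""
    tp_mi, tp_death_other = competing_split(
        rates.incidence, rates.mortality_other, rates.cycle_length
    )
    tp_mi_fatal = tp_mi * rates.p_fatal
    tp_mi_nonfatal = tp_mi - tp_mi_fatal
    tp_death_post = rate_to_prob(rates.mortality_post_mi, rates.cycle_length)
    return TransitionProbabilities(
        tp_mi=tp_mi,
        tp_death_other=tp_death_other,
        tp_mi_fatal=tp_mi_fatal,
        tp_mi_nonfatal=tp_mi_nonfatal,
        tp_death_post=np.asarray(tp_death_post),
    )


@dataclass
class StateTrace:
    """End-of-cycle census and event counts from a projection run.

    Occupancy arrays are ``(year, sex, age)``; ``alive_post_mi`` carries an
    extra trailing axis for the follow-up-year tunnel (follow-up years
    ``2..K``, last slot capped at K+).  ``alive_new_mi`` is follow-up year 1.
    Event arrays count transitions during each cycle.  ``exited_alive`` are
    individuals ageing past 99, tracked separately from deaths.
    """

    years: np.ndarray
    alive_no_mi: np.ndarray
    alive_new_mi: np.ndarray
    alive_post_mi: np.ndarray  # (year, sex, age, tunnel)
    new_mi_nonfatal: np.ndarray
    new_mi_fatal: np.ndarray
    deaths_other: np.ndarray
    deaths_post_mi: np.ndarray
    exited_alive: np.ndarray  # (year, sex)
    start_population: np.ndarray = field(default=None)  # (sex, age) cycle-0 stock

    @property
    def n_follow_up(self) -> int:
        return self.alive_post_mi.shape[3] + 1

    def mi_person_years(self) -> np.ndarray:
        """Person-years lived with MI per (year, sex, age) -- end-of-cycle census."""
        return self.alive_new_mi + self.alive_post_mi.sum(axis=3)

    def mi_person_years_by_follow_up(self) -> np.ndarray:
        """Person-years with MI per (year, sex, age, follow_up_year 1..K)."""
        return np.concatenate([self.alive_new_mi[..., None], self.alive_post_mi], axis=3)

    def alive(self) -> np.ndarray:
        """Total alive occupancy per (year, sex, age)."""
        return self.alive_no_mi + self.mi_person_years()

    def deaths(self) -> np.ndarray:
        return self.deaths_other + self.new_mi_fatal + self.deaths_post_mi

    def to_frame(self) -> "pd.DataFrame":
        import pandas as pd

        frames = []
        for name, arr in (
            (HealthState.ALIVE_NO_MI, self.alive_no_mi),
            (HealthState.ALIVE_NEW_MI, self.alive_new_mi),
            (HealthState.DEATH_OTHER, np.cumsum(self.deaths_other, axis=0)),
            (HealthState.DEATH_FATAL_MI, np.cumsum(self.new_mi_fatal, axis=0)),
            (HealthState.DEATH_POST_MI, np.cumsum(self.deaths_post_mi, axis=0)),
        ):
            y, s, a = np.meshgrid(self.years, np.arange(N_SEXES), AGES, indexing="ij")
            frames.append(
                pd.DataFrame(
                    {
                        "year": y.ravel(),
                        "age": a.ravel(),
                        "sex": np.asarray(SEXES)[s.ravel()],
                        "state": name,
                        "tunnel": 0,
                        "count": arr.ravel(),
                    }
                )
            )
        n_t = self.alive_post_mi.shape[3]
        y, s, a, t = np.meshgrid(
            self.years, np.arange(N_SEXES), AGES, np.arange(2, n_t + 2), indexing="ij"
        )
        frames.append(
            pd.DataFrame(
                {
                    "year": y.ravel(),
                    "age": a.ravel(),
                    "sex": np.asarray(SEXES)[s.ravel()],
                    "state": HealthState.ALIVE_POST_MI,
                    "tunnel": t.ravel(),
                    "count": self.alive_post_mi.ravel(),
                }
            )
        )
        return pd.concat(frames, ignore_index=True)


def _allocate_trace(n_years: int, n_tunnels: int) -> dict:
    shape = (n_years, N_SEXES, N_AGES)
    return {
        "alive_no_mi": np.zeros(shape),
        "alive_new_mi": np.zeros(shape),
        "alive_post_mi": np.zeros(shape + (n_tunnels,)),
        "new_mi_nonfatal": np.zeros(shape),
        "new_mi_fatal": np.zeros(shape),
        "deaths_other": np.zeros(shape),
        "deaths_post_mi": np.zeros(shape),
        "exited_alive": np.zeros((n_years, N_SEXES)),
    }


def run_projection(
    inputs,
    horizon: int = DEFAULT_HORIZON,
    start_year: int = DEFAULT_START_YEAR,
) -> StateTrace:
    """Run the deterministic cohort-expectation projection.

    ``inputs`` is a :class:`~miburden.synthetic.ProjectionInputs`.  The
    initial population (calendar year ``start_year - 1``) is split between
    the no-MI state and the post-MI K+ tunnel by MI prevalence; each of the
    ``horizon`` annual cycles then applies inflow, transitions and ageing as
    described in the module docstring.
    """
    if horizon < 1:
        raise ValidationError(f"horizon must be >= 1, got {horizon}")
    inputs.validate()
    tp = build_transition_probabilities(inputs.rates)
    n_tunnels = inputs.chronic_surface.n_follow_up - 1
    if n_tunnels < 1:
        raise ValidationError("chronic cost surface needs >= 2 follow-up years (tunnels)")

    trace = _allocate_trace(horizon, n_tunnels)
    years = np.arange(start_year, start_year + horizon)

    prev = inputs.mi_prevalence
    no_mi = inputs.initial_population * (1.0 - prev)
    new_mi = np.zeros((N_SEXES, N_AGES))
    post_mi = np.zeros((N_SEXES, N_AGES, n_tunnels))
    post_mi[:, :, -1] = inputs.initial_population * prev  # prevalent pool at K+
    start_population = inputs.initial_population.copy()

    for t in range(horizon):
        # (1) demographic inflow: 30-year-old entry cohort + net migrants,
        # split by MI prevalence (prevalent entrants join the K+ tunnel)
        no_mi[:, 0] += inputs.entry_cohort * (1.0 - prev[:, 0])
        post_mi[:, 0, -1] += inputs.entry_cohort * prev[:, 0]
        no_mi += inputs.net_migration * (1.0 - prev)
        post_mi[:, :, -1] += inputs.net_migration * prev

        # (2) transitions at current age
        mi_nonfatal = no_mi * tp.tp_mi_nonfatal
        mi_fatal = no_mi * tp.tp_mi_fatal
        d_other = no_mi * tp.tp_death_other
        no_mi = no_mi - mi_nonfatal - mi_fatal - d_other

        d_new = new_mi * tp.tp_death_post
        to_first_tunnel = new_mi - d_new
        d_post = post_mi * tp.tp_death_post[:, :, None]
        surv = post_mi - d_post

        post_next = np.zeros_like(post_mi)
        post_next[:, :, 0] = to_first_tunnel
        post_next[:, :, 1:] = surv[:, :, :-1]
        post_next[:, :, -1] += surv[:, :, -1]  # K+ cap absorbs
        post_mi = post_next
        new_mi = mi_nonfatal

        trace["alive_no_mi"][t] = no_mi
        trace["alive_new_mi"][t] = new_mi
        trace["alive_post_mi"][t] = post_mi
        trace["new_mi_nonfatal"][t] = mi_nonfatal
        trace["new_mi_fatal"][t] = mi_fatal
        trace["deaths_other"][t] = d_other
        trace["deaths_post_mi"][t] = d_new + d_post.sum(axis=2)

        # (3) ageing: shift along the age axis; age-99 occupants exit alive
        trace["exited_alive"][t] = (
            no_mi[:, -1] + new_mi[:, -1] + post_mi[:, -1, :].sum(axis=1)
        )
        no_mi = _age_shift(no_mi)
        new_mi = _age_shift(new_mi)
        post_mi = _age_shift(post_mi)

        if (
            np.any(no_mi < 0)
            or np.any(new_mi < 0)
            or np.any(post_mi < 0)
        ):
            raise RuntimeError(f"negative occupancy at cycle {int(years[t])}")

    return StateTrace(years=years, start_population=start_population, **trace)


def _age_shift(arr: np.ndarray) -> np.ndarray:
    out = np.zeros_like(arr)
    out[:, 1:] = arr[:, :-1]
    return out
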