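"""The long-term Markov cohort model.

The 90-day survivors are projected over annual cycles (default horizon 30
years) across four health states — minor/no disability (mRS 0–2), moderate
disability (mRS 3–4), severe disability (mRS 5) and death (mRS 6).  Each
cycle an alive patient faces, as mutually exclusive branches applied in
order to the residual mass: recurrent stroke (fatal with the
case-fatality probability; survivors are reallocated equally among the
disability states of equal and greater severity), major extracranial
hemorrhage, myocardial infarction, and age-specific non-stroke death.
Stroke recurrence risk grows by a fixed relative risk per year; ECH and MI
are temporary states that never change disability.  Costs (annual
post-hospitalization maintenance by disability band plus one-time event
hospitalizations) and utility-weighted life time accrue per cycle and are
discounted to the start of the Markov phase.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .params import ParameterSet
from .tree import (ECH_EPISODE_YEARS, MI_EPISODE_YEARS, StateDistribution)

__all__ = [
    "MortalitySchedule",
    "CycleParameters",
    "CycleEvents",
    "MarkovTrace",
    "discount_factor",
    "recurrence_at_cycle",
    "redistribute_survivors",
    "build_cycle_transition",
    "cycle_cost",
    "cycle_qaly",
    "run_markov",
]

log = logging.getLogger(__name__)

_MINOR, _MODERATE, _SEVERE, _DEAD = range(4)

#: survivor reallocation targets by origin state: equal split among the
#: states of equal and greater disability
REDISTRIBUTION_TARGETS = {
    _MINOR: (_MINOR, _MODERATE, _SEVERE),
    _MODERATE: (_MODERATE, _SEVERE),
    _SEVERE: (_SEVERE,),
}


@dataclass(frozen=True)
class MortalitySchedule:
    """Annual non-stroke death probabilities, one per cycle."""

    start_age: float
    rates: tuple[float, ...]

    def __post_init__(self):
        if any(r < 0 or r > 1 for r in self.rates):
            raise ValueError("mortality rates must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.rates)

    def age_at(self, cycle: int) -> float:
        """Age during cycle ``cycle`` (1-based)."""
        return self.start_age + cycle - 1


@dataclass(frozen=True)
class CycleParameters:
    """Event probabilities governing one annual cycle."""

    recurrence_t: float
    ich_prop: float
    death_on_recurrence: float
    ech_rate: float
    ech_fatality: float
    mi_rate: float
    mi_fatality: float
    nonstroke_death_t: float

    def __post_init__(self):
        for name, v in self.__dict__.items():
            if not 0 <= v <= 1:
                raise ValueError(f"{name} = {v} outside [0, 1]")


@dataclass
class CycleEvents:
    """Expected event masses of one cycle, for costing and disutility."""

    recurrences_band02: float = 0.0    # survivors landing back in mRS 0-2
    recurrences_band36: float = 0.0    # survivors in mRS 3-5 plus fatal
    ech_total: float = 0.0
    ech_nonfatal_by_state: tuple[float, float, float] = (0.0, 0.0, 0.0)
    mi_total: float = 0.0
    mi_nonfatal_by_state: tuple[float, float, float] = (0.0, 0.0, 0.0)


@dataclass
class MarkovTrace:
    """Per-cycle occupancy and (discounted) cost/QALY accumulators."""

    states: np.ndarray          # (horizon+1, 4); row 0 is the seed
    cost: np.ndarray            # (horizon,)
    cost_disc: np.ndarray
    qaly: np.ndarray
    qaly_disc: np.ndarray

    @property
    def total_cost(self) -> float:
        return float(self.cost_disc.sum())

    @property
    def total_qaly(self) -> float:
        return float(self.qaly_disc.sum())

    @property
    def total_cost_undiscounted(self) -> float:
        return float(self.cost.sum())

    @property
    def total_qaly_undiscounted(self) -> float:
        return float(self.qaly.sum())

    def to_frame(self, start_age: float = 0.0) -> "pandas.DataFrame":  # noqa: F821
        import pandas as pd

        h = len(self.cost)
        return pd.DataFrame({
            "cycle": np.arange(h + 1),
            "age": start_age + np.arange(h + 1),
            "p_minor": self.states[:, 0],
            "p_moderate": self.states[:, 1],
            "p_severe": self.states[:, 2],
            "p_dead": self.states[:, 3],
            "cost": np.concatenate([[0.0], self.cost]),
            "cost_discounted": np.concatenate([[0.0], self.cost_disc]),
            "qaly": np.concatenate([[0.0], self.qaly]),
            "qaly_discounted": np.concatenate([[0.0], self.qaly_disc]),
        })


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def discount_factor(r: float, t: int) -> float:
    """Present-value factor ``(1 + r)^-t`` for cycle ``t``."""
    if r < 0 or t < 0:
        raise ValueError("discount rate and cycle index must be >= 0")
    return (1.0 + r) ** (-t)


def recurrence_at_cycle(base_rate: float, rr_per_year: float, t: int) -> float:
    """Recurrence probability in cycle ``t`` (1-based): base * rr^(t-1)."""
    if t < 1:
        raise ValueError("cycle index starts at 1")
    p = base_rate * rr_per_year ** (t - 1)
    if p > 1:
        raise ValueError(f"recurrence probability {p} exceeds 1 at cycle {t}")
    return p


def redistribute_survivors(origin: int, survivor_mass: float
                           ) -> tuple[float, float, float, float]:
    """Spread recurrence survivors equally over equal-or-worse states."""
    if origin == _DEAD:
        raise ValueError("dead patients cannot have a recurrence")
    out = [0.0, 0.0, 0.0, 0.0]
    targets = REDISTRIBUTION_TARGETS[origin]
    share = survivor_mass / len(targets)
    for s in targets:
        out[s] += share
    return tuple(out)


def build_cycle_transition(dist: StateDistribution, cp: CycleParameters
                           ) -> tuple[StateDistribution, CycleEvents]:
    """Advance the cohort one cycle; also return the expected event masses.

    Branches are mutually exclusive and applied in order — recurrence, then
    major ECH, then MI, then non-stroke death — each on the mass not
    consumed by the previous branches.  Death is absorbing.
    """
    masses = dist.as_tuple()
    out = [0.0, 0.0, 0.0, masses[_DEAD]]
    ev = CycleEvents()
    ech_nf = [0.0, 0.0, 0.0]
    mi_nf = [0.0, 0.0, 0.0]
    for s in (_MINOR, _MODERATE, _SEVERE):
        m = masses[s]
        if m == 0.0:
            continue
        rec = m * cp.recurrence_t
        rec_dead = rec * cp.death_on_recurrence
        rec_surv = rec - rec_dead
        contrib = redistribute_survivors(s, rec_surv)
        for k in range(3):
            out[k] += contrib[k]
        out[_DEAD] += rec_dead
        # survivors landing back in mRS 0-2 only happen from the minor state
        ev.recurrences_band02 += contrib[_MINOR]
        ev.recurrences_band36 += rec - contrib[_MINOR]

        resid = m - rec
        ech = resid * cp.ech_rate
        ech_dead = ech * cp.ech_fatality
        resid -= ech
        mi = resid * cp.mi_rate
        mi_dead = mi * cp.mi_fatality
        resid -= mi
        ns_dead = resid * cp.nonstroke_death_t
        out[s] += (ech - ech_dead) + (mi - mi_dead) + (resid - ns_dead)
        out[_DEAD] += ech_dead + mi_dead + ns_dead
        ev.ech_total += ech
        ev.mi_total += mi
        ech_nf[s] += ech - ech_dead
        mi_nf[s] += mi - mi_dead
    ev.ech_nonfatal_by_state = tuple(ech_nf)
    ev.mi_nonfatal_by_state = tuple(mi_nf)
    total = sum(out)
    assert abs(total - sum(masses)) < 1e-9, "state mass not conserved"
    return StateDistribution(*out), ev


def cycle_cost(state_dist_end: StateDistribution, events: CycleEvents,
               params: ParameterSet) -> float:
    """Cost accrued in one cycle (2019 CNY, undiscounted).

    Annual post-hospitalization maintenance is accrued by every alive
    patient by end-of-cycle disability band; this cycle's recurrent strokes
    add one-time hospitalizations split ischemic/ICH and by resulting band
    (fatal recurrences costed at the mRS 3-6 price); ECH and MI events add
    their one-time hospitalization costs.
    """
    cost = (state_dist_end.p_minor * params["annual_posthosp_cost_mrs02"]
            + (state_dist_end.p_moderate + state_dist_end.p_severe)
            * params["annual_posthosp_cost_mrs35"])
    ich = params["ich_prop_longterm"]
    price02 = ((1 - ich) * params["cost_hosp_ischemic_mrs02"]
               + ich * params["cost_hosp_ich_mrs02"])
    price36 = ((1 - ich) * params["cost_hosp_ischemic_mrs36"]
               + ich * params["cost_hosp_ich_mrs36"])
    cost += events.recurrences_band02 * price02
    cost += events.recurrences_band36 * price36
    cost += events.ech_total * params["cost_hosp_ech"]
    cost += events.mi_total * params["cost_hosp_mi"]
    return cost


def cycle_qaly(state_dist_end: StateDistribution, events: CycleEvents,
               params: ParameterSet) -> float:
    """Quality-adjusted life-years accrued in one cycle.

    Utility-weighted end-of-cycle occupancy for one year, minus temporary
    disutility for nonfatal ECH (2-week episode) and MI (30-day episode):
    in the default multiplicative mode the episode utility scales the
    state utility for the episode duration.
    """
    utils = (params["utility_mrs02"], params["utility_mrs34"],
             params["utility_mrs5"], params["utility_death"])
    qaly = sum(p * u for p, u in zip(state_dist_end.as_tuple(), utils))
    multiplicative = (params.structural.temporary_disutility_mode
                      == "multiplicative")
    for s in (_MINOR, _MODERATE, _SEVERE):
        u = utils[s]
        ech_nf = events.ech_nonfatal_by_state[s]
        mi_nf = events.mi_nonfatal_by_state[s]
        if multiplicative:
            qaly -= ech_nf * ECH_EPISODE_YEARS * u * (1 - params["utility_ech"])
            qaly -= mi_nf * MI_EPISODE_YEARS * u * (1 - params["utility_mi"])
        else:
            qaly -= ech_nf * ECH_EPISODE_YEARS * (u - params["utility_ech"])
            qaly -= mi_nf * MI_EPISODE_YEARS * (u - params["utility_mi"])
    return qaly


def run_markov(seed: StateDistribution, params: ParameterSet,
               schedule: MortalitySchedule) -> MarkovTrace:
    """Project the cohort over ``horizon`` annual cycles from the seed.

    Cycle ``t`` (1-based) costs and QALYs are discounted by ``(1+r)^-t``
    with separate cost and outcome rates.  With the half-cycle correction
    enabled, accruals are computed on the average of start- and
    end-of-cycle occupancy instead of end-of-cycle occupancy.
    """
    horizon = params.structural.horizon_years
    if len(schedule) < horizon:
        raise ValueError(
            f"mortality schedule has {len(schedule)} rates; "
            f"horizon is {horizon}")
    base_rec = params["annual_recurrence_rate"]
    rr = params["rr_recurrence_per_year"]
    r_cost = params.discount_cost
    r_out = params.discount_outcome
    accrual = params.structural.state_accrual
    if params.structural.half_cycle_correction:
        accrual = "mid"

    states = np.empty((horizon + 1, 4))
    states[0] = seed.as_tuple()
    cost = np.empty(horizon)
    cost_d = np.empty(horizon)
    qaly = np.empty(horizon)
    qaly_d = np.empty(horizon)

    current = seed
    for t in range(1, horizon + 1):
        rec_t = recurrence_at_cycle(base_rec, rr, t)
        if rec_t > 1.0:  # pragma: no cover - guarded upstream
            log.warning("recurrence capped at 1 in cycle %d", t)
            rec_t = 1.0
        cp = CycleParameters(
            recurrence_t=rec_t,
            ich_prop=params["ich_prop_longterm"],
            death_on_recurrence=params["death_on_recurrence"],
            ech_rate=params["ech_rate_annual"],
            ech_fatality=params["ech_fatality"],
            mi_rate=params["mi_rate_annual"],
            mi_fatality=params["mi_fatality"],
            nonstroke_death_t=schedule.rates[t - 1],
        )
        nxt, events = build_cycle_transition(current, cp)
        if accrual == "start":
            accrual_dist = current
        elif accrual == "mid":
            mid = tuple((a + b) / 2 for a, b in
                        zip(current.as_tuple(), nxt.as_tuple()))
            accrual_dist = StateDistribution(*mid)
        else:
            accrual_dist = nxt
        c = cycle_cost(accrual_dist, events, params)
        q = cycle_qaly(accrual_dist, events, params)
        states[t] = nxt.as_tuple()
        cost[t - 1] = c
        qaly[t - 1] = q
        cost_d[t - 1] = c * discount_factor(r_cost, t)
        qaly_d[t - 1] = q * discount_factor(r_out, t)
        current = nxt

    return MarkovTrace(states, cost, cost_d, qaly, qaly_d)
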