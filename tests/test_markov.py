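"""Markov engine: transitions, accrual, discounting, conservation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cyp2c19_cea.markov import (CycleParameters, MortalitySchedule,
                                build_cycle_transition, cycle_cost,
                                cycle_qaly, discount_factor,
                                recurrence_at_cycle, redistribute_survivors,
                                run_markov, CycleEvents)
from cyp2c19_cea.params import default_parameters
from cyp2c19_cea.tree import StateDistribution

MINOR_ONLY = StateDistribution(1.0, 0.0, 0.0, 0.0)
ALL_DEAD = StateDistribution(0.0, 0.0, 0.0, 1.0)


def _cp(**kw):
    base = dict(recurrence_t=0.0, ich_prop=0.075, death_on_recurrence=0.0,
                ech_rate=0.0, ech_fatality=0.0, mi_rate=0.0, mi_fatality=0.0,
                nonstroke_death_t=0.0)
    base.update(kw)
    return CycleParameters(**base)


class TestPrimitives:
    @pytest.mark.parametrize("r, t, expected", [
        (0.03, 0, 1.0),
        (0.03, 1, 1 / 1.03),
        (0.0, 7, 1.0),
    ])
    def test_discount_factor(self, r, t, expected):
        assert discount_factor(r, t) == pytest.approx(expected, abs=1e-12)

    def test_recurrence_growth(self):
        assert recurrence_at_cycle(0.1219, 1.017, 1) == pytest.approx(0.1219)
        assert recurrence_at_cycle(0.1219, 1.017, 2) == pytest.approx(
            0.1219 * 1.017)
        assert recurrence_at_cycle(0.5, 1.0, 17) == 0.5

    def test_recurrence_above_one_rejected(self):
        with pytest.raises(ValueError):
            recurrence_at_cycle(0.9, 1.5, 10)

    @pytest.mark.parametrize("origin, mass, expected", [
        (0, 0.09, (0.03, 0.03, 0.03, 0.0)),
        (1, 0.10, (0.0, 0.05, 0.05, 0.0)),
        (2, 0.40, (0.0, 0.0, 0.40, 0.0)),
    ])
    def test_survivor_reallocation(self, origin, mass, expected):
        assert redistribute_survivors(origin, mass) == pytest.approx(expected)

    def test_reallocation_from_death_rejected(self):
        with pytest.raises(ValueError):
            redistribute_survivors(3, 0.1)


class TestCycleTransition:
    def test_identity_with_zero_rates(self, defaults):
        start = StateDistribution(0.6, 0.25, 0.1, 0.05)
        out, _ = build_cycle_transition(start, _cp())
        assert out.as_tuple() == pytest.approx(start.as_tuple())

    def test_death_is_absorbing(self):
        cp = _cp(recurrence_t=0.5, death_on_recurrence=0.5,
                 nonstroke_death_t=0.3)
        out, _ = build_cycle_transition(ALL_DEAD, cp)
        assert out.as_tuple() == pytest.approx((0, 0, 0, 1))

    def test_branch_tree_enumeration_oracle(self):
        # recurrence 0.10, fatality 0.20 from an all-minor cohort:
        # 0.02 die, 0.08 survivors split into thirds, 0.90 remain
        cp = _cp(recurrence_t=0.10, death_on_recurrence=0.20)
        out, ev = build_cycle_transition(MINOR_ONLY, cp)
        assert out.as_tuple() == pytest.approx(
            (0.90 + 0.08 / 3, 0.08 / 3, 0.08 / 3, 0.02))
        assert ev.recurrences_band02 == pytest.approx(0.08 / 3)
        assert ev.recurrences_band36 == pytest.approx(0.10 - 0.08 / 3)

    @settings(max_examples=60, deadline=None)
    @given(st.floats(0, 0.5), st.floats(0, 1), st.floats(0, 0.1),
           st.floats(0, 1), st.floats(0, 0.1), st.floats(0, 1),
           st.floats(0, 0.9),
           st.lists(st.floats(0.01, 1), min_size=4, max_size=4))
    def test_mass_conservation_for_arbitrary_rates(self, rec, dor, ech, echf,
                                                   mi, mif, nsd, raw):
        total = sum(raw)
        start = StateDistribution(*(x / total for x in raw))
        cp = _cp(recurrence_t=rec, death_on_recurrence=dor, ech_rate=ech,
                 ech_fatality=echf, mi_rate=mi, mi_fatality=mif,
                 nonstroke_death_t=nsd)
        out, _ = build_cycle_transition(start, cp)
        assert sum(out.as_tuple()) == pytest.approx(1.0, abs=1e-9)
        assert out.p_dead >= start.p_dead - 1e-12


class TestCycleAccrual:
    def test_maintenance_cost_all_minor(self, defaults):
        assert cycle_cost(MINOR_ONLY, CycleEvents(), defaults) == \
            pytest.approx(8767.42)

    def test_dead_accrue_nothing(self, defaults):
        assert cycle_cost(ALL_DEAD, CycleEvents(), defaults) == 0.0
        assert cycle_qaly(ALL_DEAD, CycleEvents(), defaults) == 0.0

    def test_event_cost_additivity(self, defaults):
        ev = CycleEvents(mi_total=1.0)
        assert cycle_cost(MINOR_ONLY, ev, defaults) == pytest.approx(
            8767.42 + 21276.20)

    def test_utility_all_minor(self, defaults):
        assert cycle_qaly(MINOR_ONLY, CycleEvents(), defaults) == \
            pytest.approx(0.75)

    def test_temporary_mi_disutility_is_multiplicative(self, defaults):
        ev = CycleEvents(mi_total=1.0, mi_nonfatal_by_state=(1.0, 0.0, 0.0))
        got = cycle_qaly(MINOR_ONLY, ev, defaults)
        assert got == pytest.approx(0.75 - (30 / 365.25) * 0.75 * 0.16,
                                    abs=1e-9)


def _zero_event_params(horizon=30):
    ps = default_parameters().with_base(
        annual_recurrence_rate=0.0, ech_rate_annual=0.0, mi_rate_annual=0.0)
    ps.structural.horizon_years = horizon
    return ps


class TestRunMarkov:
    def test_all_dead_seed_accrues_nothing(self, defaults, schedule):
        trace = run_markov(ALL_DEAD, defaults, schedule)
        assert trace.total_cost == 0.0
        assert trace.total_qaly == 0.0

    def test_schedule_shorter_than_horizon_rejected(self, defaults):
        short = MortalitySchedule(62.0, (0.01,) * 10)
        with pytest.raises(ValueError):
            run_markov(MINOR_ONLY, defaults, short)

    def test_zero_event_annuity_closed_form(self):
        ps = _zero_event_params()
        sched = MortalitySchedule(62.0, (0.0,) * 30)
        trace = run_markov(MINOR_ONLY, ps, sched)
        assert trace.total_qaly_undiscounted == pytest.approx(30 * 0.75,
                                                              abs=1e-9)
        annuity = sum(0.75 * 1.03 ** (-t) for t in range(1, 31))
        assert trace.total_qaly == pytest.approx(annuity, abs=1e-9)

    def test_discounting_monotonicity(self, schedule):
        ps0 = default_parameters().with_base(discount_cost=0.0,
                                             discount_outcome=0.0)
        ps0.specs["discount_cost"].low = 0.0
        ps0.specs["discount_outcome"].low = 0.0
        seed = StateDistribution(0.95, 0.03, 0.01, 0.01)
        t0 = run_markov(seed, ps0, schedule)
        t3 = run_markov(seed, default_parameters(), schedule)
        assert t3.total_cost < t0.total_cost
        assert t3.total_qaly < t0.total_qaly

    def test_cumulative_death_is_monotone(self, base_result):
        for arm in (base_result.genetic, base_result.no_testing):
            dead = arm.trace.states[:, 3]
            assert np.all(np.diff(dead) >= -1e-12)

    def test_mass_conserved_every_cycle(self, base_result):
        sums = base_result.genetic.trace.states.sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_raising_utility_never_lowers_qalys(self, schedule, defaults):
        lo = run_markov(StateDistribution(0.9, 0.05, 0.03, 0.02), defaults,
                        schedule)
        hi_ps = defaults.with_base(utility_mrs34=0.5)
        hi = run_markov(StateDistribution(0.9, 0.05, 0.03, 0.02), hi_ps,
                        schedule)
        assert hi.total_qaly >= lo.total_qaly

    def test_raising_cost_never_lowers_cost(self, schedule, defaults):
        lo = run_markov(MINOR_ONLY, defaults, schedule)
        hi = run_markov(MINOR_ONLY,
                        defaults.with_base(annual_posthosp_cost_mrs02=10945.0),
                        schedule)
        assert hi.total_cost >= lo.total_cost

    def test_half_cycle_correction_lies_between_conventions(self, schedule):
        seed = StateDistribution(0.95, 0.03, 0.01, 0.01)
        totals = {}
        for accrual in ("start", "mid", "end"):
            ps = default_parameters()
            ps.structural.state_accrual = accrual
            totals[accrual] = run_markov(seed, ps, schedule).total_qaly
        assert totals["end"] <= totals["mid"] <= totals["start"]
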