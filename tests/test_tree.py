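"""The 90-day decision tree: derivations, distributions, costs, QALYs."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cyp2c19_cea.params import default_parameters
from cyp2c19_cea.tree import (DAYS_90_YEARS, StateDistribution,
                              adjusted_disability_rate, apply_hazard_ratio,
                              build_arm, mix_subgroups, ninety_day_cost_qaly,
                              ninety_day_distribution, proportion_within_90d)


class TestEarlyRecurrenceFraction:
    def test_published_clopidogrel_aspirin_fraction(self):
        # 8.3% of patients recur by day 90, 10.3% by one year
        assert proportion_within_90d(0.083, 0.103) == pytest.approx(
            0.806, abs=5e-4)

    @pytest.mark.parametrize("x", [0.01, 0.5, 1.0])
    def test_identity_when_all_recurrences_are_early(self, x):
        assert proportion_within_90d(x, x) == 1.0

    def test_exact_halving(self):
        assert proportion_within_90d(0.05, 0.10) == pytest.approx(0.5)

    def test_inconsistent_inputs_rejected(self):
        with pytest.raises(ValueError):
            proportion_within_90d(0.2, 0.1)


class TestHazardRatioAdjustment:
    def test_dipyridamole_switch_recurrence(self):
        # aspirin-monotherapy 90-day risk x HR of the combination
        assert apply_hazard_ratio(0.0932, 0.78) == pytest.approx(
            0.0727, abs=5e-5)

    def test_null_ratio_and_zero_probability(self):
        assert apply_hazard_ratio(0.42, 1.0) == 0.42
        assert apply_hazard_ratio(0.0, 0.5) == 0.0

    def test_product_above_one_rejected(self):
        with pytest.raises(ValueError):
            apply_hazard_ratio(0.9, 1.5)


class TestDisabilityRateAdjustment:
    def test_no_switchers_means_no_adjustment(self):
        assert adjusted_disability_rate(0.31, 0.78, 0.0) == pytest.approx(0.31)

    def test_zero_disability_preserved(self):
        assert adjusted_disability_rate(0.0, 0.78, 0.37) == 0.0

    def test_left_to_right_parenthesization(self):
        # (A*(B-C)/B)*(1-C) with the published inputs
        assert adjusted_disability_rate(0.0527, 0.78, 0.37) == pytest.approx(
            0.01745, abs=5e-6)

    def test_ratio_policy_alternative(self):
        expected = 0.0527 * ((0.78 - 0.37) / 0.78) / (1 - 0.37)
        got = adjusted_disability_rate(0.0527, 0.78, 0.37, policy="ratio")
        assert got == pytest.approx(expected)


class TestSubgroupMixing:
    def test_single_pooled_subgroup_is_identity(self, defaults):
        arm = build_arm("no_testing", defaults)
        assert mix_subgroups(arm)["recurrence_90d"] == pytest.approx(0.082)

    def test_weighted_mean_oracle(self, defaults):
        pooled = mix_subgroups(build_arm("genetic_testing", defaults))
        expected = 0.41 * 0.0717 + 0.22 * 0.0871 + 0.37 * 0.0727
        assert pooled["recurrence_90d"] == pytest.approx(expected)

    def test_ech_mi_risks_shared_across_subgroups(self, defaults):
        pooled = mix_subgroups(build_arm("genetic_testing", defaults))
        assert pooled["ech_90d"] == pytest.approx(0.0108)
        assert pooled["mi_90d"] == pytest.approx(0.0012)

    def test_mixture_of_equal_risks_is_that_risk(self, defaults):
        ps = defaults.with_base(rec90_noncarrier=0.08,
                                rec90_carrier_high_esrs=0.08,
                                rec90_carrier_low_esrs=0.08)
        pooled = mix_subgroups(build_arm("genetic_testing", ps))
        assert pooled["recurrence_90d"] == pytest.approx(0.08)


class TestNinetyDayDistribution:
    def test_published_table_values(self, defaults):
        g = ninety_day_distribution(build_arm("genetic_testing", defaults),
                                    defaults)
        n = ninety_day_distribution(build_arm("no_testing", defaults),
                                    defaults)
        assert g.as_tuple() == pytest.approx((0.9506, 0.0404, 0.0054, 0.0036))
        assert n.as_tuple() == pytest.approx((0.9376, 0.0527, 0.0058, 0.0039))

    def test_genetic_arm_dominates_on_minor_disability(self, defaults):
        g = ninety_day_distribution(build_arm("genetic_testing", defaults),
                                    defaults)
        n = ninety_day_distribution(build_arm("no_testing", defaults),
                                    defaults)
        assert g.p_minor >= n.p_minor

    @settings(max_examples=40, deadline=None)
    @given(p_minor_g=st.floats(0.939, 0.961), p_minor_n=st.floats(0.926, 0.948),
           renorm=st.sampled_from(["moderate", "proportional"]))
    def test_conservation_under_renormalization(self, p_minor_g, p_minor_n,
                                                renorm):
        ps = default_parameters().with_base(p90_minor_genetic=p_minor_g,
                                            p90_minor_no_testing=p_minor_n)
        ps.structural.p90_renormalization = renorm
        for arm in ("genetic_testing", "no_testing"):
            d = ninety_day_distribution(build_arm(arm, ps), ps)
            assert sum(d.as_tuple()) == pytest.approx(1.0, abs=1e-9)
            assert min(d.as_tuple()) >= -1e-12

    def test_derived_mode_reproduces_pooled_no_testing(self, defaults):
        ps = defaults
        ps.structural.ninety_day_mode = "derived"
        d = ninety_day_distribution(build_arm("no_testing", ps), ps)
        printed = (0.9376, 0.0527, 0.0058, 0.0039)
        assert max(abs(a - b) for a, b in zip(d.as_tuple(), printed)) < 0.005

    def test_derived_mode_monotone_in_subgroup_recurrence(self, defaults):
        ps = defaults
        ps.structural.ninety_day_mode = "derived"
        lo = ninety_day_distribution(build_arm("genetic_testing", ps), ps)
        hi_ps = ps.with_base(rec90_noncarrier=0.0717 * 1.3)
        hi_ps.structural.ninety_day_mode = "derived"
        hi = ninety_day_distribution(build_arm("genetic_testing", hi_ps),
                                     hi_ps)
        assert hi.p_minor <= lo.p_minor


class TestNinetyDayCostQaly:
    def _no_event_params(self):
        return default_parameters().with_base(
            rec90_pooled_no_testing=0.0, ech_rate_90d=0.0, mi_rate_90d=0.0,
            p90_minor_no_testing=1.0, p90_moderate_no_testing=0.0,
            p90_severe_no_testing=0.0, p90_dead_no_testing=0.0)

    def test_no_event_arm_reduces_to_drug_cost(self):
        ps = self._no_event_params()
        out = ninety_day_cost_qaly(build_arm("no_testing", ps), ps)
        assert out.cost_90d == pytest.approx(490.45)

    def test_testing_fee_additivity(self, defaults):
        with_fee = ninety_day_cost_qaly(
            build_arm("genetic_testing", defaults), defaults)
        no_fee_ps = defaults.with_base(cost_genetic_testing=0.0)
        no_fee_ps.specs["cost_genetic_testing"].low = 0.0
        without = ninety_day_cost_qaly(
            build_arm("genetic_testing", no_fee_ps), no_fee_ps)
        assert with_fee.cost_90d - without.cost_90d == pytest.approx(1076.5)

    def test_all_minor_survivors_utility_oracle(self):
        ps = self._no_event_params()
        out = ninety_day_cost_qaly(build_arm("no_testing", ps), ps)
        assert out.qaly_90d == pytest.approx(0.75 * DAYS_90_YEARS, abs=1e-9)

    def test_qaly_bounded_by_period_length(self, defaults):
        for arm in ("genetic_testing", "no_testing"):
            out = ninety_day_cost_qaly(build_arm(arm, defaults), defaults)
            assert 0 <= out.qaly_90d <= 90 / 365


def test_state_distribution_rejects_non_distribution():
    with pytest.raises(ValueError):
        StateDistribution(0.5, 0.5, 0.5, 0.5)
    with pytest.raises(ValueError):
        StateDistribution(-0.1, 0.6, 0.3, 0.2)
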