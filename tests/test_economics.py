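import numpy as np
import pytest

from prostox_cea import (
    accumulate_outcomes, aggregate_arm, aggregate_printed_table, cost_impact,
    icer, price_threshold_sweep, run_cohort,
)
from prostox_cea.economics import ArmOutcome, DOMINANT, UNDEFINED, printed_table_arm_outcomes
from prostox_cea.markov import CohortTrace
from prostox_cea.params import PROSTOX, SOC
from prostox_cea.tree import TrackWeights


def one_cycle_trace(track="T7"):
    # everyone survives the single cycle without toxicity
    return CohortTrace(track=track, notox=[1.0, 1.0], tox=[0.0, 0.0],
                       dead=[0.0, 0.0], cum_tox=[0.0, 0.0])


def soc_weights(t7=0.0, t8=0.0, t9=0.0):
    w = dict.fromkeys([f"T{i}" for i in range(1, 10)], 0.0)
    w.update({"T7": t7, "T8": t8, "T9": t9})
    return TrackWeights(arm=SOC, weights=w)


class TestAccumulateOutcomes:
    def test_undiscounted_single_cycle(self, params):
        p = params.model_copy(update={"discounting_enabled": False})
        out = accumulate_outcomes(one_cycle_trace(), p, "T7")
        assert out.annual_costs[0] == pytest.approx(2914.90)
        assert out.annual_qalys[0] == pytest.approx(0.90)
        assert out.treatment_cost == 20670.28

    def test_discounted_single_cycle(self, params):
        out = accumulate_outcomes(one_cycle_trace(), params, "T7")
        assert out.annual_costs[0] == pytest.approx(2914.90 / 1.03)
        assert out.annual_qalys[0] == pytest.approx(0.90 / 1.03)

    def test_all_dead_trace_accrues_nothing_after_entry(self, params):
        trace = CohortTrace(track="T9", notox=[1, 0, 0], tox=[0, 0, 0],
                            dead=[0, 1, 1], cum_tox=[0, 0, 0])
        out = accumulate_outcomes(trace, params, "T9")
        assert out.annual_costs.sum() == 0.0
        assert out.lifetime_qalys == 0.0
        assert out.lifetime_cost == out.treatment_cost

    def test_discounting_never_increases_qalys(self, params, life_table):
        trace = run_cohort(params, "T7", life_table)
        on = accumulate_outcomes(trace, params, "T7")
        off = accumulate_outcomes(
            trace, params.model_copy(update={"discounting_enabled": False}), "T7")
        assert off.lifetime_qalys >= on.lifetime_qalys
        assert off.lifetime_cost >= on.lifetime_cost


class TestAggregateArm:
    def test_single_track_identity(self, params):
        out = accumulate_outcomes(one_cycle_trace(), params, "T7")
        arm = aggregate_arm({"T7": out}, soc_weights(t7=1.0), params)
        assert arm.t0_cost == out.treatment_cost
        assert arm.lifetime_cost == pytest.approx(out.lifetime_cost)
        assert arm.lifetime_qalys == pytest.approx(out.lifetime_qalys)

    def test_equal_weights_average(self, params, life_table):
        outs = {t: accumulate_outcomes(run_cohort(params, t, life_table), params, t)
                for t in ("T7", "T8")}
        arm = aggregate_arm(outs, soc_weights(t7=0.5, t8=0.5), params)
        assert arm.lifetime_cost == pytest.approx(
            (outs["T7"].lifetime_cost + outs["T8"].lifetime_cost) / 2)

    def test_linearity_in_weights(self, params, life_table):
        outs = {t: accumulate_outcomes(run_cohort(params, t, life_table), params, t)
                for t in ("T7", "T9")}
        for w in (0.0, 0.25, 0.9):
            arm = aggregate_arm(outs, soc_weights(t7=w, t9=1 - w), params)
            expected = w * outs["T7"].lifetime_qalys + (1 - w) * outs["T9"].lifetime_qalys
            assert arm.lifetime_qalys == pytest.approx(expected)

    def test_missing_weighted_track_rejected(self, params):
        out = accumulate_outcomes(one_cycle_trace(), params, "T7")
        with pytest.raises(ValueError, match="T8"):
            aggregate_arm({"T7": out}, soc_weights(t7=0.5, t8=0.5), params)


class TestPrintedTableAggregation:
    def test_soc_year5_weighted_cost(self, printed_table, params):
        agg = aggregate_printed_table(printed_table, params)
        assert round(agg[SOC]["annual_costs"][4]) == 1109

    def test_five_year_cumulative_totals(self, printed_table, params):
        agg = aggregate_printed_table(printed_table, params)
        assert agg[PROSTOX]["five_year_total"] == pytest.approx(47_683, abs=5)
        assert agg[SOC]["five_year_total"] == pytest.approx(67_298, abs=5)

    def test_lifetime_qalys(self, printed_table, params):
        agg = aggregate_printed_table(printed_table, params)
        assert round(agg[PROSTOX]["lifetime_qalys"], 2) == 11.63
        assert agg[PROSTOX]["lifetime_qalys"] - agg[SOC]["lifetime_qalys"] == \
            pytest.approx(0.24, abs=0.01)

    def test_cumulative_savings_positive_every_year(self, printed_table, params):
        # the printed table's weighted annual cells run higher for the tested
        # arm, so the entry-cost gap shrinks slightly year over year but
        # savings stay comfortably positive throughout
        arms = printed_table_arm_outcomes(printed_table, params)
        impact = cost_impact(arms[PROSTOX], arms[SOC], 5)
        assert np.all(impact["cumulative_savings"] > 0)
        assert impact["cumulative_savings"][0] > 0  # treatment-cost gap at entry


class TestCostImpact:
    def test_identical_arms_zero_savings(self, printed_table, params):
        arm = printed_table_arm_outcomes(printed_table, params)[SOC]
        impact = cost_impact(arm, arm, 5)
        np.testing.assert_array_equal(impact["cumulative_savings"], 0.0)

    def test_antisymmetry(self, printed_table, params):
        arms = printed_table_arm_outcomes(printed_table, params)
        fwd = cost_impact(arms[PROSTOX], arms[SOC], 5)["cumulative_savings"]
        rev = cost_impact(arms[SOC], arms[PROSTOX], 5)["cumulative_savings"]
        np.testing.assert_allclose(fwd, -rev)

    def test_horizon_beyond_stream_rejected(self, printed_table, params):
        arms = printed_table_arm_outcomes(printed_table, params)
        with pytest.raises(ValueError, match="horizon"):
            cost_impact(arms[PROSTOX], arms[SOC], 6)


class TestIcer:
    @staticmethod
    def arm(cost, qalys, label="X"):
        return ArmOutcome(arm=label, t0_cost=cost, annual_costs=np.zeros(1),
                          cumulative_costs=np.array([cost, cost]),
                          lifetime_cost=cost, lifetime_qalys=qalys)

    def test_direct_division(self):
        res = icer(self.arm(1100, 10.5), self.arm(1000, 10.0))
        assert res.icer == pytest.approx(200.0)
        assert res.label == "tradeoff"

    def test_fixture_arms_are_dominant(self, printed_table, params):
        arms = printed_table_arm_outcomes(printed_table, params)
        res = icer(arms[PROSTOX], arms[SOC])
        assert res.label == DOMINANT
        assert res.icer is None
        assert res.delta_qalys == pytest.approx(0.24, abs=0.01)
        assert res.delta_cost < 0

    def test_identical_arms_undefined(self):
        res = icer(self.arm(1000, 10.0), self.arm(1000, 10.0))
        assert res.label == UNDEFINED and res.icer is None


class TestPriceSweep:
    def test_base_price_identity_and_unit_slope(self):
        sweep = price_threshold_sweep([4000, 4001, 10_000], base_savings=19_615,
                                      base_test_cost=4000)
        assert sweep[4000.0] == 19_615
        assert sweep[4001.0] == 19_614
        assert sweep[10_000.0] == 19_615 - 6000

    def test_exactly_affine(self):
        prices = np.linspace(0, 20_000, 11)
        sweep = price_threshold_sweep(prices, base_savings=19_615, base_test_cost=4000)
        values = np.array([sweep[p] for p in prices])
        np.testing.assert_allclose(np.diff(values) / np.diff(prices), -1.0)

    def test_negative_price_rejected(self):
        with pytest.raises(ValueError):
            price_threshold_sweep([-1], 0.0, 4000)
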