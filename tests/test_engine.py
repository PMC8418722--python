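"""Markov engine: transition assembly, rewards, discounting, aggregation."""

import dataclasses
import math

import numpy as np
import pytest

from pharmascreen.engine import (STATES, ModelInputs, cycle_rewards, discount,
                                 run_cohort, run_scenario, run_stratum,
                                 transition_matrix)
from pharmascreen.parameters import (CohortDefinition, EconomicSettings,
                                     HazardInputs, ParameterSet, Stratum,
                                     default_parameters, fixed)
from pharmascreen.survival import LifeTable, WeibullFit
from pharmascreen.synthetic import synth_life_table


def _zero_hazard_inputs(ref):
    """No incidence, no complications, no mortality: nothing ever happens."""
    import pandas as pd
    lt = LifeTable(pd.DataFrame([(a, g, 0.0) for g in ("women", "men")
                                 for a in range(0, 140)],
                                columns=["age", "gender", "qx"]))
    null_fit = WeibullFit("PH", 1.0, {"intercept": -745.0})  # hazard ~ 0
    hz = HazardInputs(t2d_mortality_hr_women=fixed(1.0),
                      t2d_mortality_hr_men=fixed(1.0),
                      complication_mortality_hr=fixed(1.0))
    return dataclasses.replace(
        ref, params=ref.params.with_(hazards=hz),
        incidence_fit=null_fit, complication_fit=null_fit, life_table=lt)


WOMAN = Stratum("women", 40, "12-14", 100)


class TestTransitionMatrix:
    def test_no_hazards_gives_identity(self, ref_inputs):
        M = transition_matrix(_zero_hazard_inputs(ref_inputs), WOMAN,
                              "comparator", 1)
        np.testing.assert_allclose(M, np.eye(4), atol=1e-12)

    def test_rows_stochastic_and_dead_absorbing(self, ref_inputs):
        for cyc in (1, 10, 25):
            M = transition_matrix(ref_inputs, WOMAN, "intervention", cyc)
            np.testing.assert_allclose(M.sum(axis=1), 1.0, atol=1e-12)
            assert M[3, 3] == 1.0
            assert M[1, 0] == M[2, 0] == M[2, 1] == 0.0

    def test_unit_hr_arm_equals_comparator(self, ref_inputs):
        hz = dataclasses.replace(ref_inputs.params.hazards,
                                 intervention_hr=fixed(1.0))
        inputs = dataclasses.replace(ref_inputs,
                                     params=ref_inputs.params.with_(hazards=hz))
        for cyc in (1, 8, 15):
            np.testing.assert_allclose(
                transition_matrix(inputs, WOMAN, "intervention", cyc),
                transition_matrix(inputs, WOMAN, "comparator", cyc),
                atol=1e-15)

    def test_intervention_scales_incidence_by_hr_on_survivors(self, ref_inputs):
        Mc = transition_matrix(ref_inputs, WOMAN, "comparator", 1)
        Mi = transition_matrix(ref_inputs, WOMAN, "intervention", 1)
        q0 = Mc[0, 3]
        p = Mc[0, 1] / (1 - q0)
        p_hr = 1 - (1 - p) ** ref_inputs.params.hazards.intervention_hr.point
        assert Mi[0, 1] == pytest.approx((1 - q0) * p_hr, rel=1e-12)

    def test_effect_ends_after_duration(self, ref_inputs):
        dur = ref_inputs.params.hazards.intervention_effect_duration_years
        Mi = transition_matrix(ref_inputs, WOMAN, "intervention", dur + 1)
        Mc = transition_matrix(ref_inputs, WOMAN, "comparator", dur + 1)
        np.testing.assert_allclose(Mi, Mc, atol=1e-15)


class TestCycleRewards:
    SETT = EconomicSettings(perspective="societal")

    def test_all_at_risk_woman(self):
        costs, qaly = cycle_rewards(np.array([1.0, 0, 0, 0]), 40, "women",
                                    default_parameters(), self.SETT)
        assert qaly == pytest.approx(8573 / (8573 + 889), abs=5e-4)
        assert sum(costs.values()) == 0.0

    def test_all_dead_contributes_nothing(self):
        costs, qaly = cycle_rewards(np.array([0, 0, 0, 1.0]), 70, "men",
                                    default_parameters(), self.SETT)
        assert qaly == 0.0 and sum(costs.values()) == 0.0

    def test_t2d_man_over_65_direct_equals_societal(self):
        p = default_parameters()
        occ = np.array([0, 1.0, 0, 0])
        direct = EconomicSettings(perspective="direct_only")
        c_soc, _ = cycle_rewards(occ, 66, "men", p, self.SETT)
        c_dir, _ = cycle_rewards(occ, 66, "men", p, direct)
        assert sum(c_soc.values()) == pytest.approx(3315 + 551 + 584)
        assert sum(c_dir.values()) == sum(c_soc.values())

    def test_productivity_applies_under_65_societal_only(self):
        p = default_parameters()
        occ = np.array([0, 1.0, 0, 0])
        c_soc, _ = cycle_rewards(occ, 64, "men", p, self.SETT)
        assert c_soc["productivity"] == pytest.approx(7632)

    def test_complications_add_cost_and_disutility(self):
        p = default_parameters()
        c, q = cycle_rewards(np.array([0, 0, 1.0, 0]), 50, "women", p,
                             self.SETT)
        assert c["complications"] == pytest.approx(4401)
        base = p.utilities.baseline_utility("women", 50)
        assert q == pytest.approx(base - 0.041 - 0.119, abs=2e-3)


class TestDiscount:
    def test_closed_form(self):
        assert discount(100, 0.03, 10) == pytest.approx(74.41, abs=5e-3)

    def test_zero_rate_and_zero_cycle_identity(self):
        assert discount(123.4, 0.0, 7) == 123.4
        assert discount(123.4, 0.05, 0) == 123.4


class TestRunStratum:
    def test_single_cycle_qaly_discounted_once(self, ref_inputs):
        inputs = _zero_hazard_inputs(ref_inputs)
        sett = EconomicSettings(discount_rate=0.03, horizon_years=1)
        tr = run_stratum(inputs, Stratum("women", 30, "0-6", 1),
                         "comparator", sett)
        assert tr.qalys_discounted.sum() == pytest.approx(
            (8573 / (8573 + 889)) / 1.03, rel=1e-9)

    def test_zero_discount_equals_undiscounted(self, ref_inputs):
        sett = EconomicSettings(discount_rate=0.0, horizon_years=15)
        tr = run_stratum(ref_inputs, WOMAN, "intervention", sett)
        assert tr.costs_discounted.sum() == pytest.approx(tr.costs.sum())
        assert tr.qalys_discounted.sum() == pytest.approx(tr.qalys.sum())

    def test_occupancy_conserved_and_dead_monotone_30_cycles(self, ref_inputs):
        sett = EconomicSettings(horizon_years=30)
        for s in ref_inputs.cohort.strata:
            for arm in ("comparator", "intervention"):
                tr = run_stratum(ref_inputs, s, arm, sett)
                np.testing.assert_allclose(tr.occupancy.sum(axis=1), 1.0,
                                           atol=1e-12)
                dead = tr.occupancy[:, 3]
                assert (np.diff(dead) >= -1e-15).all()
                assert ((tr.occupancy >= -1e-15)
                        & (tr.occupancy <= 1 + 1e-15)).all()

    def test_matches_matrix_product_route(self, ref_inputs):
        """Fast scalar path vs explicit transition-matrix composition."""
        sett = EconomicSettings(horizon_years=12)
        for s in (WOMAN, Stratum("men", 62, "20-26", 10)):
            for arm in ("comparator", "intervention"):
                tr = run_stratum(ref_inputs, s, arm, sett)
                occ = np.zeros((13, 4))
                occ[0, 0] = 1.0
                dur = 0.0
                for cyc in range(1, 13):
                    M = transition_matrix(ref_inputs, s, arm, cyc,
                                          t2d_duration=dur)
                    occ[cyc] = occ[cyc - 1] @ M
                    stay = occ[cyc - 1][1] * M[1, 1]
                    ent = occ[cyc - 1][0] * M[0, 1]
                    dur = stay * (dur + 1) / (stay + ent) if stay + ent else 0
                np.testing.assert_allclose(tr.occupancy, occ, atol=1e-12)

    def test_intervention_t2d_occupancy_lower_while_effect_active(
            self, ref_inputs):
        """With HR < 1 the intervention arm carries less prevalent T2D every
        cycle the effect is active; once the effect ends the larger surviving
        at-risk pool converts at full hazard, so prevalence may later cross
        over, but cumulative incidence stays lower throughout."""
        dur = ref_inputs.params.hazards.intervention_effect_duration_years
        sett = EconomicSettings(horizon_years=30)
        for s in ref_inputs.cohort.strata[::7]:
            ci = run_stratum(ref_inputs, s, "intervention", sett)
            cc = run_stratum(ref_inputs, s, "comparator", sett)
            t2dish_i = ci.occupancy[:, 1] + ci.occupancy[:, 2]
            t2dish_c = cc.occupancy[:, 1] + cc.occupancy[:, 2]
            assert (t2dish_i[:dur + 1] <= t2dish_c[:dur + 1] + 1e-12).all()
            # ever-at-risk fraction never drops below the comparator's
            assert (ci.occupancy[:, 0] >= cc.occupancy[:, 0] - 1e-12).all()


class TestBruteForceOracle:
    def test_three_cycle_two_stratum_totals(self, ref_inputs):
        """Engine totals vs an exhaustive hand-enumerated matrix-product
        computation for a toy cohort."""
        strata = (Stratum("women", 50, "15-19", 3),
                  Stratum("men", 58, "20-26", 7))
        inputs = dataclasses.replace(ref_inputs,
                                     cohort=CohortDefinition(strata=strata))
        sett = EconomicSettings(discount_rate=0.03, horizon_years=3)
        arm_res = run_cohort(inputs, "intervention", sett)

        exp_cost = {"women": 0.0, "men": 0.0}
        exp_qaly = {"women": 0.0, "men": 0.0}
        for s in strata:
            occ = np.array([1.0, 0, 0, 0])
            dur = 0.0
            cost = (inputs.params.costs.recruitment_per_eligible.point
                    + inputs.params.costs.intervention_per_participant.point)
            qaly = 0.0
            for cyc in (1, 2, 3):
                M = transition_matrix(inputs, s, "intervention", cyc,
                                      t2d_duration=dur)
                stay = occ[1] * M[1, 1]
                ent = occ[0] * M[0, 1]
                occ = occ @ M
                dur = stay * (dur + 1) / (stay + ent) if stay + ent else 0.0
                cdict, q = cycle_rewards(occ, s.entry_age + cyc - 1, s.gender,
                                         inputs.params,
                                         EconomicSettings(perspective="societal"))
                cost += sum(cdict.values()) / 1.03 ** cyc
                qaly += q / 1.03 ** cyc
            exp_cost[s.gender] += cost * s.count
            exp_qaly[s.gender] += qaly * s.count
        for g, n in (("women", 3), ("men", 7)):
            assert arm_res.total_cost(g, "societal") * n == pytest.approx(
                exp_cost[g], abs=1e-12 * max(1, exp_cost[g]))
            assert arm_res.total_qalys(g) * n == pytest.approx(
                exp_qaly[g], abs=1e-12 * max(1, exp_qaly[g]))


class TestScenarioAggregation:
    def test_overall_is_count_weighted_gender_mean(self, small_inputs):
        res = run_scenario(small_inputs, EconomicSettings(horizon_years=20))
        n_w, n_m = res.counts["women"], res.counts["men"]
        for persp in ("societal", "direct_only"):
            manual = (res.savings("women", persp) * n_w
                      + res.savings("men", persp) * n_m) / (n_w + n_m)
            assert res.savings("overall", persp) == pytest.approx(
                manual, rel=1e-9)
        assert res.population_savings() == pytest.approx(
            res.population_savings("women") + res.population_savings("men"),
            rel=1e-9)

    def test_empty_cohort_warns_and_returns_zero(self, ref_inputs):
        empty = dataclasses.replace(ref_inputs,
                                    cohort=CohortDefinition(strata=()))
        with pytest.warns(UserWarning, match="empty cohort"):
            arm = run_cohort(empty, "comparator",
                             EconomicSettings(horizon_years=5))
        assert arm.total_qalys("women") == 0.0

    def test_intervention_dominates_with_protective_hr(self, small_inputs):
        res = run_scenario(small_inputs, EconomicSettings(horizon_years=20))
        assert res.delta_qaly("overall") > 0
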