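"""Per-person operations and the vectorised strategy engine."""

import numpy as np
import pytest

import fallsim as fs
from fallsim.microsim import (FallerType, OUTCOME_FIELDS, CycleEvent,
                              assign_intervention, classify_faller,
                              cycle_outcomes, discount_factor,
                              eligible_proactive, eligible_reactive,
                              eligible_self_referred, fall_probability,
                              ltc_admission, make_strategy, mortality_step,
                              update_frailty, update_time_varying)

from conftest import summaries_equal


def make_person(params, **overrides):
    cohort = fs.generate_baseline_cohort(1, params, seed=0)
    person = cohort[0]
    for key, value in overrides.items():
        setattr(person, key, value)
    return person


class TestDiscounting:
    @pytest.mark.parametrize("cycle, rate, expected", [
        (0, 0.035, 1.0),
        (7, 0.0, 1.0),
        (2, 0.035, 1.0 / 1.035**2),
        (1, 0.035, 1.0 / 1.035),
    ])
    def test_values(self, cycle, rate, expected):
        assert discount_factor(cycle, rate) == pytest.approx(expected, rel=1e-12)

    def test_negative_cycle_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(-1, 0.035)


class TestFallProbability:
    def test_zero_coefficients_give_half(self, params):
        c = params.fall_risk_coefficients
        for name in vars(c):
            setattr(c, name, 0.0)
        params.ses_gradients.fall_odds = (1.0, 1.0, 1.0, 1.0)
        person = make_person(params)
        assert fall_probability(person, params) == pytest.approx(0.5)

    def test_logistic_evaluation(self, params):
        """Intercept -1.0 plus frailty 50 at coefficient 0.8 -> logistic(-0.6)."""
        c = params.fall_risk_coefficients
        for name in vars(c):
            setattr(c, name, 0.0)
        c.intercept, c.frailty = -1.0, 0.8
        params.ses_gradients.fall_odds = (1.0, 1.0, 1.0, 1.0)
        person = make_person(params, frailty=50.0, falls_history=False,
                             physical_activity_low=False,
                             cognitive_impairment=False, fear_of_falling=False,
                             abnormal_gait_balance=False)
        expected = 1.0 / (1.0 + np.exp(0.6))
        assert fall_probability(person, params) == pytest.approx(expected, rel=1e-9)
        assert fall_probability(person, params) == pytest.approx(0.3543, abs=5e-5)

    def test_protective_effect_lowers_probability(self, params):
        person = make_person(params)
        assert (fall_probability(person, params, active_effect=0.5)
                < fall_probability(person, params, active_effect=1.0))

    def test_effect_outside_unit_interval_rejected(self, params):
        with pytest.raises(ValueError):
            fall_probability(make_person(params), params, active_effect=1.5)


class TestFallerClassification:
    def test_no_fall(self, params):
        rng = np.random.default_rng(0)
        assert classify_faller(False, params, rng) == (FallerType.NO_FALL, 0)

    def test_degenerate_split(self, params):
        split = params.faller_type_split
        split.single_non_ma, split.single_ma = 1.0, 0.0
        split.recurrent_non_ma = split.recurrent_with_ma = 0.0
        rng = np.random.default_rng(0)
        for _ in range(50):
            assert classify_faller(True, params, rng) == (FallerType.SINGLE_NON_MA, 0)

    def test_hospitalisation_frequency(self, params):
        """Single-MA falls hospitalise at 28% (within 3 standard errors)."""
        split = params.faller_type_split
        split.single_non_ma, split.single_ma = 0.0, 1.0
        split.recurrent_non_ma = split.recurrent_with_ma = 0.0
        rng = np.random.default_rng(1)
        n = 100000
        hosp = sum(classify_faller(True, params, rng)[1] for _ in range(n))
        se = np.sqrt(0.28 * 0.72 / n)
        assert abs(hosp / n - 0.28) < 3 * se

    def test_invalid_split_rejected(self, params):
        params.faller_type_split.single_ma = 0.9
        with pytest.raises(ValueError, match="sum to 1"):
            classify_faller(True, params, np.random.default_rng(0))


class TestMortality:
    def test_zero_risk_survives(self, params):
        params.fatal_fall_params.intercept = -60.0
        params.other_cause_mortality_params.q60_male = 0.0
        params.other_cause_mortality_params.q60_female = 0.0
        person = make_person(params)
        assert mortality_step(person, params, np.random.default_rng(0)) is None

    def test_certain_schedule_dies_other_cause(self, params):
        params.fatal_fall_params.intercept = -60.0
        params.other_cause_mortality_params.q60_male = 1.0
        params.other_cause_mortality_params.q60_female = 1.0
        params.other_cause_mortality_params.cap = 1.0
        params.ses_gradients.mortality = (1.0, 1.0, 1.0, 1.0)
        person = make_person(params, age=60.0, frailty=0.0)
        assert mortality_step(person, params, np.random.default_rng(0)) == "other_cause"

    def test_combined_death_frequency(self, params):
        """Death frequency matches 1-(1-p_fatal)(1-q) at a fixed profile."""
        from fallsim.microsim import _fatal_fall_prob, _other_cause_prob
        params.ses_gradients.mortality = (1.0, 1.0, 1.0, 1.0)
        person = make_person(params, age=70.0, frailty=20.0, sex="M")
        p_fatal = _fatal_fall_prob(params, 70.0, 20.0)
        q = float(_other_cause_prob(params, 70.0, False, 20.0))
        expected = 1.0 - (1.0 - p_fatal) * (1.0 - q)
        rng = np.random.default_rng(2)
        n = 50000
        deaths = sum(mortality_step(person, params, rng) is not None
                     for _ in range(n))
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(deaths / n - expected) < 3 * se


class TestFrailtyAndTimeVarying:
    def test_zero_increments_leave_frailty(self, params):
        params.frailty_progression.base_increments = (0.0, 0.0, 0.0)
        person = make_person(params, frailty=30.0)
        assert update_frailty(person, FallerType.NO_FALL, params) == 30.0

    def test_clamped_at_hundred(self, params):
        params.frailty_progression.base_increments = (2.0, 2.0, 2.0)
        person = make_person(params, frailty=99.5)
        assert update_frailty(person, FallerType.NO_FALL, params) == 100.0

    def test_scenario_multiplier_arithmetic(self, params):
        """(base 0.8 + recurrent-MA add-on 1.2) x 1.2 = +2.4 points."""
        params.frailty_progression.base_increments = (0.8, 0.8, 0.8)
        params.frailty_progression.faller_addons["recurrent_with_ma"] = 1.2
        person = make_person(params, frailty=10.0, age=65.0)
        new = update_frailty(person, FallerType.RECURRENT_WITH_MA, params,
                             scenario_multiplier=1.2)
        assert new == pytest.approx(12.4)

    def test_falls_history_set_from_faller_type(self, params):
        person = make_person(params, falls_history=False)
        updated = update_time_varying(person, FallerType.SINGLE_MA, params,
                                      np.random.default_rng(0))
        assert updated.falls_history
        updated = update_time_varying(person, FallerType.NO_FALL, params,
                                      np.random.default_rng(0))
        assert not updated.falls_history

    def test_zero_transitions_only_age_changes(self, params):
        for attr in ("cognitive_impairment_incidence", "fear_of_falling_onset",
                     "gait_balance_onset"):
            getattr(params, attr).intercept = -60.0
        params.activity_transition.decline.intercept = -60.0
        params.activity_transition.recovery_prob = 0.0
        person = make_person(params, cognitive_impairment=False,
                             fear_of_falling=False, abnormal_gait_balance=False,
                             physical_activity_low=False)
        updated = update_time_varying(person, FallerType.NO_FALL, params,
                                      np.random.default_rng(0))
        assert updated.age == person.age + 1
        assert not (updated.cognitive_impairment or updated.fear_of_falling
                    or updated.abnormal_gait_balance
                    or updated.physical_activity_low)

    def test_cognitive_incidence_scenario_multiplier(self, params):
        """Acquisition frequency tracks incidence x multiplier (~0.06)."""
        inc = params.cognitive_impairment_incidence
        inc.intercept = np.log(0.05 / 0.95)
        inc.age_slope = inc.frailty_slope = 0.0
        person = make_person(params, age=60.0, frailty=0.0,
                             cognitive_impairment=False)
        rng = np.random.default_rng(3)
        n = 100000
        acquired = sum(update_time_varying(person, FallerType.NO_FALL, params,
                                           rng, cognitive_multiplier=1.2)
                       .cognitive_impairment for _ in range(n))
        expected = 0.06
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(acquired / n - expected) < 3 * se


class TestLTC:
    def test_forced_probabilities(self, params):
        params.ltc_admission_params.intercept = -600.0
        person = make_person(params)
        assert not ltc_admission(person, params, np.random.default_rng(0))
        params.ltc_admission_params.intercept = 600.0
        assert ltc_admission(person, params, np.random.default_rng(0))

    def test_monotone_in_frailty(self, params):
        from fallsim.microsim import _ltc_prob
        assert _ltc_prob(params, 75.0, 60.0) > _ltc_prob(params, 75.0, 10.0)


class TestEligibility:
    def test_reactive_requires_previous_ma_fall(self, params):
        person = make_person(params)
        for ftype, expected in [(FallerType.SINGLE_MA, True),
                                (FallerType.RECURRENT_WITH_MA, True),
                                (FallerType.NO_FALL, False),
                                (FallerType.RECURRENT_NON_MA, False)]:
            event = CycleEvent(person_id=0, cycle=0, faller_type=ftype)
            assert eligible_reactive(person, event) is expected
        assert eligible_reactive(person, None) is False

    def test_proactive_conjunction_rule(self, params):
        params.access_params.gp_access_rate = 1.0
        params.ses_gradients.gp_access = (1.0, 1.0, 1.0, 1.0)
        rng = np.random.default_rng(0)
        both = make_person(params, falls_history=True, abnormal_gait_balance=True)
        assert eligible_proactive(both, params, rng)
        history_only = make_person(params, falls_history=True,
                                   abnormal_gait_balance=False)
        assert not eligible_proactive(history_only, params, rng)
        assert eligible_proactive(history_only, params, rng, screening_rule="or")

    def test_proactive_no_gp_access(self, params):
        params.access_params.gp_access_rate = 0.0
        person = make_person(params, falls_history=True, abnormal_gait_balance=True)
        assert not any(eligible_proactive(person, params, np.random.default_rng(s))
                       for s in range(20))

    def test_self_referral_open_to_community(self, params):
        person = make_person(params)
        assert eligible_self_referred(person)
        person.in_ltc = True
        with pytest.raises(ValueError):
            eligible_self_referred(person)
        person.in_ltc, person.alive = False, False
        with pytest.raises(ValueError):
            eligible_self_referred(person)


class TestAssignment:
    def test_zero_demand_means_no_receipt(self, params):
        for pw in ("R", "P", "SR"):
            acc = getattr(params.access_params, pw)
            acc.demand_usual = acc.demand_recommended = 0.0
        config = make_strategy("RC", params)
        person = make_person(params)
        assert assign_intervention(person, config, params,
                                   np.random.default_rng(0)) is None

    def test_precedence_reactive_first(self, params):
        """Eligible for R and SR with certain supply/demand -> R received."""
        for pw in ("R", "P", "SR"):
            acc = getattr(params.access_params, pw)
            acc.supply_recommended = acc.demand_recommended = 1.0
        params.access_params.gp_access_rate = 0.0
        config = make_strategy("RC", params)
        person = make_person(params)
        last = CycleEvent(person_id=0, cycle=0, faller_type=FallerType.SINGLE_MA)
        assert assign_intervention(person, config, params,
                                   np.random.default_rng(0), last) == "R"

    def test_receipt_frequency_matches_supply_times_demand(self, params):
        """Under UC, a person eligible only for SR enrols at ~s x d."""
        params.access_params.gp_access_rate = 0.0
        acc = params.access_params.SR
        config = make_strategy("UC", params)
        person = make_person(params, falls_history=False,
                             abnormal_gait_balance=False)
        rng = np.random.default_rng(4)
        n = 50000
        got = sum(assign_intervention(person, config, params, rng) == "SR"
                  for _ in range(n))
        expected = acc.supply_usual * acc.demand_usual
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(got / n - expected) < 3 * se


class TestCycleOutcomes:
    def test_utility_decomposition(self, params):
        """0.8 baseline - 0.1 frailty decrement - 0.05 acute loss = 0.65."""
        up = params.utility_params
        up.base_60_male = up.base_60_female = 0.8
        up.age_slope = 0.0
        up.frailty_decrement = 0.004
        up.acute_loss["single_ma"] = 0.05
        params.ses_gradients.utility = (1.0, 1.0, 1.0, 1.0)
        person = make_person(params, age=60.0, frailty=25.0)
        event = CycleEvent(person_id=0, cycle=0, faller_type=FallerType.SINGLE_MA)
        utility, _ = cycle_outcomes(person, event, params)
        assert utility == pytest.approx(0.8 - 0.1 - 0.05)

    def test_no_fall_zero_base_cost(self, params):
        cp = params.cost_params
        cp.public_base = cp.public_age_slope = cp.public_frailty_slope = 0.0
        person = make_person(params)
        event = CycleEvent(person_id=0, cycle=0)
        _, costs = cycle_outcomes(person, event, params)
        assert costs["public_allcause"] == 0.0
        assert costs["public_fall"] == 0.0

    def test_hospitalised_ma_fall_costed_at_configured_level(self, params):
        person = make_person(params)
        event = CycleEvent(person_id=0, cycle=0,
                           faller_type=FallerType.SINGLE_MA, hospitalised_ma=1)
        _, costs = cycle_outcomes(person, event, params)
        expected = (params.cost_params.fall_public["single_ma"]
                    + params.cost_params.hospitalised_ma_cost)
        assert costs["public_fall"] == pytest.approx(expected)


def _frozen_world(params):
    """No falls, no deaths, no LTC, utility pinned at 1: pure person-years."""
    params.fall_risk_coefficients.intercept = -600.0
    params.fatal_fall_params.intercept = -600.0
    params.other_cause_mortality_params.q60_male = 0.0
    params.other_cause_mortality_params.q60_female = 0.0
    params.ltc_admission_params.intercept = -600.0
    up = params.utility_params
    up.base_60_male = up.base_60_female = 1.0
    up.age_slope = up.frailty_decrement = 0.0
    params.ses_gradients.utility = (1.0, 1.0, 1.0, 1.0)
    return params


class TestRunStrategy:
    def test_person_years_undiscounted(self, params):
        """100 immortal people, 3 cycles, no discounting -> 300 QALYs."""
        _frozen_world(params)
        params.economics.discount_rate = 0.0
        spec = fs.PopulationSpec(n_baseline=100, entry_size=0)
        summary = fs.run_strategy(params, make_strategy("UC", params), spec,
                                  master_seed=1, horizon=3)
        assert summary.total("qalys") == pytest.approx(300.0)

    def test_person_years_discounted_annuity(self, params):
        """Per-person QALYs equal 1 + 1.035^-1 + 1.035^-2 under discounting."""
        _frozen_world(params)
        spec = fs.PopulationSpec(n_baseline=100, entry_size=0)
        summary = fs.run_strategy(params, make_strategy("UC", params), spec,
                                  master_seed=1, horizon=3)
        annuity = 1.0 + 1.035**-1 + 1.035**-2
        assert summary.total("qalys") / 100 == pytest.approx(annuity, rel=1e-12)

    def test_quartile_subtotals_sum_to_totals(self, small_summaries):
        for summary in small_summaries.values():
            for fname in OUTCOME_FIELDS:
                by_q = getattr(summary, fname)
                assert by_q.sum() == pytest.approx(summary.total(fname), rel=1e-9)

    def test_fall_related_cost_within_all_cause(self, small_summaries):
        for summary in small_summaries.values():
            assert np.all(summary.cost_public_fall
                          <= summary.cost_public_allcause + 1e-9)

    def test_absorbing_death_stops_accrual(self, params):
        """Certain first-cycle death leaves nothing accrued."""
        params.other_cause_mortality_params.q60_male = 1.0
        params.other_cause_mortality_params.q60_female = 1.0
        params.other_cause_mortality_params.cap = 1.0
        params.ses_gradients.mortality = (1.0, 1.0, 1.0, 1.0)
        spec = fs.PopulationSpec(n_baseline=200, entry_size=0)
        summary = fs.run_strategy(params, make_strategy("UC", params), spec,
                                  master_seed=1, horizon=5)
        # intervention assignment precedes mortality within the cycle, so
        # only non-intervention accumulators must stay empty
        for fname in OUTCOME_FIELDS:
            if not fname.startswith("cost_int_"):
                assert summary.total(fname) == 0.0

    def test_absorbing_ltc_allows_one_cycle(self, params):
        """Certain LTC admission: exactly one cycle of utility accrues."""
        _frozen_world(params)
        params.ltc_admission_params.intercept = 600.0
        params.economics.discount_rate = 0.0
        spec = fs.PopulationSpec(n_baseline=150, entry_size=0)
        summary = fs.run_strategy(params, make_strategy("UC", params), spec,
                                  master_seed=1, horizon=6)
        assert summary.total("qalys") == pytest.approx(150.0)

    def test_determinism(self, params):
        spec = fs.PopulationSpec(n_baseline=400)
        config = make_strategy("R+SR", params)
        a = fs.run_strategy(params, config, spec, master_seed=9, horizon=12)
        b = fs.run_strategy(params, config, spec, master_seed=9, horizon=12)
        assert summaries_equal(a, b)

    def test_null_intervention_equivalence_small(self, null_intervention_params):
        """RR=1 and free interventions make all strategies bit-identical."""
        spec = fs.PopulationSpec(n_baseline=500)
        sums = {name: fs.run_strategy(null_intervention_params,
                                      make_strategy(name, null_intervention_params),
                                      spec, master_seed=5, horizon=12)
                for name in fs.STRATEGY_NAMES}
        ref = sums["UC"]
        assert all(summaries_equal(s, ref) for s in sums.values())

    def test_intervention_reduces_fall_burden(self, params):
        """Scaling up all pathways cuts discounted fall-related cost vs UC."""
        spec = fs.PopulationSpec(n_baseline=8000)
        uc = fs.run_strategy(params, make_strategy("UC", params), spec, 2)
        rc = fs.run_strategy(params, make_strategy("RC", params), spec, 2)
        assert rc.total("cost_public_fall") < uc.total("cost_public_fall")
        assert rc.total("cost_int_public") > uc.total("cost_int_public")

    def test_fall_risk_monotonicity(self, params):
        """A higher fall-risk intercept raises expected fall burden (n=50k)."""
        spec = fs.PopulationSpec(n_baseline=50000)
        base = fs.run_strategy(params, make_strategy("UC", params), spec, 3,
                               horizon=10)
        risky = params.copy()
        risky.fall_risk_coefficients.intercept += 0.5
        more = fs.run_strategy(risky, make_strategy("UC", risky), spec, 3,
                               horizon=10)
        assert more.total("cost_public_fall") > base.total("cost_public_fall")

    def test_frailty_monotonicity(self, params):
        """20% higher baseline frailty lowers total expected QALYs (n=50k)."""
        spec = fs.PopulationSpec(n_baseline=50000)
        base = fs.run_strategy(params, make_strategy("UC", params), spec, 3,
                               horizon=10)
        frail = params.copy()
        frail.adjustments.baseline_frailty = 1.2
        less = fs.run_strategy(frail, make_strategy("UC", frail), spec, 3,
                               horizon=10)
        assert less.total("qalys") < base.total("qalys")

    def test_invalid_config_rejected_before_simulation(self, params):
        config = make_strategy("RC", params)
        broken = fs.StrategyConfig(name="RC", levels=dict(config.levels),
                                   supply={**config.supply, "R": 0.5},
                                   demand=dict(config.demand))
        with pytest.raises(ValueError, match="supply"):
            fs.run_strategy(params, broken, fs.PopulationSpec(n_baseline=10),
                            master_seed=0, horizon=2)

    def test_horizon_validation(self, params):
        with pytest.raises(ValueError, match="horizon"):
            fs.run_strategy(params, make_strategy("UC", params),
                            fs.PopulationSpec(n_baseline=10), 0, horizon=0)

    def test_event_log_shape(self, params):
        spec = fs.PopulationSpec(n_baseline=50, entry_size=0)
        summary, events = fs.run_strategy(params, make_strategy("UC", params),
                                          spec, 1, horizon=3,
                                          collect_events=True)
        assert {"person_id", "cycle", "intervention", "died",
                "faller_type"} <= set(events.columns)
        assert events["cycle"].max() <= 2

    def test_summary_frame_round_trip(self, small_summaries):
        import pandas as pd
        from fallsim.microsim import StrategySummary
        frame = pd.concat([s.to_frame() for s in small_summaries.values()],
                          ignore_index=True)
        rebuilt = StrategySummary.from_frame(frame)
        for name, summary in small_summaries.items():
            assert summaries_equal(rebuilt[name], summary)
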