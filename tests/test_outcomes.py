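"""Outcome valuation: mixing equations, utilities, costs, discounting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smokecea.engine import run_cohort
from smokecea.outcomes import (
    accumulate,
    cycle_healthcare_cost,
    cycle_utility,
    discount_factor,
    mixed_incidence,
    mixed_prevalence,
    productivity_loss,
)
from smokecea.parameters import UtilityParams, ValidationError
from smokecea.fixtures import toy_scenario

from conftest import constant_mortality, zero_mortality


class TestMixing:
    def test_printed_formula_hand_arithmetic(self):
        assert mixed_incidence(0.01, 0.005, 100, 100) == pytest.approx(1.5)

    def test_zero_counts_give_zero(self):
        assert mixed_incidence(0.3, 0.3, 0, 0) == 0.0

    def test_rr_weighted_incidence_all_smokers(self):
        # background 0.001/yr, smoker RR 8.78, 1000 smokers, no former
        inc_smoker = 0.001 * 8.78
        inc_former = 0.001 * 3.01
        assert mixed_incidence(inc_smoker, inc_former, 1000, 0) == pytest.approx(8.78)

    def test_prevalence_mixture(self):
        assert mixed_prevalence(0.2, 0.1, 0.5, 0.5) == pytest.approx(0.15)
        assert mixed_prevalence(0.37, 0.37, 1.0, 0.0) == pytest.approx(0.37)
        assert mixed_prevalence(0.0, 0.0, 0.3, 0.7) == 0.0

    def test_negative_and_out_of_range_inputs_rejected(self):
        with pytest.raises(ValidationError):
            mixed_incidence(-0.1, 0.0, 1, 1)
        with pytest.raises(ValidationError):
            mixed_prevalence(1.2, 0.0, 0.5, 0.5)
        with pytest.raises(ValidationError):
            mixed_prevalence(0.5, 0.5, 0.8, 0.7)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(a=st.floats(0, 1), b=st.floats(0, 1), k=st.floats(0, 5),
           n1=st.floats(0, 1e4), n2=st.floats(0, 1e4))
    def test_incidence_linear_in_each_argument(self, a, b, k, n1, n2):
        base = mixed_incidence(a, b, n1, n2)
        assert mixed_incidence(a * k, b, n1, n2) == pytest.approx(
            base + a * (k - 1) * n1, rel=1e-9, abs=1e-9)
        assert mixed_incidence(a, b, n1 * k, n2) == pytest.approx(
            base + a * (k - 1) * n1, rel=1e-9, abs=1e-9)


class TestCycleUtility:
    def test_healthy_smoker_cohort_half_year(self):
        u = UtilityParams()
        q = cycle_utility({"smoker": 1000.0}, u, {"smoker": []})
        assert q == pytest.approx(1000 * 0.5 * 0.75)  # 375 QALYs

    def test_no_one_alive_gives_zero(self):
        assert cycle_utility({"smoker": 0.0, "former_smoker": 0.0},
                             UtilityParams(), {}) == 0.0

    def test_lowest_utility_rule_takes_worst_decrement(self):
        # former smoker with both diseases surely prevalent: 0.78 - 0.25
        u = UtilityParams()
        q = cycle_utility({"former_smoker": 1.0}, u,
                          {"former_smoker": [(1.0, 0.10), (1.0, 0.25)]})
        assert q == pytest.approx(0.5 * (0.78 - 0.25))

    def test_independent_comorbidity_mix_single_person(self):
        # one disease at prevalence p: expected utility p*(u-d) + (1-p)*u
        u = UtilityParams()
        p, d = 0.3, 0.2
        q = cycle_utility({"smoker": 1.0}, u, {"smoker": [(p, d)]})
        assert q == pytest.approx(0.5 * (0.75 - p * d))

    def test_clamped_at_zero_with_warning(self):
        u = UtilityParams(u_smoker_healthy=0.1, u_former_healthy=0.1)
        with pytest.warns(RuntimeWarning, match="clamped"):
            q = cycle_utility({"smoker": 1.0}, u, {"smoker": [(1.0, 0.9)]})
        assert q == 0.0


class TestDiscounting:
    @pytest.mark.parametrize("rate, cycle, expected", [
        (0.03, 0, 1.0),
        (0.03, 2, 1 / 1.03),
        (0.06, 2, 1 / 1.06),
        (0.0, 7, 1.0),
    ])
    def test_closed_form(self, rate, cycle, expected):
        assert discount_factor(rate, cycle) == pytest.approx(expected)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValidationError):
            discount_factor(-0.01, 1)


class TestHealthcareCost:
    def test_cycle0_program_cost_combined(self, male_params):
        cost = cycle_healthcare_cost({}, {}, male_params.diseases,
                                     male_params.program_costs, 0, "combined", 1000)
        assert cost == pytest.approx(187.90 * 1000 + 1900)  # 189,800

    def test_cycle0_program_cost_advice(self, male_params):
        cost = cycle_healthcare_cost({}, {}, male_params.diseases,
                                     male_params.program_costs, 0, "advice", 1000)
        assert cost == pytest.approx(166950.0)

    def test_incident_lung_cancer_case_year_rate(self, male_params):
        # one case-year = two half-year cycles at the annual case rate
        per_cycle = cycle_healthcare_cost({"lung_cancer": 1.0}, {},
                                          male_params.diseases,
                                          male_params.program_costs, 3,
                                          "combined", 1000)
        assert 2 * per_cycle == pytest.approx(13206.0)

    def test_unknown_disease_rejected(self, male_params):
        with pytest.raises(ValidationError):
            cycle_healthcare_cost({"gout": 1.0}, {}, male_params.diseases,
                                  male_params.program_costs, 1, "combined", 1000)

    def test_no_disease_reduces_to_program_cost_only(self, male_params):
        p = male_params.copy()
        p.diseases = []
        trace = run_cohort(p, "combined")
        res = accumulate(trace, p, "healthcare")
        assert res.total_cost == pytest.approx(
            p.program_costs.initial_cost("combined", 1000))


class TestProductivityLoss:
    def test_zero_employment_gives_zero(self, male_params):
        lab = male_params.labour
        lab.employment = {s: {b: 0.0 for b in bands}
                          for s, bands in lab.employment.items()}
        assert productivity_loss({"smoker": 100.0}, lab, 40, "male") == 0.0

    def test_hand_arithmetic_male_35_44(self, male_params):
        # daily wage 15.90 * 155*12/365 ; 100 smokers, employment 0.9405
        loss = productivity_loss({"smoker": 100.0}, male_params.labour, 40, "male")
        daily = 15.90 * 155 * 12 / 365
        assert loss == pytest.approx(100 * 0.9405 * 11 * daily * 0.5)

    def test_status_ratio_is_sick_day_ratio(self, male_params):
        lab = male_params.labour
        smoker = productivity_loss({"smoker": 50.0}, lab, 50, "female")
        former = productivity_loss({"former_smoker": 50.0}, lab, 50, "female")
        assert smoker / former == pytest.approx(11 / 7)

    def test_age_below_16_rejected(self, male_params):
        with pytest.raises(ValidationError):
            productivity_loss({"smoker": 1.0}, male_params.labour, 15, "male")


class TestAccumulate:
    def test_qalys_equal_life_years_at_discount0_utility1(self, male_params):
        p = male_params.copy()
        p.settings.discount_rate_costs = 0.0
        p.settings.discount_rate_effects = 0.0
        p.utilities = UtilityParams(u_smoker_healthy=1.0, u_former_healthy=1.0)
        p.diseases = []
        trace = run_cohort(p, "advice")
        res = accumulate(trace, p, "healthcare")
        assert res.total_qalys == pytest.approx(trace.total_life_years, abs=1e-9)

    def test_societal_equals_healthcare_plus_productivity(self, female_params):
        trace = run_cohort(female_params, "combined")
        hc = accumulate(trace, female_params, "healthcare")
        soc = accumulate(trace, female_params, "societal")
        # exact additivity: bitwise, not approximate
        assert soc.total_cost == hc.total_cost + soc.total_productivity_loss
        assert soc.total_qalys == hc.total_qalys

    def test_totals_nonincreasing_in_discount_rate(self, male_params):
        totals = []
        for rate in (0.0, 0.03, 0.06, 0.10):
            p = male_params.copy()
            p.settings.discount_rate_costs = rate
            p.settings.discount_rate_effects = rate
            trace = run_cohort(p, "combined")
            res = accumulate(trace, p, "societal")
            totals.append((res.total_cost, res.total_qalys))
        assert all(b[0] <= a[0] + 1e-9 and b[1] <= a[1] + 1e-9
                   for a, b in zip(totals, totals[1:]))

    def test_toy_scenario_matches_spreadsheet_oracle(self):
        p, expected = toy_scenario()
        for arm in ("combined", "advice"):
            trace = run_cohort(p, arm)
            for persp in ("healthcare", "societal"):
                res = accumulate(trace, p, persp)
                assert res.total_cost == pytest.approx(
                    expected[arm][persp]["cost"], abs=1e-9)
                assert res.total_qalys == pytest.approx(
                    expected[arm][persp]["qalys"], abs=1e-9)

    def test_ledger_schema_and_discounted_bounds(self, male_params):
        trace = run_cohort(male_params, "combined")
        res = accumulate(trace, male_params, "societal")
        led = res.ledger
        for col in ("qaly_undisc", "hc_cost_undisc", "prod_loss_undisc"):
            disc = col.replace("undisc", "disc")
            assert np.all(led[disc] <= led[col] + 1e-12)
        assert np.all((led["df_costs"] > 0) & (led["df_costs"] <= 1))
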