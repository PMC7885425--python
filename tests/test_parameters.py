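"""Parameter loading, validation, conversion, and mortality calibration."""

import numpy as np
import pytest
import yaml
from hypothesis import given, settings
from hypothesis import strategies as st

from smokecea.parameters import (
    AgeSchedule,
    CalibrationError,
    LifeTable,
    MortalitySchedule,
    ParameterSet,
    ValidationError,
    _mixture_life_expectancy,
    annual_to_cycle_probability,
    baseline_parameters,
    baseline_provenance,
    calibrate_mortality,
    load_parameters,
)


class TestBaseline:
    @pytest.mark.parametrize("arm, sex, getter, expected", [
        ("combined", "male",
         lambda p: p.transitions["combined"].p_quit_first_cycle, 0.24375),
        ("advice", "male",
         lambda p: p.transitions["advice"].p_quit_first_cycle, 0.11875),
        ("advice", "female",
         lambda p: p.transitions["advice"].p_relapse_after_first_quit_cycle, 0.5264),
        ("combined", "male",
         lambda p: p.transitions["combined"].p_relapse_after_first_quit_cycle, 0.333),
        ("combined", "male", lambda p: p.program_costs.per_patient["combined"], 187.90),
        ("advice", "female", lambda p: p.program_costs.per_patient["advice"], 166.95),
        ("combined", "male", lambda p: p.disease("lung_cancer").rr_smoker, 8.78),
        ("combined", "female", lambda p: p.disease("lung_cancer").rr_smoker, 7.48),
        ("combined", "male", lambda p: p.disease("lung_cancer").rr_former, 3.01),
        ("combined", "female", lambda p: p.disease("lung_cancer").rr_former, 2.82),
        ("combined", "male", lambda p: p.utilities.u_smoker_healthy, 0.75),
        ("combined", "male", lambda p: p.utilities.u_former_healthy, 0.78),
        ("combined", "male", lambda p: p.threshold, 22000.0),
        ("combined", "male", lambda p: p.disease("lung_cancer").cost_incident, 13206.0),
        ("combined", "male", lambda p: p.labour.hourly_wage["male"], 15.90),
        ("combined", "female", lambda p: p.labour.hourly_wage["female"], 13.60),
        ("combined", "male", lambda p: p.labour.sick_days["smoker"], 11.0),
        ("combined", "male", lambda p: p.labour.sick_days["former_smoker"], 7.0),
    ])
    def test_baseline_values(self, arm, sex, getter, expected):
        assert getter(baseline_parameters(arm, sex)) == pytest.approx(expected)

    def test_exactly_five_diseases(self, male_params):
        assert len(male_params.diseases) == 5

    def test_unknown_arm_or_sex_rejected(self):
        with pytest.raises(ValidationError):
            baseline_parameters("placebo", "male")
        with pytest.raises(ValidationError):
            baseline_parameters("combined", "other")

    def test_every_numeric_baseline_field_has_provenance(self):
        # baseline_provenance raises KeyError for an untagged numeric leaf
        tags = baseline_provenance()
        assert tags["transitions.combined.p_quit_first_cycle"].startswith("trial:")
        assert all(":" in tag for tag in tags.values())

    def test_rr_ordering_holds_for_all_diseases(self):
        for sex in ("male", "female"):
            for d in baseline_parameters("combined", sex).diseases:
                assert d.rr_smoker >= d.rr_former >= 1.0


class TestLoading:
    def test_load_merges_over_baseline(self, tmp_path):
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text(yaml.safe_dump({
            "settings": {"sex": "female", "start_age": 50},
            "transitions": {"combined": {"p_quit_first_cycle": 0.30}},
        }))
        p = load_parameters(cfg)
        assert p.settings.sex == "female"
        assert p.settings.start_age == 50
        assert p.transitions["combined"].p_quit_first_cycle == 0.30
        # untouched fields keep baseline values
        assert p.transitions["advice"].p_quit_first_cycle == 0.11875
        assert p.threshold == 22000.0

    def test_out_of_range_probability_names_field(self, tmp_path):
        cfg = tmp_path / "bad.yaml"
        cfg.write_text(yaml.safe_dump(
            {"transitions": {"advice": {"p_quit_first_cycle": 1.3}}}))
        with pytest.raises(ValidationError, match="p_quit_first_cycle"):
            load_parameters(cfg)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_parameters(tmp_path / "nope.yaml")

    def test_round_trip_is_field_identical(self, male_params, tmp_path):
        path = tmp_path / "params.yaml"
        male_params.save(path)
        reloaded = load_parameters(path)
        assert reloaded.to_dict() == male_params.to_dict()


class TestAnnualToCycle:
    @pytest.mark.parametrize("p_annual, expected", [(0.10, 0.05), (0.0, 0.0)])
    def test_halving_convention(self, p_annual, expected):
        assert annual_to_cycle_probability(p_annual) == pytest.approx(expected)

    def test_exact_mode_closed_form(self):
        assert annual_to_cycle_probability(0.02, mode="exact") == \
            pytest.approx(1 - 0.98 ** 0.5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            annual_to_cycle_probability(1.2)
        with pytest.raises(ValidationError):
            annual_to_cycle_probability(-0.1)


def _reference_schedule() -> MortalitySchedule:
    # small synthetic Gompertz table, smoker excess hazard 2x
    ages = np.arange(16.0, 111.0)
    h = 1e-4 * np.exp(0.09 * ages)
    q_former = 1 - np.exp(-h)
    q_smoker = 1 - np.exp(-2 * h)
    return MortalitySchedule.from_annual(ages, q_smoker, q_former,
                                         source="test-gompertz")


class TestCalibration:
    W = 0.34

    def test_identity_calibration(self):
        ref = _reference_schedule()
        target_le = _mixture_life_expectancy(ref, 1.0, self.W, 45)
        cal = calibrate_mortality(ref, target_le, self.W, start_age=45)
        assert cal.calibration_factor == pytest.approx(1.0, abs=1e-6)

    def test_double_rates_recovered_by_half_factor(self):
        ref = _reference_schedule()
        doubled = ref.scaled(2.0)
        target_le = _mixture_life_expectancy(ref, 1.0, self.W, 45)
        cal = calibrate_mortality(doubled, target_le, self.W, start_age=45)
        # factor relative to the doubled schedule's own rates
        assert cal.calibration_factor / doubled.calibration_factor == \
            pytest.approx(0.5, rel=1e-3)
        recovered_le = _mixture_life_expectancy(cal, 1.0, self.W, 45)
        assert abs(recovered_le - target_le) < 0.1

    @pytest.mark.parametrize("f_star", [0.3, 0.7, 1.4, 3.0])
    def test_recovery_of_known_scaling_to_3_sig_figs(self, f_star):
        ref = _reference_schedule()
        target_le = _mixture_life_expectancy(ref, f_star, self.W, 45)
        cal = calibrate_mortality(ref, target_le, self.W, start_age=45)
        assert cal.calibration_factor == pytest.approx(f_star, rel=1e-3)

    def test_idempotence(self):
        ref = _reference_schedule()
        target_le = _mixture_life_expectancy(ref, 1.6, self.W, 45)
        cal = calibrate_mortality(ref, target_le, self.W, start_age=45)
        recal = calibrate_mortality(cal, target_le, self.W, start_age=45)
        assert recal.calibration_factor / cal.calibration_factor == \
            pytest.approx(1.0, abs=1e-6)

    def test_unreachable_target_raises(self):
        ref = _reference_schedule()
        with pytest.raises(CalibrationError):
            calibrate_mortality(ref, 2.0, self.W, start_age=45)  # LE far too low

    def test_same_factor_applied_to_both_statuses(self):
        ref = _reference_schedule()
        target_le = _mixture_life_expectancy(ref, 1.5, self.W, 45)
        cal = calibrate_mortality(ref, target_le, self.W, start_age=45)
        f = cal.calibration_factor
        np.testing.assert_allclose(cal.q_cycle_smoker,
                                   np.minimum(ref.q_cycle_smoker * f, 1.0))
        np.testing.assert_allclose(cal.q_cycle_former,
                                   np.minimum(ref.q_cycle_former * f, 1.0))


class TestLifeTable:
    def test_csv_round_trip(self, tmp_path):
        import pandas as pd
        path = tmp_path / "lt.csv"
        pd.DataFrame({"age": [16, 17, 18], "sex": "male",
                      "qx": [0.001, 0.002, 0.003]}).to_csv(path, index=False)
        lt = LifeTable.read_csv(path, "male")
        assert list(lt.ages) == [16, 17, 18]
        with pytest.raises(ValidationError):
            LifeTable.read_csv(path, "female")


class TestAgeSchedule:
    def test_piecewise_constant_lookup_with_clamping(self):
        sched = AgeSchedule(breaks=(16.0, 45.0, 65.0), values=(1.0, 2.0, 3.0))
        assert sched.at(10) == 1.0   # below first band clamps
        assert sched.at(44.9) == 1.0
        assert sched.at(45.0) == 2.0
        assert sched.at(90.0) == 3.0

    def test_invalid_breaks_rejected(self):
        with pytest.raises(ValidationError):
            AgeSchedule(breaks=(10.0, 10.0), values=(1.0, 2.0))


@settings(deadline=None, max_examples=50, derandomize=True)
@given(p=st.floats(min_value=0.0, max_value=1.0))
def test_conversion_modes_agree_at_endpoints_and_order(p):
    """Exact conversion never exceeds the halving convention on [0,1]."""
    half = annual_to_cycle_probability(p, mode="half")
    exact = annual_to_cycle_probability(p, mode="exact")
    assert 0.0 <= exact <= 1.0 and 0.0 <= half <= 0.5
    assert exact >= half - 1e-12
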