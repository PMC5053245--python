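import pytest
from hypothesis import given, settings, strategies as st

from paqc.codebook import DoseRule
from paqc.errors import ScoringWarning, UnitMismatchError
from paqc.model import Prescription, Role, Route
from paqc.treatment_eval import (
    check_correct_use,
    check_dose_per_kg,
    check_fluid_plan,
    check_weight_band,
)

QUININE_LOADING = DoseRule(kind="per_kg", target=20.0, units="mg")
AL_BANDS = DoseRule(kind="weight_band", units="tablets",
                    bands=((5, 14.9, 1), (15, 24.5, 2), (25, 34.9, 3), (35, None, 4)))


class TestPerKgDose:
    @pytest.mark.parametrize("prescribed,expected", [
        (200.0, 1),   # exactly on target (20 mg/kg x 10 kg)
        (160.0, 1),   # lower bound inclusive
        (240.0, 1),   # upper bound inclusive
        (159.9, 0),
        (241.0, 0),
    ])
    def test_tolerance_band_inclusive(self, prescribed, expected):
        assert check_dose_per_kg(prescribed, 10.0, QUININE_LOADING) == expected

    def test_zero_tolerance_accepts_exact_target_only(self):
        rule = DoseRule(kind="per_kg", target=20.0, units="mg", tolerance=0.0)
        assert check_dose_per_kg(200.0, 10.0, rule) == 1
        assert check_dose_per_kg(200.1, 10.0, rule) == 0

    def test_missing_weight_scores_zero_with_warning(self):
        with pytest.warns(ScoringWarning, match="W_MISSING_WEIGHT"):
            assert check_dose_per_kg(200.0, None, QUININE_LOADING) == 0

    def test_unit_mismatch_raises(self):
        with pytest.raises(UnitMismatchError):
            check_dose_per_kg(200.0, 10.0, QUININE_LOADING, units="ml")

    @settings(max_examples=200, derandomize=True)
    @given(
        weight=st.floats(2.0, 40.0),
        ratio=st.floats(0.5, 1.5),
        scale=st.floats(0.1, 10.0),
    )
    def test_verdict_invariant_under_consistent_scaling(self, weight, ratio, scale):
        # multiplying target and prescribed amount by the same factor, or
        # moving mass between weight and per-kg target, keeps the verdict
        prescribed = 20.0 * weight * ratio
        base = check_dose_per_kg(prescribed, weight, QUININE_LOADING)
        scaled_rule = DoseRule(kind="per_kg", target=20.0 * scale, units="mg")
        assert check_dose_per_kg(prescribed * scale, weight, scaled_rule) == base


class TestWeightBands:
    @pytest.mark.parametrize("weight,tabs,expected", [
        (10.0, 1, 1),
        (5.0, 1, 1),
        (14.9, 1, 1),
        (16.0, 1, 0),   # band demands 2
        (16.0, 2, 1),
        (35.0, 4, 1),
        (60.0, 4, 1),   # open-ended top band
        (25.0, 3, 1),
    ])
    def test_band_lookup(self, weight, tabs, expected):
        assert check_weight_band(tabs, weight, AL_BANDS) == expected

    def test_below_lowest_band_warns_out_of_band(self):
        with pytest.warns(ScoringWarning, match="W_OUT_OF_BAND"):
            assert check_weight_band(1, 4.0, AL_BANDS) == 0

    def test_missing_weight_scores_zero(self):
        with pytest.warns(ScoringWarning, match="W_MISSING_WEIGHT"):
            assert check_weight_band(1, None, AL_BANDS) == 0


SHOCK_BOLUS = DoseRule(kind="fluid_bolus", target=20.0, units="ml", max_administrations=4)
ORS_SOME = DoseRule(kind="fluid_total", target=75.0, units="ml", max_administrations=4)
REHYDRATION = DoseRule(kind="fluid_total", target=100.0, units="ml",
                       window_hours=3, window_hours_under_1y=6)


def _fluid(drug, ml, hours=None, role=Role.single):
    return Prescription(drug=drug, role=role, dose_amount=ml, dose_units="ml",
                        infusion_time_hours=hours)


class TestFluidPlans:
    def test_single_shock_bolus_on_target(self):
        rx = [_fluid("normal_saline", 200.0, 1.0)]
        assert check_fluid_plan(rx, 10.0, 24.0, SHOCK_BOLUS) == 1

    def test_each_bolus_checked_not_just_total(self):
        rx = [_fluid("normal_saline", 200.0, 1.0), _fluid("normal_saline", 320.0, 1.0)]
        assert check_fluid_plan(rx, 10.0, 24.0, SHOCK_BOLUS) == 0

    def test_ors_total_volume(self):
        assert check_fluid_plan([_fluid("ors", 600.0)], 8.0, 24.0, ORS_SOME) == 1
        assert check_fluid_plan([_fluid("ors", 300.0), _fluid("ors", 300.0)],
                                8.0, 24.0, ORS_SOME) == 1
        assert check_fluid_plan([_fluid("ors", 400.0)], 8.0, 24.0, ORS_SOME) == 0

    def test_no_prescriptions_scores_zero(self):
        assert check_fluid_plan([], 8.0, 24.0, ORS_SOME) == 0

    def test_age_dependent_window(self):
        rx = [_fluid("ringers_lactate", 300.0, 1.0, Role.step1),
              _fluid("ringers_lactate", 700.0, 4.0, Role.step2)]
        # 5 h of infusion: too slow for a 2-year-old (3 h) but fine under 1 y
        assert check_fluid_plan(rx, 10.0, 24.0, REHYDRATION) == 0
        assert check_fluid_plan(rx, 10.0, 6.0, REHYDRATION) == 1

    def test_missing_weight(self):
        with pytest.warns(ScoringWarning, match="W_MISSING_WEIGHT"):
            assert check_fluid_plan([_fluid("ors", 600.0)], None, 24.0, ORS_SOME) == 0


class TestCorrectUse:
    def _rule(self, codebook, disease, classification):
        return codebook.diseases[disease].treatments[classification]

    def test_severe_pneumonia_penicillin_only(self, codebook):
        rule = self._rule(codebook, "pneumonia", "severe")
        rx = [Prescription(drug="penicillin", route=Route.im, dose_amount=500000.0,
                           dose_units="iu", frequency_per_day=4, duration="5 days")]
        assert check_correct_use(rx, "severe", 10.0, 24.0, rule) == (1, 1)

    def test_gentamicin_coprescription_voids_set(self, codebook):
        rule = self._rule(codebook, "pneumonia", "severe")
        rx = [
            Prescription(drug="penicillin", route=Route.im, dose_amount=500000.0,
                         dose_units="iu", frequency_per_day=4, duration="5 days"),
            Prescription(drug="gentamicin", route=Route.im, dose_amount=75.0,
                         dose_units="mg", frequency_per_day=1, duration="5 days"),
        ]
        assert check_correct_use(rx, "severe", 10.0, 24.0, rule) == (0, 0)

    def test_very_severe_pneumonia_needs_oxygen_too(self, codebook):
        rule = self._rule(codebook, "pneumonia", "very_severe")
        rx = [
            Prescription(drug="penicillin", route=Route.im, dose_amount=500000.0,
                         dose_units="iu", frequency_per_day=4, duration="5 days"),
            Prescription(drug="gentamicin", route=Route.im, dose_amount=75.0,
                         dose_units="mg", frequency_per_day=1, duration="5 days"),
        ]
        assert check_correct_use(rx, "very_severe", 10.0, 24.0, rule) == (0, 0)

    def test_amoxicillin_overdose_fails_correct_use_only(self, codebook):
        # 40 mg/kg exceeds 25 mg/kg x 1.2 = 30 mg/kg
        rule = self._rule(codebook, "pneumonia", "non_severe")
        rx = [Prescription(drug="amoxicillin", route=Route.oral, dose_amount=400.0,
                           dose_units="mg", frequency_per_day=3, duration="5 days")]
        assert check_correct_use(rx, "non_severe", 10.0, 24.0, rule) == (1, 0)

    def test_correct_use_never_exceeds_drug_choice(self, codebook):
        rule = self._rule(codebook, "malaria", "severe")
        for rx in ([],
                   [Prescription(drug="quinine", role=Role.loading, route=Route.iv,
                                 dose_amount=200.0, dose_units="mg", duration="stat")]):
            drug, use = check_correct_use(rx, "severe", 10.0, 24.0, rule)
            assert use <= drug

    def test_order_invariance(self, codebook):
        rule = self._rule(codebook, "pneumonia", "very_severe")
        rx = [
            Prescription(drug="penicillin", route=Route.im, dose_amount=500000.0,
                         dose_units="iu", frequency_per_day=4, duration="5 days"),
            Prescription(drug="gentamicin", route=Route.im, dose_amount=75.0,
                         dose_units="mg", frequency_per_day=1, duration="5 days"),
            Prescription(drug="oxygen", frequency_per_day=1, duration="continuous"),
        ]
        forward = check_correct_use(rx, "very_severe", 10.0, 24.0, rule)
        assert check_correct_use(rx[::-1], "very_severe", 10.0, 24.0, rule) == forward
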