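"""Reference-range resolution and row activation."""

import datetime as dt

import pytest
from hypothesis import given, settings, strategies as st

import ahpdx
from ahpdx.errors import InvalidProfileError, MissingRangeError, UnitMismatchError
from ahpdx.risk import _age_at


def rr(factor="HDL", **kw):
    return ahpdx.ReferenceRange(factor_id=factor, **kw)


class TestReferenceRangeValidation:
    def test_needs_at_least_one_bound(self):
        with pytest.raises(InvalidProfileError):
            rr(sex="any")

    def test_low_must_be_below_high(self):
        with pytest.raises(InvalidProfileError):
            rr(low=10, high=10)

    def test_age_bounds_ordered(self):
        with pytest.raises(InvalidProfileError):
            rr(high=40, age_min=50, age_max=30)


class TestFactorValidation:
    def test_elementary_factor_must_be_lab_analyte(self):
        with pytest.raises(InvalidProfileError):
            ahpdx.RiskFactor("Age", category="elementary", source="demographic")

    def test_secondary_factor_cannot_be_lab_analyte(self):
        with pytest.raises(InvalidProfileError):
            ahpdx.RiskFactor("HDL", category="secondary", source="lab_analyte")


class TestResolveRange:
    male = rr(sex="male", high=40)
    female = rr(sex="female", high=50)
    anyone = rr(sex="any", high=45)

    def test_exact_sex_beats_any(self):
        chosen = ahpdx.resolve_range("HDL", "male", 30,
                                     [self.anyone, self.male, self.female])
        assert chosen is self.male

    def test_single_any_range_matches_everyone(self):
        for sex in ("male", "female"):
            assert ahpdx.resolve_range("HDL", sex, 30, [self.anyone]) is self.anyone

    def test_no_matching_sex_raises_named_error(self):
        with pytest.raises(MissingRangeError, match="HDL.*female"):
            ahpdx.resolve_range("HDL", "female", 30, [self.male])

    def test_narrower_age_span_wins(self):
        wide = rr(sex="any", high=40)
        narrow = rr(sex="any", age_min=20, age_max=40, high=35)
        assert ahpdx.resolve_range("HDL", "male", 30, [wide, narrow]) is narrow
        # outside the narrow span, only the wide range matches
        assert ahpdx.resolve_range("HDL", "male", 50, [wide, narrow]) is wide

    @settings(deadline=None, max_examples=40)
    @given(st.lists(st.sampled_from(["male", "female", "any"]), min_size=1,
                    max_size=6), st.sampled_from(["male", "female"]))
    def test_exact_sex_always_preferred_over_any(self, sexes, patient_sex):
        ranges = [rr(sex=s, high=40 + i) for i, s in enumerate(sexes)]
        matching = [r for r in ranges if r.sex in (patient_sex, "any")]
        if not matching:
            with pytest.raises(MissingRangeError):
                ahpdx.resolve_range("HDL", patient_sex, 30, ranges)
            return
        chosen = ahpdx.resolve_range("HDL", patient_sex, 30, ranges)
        if any(r.sex == patient_sex for r in matching):
            assert chosen.sex == patient_sex
        else:
            assert chosen.sex == "any"


class TestEvaluateActivation:
    @pytest.mark.parametrize(
        "value,kw,active",
        [
            (45, dict(high=40), True),   # over a high bound
            (70, dict(low=80), True),    # under a low bound
            (40, dict(high=40), False),  # boundary is inactive (strict)
            (80, dict(low=80), False),
            (100, dict(low=80, high=150), False),
            (151, dict(low=80, high=150), True),
        ],
    )
    def test_strictly_beyond_a_bound_activates(self, value, kw, active):
        assert ahpdx.evaluate_activation(value, rr(**kw)) is active

    @settings(deadline=None, max_examples=50)
    @given(st.floats(-1e6, 1e6), st.floats(0.1, 1e3))
    def test_monotone_in_value_for_high_bound(self, value, bump):
        r = rr(high=40)
        if ahpdx.evaluate_activation(value, r):
            assert ahpdx.evaluate_activation(value + bump, r)

    @settings(deadline=None, max_examples=50)
    @given(st.floats(-1e6, 1e6), st.floats(0.1, 1e3))
    def test_monotone_in_value_for_low_bound(self, value, bump):
        r = rr(low=80)
        if ahpdx.evaluate_activation(value, r):
            assert ahpdx.evaluate_activation(value - bump, r)


class TestActivationMap:
    def test_worked_example_activates_exactly_hdl_and_ldl(
        self, hyper_profile, male_patient, worked_panel
    ):
        amap = ahpdx.activation_map(hyper_profile, worked_panel, male_patient)
        assert set(amap.active_factors) == {"HDL", "LDL"}
        assert amap["HDL"].observed_value == 45
        assert amap["Age"].observed_value == 32  # at collection date, not today

    def test_all_in_range_panel_activates_nothing(
        self, hyper_profile, male_patient, in_range_panel
    ):
        amap = ahpdx.activation_map(hyper_profile, in_range_panel, male_patient)
        assert amap.active_factors == ()

    def test_missing_analyte_is_inactive_and_unobserved(
        self, hyper_profile, male_patient
    ):
        panel = ahpdx.LabPanel(
            "panel-3", "p001", dt.date(2012, 6, 1),
            analytes=(ahpdx.Analyte("HDL", 45, "mg/dL"),
                      ahpdx.Analyte("LDL", 70, "mg/dL")),
        )
        amap = ahpdx.activation_map(hyper_profile, panel, male_patient)
        entry = amap["Triglyceridea"]
        assert not entry.active and not entry.observed
        assert set(amap.active_factors) == {"HDL", "LDL"}

    def test_unit_mismatch_is_an_error(self, hyper_profile, male_patient):
        panel = ahpdx.LabPanel(
            "panel-4", "p001", dt.date(2012, 6, 1),
            analytes=(ahpdx.Analyte("HDL", 1.16, "mmol/L"),),
        )
        with pytest.raises(UnitMismatchError, match="HDL"):
            ahpdx.activation_map(hyper_profile, panel, male_patient)

    def test_panel_order_does_not_matter(self, hyper_profile, male_patient, worked_panel):
        shuffled = ahpdx.LabPanel(
            worked_panel.panel_id, worked_panel.patient_id, worked_panel.collected,
            analytes=tuple(reversed(worked_panel.analytes)),
        )
        a1 = ahpdx.activation_map(hyper_profile, worked_panel, male_patient)
        a2 = ahpdx.activation_map(hyper_profile, shuffled, male_patient)
        assert a1.entries == a2.entries

    def test_panel_must_belong_to_patient(self, hyper_profile, male_patient):
        foreign = ahpdx.LabPanel("x", "someone-else", dt.date(2012, 6, 1),
                                 analytes=(ahpdx.Analyte("HDL", 45, "mg/dL"),))
        with pytest.raises(InvalidProfileError):
            ahpdx.activation_map(hyper_profile, foreign, male_patient)

    def test_symptom_factor_activates_via_observation(self):
        profile = ahpdx.ConditionProfile(
            condition="demo",
            factors=(
                ahpdx.RiskFactor("GLU", units="mg/dL"),
                ahpdx.RiskFactor("polyuria", category="secondary",
                                 source="clinical_observation"),
            ),
            judgments=(("GLU", "polyuria", 3),),
            ranges=(ahpdx.ReferenceRange("GLU", high=110),),
            diagnosis_threshold=50,
        )
        patient = ahpdx.Patient("p2", "female", dt.date(1990, 1, 1), dt.date(2012, 1, 1))
        panel = ahpdx.LabPanel(
            "p", "p2", dt.date(2012, 6, 1),
            analytes=(ahpdx.Analyte("GLU", 100, "mg/dL"),),
            observations=(ahpdx.Observation("polyuria", True),),
        )
        amap = ahpdx.activation_map(profile, panel, patient)
        assert amap.active_factors == ("polyuria",)


class TestAgeComputation:
    @pytest.mark.parametrize(
        "birth,on,years",
        [
            (dt.date(1980, 3, 5), dt.date(2012, 3, 4), 31),
            (dt.date(1980, 3, 5), dt.date(2012, 3, 5), 32),
            (dt.date(1980, 12, 31), dt.date(2012, 1, 1), 31),
        ],
    )
    def test_completed_years(self, birth, on, years):
        assert _age_at(birth, on) == years


class TestProfileLoading:
    def test_bundled_profile_round_trips_key_fields(self, hyper_profile):
        assert hyper_profile.condition == "hyperglycemia"
        assert hyper_profile.factor_ids == ("HDL", "LDL", "Triglyceridea", "Age")
        assert hyper_profile.diagnosis_threshold == 80
        assert hyper_profile.critical_threshold == 95

    def test_thresholds_must_be_ordered(self):
        with pytest.raises(InvalidProfileError):
            ahpdx.ConditionProfile(
                condition="bad",
                factors=(ahpdx.RiskFactor("A"), ahpdx.RiskFactor("B")),
                judgments=(("A", "B", 1),),
                ranges=(ahpdx.ReferenceRange("A", high=1),
                        ahpdx.ReferenceRange("B", high=1)),
                diagnosis_threshold=90,
                critical_threshold=80,
            )

    def test_every_measured_factor_needs_a_range(self):
        with pytest.raises(InvalidProfileError, match="B"):
            ahpdx.ConditionProfile(
                condition="bad",
                factors=(ahpdx.RiskFactor("A"), ahpdx.RiskFactor("B")),
                judgments=(("A", "B", 1),),
                ranges=(ahpdx.ReferenceRange("A", high=1),),
            )
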