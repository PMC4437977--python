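import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from screensim import (
    GlucometerSpec,
    combine_parallel,
    combine_serial,
    confirmatory_test,
    glucometer_screen,
    score_instrument,
)
from screensim.instruments import (
    CoinFlipStrategy,
    GlucometerStrategy,
    InstrumentStrategy,
    RangeItem,
    instrument_from_dict,
)

from conftest import make_profile


class TestScoring:
    @pytest.mark.parametrize(
        "name,expected_max", [("chaturvedi", 29), ("mohan", 100), ("ramachandran", 42)]
    )
    def test_max_score_by_exhaustive_enumeration(self, instruments, name, expected_max):
        spec = instruments[name]
        assert max(spec.enumerate_scores()) == expected_max
        assert spec.max_score == expected_max

    @pytest.mark.parametrize(
        "name,cut", [("chaturvedi", 16), ("mohan", 60), ("ramachandran", 21)]
    )
    def test_published_cut_points(self, instruments, name, cut):
        assert instruments[name].cut_point == cut

    def test_all_base_categories_score_zero_and_negative(self, instruments):
        p = make_profile()  # age 30, BP 110/70, no history, male waist 70
        score, positive = score_instrument(instruments["chaturvedi"], p, sex="male")
        assert score == 0 and not positive

    def test_worked_example_scores_22_and_positive(self, instruments):
        p = make_profile(
            age=45.0, systolic_bp=125.0, waist=85.0,
            family_history="one_parent_or_sibling",
        )
        score, positive = score_instrument(instruments["chaturvedi"], p, sex="male")
        assert score == 4 + 5 + 4 + 9 == 22
        assert positive  # 22 >= 16

    def test_cut_point_itself_is_positive(self, instruments):
        # blood pressure 'or' rule: diastolic alone can carry the category
        p = make_profile(age=50.0, diastolic_bp=95.0, waist=70.0)
        score, positive = score_instrument(instruments["chaturvedi"], p, sex="male")
        assert score == 6 + 7 + 0 + 0 == 13 and not positive
        p2 = make_profile(age=50.0, diastolic_bp=95.0, waist=82.0)
        score2, positive2 = score_instrument(instruments["chaturvedi"], p2, sex="male")
        assert score2 == 22 and positive2

    def test_sex_specific_waist_categories(self, instruments):
        p = make_profile(waist=82.0)
        s_male, _ = score_instrument(instruments["chaturvedi"], p, sex="male")
        s_female, _ = score_instrument(instruments["chaturvedi"], p, sex="female")
        assert s_male == 9 and s_female == 9
        p_hi = make_profile(waist=88.0)
        assert score_instrument(instruments["chaturvedi"], p_hi, sex="female")[0] == 12
        assert score_instrument(instruments["chaturvedi"], p_hi, sex="male")[0] == 9

    def test_scores_are_integers_within_range(self, instruments, eligible):
        df = eligible.frame
        for spec in instruments.values():
            score = spec.score(df)
            assert score.dtype.kind == "i"
            assert score.min() >= 0 and score.max() <= spec.max_score

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        age=st.floats(25, 64.9), sbp=st.floats(90, 200), dbp=st.floats(50, 120),
        waist=st.floats(50, 130), bump=st.floats(0.1, 40),
    )
    def test_raising_a_factor_never_lowers_the_score(
        self, instruments, age, sbp, dbp, waist, bump
    ):
        base = make_profile(age=age, systolic_bp=sbp, diastolic_bp=dbp, waist=waist)
        for spec in instruments.values():
            s0, _ = score_instrument(spec, base, sex="male")
            for field in ("age", "systolic_bp", "waist"):
                kwargs = dict(age=age, systolic_bp=sbp, diastolic_bp=dbp, waist=waist)
                kwargs[field] = kwargs[field] + bump
                higher = make_profile(**kwargs)
                s1, _ = score_instrument(spec, higher, sex="male")
                assert s1 >= s0

    def test_predicate_gap_raises_naming_factor(self):
        item = RangeItem(name="age", factor="age", bins=[{"points": 0, "max": 40}])
        df = pd.DataFrame({"age": [50.0]})
        with pytest.raises(ValueError, match="age"):
            item.points_array(df)

    def test_declared_total_mismatch_rejected(self):
        with pytest.raises(ValueError, match="total"):
            instrument_from_dict(
                {
                    "name": "bogus", "cut_point": 1, "total_score": 99,
                    "items": [
                        {"kind": "range", "factor": "age",
                         "bins": [{"points": 0, "max": 40}, {"points": 4, "min": 40}]}
                    ],
                }
            )


class TestGlucometer:
    def test_no_error_high_glucose_positive(self):
        spec = GlucometerSpec(meter_error_sd=0.0)
        rng = np.random.default_rng(0)
        _, positive = glucometer_screen(spec, make_profile(random_glucose_true=10.0), rng)
        assert positive

    def test_threshold_is_inclusive(self):
        spec = GlucometerSpec(meter_error_sd=0.0)
        rng = np.random.default_rng(0)
        _, positive = glucometer_screen(spec, make_profile(random_glucose_true=6.1), rng)
        assert positive
        _, below = glucometer_screen(spec, make_profile(random_glucose_true=6.09), rng)
        assert not below

    def test_symmetric_noise_at_threshold_splits_evenly(self):
        spec = GlucometerSpec(meter_error_sd=0.9)
        rng = np.random.default_rng(1)
        p = make_profile(random_glucose_true=6.1)
        hits = sum(glucometer_screen(spec, p, rng)[1] for _ in range(10_000))
        assert hits / 10_000 == pytest.approx(0.5, abs=0.02)

    def test_rescreening_draws_fresh_error(self):
        df = pd.DataFrame([{"random_glucose_true": 6.1, "weight": 1.0}])
        strat = GlucometerStrategy(GlucometerSpec())
        rng = np.random.default_rng(2)
        values = {float(strat.apply(df, rng).value[0]) for _ in range(5)}
        assert len(values) == 5


class TestConfirmatory:
    @pytest.mark.parametrize(
        "fasting,expected", [(7.0, True), (5.0, False), (6.99, False), (7.01, True)]
    )
    def test_fasting_criterion_boundary(self, fasting, expected):
        assert confirmatory_test(make_profile(fasting_glucose_true=fasting)) is expected


class TestCombinators:
    @pytest.fixture()
    def screened_frame(self, eligible):
        return eligible.frame

    def test_serial_with_itself_is_identity_for_deterministic_screen(
        self, instruments, screened_frame
    ):
        strat = InstrumentStrategy(instruments["chaturvedi"])
        serial = combine_serial(strat, strat)
        rng = np.random.default_rng(0)
        single = strat.apply(screened_frame, rng).positive
        composite = serial.apply(screened_frame, np.random.default_rng(0)).positive
        np.testing.assert_array_equal(single, composite)

    def test_serial_order_does_not_change_classification(
        self, instruments, screened_frame
    ):
        a = InstrumentStrategy(instruments["chaturvedi"])
        b = InstrumentStrategy(instruments["mohan"])
        ab = combine_serial(a, b).apply(screened_frame, np.random.default_rng(0))
        ba = combine_serial(b, a).apply(screened_frame, np.random.default_rng(0))
        np.testing.assert_array_equal(ab.positive, ba.positive)

    def test_serial_positives_subset_of_each_component(self, instruments, screened_frame):
        a = InstrumentStrategy(instruments["chaturvedi"])
        b = InstrumentStrategy(instruments["ramachandran"])
        rng = np.random.default_rng(0)
        pa = a.apply(screened_frame, rng).positive
        pb = b.apply(screened_frame, rng).positive
        pc = combine_serial(a, b).apply(screened_frame, np.random.default_rng(1)).positive
        assert not (pc & ~pa).any()
        assert not (pc & ~pb).any()

    def test_parallel_with_always_negative_is_identity(self, instruments, screened_frame):
        a = InstrumentStrategy(instruments["mohan"])
        never = CoinFlipStrategy(0.0)
        rng = np.random.default_rng(0)
        single = a.apply(screened_frame, rng).positive
        composite = combine_parallel(a, never).apply(
            screened_frame, np.random.default_rng(0)
        ).positive
        np.testing.assert_array_equal(single, composite)

    def test_independent_serial_sensitivity_is_product(self, eligible):
        # coin flips refer independently of status, so 'sensitivity' = p1*p2
        from screensim import evaluate_strategy, metrics_from_counts

        serial = combine_serial(CoinFlipStrategy(0.7), CoinFlipStrategy(0.6))
        counts, metrics, _ = evaluate_strategy(eligible, serial, seed=3)
        assert metrics.sensitivity == pytest.approx(0.42, abs=0.02)

    def test_independent_parallel_specificity_is_product(self, eligible):
        from screensim import evaluate_strategy

        parallel = combine_parallel(CoinFlipStrategy(0.2), CoinFlipStrategy(0.2))
        counts, metrics, _ = evaluate_strategy(eligible, parallel, seed=4)
        assert metrics.specificity == pytest.approx(0.64, abs=0.02)

    def test_serial_second_stage_tested_only_among_first_positives(
        self, instruments, screened_frame
    ):
        a = InstrumentStrategy(instruments["chaturvedi"])
        g = GlucometerStrategy(GlucometerSpec())
        out = combine_serial(a, g).apply(screened_frame, np.random.default_rng(5))
        stages = dict(out.stages)
        first_pos = a.apply(screened_frame, np.random.default_rng(0)).positive
        np.testing.assert_array_equal(stages["glucometer"], first_pos)
        assert stages["questionnaire"].all()
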