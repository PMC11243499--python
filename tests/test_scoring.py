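"""Unit and property tests for questionnaire scoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from wbqn.config import ScaleMapping, ScoringConfig
from wbqn.foods import FoodLookupError, FoodTable
from wbqn.records import (
    ActivityProfile,
    BreastfeedingGroup,
    ExcretionReport,
    FoodDiaryEntry,
    FoodItem,
    LactationReport,
    LiquidIntake,
    ParticipantRecord,
    urination_frequency_to_points,
)
from wbqn.scoring import (
    IntakeBreakdown,
    LossBreakdown,
    ScaleRangeError,
    assign_quartile,
    fecal_loss,
    food_water_intake,
    guideline_balance,
    liquid_water_intake,
    map_scale,
    milk_loss,
    score_frame,
    score_record,
    sweat_loss,
    total_water_intake,
    total_water_loss,
    urine_loss,
    water_balance,
)
from wbqn.simulate import default_cohort_config, generate_cohort


def line_oracle(points, mapping):
    """Independent two-point line formula for cross-checking map_scale."""
    t = (points - mapping.point_min) / (mapping.point_max - mapping.point_min)
    return (1 - t) * mapping.value_min + t * mapping.value_max


@pytest.fixture()
def scales(config):
    return config.scales


class TestMapScale:
    @pytest.mark.parametrize(
        "scale,points,expected",
        [
            ("urine", 1, 600.0),
            ("urine", 5, 3000.0),
            ("urine", 3, 1800.0),            # 600 + 2*(3000-600)/4
            ("urine", 2, 1200.0),
            ("fecal", 1, 200.0),
            ("fecal", 5, 50.0),
            ("fecal", 3, 125.0),             # decreasing mapping
            ("sweat_intensive", 1, 1000.0),
            ("sweat_intensive", 10, 2000.0),
            ("sweat_moderate", 1, 400.0),
            ("sweat_moderate", 10, 700.0),
            ("sweat_sedentary", 1, 0.01),
            ("sweat_sedentary", 10, 0.02),
        ],
    )
    def test_published_and_interpolated_values(self, scales, scale, points,
                                               expected):
        assert map_scale(points, scales[scale]) == expected

    def test_out_of_range_names_the_scale(self, scales):
        with pytest.raises(ScaleRangeError, match="urine"):
            map_scale(6, scales["urine"])
        with pytest.raises(ScaleRangeError):
            map_scale(0, scales["sweat_intensive"])

    def test_monotone_directions(self, scales):
        urine = [map_scale(p, scales["urine"]) for p in range(1, 6)]
        fecal = [map_scale(p, scales["fecal"]) for p in range(1, 6)]
        assert urine == sorted(urine) and len(set(urine)) == 5
        assert fecal == sorted(fecal, reverse=True) and len(set(fecal)) == 5
        for key in ("sweat_intensive", "sweat_moderate", "sweat_sedentary"):
            vals = [map_scale(p, scales[key]) for p in range(1, 11)]
            assert all(a < b for a, b in zip(vals, vals[1:]))

    @settings(derandomize=True, max_examples=200)
    @given(points=hst.floats(min_value=1, max_value=5),
           lo=hst.floats(min_value=0, max_value=1e4),
           hi=hst.floats(min_value=0, max_value=1e4))
    def test_matches_line_oracle(self, points, lo, hi):
        mapping = ScaleMapping(name="t", point_min=1, point_max=5,
                               value_min=lo, value_max=hi,
                               unit="mL/day")
        assert map_scale(points, mapping) == pytest.approx(
            line_oracle(points, mapping), abs=1e-9)


class TestFoodWater:
    def test_breast_milk_fraction_example(self):
        foods = FoodTable([FoodItem(food_id="m", name="milk",
                                    water_fraction=0.87)])
        assert food_water_intake(
            [FoodDiaryEntry(food_id="m", amount=100)], foods
        ) == pytest.approx(87.0)

    def test_empty_diary_is_zero(self, foods):
        assert food_water_intake([], foods) == 0.0

    def test_sums_over_entries(self):
        foods = FoodTable([
            FoodItem(food_id="a", water_fraction=0.5),
            FoodItem(food_id="b", water_fraction=0.1),
        ])
        diary = [FoodDiaryEntry(food_id="a", amount=200),
                 FoodDiaryEntry(food_id="b", amount=100)]
        assert food_water_intake(diary, foods) == pytest.approx(110.0)

    def test_unknown_food_id_named_in_error(self, foods):
        with pytest.raises(FoodLookupError, match="NOPE"):
            food_water_intake([FoodDiaryEntry(food_id="NOPE", amount=1)],
                              foods)


class TestLiquids:
    def test_all_zero(self):
        water, other, bev = liquid_water_intake(LiquidIntake())
        assert (water, other) == (0.0, 0.0)
        assert all(v == 0 for v in bev.values())

    def test_water_kept_separate_from_other_liquids(self):
        water, other, bev = liquid_water_intake(
            LiquidIntake(drinking_water=1000, coffee=300, milk=200))
        assert (water, other) == (1000.0, 500.0)
        assert bev["coffee"] == 300 and bev["milk"] == 200

    def test_single_category_pass_through(self):
        water, other, bev = liquid_water_intake(LiquidIntake(other=684))
        assert (water, other) == (0.0, 684.0)
        assert bev["other"] == 684.0

    def test_negative_volume_rejected(self):
        with pytest.raises(ValueError):
            LiquidIntake(coffee=-1)


def _record(**overrides) -> ParticipantRecord:
    base = dict(
        participant_id="p1", age=30, weight=65, height=1.65,
        lactation=LactationReport(group=BreastfeedingGroup.exclusive,
                                  feeds_per_day=8, minutes_per_feed=15),
        excretion=ExcretionReport(urine_points=1, fecal_points=1),
    )
    base.update(overrides)
    return ParticipantRecord(**base)


class TestLoss:
    def test_one_hour_intensive_minimal_rating(self, config):
        act = ActivityProfile(hours_intensive=1, sweat_points_intensive=1)
        assert sweat_loss(act, config) == pytest.approx(1000.0)

    def test_no_activity_no_sweat(self, config):
        assert sweat_loss(ActivityProfile(), config) == 0.0

    def test_mixed_categories(self, config):
        act = ActivityProfile(hours_moderate=2, sweat_points_moderate=10,
                              hours_sedentary=16, sweat_points_sedentary=10)
        assert sweat_loss(act, config) == pytest.approx(1400.32)

    @pytest.mark.parametrize("points,expected", [(1, 600), (2, 1200), (5, 3000)])
    def test_urine_scale(self, config, points, expected):
        rep = ExcretionReport(urine_points=points, fecal_points=1)
        assert urine_loss(rep, config) == expected

    @pytest.mark.parametrize("points,expected", [(1, 200), (5, 50)])
    def test_fecal_scale(self, config, points, expected):
        rep = ExcretionReport(urine_points=1, fecal_points=points)
        assert fecal_loss(rep, config) == expected

    def test_milk_loss_zero_for_non_breastfeeding(self):
        lact = LactationReport(group=BreastfeedingGroup.none)
        assert milk_loss(lact, 6.25, 0.87) == 0.0

    def test_milk_loss_product(self):
        lact = LactationReport(group=BreastfeedingGroup.exclusive,
                               feeds_per_day=8, minutes_per_feed=15)
        assert milk_loss(lact, 0.718, 0.87) == pytest.approx(74.9592)
        doubled = lact.model_copy(update={"feeds_per_day": 16})
        assert milk_loss(doubled, 0.718, 0.87) == pytest.approx(2 * 74.9592)

    def test_total_loss_excludes_milk_by_default(self, config):
        loss = total_water_loss(_record(), config)
        assert loss.total == pytest.approx(800.0)  # 600 + 200 + 0
        assert not loss.includes_milk

    def test_total_loss_with_milk_term(self):
        cfg = ScoringConfig()
        cfg.milk_loss.enabled = True
        loss = total_water_loss(_record(), cfg)
        expected_milk = 8 * 15 * 6.25 * 0.87
        assert loss.milk == pytest.approx(expected_milk)
        assert loss.total == pytest.approx(800.0 + expected_milk)


class TestBalance:
    def test_observed_deficit(self):
        intake = IntakeBreakdown(2000, 0, 0)
        loss = LossBreakdown(urine=2475.36, feces=0, sweat=0)
        balance, flag = water_balance(intake, loss)
        assert balance == pytest.approx(-475.36)
        assert flag == 0

    def test_zero_balance_coded_positive(self):
        balance, flag = water_balance(IntakeBreakdown(800, 0, 0),
                                      LossBreakdown(600, 200, 0))
        assert balance == 0.0 and flag == 1

    def test_empty_intake(self):
        balance, flag = water_balance(IntakeBreakdown(0, 0, 0),
                                      LossBreakdown(600, 200, 0))
        assert balance == -800.0 and flag == 0

    @pytest.mark.parametrize(
        "intake,group,expected",
        [(2700, "exclusive", (0.0, True)),
         (2000, "mixed", (0.0, True)),
         (2500, "exclusive", (-200.0, False))],
    )
    def test_guideline_balance(self, intake, group, expected):
        diff, ok = guideline_balance(intake, group)
        assert (diff, ok) == pytest.approx(expected)

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            guideline_balance(2000, "sometimes")


class TestQuartiles:
    CUTOFFS = (-994.47, 33.31, 921.24)

    @pytest.mark.parametrize(
        "balance,expected",
        [(-1000, "Q1"), (1000, "Q4"), (33.31, "Q3"), (-994.47, "Q2"),
         (921.24, "Q4"), (0.0, "Q2")],
    )
    def test_assignment(self, balance, expected):
        assert assign_quartile(balance, self.CUTOFFS) == expected

    def test_non_ascending_cutoffs_rejected(self):
        with pytest.raises(ValueError):
            assign_quartile(0.0, (1.0, 1.0, 2.0))


class TestRecordScoring:
    def test_total_intake_additivity(self, foods, config):
        rec = _record(liquids=LiquidIntake(drinking_water=1000, coffee=500),
                      diary=[FoodDiaryEntry(food_id="F01", amount=100)])
        intake = total_water_intake(rec, foods)
        assert intake.total == pytest.approx(
            intake.from_drinking_water + intake.from_liquids_excl_water
            + intake.from_foods)
        assert intake.from_liquids_excl_water == pytest.approx(
            sum(intake.beverages.values()))

    def test_all_zero_record(self, foods, config):
        scored = score_record(_record(), foods, config)
        assert scored.intake.total == 0.0
        assert scored.balance.balance_observed == pytest.approx(-800.0)
        assert scored.balance.negative_flag == 0

    @settings(derandomize=True, max_examples=100)
    @given(water=hst.floats(0, 5000), coffee=hst.floats(0, 2000),
           extra=hst.floats(0, 3000))
    def test_intake_dominance(self, foods, water, coffee, extra):
        """Increasing any intake component weakly increases balance."""
        cfg = ScoringConfig()
        lo = _record(liquids=LiquidIntake(drinking_water=water, coffee=coffee))
        hi = _record(liquids=LiquidIntake(drinking_water=water + extra,
                                          coffee=coffee))
        b_lo = score_record(lo, foods, cfg).balance.balance_observed
        b_hi = score_record(hi, foods, cfg).balance.balance_observed
        assert b_hi >= b_lo

    @settings(derandomize=True, max_examples=100)
    @given(urine=hst.integers(1, 4), hours=hst.floats(0, 4))
    def test_loss_dominance(self, foods, urine, hours):
        """Increasing any loss component weakly decreases balance."""
        cfg = ScoringConfig()
        lo = _record(excretion=ExcretionReport(urine_points=urine,
                                               fecal_points=1))
        hi = _record(excretion=ExcretionReport(urine_points=urine + 1,
                                               fecal_points=1),
                     activity=ActivityProfile(hours_intensive=hours,
                                              sweat_points_intensive=5))
        b_lo = score_record(lo, foods, cfg).balance.balance_observed
        b_hi = score_record(hi, foods, cfg).balance.balance_observed
        assert b_hi <= b_lo

    def test_frame_and_record_paths_agree(self, default_cohort, config):
        """The vectorised frame scorer matches per-record scoring exactly."""
        sub = default_cohort.frame.iloc[::7].reset_index(drop=True)
        frame_scored = score_frame(sub, default_cohort.foods, config,
                                   add_quartiles=False)
        records = type(default_cohort)(sub, default_cohort.config,
                                       default_cohort.foods).to_records()
        for i, rec in enumerate(records):
            s = score_record(rec, default_cohort.foods, config)
            assert frame_scored.loc[i, "intake_total"] == pytest.approx(
                s.intake.total, abs=1e-9)
            assert frame_scored.loc[i, "loss_total"] == pytest.approx(
                s.loss.total, abs=1e-9)
            assert frame_scored.loc[i, "balance_observed"] == pytest.approx(
                s.balance.balance_observed, abs=1e-9)
            assert frame_scored.loc[i, "negative_flag"] == \
                s.balance.negative_flag


class TestRecordValidation:
    def test_activity_hours_bounded_by_day(self):
        with pytest.raises(ValueError):
            ActivityProfile(hours_intensive=10, hours_moderate=10,
                            hours_sedentary=10)

    def test_excretion_points_bounded(self):
        with pytest.raises(ValueError):
            ExcretionReport(urine_points=7, fecal_points=1)

    def test_non_breastfeeding_cannot_report_feeds(self):
        with pytest.raises(ValueError):
            LactationReport(group=BreastfeedingGroup.none, feeds_per_day=3)

    def test_bmi_classes(self):
        rec = _record(weight=45, height=1.70)
        assert rec.bmi_class == "underweight"
        assert _record(weight=65, height=1.65).bmi_class == "normal"
        assert _record(weight=90, height=1.65).bmi_class == "obese"

    @pytest.mark.parametrize("freq,points",
                             [(1, 1), (2, 2), (3, 2), (4, 3), (6, 3),
                              (7, 4), (9, 4), (10, 5), (14, 5)])
    def test_urination_frequency_lookup(self, freq, points):
        assert urination_frequency_to_points(freq) == points
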