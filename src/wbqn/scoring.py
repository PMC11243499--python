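"""Scoring: raw questionnaire responses -> water intake, loss and balance.

Every quantity is a daily volume in mL/day. The instrument's rules are:

* dietary water   = sum over diary items of grams/day x water fraction
  (1 g water = 1 mL);
* liquid water    = plain drinking water, reported separately, plus the sum
  of all other beverage categories;
* total intake    = drinking water + other liquids + food water;
* sweat loss      = sum over activity categories of hours/day x a rate
  (mL/h) obtained by linear interpolation on a 1-10 self-rating
  (intensive 1000-2000, moderate 400-700, sedentary 0.01-0.02 mL/h);
* urine loss      = 5-point scale mapped linearly onto 600-3000 mL/day;
* fecal loss      = 5-point scale mapped linearly onto 200-50 mL/day
  (decreasing: higher points = less frequent bowel movements);
* total loss      = urine + feces + sweat, with an optional opt-in
  lactation term (feeds/day x min/feed x milk flow x water fraction);
* observed balance = total intake - total loss, with a binary flag coded 0
  for negative balance and 1 otherwise;
* guideline balance = total intake - the EFSA adequate intake for the
  woman's group (2700 mL/day exclusive breastfeeding, 2000 otherwise),
  with intake equal to the recommendation counting as adequate.

The sedentary sweat rate is used exactly as published (0.01-0.02 mL/h)
although it is physiologically implausible - likely a unit slip in the
source instrument; it is overridable through :class:`~wbqn.config.ScaleMapping`
in the scoring configuration.

Two equivalent paths are provided: a per-record path built from the
individual operations (the reference semantics), and a vectorised
frame path (:func:`score_frame`) used for large simulated cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .config import ScaleMapping, ScoringConfig
from .foods import FoodTable
from .records import (
    ActivityProfile,
    BreastfeedingGroup,
    ExcretionReport,
    FoodDiaryEntry,
    LactationReport,
    LiquidIntake,
    ParticipantRecord,
)

__all__ = [
    "ScaleRangeError",
    "IntakeBreakdown",
    "LossBreakdown",
    "BalanceResult",
    "ScoredRecord",
    "map_scale",
    "food_water_intake",
    "liquid_water_intake",
    "total_water_intake",
    "sweat_loss",
    "urine_loss",
    "fecal_loss",
    "milk_loss",
    "total_water_loss",
    "water_balance",
    "guideline_balance",
    "assign_quartile",
    "score_record",
    "score_records",
    "score_frame",
]


class ScaleRangeError(ValueError):
    """Points fall outside the scale's defined range."""


# ---------------------------------------------------------------------------
# elementary mappings


def map_scale(points: float, mapping: ScaleMapping) -> float:
    """Convert scale points to a volume rate by two-point linear interpolation.

    Both endpoints are returned exactly (no floating drift); intermediate
    points interpolate linearly, so the mapping is monotone - increasing
    when ``value_max > value_min``, decreasing otherwise.
    """
    if not (mapping.point_min <= points <= mapping.point_max):
        raise ScaleRangeError(
            f"{points} points outside [{mapping.point_min}, {mapping.point_max}] "
            f"for scale {mapping.name!r}"
        )
    if points == mapping.point_min:
        return mapping.value_min
    if points == mapping.point_max:
        return mapping.value_max
    slope = (mapping.value_max - mapping.value_min) / (
        mapping.point_max - mapping.point_min
    )
    return mapping.value_min + (points - mapping.point_min) * slope


def _map_scale_array(points: np.ndarray, mapping: ScaleMapping) -> np.ndarray:
    """Vectorised :func:`map_scale`; endpoints exact."""
    points = np.asarray(points, dtype=float)
    if points.size and (
        points.min() < mapping.point_min or points.max() > mapping.point_max
    ):
        raise ScaleRangeError(
            f"points outside [{mapping.point_min}, {mapping.point_max}] "
            f"for scale {mapping.name!r}"
        )
    slope = (mapping.value_max - mapping.value_min) / (
        mapping.point_max - mapping.point_min
    )
    out = mapping.value_min + (points - mapping.point_min) * slope
    out = np.where(points == mapping.point_min, mapping.value_min, out)
    out = np.where(points == mapping.point_max, mapping.value_max, out)
    return out


# ---------------------------------------------------------------------------
# intake


@dataclass(frozen=True)
class IntakeBreakdown:
    """Per-source daily water intake, mL/day."""

    from_drinking_water: float
    from_liquids_excl_water: float
    from_foods: float
    beverages: dict[str, float] = field(default_factory=dict)

    @property
    def total(self) -> float:
        return self.from_drinking_water + self.from_liquids_excl_water + self.from_foods


def food_water_intake(
    diary: Iterable[FoodDiaryEntry], foods: FoodTable
) -> float:
    """Dietary water in mL/day: sum of grams/day x water fraction (1 g = 1 mL)."""
    return float(
        sum(entry.amount * foods.water_fraction(entry.food_id) for entry in diary)
    )


def liquid_water_intake(
    liquids: LiquidIntake,
) -> tuple[float, float, dict[str, float]]:
    """Split liquid intake into plain drinking water and everything else.

    Returns ``(from_drinking_water, from_liquids_excl_water, beverages)``
    where ``beverages`` maps each non-water category to its mL/day and
    ``from_liquids_excl_water`` is their exact sum.
    """
    beverages = {
        name: float(getattr(liquids, name))
        for name in LiquidIntake.beverage_fields()
    }
    return float(liquids.drinking_water), float(sum(beverages.values())), beverages


def total_water_intake(
    record: ParticipantRecord, foods: FoodTable
) -> IntakeBreakdown:
    """Total daily water intake: drinking water + other liquids + food water."""
    water, other, beverages = liquid_water_intake(record.liquids)
    return IntakeBreakdown(
        from_drinking_water=water,
        from_liquids_excl_water=other,
        from_foods=food_water_intake(record.diary, foods),
        beverages=beverages,
    )


# ---------------------------------------------------------------------------
# loss


@dataclass(frozen=True)
class LossBreakdown:
    """Per-route daily water loss, mL/day."""

    urine: float
    feces: float
    sweat: float
    milk: float = 0.0
    includes_milk: bool = False

    @property
    def total(self) -> float:
        base = self.urine + self.feces + self.sweat
        return base + self.milk if self.includes_milk else base


def sweat_loss(activity: ActivityProfile, config: ScoringConfig) -> float:
    """Sweat loss in mL/day: hours x interpolated rate per activity category."""
    return (
        activity.hours_intensive
        * map_scale(activity.sweat_points_intensive, config.scales["sweat_intensive"])
        + activity.hours_moderate
        * map_scale(activity.sweat_points_moderate, config.scales["sweat_moderate"])
        + activity.hours_sedentary
        * map_scale(activity.sweat_points_sedentary, config.scales["sweat_sedentary"])
    )


def urine_loss(excretion: ExcretionReport, config: ScoringConfig) -> float:
    """Urinary loss in mL/day from the increasing 5-point scale."""
    return map_scale(excretion.urine_points, config.scales["urine"])


def fecal_loss(excretion: ExcretionReport, config: ScoringConfig) -> float:
    """Fecal loss in mL/day from the decreasing 5-point scale."""
    return map_scale(excretion.fecal_points, config.scales["fecal"])


def milk_loss(
    lactation: LactationReport,
    flow_rate_ml_per_min: float,
    water_fraction: float,
) -> float:
    """Water exported as breast milk, mL/day (opt-in loss term).

    feeds/day x minutes/feed x milk flow (mL/min) x milk water fraction;
    identically zero for non-breastfeeding women.
    """
    if flow_rate_ml_per_min < 0:
        raise ValueError("flow rate must be >= 0")
    if not 0.0 <= water_fraction <= 1.0:
        raise ValueError("water fraction must be in [0, 1]")
    if lactation.group is BreastfeedingGroup.none:
        return 0.0
    return (
        lactation.feeds_per_day
        * lactation.minutes_per_feed
        * flow_rate_ml_per_min
        * water_fraction
    )


def total_water_loss(
    record: ParticipantRecord, config: ScoringConfig
) -> LossBreakdown:
    """Total daily water loss: urine + feces + sweat (+ optional milk term)."""
    milk = (
        milk_loss(
            record.lactation,
            config.milk_loss.flow_rate_ml_per_min,
            config.milk_loss.water_fraction,
        )
        if config.milk_loss.enabled
        else 0.0
    )
    return LossBreakdown(
        urine=urine_loss(record.excretion, config),
        feces=fecal_loss(record.excretion, config),
        sweat=sweat_loss(record.activity, config),
        milk=milk,
        includes_milk=config.milk_loss.enabled,
    )


# ---------------------------------------------------------------------------
# balance


@dataclass(frozen=True)
class BalanceResult:
    """Observed and guideline-referenced water balance for one participant.

    ``negative_flag`` follows the instrument's coding: 0 marks a negative
    observed balance (intake < loss), 1 otherwise.
    """

    balance_observed: float
    negative_flag: int
    balance_vs_guideline: float
    adequacy_flag: bool
    quartile: Optional[str] = None


def water_balance(intake: IntakeBreakdown, loss: LossBreakdown) -> tuple[float, int]:
    """Observed balance (intake total - loss total) and its binary coding."""
    balance = intake.total - loss.total
    return balance, 0 if balance < 0 else 1


def guideline_balance(
    intake_total: float,
    group: Union[str, BreastfeedingGroup],
    config: Optional[ScoringConfig] = None,
) -> tuple[float, bool]:
    """Balance against the EFSA adequate-intake recommendation for the group.

    Returns ``(intake - recommendation, adequate)``; meeting the
    recommendation exactly counts as adequate.
    """
    if config is None:
        config = ScoringConfig()
    rec = config.recommendation_for(group)
    diff = intake_total - rec
    return diff, diff >= 0.0


def assign_quartile(
    balance: float, cutoffs: Sequence[float]
) -> str:
    """Assign a water-balance quartile given three ascending cut-points.

    Half-open intervals, boundaries assigned upward: Q1 if balance < c1,
    Q2 if c1 <= balance < c2, Q3 if c2 <= balance < c3, Q4 otherwise.
    """
    c1, c2, c3 = cutoffs
    if not (c1 < c2 < c3):
        raise ValueError("quartile cutoffs must be strictly ascending")
    if balance < c1:
        return "Q1"
    if balance < c2:
        return "Q2"
    if balance < c3:
        return "Q3"
    return "Q4"


# ---------------------------------------------------------------------------
# record-level composition


@dataclass(frozen=True)
class ScoredRecord:
    record: ParticipantRecord
    intake: IntakeBreakdown
    loss: LossBreakdown
    balance: BalanceResult


def score_record(
    record: ParticipantRecord,
    foods: FoodTable,
    config: Optional[ScoringConfig] = None,
) -> ScoredRecord:
    """Score one participant record end to end (reference path)."""
    if config is None:
        config = ScoringConfig()
    intake = total_water_intake(record, foods)
    loss = total_water_loss(record, config)
    observed, flag = water_balance(intake, loss)
    vs_guideline, adequate = guideline_balance(
        intake.total, record.lactation.group, config
    )
    return ScoredRecord(
        record=record,
        intake=intake,
        loss=loss,
        balance=BalanceResult(
            balance_observed=observed,
            negative_flag=flag,
            balance_vs_guideline=vs_guideline,
            adequacy_flag=adequate,
        ),
    )


def _scored_row(s: ScoredRecord) -> dict:
    r = s.record
    row: dict = {
        "participant_id": r.participant_id,
        "group": r.lactation.group.value,
        "age": r.age,
        "weight": r.weight,
        "height": r.height,
        "bmi": r.bmi,
        "bmi_class": r.bmi_class,
        "education_years": r.education_years,
        "feeds_per_day": r.lactation.feeds_per_day,
        "minutes_per_feed": r.lactation.minutes_per_feed,
        "intake_drinking_water": s.intake.from_drinking_water,
        "intake_liquids_excl_water": s.intake.from_liquids_excl_water,
        "intake_foods": s.intake.from_foods,
        "intake_total": s.intake.total,
        "loss_urine": s.loss.urine,
        "loss_feces": s.loss.feces,
        "loss_sweat": s.loss.sweat,
        "loss_milk": s.loss.milk,
        "loss_total": s.loss.total,
        "balance_observed": s.balance.balance_observed,
        "negative_flag": s.balance.negative_flag,
        "balance_vs_guideline": s.balance.balance_vs_guideline,
        "adequacy_flag": s.balance.adequacy_flag,
    }
    for name, value in s.intake.beverages.items():
        row[f"intake_{name}"] = value
    return row


def score_records(
    records: Iterable[ParticipantRecord],
    foods: FoodTable,
    config: Optional[ScoringConfig] = None,
) -> pd.DataFrame:
    """Score an iterable of records into a tidy per-participant frame,
    appending the quartile column per the configured cut-point mode."""
    if config is None:
        config = ScoringConfig()
    rows = [_scored_row(score_record(r, foods, config)) for r in records]
    frame = pd.DataFrame(rows)
    if len(frame):
        frame["quartile"] = quartile_labels(
            frame["balance_observed"].to_numpy(), config
        )
    return frame


# ---------------------------------------------------------------------------
# vectorised frame path


def quartile_labels(balance: np.ndarray, config: ScoringConfig) -> np.ndarray:
    """Quartile labels for an array of balances; cut-points either fixed from
    config or the sample's 25/50/75 quantiles (linear interpolation)."""
    if config.quartile_cutoffs is not None:
        cutoffs = np.asarray(config.quartile_cutoffs, dtype=float)
    else:
        cutoffs = np.quantile(balance, [0.25, 0.50, 0.75])
        if not (cutoffs[0] < cutoffs[1] < cutoffs[2]):
            raise ValueError(
                "sample quantiles are not strictly ascending; supply fixed "
                "quartile cutoffs in the scoring config"
            )
    idx = np.searchsorted(cutoffs, balance, side="right")
    return np.array(["Q1", "Q2", "Q3", "Q4"])[idx]


def score_frame(
    frame: pd.DataFrame,
    foods: FoodTable,
    config: Optional[ScoringConfig] = None,
    add_quartiles: bool = True,
) -> pd.DataFrame:
    """Vectorised scoring of a wide participant frame.

    Expects the participants.csv schema: beverage columns named after
    :class:`~wbqn.records.LiquidIntake` fields (``drinking_water`` .. ``other``),
    activity hours/points columns, ``urine_points``/``fecal_points``, lactation
    columns, and per-food ``food_<id>_g_day`` columns. Produces the same
    derived columns as :func:`score_records` appended to a copy of the input.
    """
    if config is None:
        config = ScoringConfig()
    out = frame.copy()
    n = len(out)

    bev_cols = list(LiquidIntake.beverage_fields())
    bev = out[bev_cols].to_numpy(dtype=float)
    if n and (bev.min() < 0 or float(out["drinking_water"].min()) < 0):
        raise ValueError("negative beverage volume")
    out["intake_drinking_water"] = out["drinking_water"].astype(float)
    out["intake_liquids_excl_water"] = bev.sum(axis=1)
    for c in bev_cols:
        out[f"intake_{c}"] = out[c].astype(float)

    food_cols = [c for c in out.columns if c.startswith("food_") and c.endswith("_g_day")]
    if food_cols:
        ids = [c[len("food_"):-len("_g_day")] for c in food_cols]
        fracs = np.array([foods.water_fraction(i) for i in ids])
        grams = out[food_cols].to_numpy(dtype=float)
        if n and grams.min() < 0:
            raise ValueError("negative food diary amount")
        out["intake_foods"] = grams @ fracs
    else:
        out["intake_foods"] = 0.0
    out["intake_total"] = (
        out["intake_drinking_water"]
        + out["intake_liquids_excl_water"]
        + out["intake_foods"]
    )

    out["loss_urine"] = _map_scale_array(
        out["urine_points"].to_numpy(), config.scales["urine"])
    out["loss_feces"] = _map_scale_array(
        out["fecal_points"].to_numpy(), config.scales["fecal"])
    out["loss_sweat"] = (
        out["hours_intensive"].to_numpy(dtype=float)
        * _map_scale_array(out["sweat_points_intensive"].to_numpy(),
                           config.scales["sweat_intensive"])
        + out["hours_moderate"].to_numpy(dtype=float)
        * _map_scale_array(out["sweat_points_moderate"].to_numpy(),
                           config.scales["sweat_moderate"])
        + out["hours_sedentary"].to_numpy(dtype=float)
        * _map_scale_array(out["sweat_points_sedentary"].to_numpy(),
                           config.scales["sweat_sedentary"])
    )
    if config.milk_loss.enabled:
        lactating = (out["group"] != BreastfeedingGroup.none.value).to_numpy()
        out["loss_milk"] = np.where(
            lactating,
            out["feeds_per_day"].to_numpy(dtype=float)
            * out["minutes_per_feed"].to_numpy(dtype=float)
            * config.milk_loss.flow_rate_ml_per_min
            * config.milk_loss.water_fraction,
            0.0,
        )
    else:
        out["loss_milk"] = 0.0
    out["loss_total"] = (
        out["loss_urine"] + out["loss_feces"] + out["loss_sweat"] + out["loss_milk"]
    )

    out["balance_observed"] = out["intake_total"] - out["loss_total"]
    out["negative_flag"] = np.where(out["balance_observed"] < 0, 0, 1)
    rec = out["group"].map(config.efsa_recommendations)
    if n and rec.isna().any():
        bad = sorted(out.loc[rec.isna(), "group"].unique())
        raise ValueError(f"unknown breastfeeding group(s): {bad}")
    out["balance_vs_guideline"] = out["intake_total"] - rec.astype(float)
    out["adequacy_flag"] = out["balance_vs_guideline"] >= 0
    if "weight" in out.columns and "height" in out.columns:
        out["bmi"] = out["weight"].astype(float) / out["height"].astype(float) ** 2
    if add_quartiles and n:
        out["quartile"] = quartile_labels(
            out["balance_observed"].to_numpy(), config
        )
    return out
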