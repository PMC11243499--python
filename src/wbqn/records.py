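"""Domain types for participant-level water-balance questionnaire data.

A participant record holds one woman's raw questionnaire responses:
demographics and anthropometrics, breastfeeding practice, a semi-quantified
food diary (daily grams per food item), per-beverage daily volumes, physical
activity exposure with self-rated sweat intensity, excretion frequency on
5-point scales, and lactation frequency/duration. Scoring (``wbqn.scoring``)
converts a valid record into water intake, loss and balance in mL/day.
"""

from __future__ import annotations

import enum
import math
from typing import Optional

from pydantic import BaseModel, Field, NonNegativeFloat, model_validator


class BreastfeedingGroup(str, enum.Enum):
    """Feeding-practice stratum: breast milk only, breast milk plus formula or
    other foods, or no breast milk at all."""

    exclusive = "exclusive"
    mixed = "mixed"
    none = "none"


class FoodItem(BaseModel):
    """One row of a food-composition table (USDA-style water fractions)."""

    food_id: str
    name: str = ""
    water_fraction: float = Field(ge=0.0, le=1.0)


class FoodDiaryEntry(BaseModel):
    """Daily consumption of one food item, pre-resolved to grams per day
    (reported frequency times portion size)."""

    food_id: str
    amount: NonNegativeFloat  # g/day


class LiquidIntake(BaseModel):
    """Per-beverage daily volumes in mL/day. ``drinking_water`` is plain water
    and is scored separately from all other categories."""

    drinking_water: NonNegativeFloat = 0.0
    juice: NonNegativeFloat = 0.0
    soft_drink: NonNegativeFloat = 0.0
    tea: NonNegativeFloat = 0.0
    coffee: NonNegativeFloat = 0.0
    milk: NonNegativeFloat = 0.0
    milkshake_sherbet: NonNegativeFloat = 0.0
    isotonic_energy: NonNegativeFloat = 0.0
    alcoholic: NonNegativeFloat = 0.0
    other: NonNegativeFloat = 0.0

    @classmethod
    def beverage_fields(cls) -> tuple[str, ...]:
        """All categories except plain drinking water, in schema order."""
        return tuple(f for f in cls.model_fields if f != "drinking_water")


class ActivityProfile(BaseModel):
    """Daily physical-activity exposure and self-rated sweating.

    Hours are split across intensive, moderate-intensity and sedentary
    activity; for each category the participant rates sweating on a 1-10
    scale (1 minimal, 10 maximal).
    """

    hours_intensive: NonNegativeFloat = 0.0
    hours_moderate: NonNegativeFloat = 0.0
    hours_sedentary: NonNegativeFloat = 0.0
    sweat_points_intensive: int = Field(default=1, ge=1, le=10)
    sweat_points_moderate: int = Field(default=1, ge=1, le=10)
    sweat_points_sedentary: int = Field(default=1, ge=1, le=10)

    @model_validator(mode="after")
    def _hours_fit_in_a_day(self) -> "ActivityProfile":
        total = self.hours_intensive + self.hours_moderate + self.hours_sedentary
        if total > 24.0 + 1e-9:
            raise ValueError(
                f"activity hours sum to {total:.2f} h/day, exceeding 24 h"
            )
        return self


class ExcretionReport(BaseModel):
    """Urination and defecation frequency, each on the instrument's 5-point
    scale (1 = lowest urinary output / most frequent bowel movements)."""

    urine_points: int = Field(ge=1, le=5)
    fecal_points: int = Field(ge=1, le=5)


class LactationReport(BaseModel):
    """Breastfeeding practice plus nursing frequency and duration."""

    group: BreastfeedingGroup
    feeds_per_day: NonNegativeFloat = 0.0
    minutes_per_feed: NonNegativeFloat = 0.0

    @model_validator(mode="after")
    def _non_breastfeeding_has_no_feeds(self) -> "LactationReport":
        if self.group is BreastfeedingGroup.none and self.feeds_per_day != 0:
            raise ValueError("feeds_per_day must be 0 when group is 'none'")
        return self


class ParticipantRecord(BaseModel):
    """One woman's raw questionnaire responses, validated."""

    participant_id: str
    age: float = Field(gt=0)  # years
    weight: float = Field(gt=0)  # kg
    height: float = Field(gt=0)  # m
    education_years: Optional[float] = Field(default=None, ge=0)
    lactation: LactationReport
    diary: list[FoodDiaryEntry] = Field(default_factory=list)
    liquids: LiquidIntake = Field(default_factory=LiquidIntake)
    activity: ActivityProfile = Field(default_factory=ActivityProfile)
    excretion: ExcretionReport

    @property
    def bmi(self) -> float:
        """Body mass index, kg/m^2."""
        return self.weight / self.height**2

    @property
    def bmi_class(self) -> str:
        """WHO class: underweight < 18.5 <= normal < 25 <= overweight < 30 <= obese."""
        b = self.bmi
        if b < 18.5:
            return "underweight"
        if b < 25.0:
            return "normal"
        if b < 30.0:
            return "overweight"
        return "obese"

    @model_validator(mode="after")
    def _bmi_finite(self) -> "ParticipantRecord":
        if not math.isfinite(self.bmi):
            raise ValueError("BMI is not finite")
        return self


def urination_frequency_to_points(
    frequency_per_day: int, lookup: Optional[dict[int, int]] = None
) -> int:
    """Map a reported urination frequency (1 .. 10-or-more times/day) onto the
    instrument's 5-point urine scale.

    The default lookup is an assumption documented in the package docs:
    {1}->1, {2-3}->2, {4-6}->3, {7-9}->4, {10+}->5. Frequencies above 10 are
    clamped to the 10+ bin.
    """
    if frequency_per_day < 1:
        raise ValueError("urination frequency must be at least 1/day")
    if lookup is None:
        lookup = DEFAULT_URINATION_LOOKUP
    return lookup[min(frequency_per_day, max(lookup))]


DEFAULT_URINATION_LOOKUP: dict[int, int] = {
    1: 1,
    2: 2, 3: 2,
    4: 3, 5: 3, 6: 3,
    7: 4, 8: 4, 9: 4,
    10: 5,
}
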