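"""Configuration: scale endpoint mappings, guideline thresholds, scoring
options and the pipeline configuration loaded from YAML/JSON.

The instrument converts ordinal self-ratings into volumes by linear
interpolation between two published endpoints per scale. Those endpoints,
the EFSA adequate-intake recommendations, the optional lactation-loss term
and the quartile cut-point mode all live here so that every constant the
scoring uses is inspectable and overridable.
"""

from __future__ import annotations

import enum
import hashlib
import json
from pathlib import Path
from typing import Optional, Union

import yaml
from pydantic import BaseModel, Field, model_validator

from .records import DEFAULT_URINATION_LOOKUP, BreastfeedingGroup


class VolumeUnit(str, enum.Enum):
    ml_per_hour = "mL/h"
    ml_per_day = "mL/day"


class ScaleMapping(BaseModel):
    """A two-point linear mapping from scale points to a volume rate.

    ``point_min`` maps exactly to ``value_min`` and ``point_max`` exactly to
    ``value_max``; intermediate points are linearly interpolated. The mapping
    may be decreasing (``value_max < value_min``), as for fecal loss where
    higher points mean *less* frequent bowel movements.
    """

    name: str
    point_min: float
    point_max: float
    value_min: float = Field(ge=0)
    value_max: float = Field(ge=0)
    unit: VolumeUnit

    @model_validator(mode="after")
    def _ordered_points(self) -> "ScaleMapping":
        if not self.point_min < self.point_max:
            raise ValueError(f"{self.name}: point_min must be < point_max")
        return self


# Published endpoint constants of the instrument's loss scales.
def _default_scales() -> dict[str, ScaleMapping]:
    return {
        "sweat_intensive": ScaleMapping(
            name="sweat_intensive", point_min=1, point_max=10,
            value_min=1000.0, value_max=2000.0, unit=VolumeUnit.ml_per_hour),
        "sweat_moderate": ScaleMapping(
            name="sweat_moderate", point_min=1, point_max=10,
            value_min=400.0, value_max=700.0, unit=VolumeUnit.ml_per_hour),
        "sweat_sedentary": ScaleMapping(
            name="sweat_sedentary", point_min=1, point_max=10,
            value_min=0.01, value_max=0.02, unit=VolumeUnit.ml_per_hour),
        "urine": ScaleMapping(
            name="urine", point_min=1, point_max=5,
            value_min=600.0, value_max=3000.0, unit=VolumeUnit.ml_per_day),
        "fecal": ScaleMapping(
            name="fecal", point_min=1, point_max=5,
            value_min=200.0, value_max=50.0, unit=VolumeUnit.ml_per_day),
    }


#: EFSA adequate-intake recommendations, mL/day: 2700 for lactating
#: (exclusive breastfeeding) women, 2000 otherwise.
DEFAULT_EFSA_RECOMMENDATIONS: dict[str, float] = {
    "exclusive": 2700.0,
    "mixed": 2000.0,
    "none": 2000.0,
}

#: Water-balance quartile cut-points (mL/day) reported for a reference cohort
#: of breastfeeding women; usable in place of sample quantiles via config.
REFERENCE_QUARTILE_CUTOFFS: tuple[float, float, float] = (-994.47, 33.31, 921.24)


class MilkLossConfig(BaseModel):
    """Optional lactation water-loss term.

    Off by default: the instrument's total loss is urine + feces + sweat.
    When enabled, milk water loss = feeds/day x min/feed x flow_rate x
    water_fraction. The default flow rate assumes 750 mL milk/day over
    8 feeds x 15 min (6.25 mL/min); milk is ~87% water.
    """

    enabled: bool = False
    flow_rate_ml_per_min: float = Field(default=6.25, ge=0)
    water_fraction: float = Field(default=0.87, ge=0, le=1)


class ScoringConfig(BaseModel):
    """Everything the scoring stage needs beyond the raw records."""

    scales: dict[str, ScaleMapping] = Field(default_factory=_default_scales)
    efsa_recommendations: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_EFSA_RECOMMENDATIONS))
    milk_loss: MilkLossConfig = Field(default_factory=MilkLossConfig)
    # None -> derive cut-points from the sample (quantiles, linear
    # interpolation); a 3-tuple -> fixed cut-points in mL/day.
    quartile_cutoffs: Optional[tuple[float, float, float]] = None
    urination_lookup: dict[int, int] = Field(
        default_factory=lambda: dict(DEFAULT_URINATION_LOOKUP))

    @model_validator(mode="after")
    def _validate(self) -> "ScoringConfig":
        for key in ("sweat_intensive", "sweat_moderate", "sweat_sedentary",
                    "urine", "fecal"):
            if key not in self.scales:
                raise ValueError(f"missing scale mapping: {key}")
        for g in BreastfeedingGroup:
            if g.value not in self.efsa_recommendations:
                raise ValueError(f"missing EFSA recommendation for group {g.value}")
        if self.quartile_cutoffs is not None:
            c1, c2, c3 = self.quartile_cutoffs
            if not (c1 < c2 < c3):
                raise ValueError("quartile cutoffs must be strictly ascending")
        return self

    def recommendation_for(self, group: Union[str, BreastfeedingGroup]) -> float:
        key = group.value if isinstance(group, BreastfeedingGroup) else str(group)
        try:
            return self.efsa_recommendations[key]
        except KeyError:
            raise ValueError(f"unknown breastfeeding group: {key!r}") from None


class StatsOptions(BaseModel):
    alpha: float = Field(default=0.05, gt=0, lt=1)
    benjamini_hochberg: bool = False


class PipelineConfig(BaseModel):
    """Top-level configuration tying file paths, scoring, statistics and
    simulation options together for the command-line pipeline."""

    participants: Optional[Path] = None
    foods: Optional[Path] = None
    output_dir: Path = Path("wbqn_out")
    scoring: ScoringConfig = Field(default_factory=ScoringConfig)
    stats: StatsOptions = Field(default_factory=StatsOptions)
    seed: int = 0

    def config_hash(self) -> str:
        """Stable hash of the configuration, logged for provenance."""
        payload = self.model_dump_json().encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def load_pipeline_config(path: Union[str, Path]) -> PipelineConfig:
    """Load a pipeline configuration from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if data is None:
        data = {}
    return PipelineConfig.model_validate(data)
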