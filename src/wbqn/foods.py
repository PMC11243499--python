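"""Food-composition table: water fraction per food item.

The instrument scores dietary water from a 58-item semi-quantified food
diary against USDA-style water fractions (g water per g food). The exact
item list used with the real cohort is not published, so
:func:`default_food_table` builds a synthetic stand-in: 58 staple foods of a
Mediterranean diet with typical USDA water fractions. For real scoring,
load your own table with :meth:`FoodTable.from_csv`.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Union

import pandas as pd

from .records import FoodItem


class FoodLookupError(KeyError):
    """A diary references a food_id absent from the composition table."""


class FoodTable:
    """A validated food-composition table with O(1) water-fraction lookup."""

    def __init__(self, items: Iterable[FoodItem]):
        items = list(items)
        ids = [it.food_id for it in items]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate food_id(s) in composition table: {dupes}")
        self._items: dict[str, FoodItem] = {it.food_id: it for it in items}

    def __len__(self) -> int:
        return len(self._items)

    def __contains__(self, food_id: str) -> bool:
        return food_id in self._items

    def __iter__(self):
        return iter(self._items.values())

    @property
    def food_ids(self) -> list[str]:
        return list(self._items)

    def water_fraction(self, food_id: str) -> float:
        try:
            return self._items[food_id].water_fraction
        except KeyError:
            raise FoodLookupError(
                f"food_id {food_id!r} not found in composition table"
            ) from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(it.food_id, it.name, it.water_fraction) for it in self],
            columns=["food_id", "name", "water_fraction"],
        )

    def to_csv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "FoodTable":
        required = {"food_id", "name", "water_fraction"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"foods table missing column(s): {sorted(missing)}")
        return cls(
            FoodItem(food_id=str(r.food_id), name=str(r.name),
                     water_fraction=float(r.water_fraction))
            for r in frame.itertuples(index=False)
        )

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "FoodTable":
        return cls.from_frame(pd.read_csv(path, dtype={"food_id": str}))


# Synthetic stand-in composition table (the cohort's own 58-item list is
# unpublished). Water fractions are typical USDA values for the food as eaten.
_SYNTHETIC_FOODS: list[tuple[str, str, float]] = [
    ("F01", "cucumber, raw", 0.95),
    ("F02", "lettuce, raw", 0.96),
    ("F03", "tomato, raw", 0.94),
    ("F04", "zucchini, cooked", 0.94),
    ("F05", "spinach, cooked", 0.91),
    ("F06", "green beans, cooked", 0.89),
    ("F07", "broccoli, cooked", 0.89),
    ("F08", "cabbage, raw", 0.92),
    ("F09", "carrot, raw", 0.88),
    ("F10", "pepper, raw", 0.92),
    ("F11", "eggplant, cooked", 0.92),
    ("F12", "okra, cooked", 0.90),
    ("F13", "watermelon", 0.91),
    ("F14", "melon", 0.90),
    ("F15", "orange", 0.87),
    ("F16", "apple", 0.86),
    ("F17", "pear", 0.84),
    ("F18", "peach", 0.89),
    ("F19", "grapes", 0.81),
    ("F20", "strawberries", 0.91),
    ("F21", "banana", 0.75),
    ("F22", "kiwi", 0.83),
    ("F23", "apricot", 0.86),
    ("F24", "cherries", 0.82),
    ("F25", "yogurt, plain", 0.85),
    ("F26", "yogurt, strained", 0.81),
    ("F27", "feta cheese", 0.55),
    ("F28", "hard cheese", 0.39),
    ("F29", "egg, boiled", 0.75),
    ("F30", "chicken, roasted", 0.64),
    ("F31", "beef, cooked", 0.58),
    ("F32", "pork, cooked", 0.57),
    ("F33", "fish, baked", 0.70),
    ("F34", "sardines, grilled", 0.62),
    ("F35", "octopus, cooked", 0.77),
    ("F36", "lentil soup", 0.85),
    ("F37", "bean soup", 0.84),
    ("F38", "chickpeas, cooked", 0.60),
    ("F39", "rice, cooked", 0.68),
    ("F40", "pasta, cooked", 0.62),
    ("F41", "potato, boiled", 0.77),
    ("F42", "potato, fried", 0.47),
    ("F43", "bread, white", 0.36),
    ("F44", "bread, whole grain", 0.38),
    ("F45", "rusks", 0.06),
    ("F46", "breakfast cereal", 0.05),
    ("F47", "vegetable soup", 0.90),
    ("F48", "chicken soup", 0.88),
    ("F49", "tomato sauce dishes", 0.80),
    ("F50", "stuffed vegetables", 0.78),
    ("F51", "pie, cheese", 0.40),
    ("F52", "pie, spinach", 0.50),
    ("F53", "olives", 0.75),
    ("F54", "ice cream", 0.61),
    ("F55", "custard dessert", 0.72),
    ("F56", "fruit compote", 0.82),
    ("F57", "honey", 0.17),
    ("F58", "nuts", 0.04),
]


def default_food_table() -> FoodTable:
    """The packaged synthetic 58-item composition table (see module docs)."""
    return FoodTable(
        FoodItem(food_id=i, name=n, water_fraction=w)
        for i, n, w in _SYNTHETIC_FOODS
    )
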