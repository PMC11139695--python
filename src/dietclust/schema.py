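"""Questionnaire schema for the brief-type diet history questionnaire (BDHQ).

The instrument covers 79 ordinal variables: 58 food and non-alcoholic
beverage items, 12 dietary behaviors, and 9 cooking methods.  Each variable
has an ordered label scale (2, 5, 7, 8, or 9 categories) and a weight map
assigning integer points 1..L to the categories, used by the trend score.

Responses are stored as labels throughout; they are encoded to integer
scale positions only at analysis time so the weight maps stay auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

CATEGORIES = ("food_item", "dietary_behavior", "cooking_method")
VALID_SCALE_LENGTHS = (2, 5, 7, 8, 9)


class SchemaError(ValueError):
    """Raised when a schema file or definition is structurally invalid."""


@dataclass(frozen=True)
class VariableDef:
    """One ordinal questionnaire variable.

    Parameters
    ----------
    id : str
        Short machine name, unique within a schema.
    category : str
        One of ``food_item``, ``dietary_behavior``, ``cooking_method``.
    scale_labels : tuple of str
        Ordered response labels, lowest first.
    weight_map : dict
        Label -> integer points.  Strictly increasing over scale order,
        minimum 1.
    """

    id: str
    category: str
    scale_labels: tuple[str, ...]
    weight_map: Mapping[str, int]

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise SchemaError(
                f"variable {self.id!r}: unknown category {self.category!r}"
            )
        if len(self.scale_labels) not in VALID_SCALE_LENGTHS:
            raise SchemaError(
                f"variable {self.id!r}: scale length {len(self.scale_labels)} "
                f"not in {VALID_SCALE_LENGTHS}"
            )
        weights = [self.weight_map[lab] for lab in self.scale_labels]
        if weights[0] < 1:
            raise SchemaError(f"variable {self.id!r}: minimum weight must be >= 1")
        if any(b <= a for a, b in zip(weights, weights[1:])):
            raise SchemaError(
                f"variable {self.id!r}: weight map not strictly increasing"
            )

    @property
    def n_categories(self) -> int:
        return len(self.scale_labels)

    @property
    def weights(self) -> tuple[int, ...]:
        """Weights in scale order."""
        return tuple(self.weight_map[lab] for lab in self.scale_labels)

    def weight(self, label: str) -> int:
        """Points for a response label (the trend-score weight)."""
        try:
            return self.weight_map[label]
        except KeyError:
            raise KeyError(
                f"label {label!r} is not on the scale of variable {self.id!r}"
            ) from None

    def position(self, label: str) -> int:
        """1-based scale position of a response label."""
        try:
            return self.scale_labels.index(label) + 1
        except ValueError:
            raise KeyError(
                f"label {label!r} is not on the scale of variable {self.id!r}"
            ) from None


@dataclass(frozen=True)
class QuestionnaireSchema:
    """An ordered collection of :class:`VariableDef`."""

    variables: tuple[VariableDef, ...]
    name: str = "custom"
    _by_id: dict = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        by_id = {}
        for var in self.variables:
            if var.id in by_id:
                raise SchemaError(f"duplicate variable id {var.id!r}")
            by_id[var.id] = var
        object.__setattr__(self, "_by_id", by_id)

    def __len__(self) -> int:
        return len(self.variables)

    def __iter__(self):
        return iter(self.variables)

    def __contains__(self, var_id: str) -> bool:
        return var_id in self._by_id

    def __getitem__(self, var_id: str) -> VariableDef:
        try:
            return self._by_id[var_id]
        except KeyError:
            raise SchemaError(f"unknown variable {var_id!r}") from None

    @property
    def variable_ids(self) -> list[str]:
        return [v.id for v in self.variables]

    def by_category(self, categories: Iterable[str]) -> list[VariableDef]:
        cats = set(categories)
        unknown = cats - set(CATEGORIES)
        if unknown:
            raise SchemaError(f"unknown categories: {sorted(unknown)}")
        return [v for v in self.variables if v.category in cats]

    def category_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CATEGORIES}
        for v in self.variables:
            counts[v.category] += 1
        return counts


# ---------------------------------------------------------------------------
# YAML I/O
# ---------------------------------------------------------------------------

def save_schema(schema: QuestionnaireSchema, path: str | Path) -> None:
    """Write a schema to YAML."""
    doc = {
        "name": schema.name,
        "variables": [
            {
                "id": v.id,
                "category": v.category,
                "scale_labels": list(v.scale_labels),
                "weights": [v.weight_map[lab] for lab in v.scale_labels],
            }
            for v in schema.variables
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False, allow_unicode=True))


def _schema_from_doc(doc: Mapping) -> QuestionnaireSchema:
    if not isinstance(doc, Mapping) or "variables" not in doc:
        raise SchemaError("schema file must contain a 'variables' list")
    variables = []
    for entry in doc["variables"]:
        labels = tuple(entry["scale_labels"])
        weights = entry.get("weights", list(range(1, len(labels) + 1)))
        if len(weights) != len(labels):
            raise SchemaError(
                f"variable {entry.get('id')!r}: weights/labels length mismatch"
            )
        variables.append(
            VariableDef(
                id=entry["id"],
                category=entry["category"],
                scale_labels=labels,
                weight_map=dict(zip(labels, weights)),
            )
        )
    return QuestionnaireSchema(tuple(variables), name=doc.get("name", "custom"))


def load_schema(path: str | Path) -> QuestionnaireSchema:
    """Read a schema from YAML."""
    doc = yaml.safe_load(Path(path).read_text())
    return _schema_from_doc(doc)


# ---------------------------------------------------------------------------
# The packaged BDHQ schema (79 variables)
# ---------------------------------------------------------------------------

# Canonical label scales.  Weights are the consecutive integers 1..L in
# scale order for every row of the scoring table.
FREQ7 = (
    "never",
    "less than 1 time per week",
    "1 time per week",
    "2-3 times per week",
    "4-6 times per week",
    "1 time per day",
    "2 or more times per day",
)
BEVERAGE8 = (
    "never",
    "less than 1 cup per week",
    "1 cup per week",
    "2-3 cups per week",
    "4-6 cups per week",
    "1 cup per day",
    "2-3 cups per day",
    "4 cups or more per day",
)
FREQ9 = (
    "never",
    "less than 1 time per week",
    "1 time per week",
    "2 times per week",
    "3 times per week",
    "4 times per week",
    "5 times per week",
    "6 times per week",
    "1 time per day",
)
ALCOHOL7 = (
    "never",
    "less than 0.5 cup per week",
    "0.5 cup per week",
    "1 cup per week",
    "2 cups per day",
    "3 cups per day",
    "4 cups or more per day",
)
COOK7 = (
    "never",
    "less than 1 time per week",
    "1 time per week",
    "2-3 times per week",
    "4-6 times per week",
    "1 time per day",
    "2 times per day",
)

_FOOD_FREQ7 = [
    "chicken_meat", "pork_beef", "ham_sausage_bacon", "liver",
    "squid_octopus_shrimp_shellfish", "small_fish_with_bones", "canned_tuna",
    "dried_salted_fish", "oily_fish", "lean_fish", "egg", "tofu_fried_tofu",
    "natto", "potatoes", "pickled_green_leafy_vegetables",
    "other_pickled_vegetables", "lettuce_cabbage_raw", "green_leafy_vegetables",
    "cabbage_chinese_cabbage", "carrots_pumpkin", "japanese_radish_turnip",
    "other_root_vegetables", "tomatoes", "mushrooms", "seaweeds",
    "western_confectioneries", "japanese_confectioneries",
    "senbei_rice_crackers", "ice_cream", "citrus_fruit",
    "persimmons_strawberries_kiwifruit", "other_fruits", "mayonnaise", "bread",
    "buckwheat_noodles", "japanese_wheat_noodles", "chinese_noodles", "pasta",
    "other_grains", "sugar", "citrus_fruits_seasonal", "persimmon_seasonal",
    "strawberry_seasonal",
]
_FOOD_BEV8 = ["green_tea", "black_tea_oolong_tea", "coffee", "cola_soft_drink",
              "juice_100pct"]
_FOOD_FREQ9 = ["miso_soup", "rice", "alcohol_frequency"]
_FOOD_ALC7 = ["nihonshu_sake", "beer", "shochu", "whisky", "wine"]

_BEHAVIOR_SCALES: dict[str, tuple[str, ...]] = {
    "noodle_soup": ("do not like", "do not like much", "neutral", "like",
                    "like very much"),
    "seasoning_taste_home_vs_out": ("light", "somewhat light", "neutral",
                                    "somewhat heavy", "heavy"),
    "meat_fat_preference": ("do not eat", "do not like much", "neutral",
                            "like", "like very much"),
    "breakfast": FREQ9,
    "soy_sauce_amount": ("very little", "little", "moderate", "much",
                         "very much"),
    "soy_sauce_frequency": ("never use", "rarely use", "sometimes use",
                            "often use", "always use"),
    "side_dishes_home_vs_out": ("much more at home", "more at home", "same",
                                "more eating out", "much more eating out"),
    "rice_amount_home_vs_out": ("much more at home", "more at home", "same",
                                "more eating out", "much more eating out"),
    "eating_speed": ("very slow", "slow", "medium", "fast", "very fast"),
    "conscious_eating_changes": ("negative", "positive"),
    "supplements": FREQ7,
    "dietary_guidance": ("not received", "received"),
}

_COOKING_METHODS = [
    "raw_fish_sashimi_sushi", "grilled_fish", "boiled_fish",
    "tempura_fried_fish", "grilled_meat_steak", "hamburg_curry_meat_sauce",
    "deep_fried_meat", "stir_fried_meat", "stewed_meat",
]


def _consecutive(labels: tuple[str, ...]) -> dict[str, int]:
    return {lab: i + 1 for i, lab in enumerate(labels)}


def _build_bdhq_schema() -> QuestionnaireSchema:
    variables: list[VariableDef] = []

    def add(var_id: str, category: str, labels: tuple[str, ...]) -> None:
        variables.append(
            VariableDef(var_id, category, labels, _consecutive(labels))
        )

    add("reduced_fat_milk_yogurt", "food_item", FREQ7)
    add("milk_yogurt", "food_item", FREQ7)
    for vid in _FOOD_FREQ7:
        add(vid, "food_item", FREQ7)
    for vid in _FOOD_BEV8:
        add(vid, "food_item", BEVERAGE8)
    for vid in _FOOD_FREQ9:
        add(vid, "food_item", FREQ9)
    for vid in _FOOD_ALC7:
        add(vid, "food_item", ALCOHOL7)
    for vid, labels in _BEHAVIOR_SCALES.items():
        add(vid, "dietary_behavior", labels)
    for vid in _COOKING_METHODS:
        add(vid, "cooking_method", COOK7)

    schema = QuestionnaireSchema(tuple(variables), name="bdhq79")
    counts = schema.category_counts()
    assert counts == {"food_item": 58, "dietary_behavior": 12,
                      "cooking_method": 9}, counts
    return schema


def bdhq_schema() -> QuestionnaireSchema:
    """The packaged 79-variable BDHQ schema.

    Loads the YAML fixture shipped with the package; falls back to the
    in-code builder if the data file is unavailable.
    """
    try:
        ref = resources.files("dietclust").joinpath("data/bdhq_schema.yaml")
        return _schema_from_doc(yaml.safe_load(ref.read_text()))
    except (FileNotFoundError, ModuleNotFoundError):  # pragma: no cover
        return _build_bdhq_schema()
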