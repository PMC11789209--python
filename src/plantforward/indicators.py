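"""Extraction of the 14 sustainability indicators from a classified menu.

Each indicator lives on a 0–100 scale and may be *missing* — missing is a
first-class value (``None``), never coerced to 0, and feeds the downstream
missing-data rules of :mod:`plantforward.scoring`.  The indicators fall into
three groups:

main meals (8)
    Daily vegan availability ("base offer", binary per slot), percentage of
    vegan mains, percentage of vegetarian mains (vegan included — vegan is a
    subset of vegetarian), and a ruminant-avoidance score, each for lunch and
    dinner separately.
smaller meals (2)
    Percentage of vegan and of vegetarian smaller meals.
menu presentation (4)
    Environmental-impact descriptors (0/50/100), vegan options positioned
    first in every main section (0/100), positive-label use and absence of
    negative labels (each 0/50/100 with a 20 % regular-use threshold).

Ruminant-avoidance mapping: with ``r`` the percentage of mains free of
beef/lamb/goat, the default ``clamped`` mapping is ``max(0, 3 r − 200)`` —
100 for a ruminant-free slot, falling linearly to 0 once at least a third of
mains contain ruminant meat.  The plain ``identity`` mapping (score = r) is
available as an option.  Boundary cases are computed with integer
numerators, so a slot with exactly one third ruminant mains scores exactly 0.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Literal, Optional

from .classify import Lexicon, annotate_menu
from .model import (
    DietClass,
    EnvironmentalMessaging,
    MAIN_SLOTS,
    MealItem,
    Menu,
    MenuStyle,
    Slot,
    SmallerMealsStatus,
)

__all__ = [
    "IndicatorVector",
    "INDICATOR_NAMES",
    "INDICATOR_GROUPS",
    "ExtractionOptions",
    "base_offer",
    "percent_class_mains",
    "ruminant_indicator",
    "smaller_meal_percents",
    "environmental_descriptor_indicator",
    "positioning_indicator",
    "label_use_indicator",
    "extract_indicators",
]

#: Indicator groups (the three subscore dimensions), in reporting order.
INDICATOR_GROUPS: dict[str, tuple[str, ...]] = {
    "main_meals": (
        "base_offer_lunch", "base_offer_dinner",
        "pct_vegan_lunch", "pct_vegan_dinner",
        "pct_vegetarian_lunch", "pct_vegetarian_dinner",
        "ruminant_free_lunch", "ruminant_free_dinner",
    ),
    "smaller_meals": ("pct_vegan_smaller", "pct_vegetarian_smaller"),
    "menu_presentation": (
        "env_descriptors", "vegan_first", "positive_labels", "no_negative_labels",
    ),
}

INDICATOR_NAMES: tuple[str, ...] = tuple(
    name for group in INDICATOR_GROUPS.values() for name in group)


@dataclass(frozen=True)
class IndicatorVector:
    """The 14 indicator values; ``None`` marks a missing indicator."""

    base_offer_lunch: Optional[float] = None
    base_offer_dinner: Optional[float] = None
    pct_vegan_lunch: Optional[float] = None
    pct_vegan_dinner: Optional[float] = None
    pct_vegetarian_lunch: Optional[float] = None
    pct_vegetarian_dinner: Optional[float] = None
    ruminant_free_lunch: Optional[float] = None
    ruminant_free_dinner: Optional[float] = None
    pct_vegan_smaller: Optional[float] = None
    pct_vegetarian_smaller: Optional[float] = None
    env_descriptors: Optional[float] = None
    vegan_first: Optional[float] = None
    positive_labels: Optional[float] = None
    no_negative_labels: Optional[float] = None

    def __post_init__(self) -> None:
        for name, value in self.as_dict().items():
            if value is not None and not (0.0 <= value <= 100.0):
                raise ValueError(f"indicator {name} = {value} outside [0, 100]")

    def as_dict(self) -> dict[str, Optional[float]]:
        return {name: getattr(self, name) for name in INDICATOR_NAMES}

    @classmethod
    def from_dict(cls, values: dict[str, Optional[float]]) -> "IndicatorVector":
        unknown = set(values) - set(INDICATOR_NAMES)
        if unknown:
            raise ValueError(f"unknown indicator names: {sorted(unknown)}")
        return cls(**values)

    def replace(self, **updates: Optional[float]) -> "IndicatorVector":
        return dataclasses.replace(self, **updates)


@dataclass(frozen=True)
class ExtractionOptions:
    """Tunables of indicator extraction.

    ``label_threshold`` is the percentage of plant dishes above which label
    use counts as "regular" (strictly greater than; exactly the threshold
    falls in the "sometimes" band).  ``a_la_carte_always_available`` treats a
    standing menu as available every day, so a single vegan main satisfies
    the daily base offer.
    """

    ruminant_mapping: Literal["clamped", "identity"] = "clamped"
    label_threshold: float = 20.0
    a_la_carte_always_available: bool = True


def _is_vegan(it: MealItem) -> bool:
    return it.diet_class is DietClass.vegan


def _is_vegetarian(it: MealItem) -> bool:
    return it.diet_class in (DietClass.vegan, DietClass.vegetarian_not_vegan)


def _require_resolved(items: list[MealItem]) -> None:
    for it in items:
        if it.diet_class is None or it.contains_ruminant is None:
            raise ValueError(
                f"item {it.name!r} has unresolved annotations; classify the menu first")


def base_offer(menu: Menu, slot: Slot, options: ExtractionOptions = ExtractionOptions()) -> Optional[float]:
    """Daily vegan availability for one main slot (100/0, or missing).

    Cyclical: 100 iff every day 1–7 offers at least one vegan main in the
    slot (a repeated dish qualifies).  À la carte: the standing menu is
    available daily, so 100 iff at least one vegan main exists in the slot.
    Missing iff the slot has no mains at all.
    """
    mains = menu.mains(slot)
    if not mains:
        return None
    _require_resolved(mains)
    if menu.style is MenuStyle.a_la_carte and options.a_la_carte_always_available:
        return 100.0 if any(_is_vegan(it) for it in mains) else 0.0
    vegan_days = {it.day for it in mains if _is_vegan(it) and it.day is not None}
    return 100.0 if set(range(1, 8)) <= vegan_days else 0.0


def percent_class_mains(
    menu: Menu, slot: Slot, class_predicate: Literal["vegan", "vegetarian"]
) -> Optional[float]:
    """Percentage of mains in a slot that are vegan (or vegetarian-incl-vegan)."""
    mains = menu.mains(slot)
    if not mains:
        return None
    _require_resolved(mains)
    pred = _is_vegan if class_predicate == "vegan" else _is_vegetarian
    return 100.0 * sum(pred(it) for it in mains) / len(mains)


def ruminant_indicator(
    menu: Menu, slot: Slot, mapping: Literal["clamped", "identity"] = "clamped"
) -> Optional[float]:
    """Ruminant-avoidance score for one main slot (see module docstring)."""
    mains = menu.mains(slot)
    if not mains:
        return None
    _require_resolved(mains)
    n = len(mains)
    without = sum(not it.contains_ruminant for it in mains)
    if mapping == "identity":
        return 100.0 * without / n
    # integer numerator: 300*without - 200*n <= 0 exactly when ruminant share >= 1/3
    return max(0.0, (300 * without - 200 * n) / n)


def smaller_meal_percents(menu: Menu) -> tuple[Optional[float], Optional[float]]:
    """(vegan %, vegetarian %) over smaller meals; both missing when the
    section is absent or unassessable."""
    if menu.smaller_meals_status is not SmallerMealsStatus.listed:
        return (None, None)
    smaller = menu.smaller_items()
    if not smaller:
        return (None, None)
    _require_resolved(smaller)
    n = len(smaller)
    return (
        100.0 * sum(_is_vegan(it) for it in smaller) / n,
        100.0 * sum(_is_vegetarian(it) for it in smaller) / n,
    )


def environmental_descriptor_indicator(menu: Menu) -> Optional[float]:
    """Environmental-impact messaging: 100 menu-wide, 50 partial, 0 absent.

    Menu-wide messaging is the menu-level flag; item-level flags (some days
    or sections only) yield the partial score.  Missing iff every flag is
    unknown.
    """
    item_flags = {it.label_flags.environmental_messaging for it in menu.items}
    if menu.environmental_messaging is EnvironmentalMessaging.yes:
        return 100.0
    if menu.environmental_messaging is EnvironmentalMessaging.partial:
        return 50.0
    if item_flags & {EnvironmentalMessaging.yes, EnvironmentalMessaging.partial}:
        return 50.0
    if menu.environmental_messaging is EnvironmentalMessaging.no:
        return 0.0
    if EnvironmentalMessaging.no in item_flags:
        return 0.0
    return None


def positioning_indicator(menu: Menu) -> Optional[float]:
    """100 iff the first-listed item of *every* main (day, slot) section is
    vegan; 0 otherwise; missing when the menu has no mains."""
    sections = menu.sections(MAIN_SLOTS)
    if not sections:
        return None
    _require_resolved(menu.mains())
    for sec in sections.values():
        if not _is_vegan(sec[0]):
            return 0.0
    return 100.0


def label_use_indicator(
    menu: Menu,
    polarity: Literal["positive", "negative"],
    options: ExtractionOptions = ExtractionOptions(),
) -> Optional[float]:
    """Label-use score over all vegan/vegetarian dishes (mains and smaller).

    positive polarity: regular use (> threshold %) = 100, sometimes = 50,
    none = 0.  negative polarity: none = 100, sometimes = 50, regular = 0.
    Missing when the menu has no plant dishes.
    """
    items = [it for it in menu.items]
    _require_resolved(items)
    plant = [it for it in items if _is_vegetarian(it)]
    if not plant:
        return None
    if polarity == "positive":
        labelled = sum(bool(it.label_flags.positive_label_present) for it in plant)
    else:
        labelled = sum(bool(it.label_flags.explicit_diet_label_present) for it in plant)
    d = len(plant)
    # band decided on exact rationals: q > t  <=>  100*labelled > t*d
    if labelled == 0:
        band = "none"
    elif 100 * labelled > options.label_threshold * d:
        band = "regular"
    else:
        band = "sometimes"
    if polarity == "positive":
        return {"none": 0.0, "sometimes": 50.0, "regular": 100.0}[band]
    return {"none": 100.0, "sometimes": 50.0, "regular": 0.0}[band]


def extract_indicators(
    menu: Menu,
    lexicon: Optional[Lexicon] = None,
    options: ExtractionOptions = ExtractionOptions(),
) -> IndicatorVector:
    """Compute all 14 indicators of a validated (and, if cyclical,
    first-week-truncated) menu.

    When a lexicon is given, underived annotations are filled from dish
    names first; file-supplied annotations keep precedence either way.
    """
    if lexicon is not None:
        menu = annotate_menu(menu, lexicon)
    pvg_s, pveg_s = smaller_meal_percents(menu)
    return IndicatorVector(
        base_offer_lunch=base_offer(menu, Slot.lunch_main, options),
        base_offer_dinner=base_offer(menu, Slot.dinner_main, options),
        pct_vegan_lunch=percent_class_mains(menu, Slot.lunch_main, "vegan"),
        pct_vegan_dinner=percent_class_mains(menu, Slot.dinner_main, "vegan"),
        pct_vegetarian_lunch=percent_class_mains(menu, Slot.lunch_main, "vegetarian"),
        pct_vegetarian_dinner=percent_class_mains(menu, Slot.dinner_main, "vegetarian"),
        ruminant_free_lunch=ruminant_indicator(menu, Slot.lunch_main, options.ruminant_mapping),
        ruminant_free_dinner=ruminant_indicator(menu, Slot.dinner_main, options.ruminant_mapping),
        pct_vegan_smaller=pvg_s,
        pct_vegetarian_smaller=pveg_s,
        env_descriptors=environmental_descriptor_indicator(menu),
        vegan_first=positioning_indicator(menu),
        positive_labels=label_use_indicator(menu, "positive", options),
        no_negative_labels=label_use_indicator(menu, "negative", options),
    )
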