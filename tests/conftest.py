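"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pytest
from hypothesis import settings

from plantforward.indicators import INDICATOR_NAMES, IndicatorVector
from plantforward.model import (
    DietClass,
    EnvironmentalMessaging,
    LabelFlags,
    MealItem,
    Menu,
    MenuStyle,
    Slot,
    SmallerMealsStatus,
)

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


# ---------------------------------------------------------------------------
# Independent brute-force oracles (kept deliberately naive)


def oracle_subscore(values: dict, weights: dict, names: Sequence[str],
                    threshold: float = 0.5) -> Optional[float]:
    """Weighted mean over present values; None below the availability bar."""
    total_weight = 0.0
    avail_weight = 0.0
    acc = 0.0
    for name in names:
        w = weights[name]
        total_weight += w
        v = values.get(name)
        if v is not None:
            avail_weight += w
            acc += w * v
    if avail_weight / total_weight < threshold:
        return None
    return acc / avail_weight


def oracle_final(subscores: dict, final_weights: dict) -> Optional[float]:
    acc = 0.0
    wsum = 0.0
    for g, w in final_weights.items():
        v = subscores.get(g)
        if v is not None:
            acc += w * v
            wsum += w
    return None if wsum == 0.0 else acc / wsum


def random_indicator_vector(rng: np.random.Generator,
                            p_missing: float = 0.3) -> IndicatorVector:
    values = {}
    for name in INDICATOR_NAMES:
        values[name] = None if rng.random() < p_missing else float(
            np.round(rng.uniform(0, 100), 6))
    return IndicatorVector(**values)


# ---------------------------------------------------------------------------
# Compact menu builder for unit-level indicator tests
#
# Dish specs are strings: "vegan", "veg" (vegetarian-not-vegan), "omni",
# "rum" (omnivorous with ruminant meat), "proc:<category>", with optional
# "+neg" / "+pos" label suffixes, e.g. "vegan+neg".


def _item_from_spec(spec: str, slot: Slot, day: Optional[int], position: int) -> MealItem:
    parts = spec.split("+")
    base = parts[0]
    flags = LabelFlags(
        explicit_diet_label_present="neg" in parts[1:],
        positive_label_present="pos" in parts[1:],
    )
    kwargs: dict = {
        "name": f"{spec} dish",
        "slot": slot,
        "day": day,
        "position": position,
        "contains_ruminant": False,
        "processed_meat": frozenset(),
        "label_flags": flags,
    }
    if base == "vegan":
        kwargs["diet_class"] = DietClass.vegan
    elif base == "veg":
        kwargs["diet_class"] = DietClass.vegetarian_not_vegan
    elif base == "omni":
        kwargs["diet_class"] = DietClass.omnivorous
    elif base == "rum":
        kwargs["diet_class"] = DietClass.omnivorous
        kwargs["contains_ruminant"] = True
    elif base.startswith("proc:"):
        kwargs["diet_class"] = DietClass.omnivorous
        kwargs["processed_meat"] = frozenset({base.split(":", 1)[1]})
    else:
        raise ValueError(f"unknown dish spec {base!r}")
    return MealItem(**kwargs)


def build_menu(
    lunch: Sequence[Sequence[str]] = (),
    dinner: Sequence[Sequence[str]] = (),
    smaller: Sequence[str] = (),
    *,
    hospital_id: str = "TEST",
    style: MenuStyle = MenuStyle.cyclical,
    smaller_meals_status: SmallerMealsStatus = SmallerMealsStatus.listed,
    environmental_messaging: EnvironmentalMessaging = EnvironmentalMessaging.no,
    **menu_kwargs,
) -> Menu:
    """Build a fully annotated menu from per-day dish-spec lists."""
    items: list[MealItem] = []
    for slot, days in ((Slot.lunch_main, lunch), (Slot.dinner_main, dinner)):
        for d, specs in enumerate(days, start=1):
            day = d if style is MenuStyle.cyclical else None
            for pos, spec in enumerate(specs, start=1):
                items.append(_item_from_spec(spec, slot, day, pos))
    for pos, spec in enumerate(smaller, start=1):
        items.append(_item_from_spec(spec, Slot.smaller, None, pos))
    if style is MenuStyle.cyclical and "n_weeks" not in menu_kwargs:
        menu_kwargs["n_weeks"] = 1
    return Menu(
        hospital_id=hospital_id,
        style=style,
        smaller_meals_status=smaller_meals_status,
        environmental_messaging=environmental_messaging,
        items=tuple(items),
        **menu_kwargs,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def worked_example():
    from plantforward.synthetic import worked_example_menu

    return worked_example_menu()
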