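"""Synthetic hospital-menu cohorts with known ground-truth composition.

Real in-patient menus arrive as heterogeneous freedom-of-information
documents and are not redistributable, so every pipeline stage is exercised
against generated cohorts instead.  A :class:`MenuProfile` describes one
hospital's menu-construction behaviour — cyclical weekly structure, class
mix of mains and smaller meals, labelling and positioning habits,
missingness of the smaller-meals section — and :func:`generate_menu` turns
it into a schema-valid :class:`~plantforward.model.Menu`.

Dish names are drawn from class-specific template pools that are guaranteed
to round-trip through the default lexicon of :mod:`plantforward.classify`;
the generator leaves dietary annotations underived so that the classifier is
on the hot path and classifier regressions surface in generator tests.  This
coupling is deliberate.

Two modes:

* **exact-count mode** (``profile.exact``): per-day class counts are fixed
  and the ground-truth :class:`~plantforward.indicators.IndicatorVector` is
  computed analytically from the counts (:func:`exact_ground_truth`), so the
  full pipeline can be checked for exact agreement.
* **probabilistic mode**: dish classes are i.i.d. draws from the profile's
  per-dish probabilities; cohort-level indicator means then converge to the
  profile expectations (:meth:`MenuProfile.expected_percent_indicators`).

Randomness: a single root seed is fanned out through
``numpy.random.SeedSequence`` — one child stream per hospital plus one for
profile sampling — so cohorts are reproducible across runs and platforms.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Dict, Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .classify import DEFAULT_LEXICON, detect_processed_meat, detect_ruminant
from .indicators import ExtractionOptions, IndicatorVector
from .model import (
    DietClass,
    EnvironmentalMessaging,
    LabelFlags,
    MealItem,
    Menu,
    MenuStyle,
    ProcessedMeatCategory,
    Provider,
    Slot,
    SmallerMealsStatus,
)

__all__ = [
    "TEMPLATES",
    "ExactSlotCounts",
    "ExactSmallerCounts",
    "ExactComposition",
    "MenuProfile",
    "SyntheticMenu",
    "generate_menu",
    "generate_cohort",
    "study_cohort_profiles",
    "exact_ground_truth",
    "cohort_manifest",
    "write_cohort",
    "worked_example_menu",
]

#: Dish-name template pools; every name classifies as its pool's class under
#: the default lexicon (checked by the test suite).
TEMPLATES: Dict[str, tuple[str, ...]] = {
    "vegan": (
        "Vegetable tagine with chickpeas",
        "Chickpea and spinach curry",
        "Lentil bolognese",
        "Mushroom stroganoff",
        "Roasted vegetable pasta",
        "Butternut squash risotto",
    ),
    "vegetarian": (
        "Cheese and tomato pasta",
        "Macaroni cheese",
        "Cheese and onion quiche",
        "Egg salad with new potatoes",
        "Vegetable omelette",
        "Margherita pizza with cheese",
    ),
    "plain_omni": (
        "Roast chicken dinner",
        "Chicken korma",
        "Grilled salmon with herbs",
        "Tuna pasta bake",
        "Pork loin with apple",
        "Fish pie",
        "Turkey escalope",
    ),
    "ruminant": (
        "Beef lasagne",
        "Lamb hotpot",
        "Beef and onion pie",
        "Lamb curry",
        "Beef stew with dumplings",
    ),
    "ham": ("Roast ham with parsley sauce", "Ham and leek pie"),
    "bacon": ("Bacon and onion quiche", "Bacon chop with cabbage"),
    "sausage": ("Sausage and mash", "Sausages with onion gravy", "Sausage casserole"),
    "corned_beef": ("Corned beef hash",),
    "other": ("Pepperoni pizza", "Chorizo and chicken paella"),
    "meat_alt": ("Vegetable burger", "Tofu stir fry", "Soya bolognese", "Jackfruit burger"),
    "meat_alt_vegetarian": (
        "Vegetable burger with cheese",
        "Soya mince lasagne with cheese",
        "Tofu noodles with egg",
    ),
    "dairy_alt": ("Dairy free coconut pot", "Fruit smoothie with oat drink"),
    "smaller_vegan": (
        "Vegetable soup",
        "Jacket potato with baked beans",
        "Mixed salad",
        "Houmous salad sandwich",
    ),
    "smaller_vegetarian": (
        "Cheese sandwich",
        "Egg mayonnaise sandwich",
        "Jacket potato with cheese",
        "Cream of tomato soup",
    ),
    "smaller_omni": (
        "Ham sandwich",
        "Tuna mayonnaise sandwich",
        "Chicken soup",
        "Jacket potato with tuna",
    ),
}

_PROCESSED_POOLS = {
    ProcessedMeatCategory.ham: "ham",
    ProcessedMeatCategory.bacon: "bacon",
    ProcessedMeatCategory.sausage: "sausage",
    ProcessedMeatCategory.corned_beef: "corned_beef",
    ProcessedMeatCategory.other: "other",
}

#: Default processed-meat category mix (sausage-heavy, as on real menus).
DEFAULT_CATEGORY_WEIGHTS: Dict[ProcessedMeatCategory, float] = {
    ProcessedMeatCategory.sausage: 0.45,
    ProcessedMeatCategory.ham: 0.28,
    ProcessedMeatCategory.bacon: 0.15,
    ProcessedMeatCategory.corned_beef: 0.05,
    ProcessedMeatCategory.other: 0.07,
}


class ExactSlotCounts(BaseModel):
    """Per-day composition of one main slot in exact-count mode.

    ``vegetarian_per_day`` counts vegetarian-not-vegan dishes; ruminant and
    processed dishes are distinct omnivorous dishes.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    mains_per_day: int = Field(ge=1)
    vegan_per_day: int = Field(default=0, ge=0)
    vegetarian_per_day: int = Field(default=0, ge=0)
    ruminant_per_day: int = Field(default=0, ge=0)
    processed_per_day: int = Field(default=0, ge=0)

    @model_validator(mode="after")
    def _feasible(self) -> "ExactSlotCounts":
        used = (self.vegan_per_day + self.vegetarian_per_day
                + self.ruminant_per_day + self.processed_per_day)
        if used > self.mains_per_day:
            raise ValueError(
                f"class counts total {used} but only {self.mains_per_day} mains per day")
        return self


class ExactSmallerCounts(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")

    n: int = Field(ge=1)
    vegan: int = Field(default=0, ge=0)
    vegetarian: int = Field(default=0, ge=0)

    @model_validator(mode="after")
    def _feasible(self) -> "ExactSmallerCounts":
        if self.vegan + self.vegetarian > self.n:
            raise ValueError("vegan + vegetarian smaller meals exceed the section size")
        return self


class ExactComposition(BaseModel):
    """Fixed per-day composition with analytically known indicators.

    ``neg_labelled_plant`` / ``pos_labelled_plant`` are the total numbers of
    plant dishes (across the whole assessed menu) that carry an explicit
    diet label respectively a positive label; the two sets are disjoint.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    lunch: ExactSlotCounts
    dinner: ExactSlotCounts
    smaller: Optional[ExactSmallerCounts] = None
    neg_labelled_plant: int = Field(default=0, ge=0)
    pos_labelled_plant: int = Field(default=0, ge=0)

    def n_plant_dishes(self) -> int:
        n = 7 * (self.lunch.vegan_per_day + self.lunch.vegetarian_per_day
                 + self.dinner.vegan_per_day + self.dinner.vegetarian_per_day)
        if self.smaller is not None:
            n += self.smaller.vegan + self.smaller.vegetarian
        return n

    @model_validator(mode="after")
    def _labels_feasible(self) -> "ExactComposition":
        if self.neg_labelled_plant + self.pos_labelled_plant > self.n_plant_dishes():
            raise ValueError("more labelled plant dishes requested than plant dishes exist")
        return self


class MenuProfile(BaseModel):
    """Menu-construction behaviour of one synthetic hospital.

    Probabilities are per-dish marginals: ``p_ruminant`` and ``p_processed``
    are the marginal probabilities that a main contains ruminant meat
    respectively processed meat (both imply an omnivorous dish, so they must
    not exceed ``1 - p_vegan - p_vegetarian``).  ``category_prevalence``, if
    set, overrides per-dish processed sampling with direct menu-level
    Bernoulli inclusion of each category.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    style: MenuStyle = MenuStyle.cyclical
    n_weeks: int = Field(default=1, ge=1, le=4)
    mains_per_slot: tuple[int, int] = (3, 5)
    n_smaller: int = Field(default=8, ge=1)
    p_vegan: float = Field(default=0.08, ge=0.0, le=1.0)
    p_vegetarian: float = Field(default=0.30, ge=0.0, le=1.0)
    p_ruminant: float = Field(default=0.18, ge=0.0, le=1.0)
    p_processed: float = Field(default=0.09, ge=0.0, le=1.0)
    p_vegan_smaller: float = Field(default=0.12, ge=0.0, le=1.0)
    p_vegetarian_smaller: float = Field(default=0.45, ge=0.0, le=1.0)
    p_negative_label: float = Field(default=0.35, ge=0.0, le=1.0)
    p_positive_label: float = Field(default=0.0, ge=0.0, le=1.0)
    p_meat_alternative: float = Field(default=0.10, ge=0.0, le=1.0)
    p_dairy_alternative: float = Field(default=0.08, ge=0.0, le=1.0)
    environmental_messaging: EnvironmentalMessaging = EnvironmentalMessaging.no
    vegan_first: bool = False
    daily_vegan_lunch: bool = False
    daily_vegan_dinner: bool = False
    smaller_meals_status: SmallerMealsStatus = SmallerMealsStatus.listed
    provider: Provider = Provider.unknown
    category_weights: Dict[ProcessedMeatCategory, float] = Field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_WEIGHTS))
    category_prevalence: Optional[Dict[ProcessedMeatCategory, float]] = None
    exact: Optional[ExactComposition] = None

    @model_validator(mode="after")
    def _feasible(self) -> "MenuProfile":
        lo, hi = self.mains_per_slot
        if not (1 <= lo <= hi):
            raise ValueError(f"mains_per_slot range {self.mains_per_slot} invalid")
        if self.p_vegan + self.p_vegetarian > 1.0 + 1e-12:
            raise ValueError("p_vegan + p_vegetarian must not exceed 1")
        p_omni = 1.0 - self.p_vegan - self.p_vegetarian
        for name in ("p_ruminant", "p_processed"):
            if getattr(self, name) > p_omni + 1e-12:
                raise ValueError(f"{name} exceeds the omnivorous share {p_omni:.3f}")
        if self.p_vegan_smaller + self.p_vegetarian_smaller > 1.0 + 1e-12:
            raise ValueError("p_vegan_smaller + p_vegetarian_smaller must not exceed 1")
        if self.exact is not None:
            if self.style is not MenuStyle.cyclical or self.n_weeks != 1:
                raise ValueError("exact-count mode requires a 1-week cyclical menu")
            if self.category_prevalence is not None:
                raise ValueError("category_prevalence is not supported in exact-count mode")
        return self

    def expected_percent_indicators(self) -> Dict[str, float]:
        """Expected values of the percentage indicators under this profile.

        Only defined for plain probabilistic profiles (no daily-vegan forcing,
        no category-prevalence overrides); the ruminant expectation refers to
        the *identity* mapping (the clamp is nonlinear, so its mean has no
        closed form).
        """
        if self.exact is not None:
            raise ValueError("exact-count profiles carry exact ground truth instead")
        if self.daily_vegan_lunch or self.daily_vegan_dinner or self.category_prevalence:
            raise ValueError("expectations undefined with forcing overrides active")
        out = {
            "pct_vegan_lunch": 100.0 * self.p_vegan,
            "pct_vegan_dinner": 100.0 * self.p_vegan,
            "pct_vegetarian_lunch": 100.0 * (self.p_vegan + self.p_vegetarian),
            "pct_vegetarian_dinner": 100.0 * (self.p_vegan + self.p_vegetarian),
            "ruminant_free_lunch": 100.0 * (1.0 - self.p_ruminant),
            "ruminant_free_dinner": 100.0 * (1.0 - self.p_ruminant),
        }
        if self.smaller_meals_status is SmallerMealsStatus.listed:
            out["pct_vegan_smaller"] = 100.0 * self.p_vegan_smaller
            out["pct_vegetarian_smaller"] = 100.0 * (
                self.p_vegan_smaller + self.p_vegetarian_smaller)
        return out


@dataclass
class _Dish:
    name: str
    cls: DietClass
    meat_alt: bool = False
    dairy_alt: bool = False
    neg_label: bool = False
    pos_label: bool = False


@dataclass(frozen=True)
class SyntheticMenu:
    """A generated menu plus its ground truth (exact-count mode only)."""

    menu: Menu
    ground_truth: Optional[IndicatorVector]
    profile: MenuProfile


def _pick(rng: np.random.Generator, pool_key: str) -> str:
    pool = TEMPLATES[pool_key]
    return pool[int(rng.integers(len(pool)))]


def _finalize_name(dish: _Dish) -> str:
    if dish.neg_label:
        tag = "Vegan" if dish.cls is DietClass.vegan else "Vegetarian"
        return f"{tag} {dish.name[0].lower()}{dish.name[1:]}"
    if dish.pos_label:
        return f"Plant-powered {dish.name[0].lower()}{dish.name[1:]}"
    return dish.name


def _dish_to_item(dish: _Dish, slot: Slot, day: Optional[int], position: int) -> MealItem:
    # annotations are intentionally left underived: the classifier fills them
    return MealItem(
        name=_finalize_name(dish),
        slot=slot,
        day=day,
        position=position,
        is_meat_alternative=dish.meat_alt,
        is_dairy_alternative=dish.dairy_alt,
        label_flags=LabelFlags(),
    )


class _LabelAssigner:
    """Hands out a fixed number of negative/positive labels to plant dishes
    in menu traversal order (exact-count mode)."""

    def __init__(self, n_neg: int, n_pos: int):
        self.n_neg = n_neg
        self.n_pos = n_pos

    def assign(self, dish: _Dish) -> None:
        if dish.cls is DietClass.omnivorous:
            return
        if self.n_neg > 0:
            dish.neg_label = True
            self.n_neg -= 1
        elif self.n_pos > 0:
            dish.pos_label = True
            self.n_pos -= 1


def _exact_day_dishes(
    counts: ExactSlotCounts, vegan_first: bool, rng: np.random.Generator,
    labels: _LabelAssigner,
) -> list[_Dish]:
    vegans = [_Dish(_pick(rng, "vegan"), DietClass.vegan)
              for _ in range(counts.vegan_per_day)]
    vegs = [_Dish(_pick(rng, "vegetarian"), DietClass.vegetarian_not_vegan)
            for _ in range(counts.vegetarian_per_day)]
    rums = [_Dish(_pick(rng, "ruminant"), DietClass.omnivorous)
            for _ in range(counts.ruminant_per_day)]
    # non-ruminant processed categories only, so ruminant counts stay analytic
    non_rum_weights = {c: w for c, w in DEFAULT_CATEGORY_WEIGHTS.items()
                       if c is not ProcessedMeatCategory.corned_beef}
    procs = []
    for _ in range(counts.processed_per_day):
        cat = _weighted_category(non_rum_weights, rng)
        procs.append(_Dish(_pick(rng, _PROCESSED_POOLS[cat]), DietClass.omnivorous))
    n_plain = counts.mains_per_day - len(vegans) - len(vegs) - len(rums) - len(procs)
    plains = [_Dish(_pick(rng, "plain_omni"), DietClass.omnivorous) for _ in range(n_plain)]
    if vegan_first:
        day = vegans + vegs + plains + procs + rums
    else:
        day = vegs + plains + rums + procs + vegans
    for dish in day:
        labels.assign(dish)
    return day


def _weighted_category(
    weights: Dict[ProcessedMeatCategory, float], rng: np.random.Generator
) -> ProcessedMeatCategory:
    cats = list(weights)
    p = np.asarray([weights[c] for c in cats], dtype=float)
    return cats[int(rng.choice(len(cats), p=p / p.sum()))]


def _draw_main(profile: MenuProfile, rng: np.random.Generator) -> _Dish:
    u = rng.random()
    if u < profile.p_vegan:
        dish = _Dish(_pick(rng, "vegan"), DietClass.vegan)
    elif u < profile.p_vegan + profile.p_vegetarian:
        dish = _Dish(_pick(rng, "vegetarian"), DietClass.vegetarian_not_vegan)
    else:
        # omnivorous: processed first (category by weights; corned beef is
        # also ruminant), then top the ruminant rate up among the remainder
        # so the p_ruminant marginal holds exactly
        p_omni = 1.0 - profile.p_vegan - profile.p_vegetarian
        b = (profile.p_processed / p_omni if p_omni > 0 else 0.0)
        if profile.category_prevalence is not None:
            b = 0.0  # processed items are inserted menu-wide instead
        rum_target = profile.p_ruminant / p_omni if p_omni > 0 else 0.0
        total_w = sum(profile.category_weights.values())
        w_cb = profile.category_weights.get(ProcessedMeatCategory.corned_beef, 0.0) / total_w
        if rng.random() < b:
            cat = _weighted_category(profile.category_weights, rng)
            return _Dish(_pick(rng, _PROCESSED_POOLS[cat]), DietClass.omnivorous)
        rum_rest = max(0.0, (rum_target - b * w_cb) / (1.0 - b)) if b < 1.0 else 0.0
        if rng.random() < rum_rest:
            return _Dish(_pick(rng, "ruminant"), DietClass.omnivorous)
        return _Dish(_pick(rng, "plain_omni"), DietClass.omnivorous)
    # plant dish: labelling and meat-alternative behaviour
    if rng.random() < profile.p_negative_label:
        dish.neg_label = True
    elif rng.random() < profile.p_positive_label:
        dish.pos_label = True
    if rng.random() < profile.p_meat_alternative:
        pool = "meat_alt" if dish.cls is DietClass.vegan else "meat_alt_vegetarian"
        dish.name = _pick(rng, pool)
        dish.meat_alt = True
    return dish


def _draw_smaller(profile: MenuProfile, rng: np.random.Generator) -> _Dish:
    u = rng.random()
    if u < profile.p_vegan_smaller:
        dish = _Dish(_pick(rng, "smaller_vegan"), DietClass.vegan)
    elif u < profile.p_vegan_smaller + profile.p_vegetarian_smaller:
        dish = _Dish(_pick(rng, "smaller_vegetarian"), DietClass.vegetarian_not_vegan)
    else:
        return _Dish(_pick(rng, "smaller_omni"), DietClass.omnivorous)
    if rng.random() < profile.p_negative_label:
        dish.neg_label = True
    elif rng.random() < profile.p_positive_label:
        dish.pos_label = True
    return dish


def _apply_category_prevalence(
    sections: dict[tuple[Optional[int], Slot], list[_Dish]],
    prevalence: Dict[ProcessedMeatCategory, float],
    rng: np.random.Generator,
) -> None:
    """Force menu-level inclusion/exclusion of each processed-meat category.

    Inclusion of each category is an independent Bernoulli draw, so measured
    cohort prevalences are exact binomial proportions of the requested ones.
    """
    def cats_of(dish: _Dish) -> frozenset:
        return detect_processed_meat(dish.name, DEFAULT_LEXICON)

    for cat in ProcessedMeatCategory:
        p = prevalence.get(cat)
        want = (rng.random() < p) if p is not None else False
        carriers = [d for sec in sections.values() for d in sec if cat in cats_of(d)]
        if want and not carriers:
            candidates = [
                d for sec in sections.values() for d in sec
                if d.cls is DietClass.omnivorous and not cats_of(d)
                and not detect_ruminant(d.name, DEFAULT_LEXICON)
            ]
            if candidates:
                target = candidates[int(rng.integers(len(candidates)))]
            else:  # no convertible main: grow the first section instead
                first_key = next(iter(sections))
                target = _Dish("placeholder", DietClass.omnivorous)
                sections[first_key].append(target)
            target.name = _pick(rng, _PROCESSED_POOLS[cat])
        elif not want:
            for d in carriers:
                d.name = _pick(rng, "plain_omni")


def generate_menu(
    profile: MenuProfile,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    hospital_id: str = "H001",
    trust_abbrev: str = "",
) -> SyntheticMenu:
    """Generate one schema-valid menu (and, in exact-count mode, its
    analytically derived ground-truth indicator vector)."""
    if rng is None:
        rng = np.random.default_rng(seed)

    sections: dict[tuple[Optional[int], Slot], list[_Dish]] = {}
    smaller: list[_Dish] = []

    if profile.exact is not None:
        labels = _LabelAssigner(profile.exact.neg_labelled_plant,
                                profile.exact.pos_labelled_plant)
        for day in range(1, 8):
            sections[(day, Slot.lunch_main)] = _exact_day_dishes(
                profile.exact.lunch, profile.vegan_first, rng, labels)
            sections[(day, Slot.dinner_main)] = _exact_day_dishes(
                profile.exact.dinner, profile.vegan_first, rng, labels)
        if (profile.exact.smaller is not None
                and profile.smaller_meals_status is SmallerMealsStatus.listed):
            sm = profile.exact.smaller
            smaller = (
                [_Dish(_pick(rng, "smaller_vegan"), DietClass.vegan) for _ in range(sm.vegan)]
                + [_Dish(_pick(rng, "smaller_vegetarian"), DietClass.vegetarian_not_vegan)
                   for _ in range(sm.vegetarian)]
                + [_Dish(_pick(rng, "smaller_omni"), DietClass.omnivorous)
                   for _ in range(sm.n - sm.vegan - sm.vegetarian)]
            )
            for dish in smaller:
                labels.assign(dish)
        ground_truth: Optional[IndicatorVector] = exact_ground_truth(profile)
    else:
        days: Sequence[Optional[int]]
        if profile.style is MenuStyle.cyclical:
            days = list(range(1, 7 * profile.n_weeks + 1))
        else:
            days = [None]
        n_per_slot = {
            slot: int(rng.integers(profile.mains_per_slot[0], profile.mains_per_slot[1] + 1))
            for slot in (Slot.lunch_main, Slot.dinner_main)
        }
        for day in days:
            for slot in (Slot.lunch_main, Slot.dinner_main):
                sec = [_draw_main(profile, rng) for _ in range(n_per_slot[slot])]
                force = (profile.daily_vegan_lunch if slot is Slot.lunch_main
                         else profile.daily_vegan_dinner)
                if force and not any(d.cls is DietClass.vegan for d in sec):
                    sec[int(rng.integers(len(sec)))] = _Dish(
                        _pick(rng, "vegan"), DietClass.vegan)
                if profile.vegan_first:
                    sec.sort(key=lambda d: d.cls is not DietClass.vegan)
                sections[(day, slot)] = sec
        if profile.category_prevalence is not None:
            _apply_category_prevalence(sections, profile.category_prevalence, rng)
        if profile.smaller_meals_status is SmallerMealsStatus.listed:
            smaller = [_draw_smaller(profile, rng) for _ in range(profile.n_smaller)]
            if rng.random() < profile.p_dairy_alternative:
                smaller.append(_Dish(_pick(rng, "dairy_alt"), DietClass.vegan, dairy_alt=True))
        ground_truth = None

    items: list[MealItem] = []
    for (day, slot), sec in sections.items():
        for pos, dish in enumerate(sec, start=1):
            items.append(_dish_to_item(dish, slot, day, pos))
    for pos, dish in enumerate(smaller, start=1):
        items.append(_dish_to_item(dish, Slot.smaller, None, pos))

    menu = Menu(
        hospital_id=hospital_id,
        trust_abbrev=trust_abbrev,
        provider=profile.provider,
        style=profile.style,
        n_weeks=profile.n_weeks if profile.style is MenuStyle.cyclical else None,
        environmental_messaging=profile.environmental_messaging,
        smaller_meals_status=profile.smaller_meals_status,
        items=tuple(items),
    )
    return SyntheticMenu(menu=menu, ground_truth=ground_truth, profile=profile)


def _band(labelled: int, total: int, threshold: float) -> str:
    if labelled == 0:
        return "none"
    if 100 * labelled > threshold * total:
        return "regular"
    return "sometimes"


def exact_ground_truth(
    profile: MenuProfile, options: ExtractionOptions = ExtractionOptions()
) -> IndicatorVector:
    """Indicator vector implied analytically by an exact-count profile."""
    ex = profile.exact
    if ex is None:
        raise ValueError("profile has no exact composition")

    def slot_truth(c: ExactSlotCounts) -> dict:
        n, k_veg, k_vg = c.mains_per_day, c.vegetarian_per_day, c.vegan_per_day
        without_rum = n - c.ruminant_per_day
        if options.ruminant_mapping == "identity":
            rum = 100.0 * without_rum / n
        else:
            rum = max(0.0, (300 * without_rum - 200 * n) / n)
        first_vegan = k_vg >= 1 and (profile.vegan_first or k_vg == n)
        return {
            "bo": 100.0 if k_vg >= 1 else 0.0,
            "pvg": 100.0 * k_vg / n,
            "pveg": 100.0 * (k_vg + k_veg) / n,
            "rum": rum,
            "first_vegan": first_vegan,
        }

    lunch, dinner = slot_truth(ex.lunch), slot_truth(ex.dinner)

    if ex.smaller is not None and profile.smaller_meals_status is SmallerMealsStatus.listed:
        pvg_s: Optional[float] = 100.0 * ex.smaller.vegan / ex.smaller.n
        pveg_s: Optional[float] = 100.0 * (ex.smaller.vegan + ex.smaller.vegetarian) / ex.smaller.n
    else:
        pvg_s = pveg_s = None

    env = {
        EnvironmentalMessaging.yes: 100.0,
        EnvironmentalMessaging.partial: 50.0,
        EnvironmentalMessaging.no: 0.0,
        EnvironmentalMessaging.unknown: None,
    }[profile.environmental_messaging]

    n_plant = ex.n_plant_dishes()
    if n_plant == 0:
        pos_l = neg_l = None
    else:
        pos_l = {"none": 0.0, "sometimes": 50.0, "regular": 100.0}[
            _band(ex.pos_labelled_plant, n_plant, options.label_threshold)]
        neg_l = {"none": 100.0, "sometimes": 50.0, "regular": 0.0}[
            _band(ex.neg_labelled_plant, n_plant, options.label_threshold)]

    return IndicatorVector(
        base_offer_lunch=lunch["bo"],
        base_offer_dinner=dinner["bo"],
        pct_vegan_lunch=lunch["pvg"],
        pct_vegan_dinner=dinner["pvg"],
        pct_vegetarian_lunch=lunch["pveg"],
        pct_vegetarian_dinner=dinner["pveg"],
        ruminant_free_lunch=lunch["rum"],
        ruminant_free_dinner=dinner["rum"],
        pct_vegan_smaller=pvg_s,
        pct_vegetarian_smaller=pveg_s,
        env_descriptors=env,
        vegan_first=100.0 if (lunch["first_vegan"] and dinner["first_vegan"]) else 0.0,
        positive_labels=pos_l,
        no_negative_labels=neg_l,
    )


# ---------------------------------------------------------------------------
# Cohorts


def _allocate(counts: Dict, n: int) -> list:
    """Scale integer counts to n by largest remainder, preserving order."""
    total = sum(counts.values())
    exact = {k: n * v / total for k, v in counts.items()}
    base = {k: int(np.floor(e)) for k, e in exact.items()}
    short = n - sum(base.values())
    by_frac = sorted(counts, key=lambda k: exact[k] - base[k], reverse=True)
    for k in by_frac[:short]:
        base[k] += 1
    out = []
    for k, c in base.items():
        out.extend([k] * c)
    return out


def study_cohort_profiles(n: int, rng: np.random.Generator) -> list[MenuProfile]:
    """Profiles emulating the audited cohort's composition.

    Provider mix 17 in-house / 14 contracted / 3 mixed / 2 unknown (scaled to
    ``n``), smaller-meals availability 31 listed / 2 ward-based / 3 not
    listed, 7-day cyclical menus (a quarter on a 2-week cycle), sparse vegan
    provision with roughly half of hospitals offering none, frequent negative
    labelling, rare positive labelling, environmental messaging and
    vegan-first positioning.
    """
    providers = _allocate(
        {Provider.in_house: 17, Provider.contracted: 14, Provider.mixed: 3,
         Provider.unknown: 2}, n)
    statuses = _allocate(
        {SmallerMealsStatus.listed: 31, SmallerMealsStatus.ward_based_unassessable: 2,
         SmallerMealsStatus.not_listed: 3}, n)
    rng.shuffle(providers)
    rng.shuffle(statuses)

    profiles = []
    for provider, status in zip(providers, statuses):
        p_vegan = 0.0 if rng.random() < 0.45 else float(rng.uniform(0.03, 0.20))
        p_veg = float(rng.uniform(0.15, 0.45))
        p_omni = 1.0 - p_vegan - p_veg
        env_u = rng.random()
        profiles.append(MenuProfile(
            n_weeks=2 if rng.random() < 0.25 else 1,
            mains_per_slot=(3, 5),
            n_smaller=int(rng.integers(6, 11)),
            p_vegan=p_vegan,
            p_vegetarian=p_veg,
            p_ruminant=min(float(rng.uniform(0.08, 0.40)), p_omni),
            p_processed=min(float(rng.uniform(0.02, 0.16)), p_omni),
            p_vegan_smaller=float(rng.uniform(0.0, 0.25)),
            p_vegetarian_smaller=float(rng.uniform(0.20, 0.60)),
            p_negative_label=0.0 if rng.random() < 0.30 else float(rng.uniform(0.2, 0.8)),
            p_positive_label=0.0 if rng.random() < 0.90 else float(rng.uniform(0.05, 0.30)),
            environmental_messaging=(
                EnvironmentalMessaging.yes if env_u < 0.03
                else EnvironmentalMessaging.partial if env_u < 0.09
                else EnvironmentalMessaging.no),
            vegan_first=bool(rng.random() < 0.08),
            daily_vegan_lunch=bool(rng.random() < 0.19),
            daily_vegan_dinner=bool(rng.random() < 0.22),
            smaller_meals_status=status,
            provider=provider,
        ))
    return profiles


def generate_cohort(
    n: int,
    seed: int,
    profile: Optional[MenuProfile] = None,
    profiles: Optional[Sequence[MenuProfile]] = None,
    sampler: Optional[Callable[[int, np.random.Generator], list[MenuProfile]]] = None,
) -> list[SyntheticMenu]:
    """Generate a reproducible cohort of ``n`` menus.

    Exactly one source of profiles applies: an explicit ``profiles`` list, a
    single ``profile`` reused for every hospital, or a ``sampler`` drawing
    per-hospital profiles (default: :func:`study_cohort_profiles`).  The root
    seed is fanned out with ``SeedSequence`` — one independent stream per
    hospital — so the same seed yields a byte-identical cohort.
    """
    if n < 1:
        raise ValueError("cohort size must be at least 1")
    root = np.random.SeedSequence(seed)
    sampler_seq, *menu_seqs = root.spawn(n + 1)
    if profiles is not None:
        if len(profiles) != n:
            raise ValueError(f"{len(profiles)} profiles supplied for a cohort of {n}")
        chosen = list(profiles)
    elif profile is not None:
        chosen = [profile] * n
    else:
        chosen = (sampler or study_cohort_profiles)(n, np.random.default_rng(sampler_seq))
    return [
        generate_menu(
            prof,
            rng=np.random.default_rng(seq),
            hospital_id=f"H{i + 1:03d}",
            trust_abbrev=f"TR{i + 1:02d}",
        )
        for i, (prof, seq) in enumerate(zip(chosen, menu_seqs))
    ]


def cohort_manifest(cohort: Sequence[SyntheticMenu]) -> dict:
    """JSON-serializable manifest of per-hospital ground truths."""
    return {
        "n": len(cohort),
        "hospitals": [
            {
                "hospital_id": sm.menu.hospital_id,
                "trust_abbrev": sm.menu.trust_abbrev,
                "provider": sm.menu.provider.value,
                "style": sm.menu.style.value,
                "smaller_meals_status": sm.menu.smaller_meals_status.value,
                "n_items": len(sm.menu.items),
                "ground_truth": None if sm.ground_truth is None else sm.ground_truth.as_dict(),
            }
            for sm in cohort
        ],
    }


def write_cohort(cohort: Sequence[SyntheticMenu], outdir: str | Path) -> Path:
    """Write each menu as ``<hospital_id>.json`` plus ``manifest.json``."""
    from .model import write_menu

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sm in cohort:
        write_menu(sm.menu, outdir / f"{sm.menu.hospital_id}.json")
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(
        json.dumps(cohort_manifest(cohort), indent=2, ensure_ascii=False) + "\n",
        encoding="utf-8")
    return manifest_path


def worked_example_menu() -> SyntheticMenu:
    """The documented worked example: a 7-day cyclical menu, two mains per
    slot (one vegan, one vegetarian, no ruminant meat), four smaller meals
    (two vegan, two vegetarian), every vegan dish negatively labelled, the
    vegetarian dish always listed first, and no environmental messaging.

    Indicator values: base offers 100/100, vegan mains 50/50, vegetarian
    mains 100/100, ruminant-free 100/100, smaller meals 50/100, presentation
    all 0 — giving subscores 80, 66.67, 0 and a final score of 51.1.
    """
    profile = MenuProfile(
        exact=ExactComposition(
            lunch=ExactSlotCounts(mains_per_day=2, vegan_per_day=1, vegetarian_per_day=1),
            dinner=ExactSlotCounts(mains_per_day=2, vegan_per_day=1, vegetarian_per_day=1),
            smaller=ExactSmallerCounts(n=4, vegan=2, vegetarian=2),
            # 16 of 32 plant dishes negatively labelled: regular use, score 0
            neg_labelled_plant=16,
        ),
        environmental_messaging=EnvironmentalMessaging.no,
        vegan_first=False,
        provider=Provider.in_house,
    )
    sm = generate_menu(profile, seed=20240001, hospital_id="WORKED_A", trust_abbrev="WEA")
    return sm
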