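"""Indicator extraction: value mappings, boundaries, missing-data semantics."""

import pytest

from plantforward.indicators import (
    ExtractionOptions,
    IndicatorVector,
    base_offer,
    environmental_descriptor_indicator,
    extract_indicators,
    label_use_indicator,
    percent_class_mains,
    positioning_indicator,
    ruminant_indicator,
    smaller_meal_percents,
)
from plantforward.model import (
    EnvironmentalMessaging,
    MenuStyle,
    Slot,
    SmallerMealsStatus,
)

from conftest import build_menu

IDENTITY = ExtractionOptions(ruminant_mapping="identity")


# --- base offer -------------------------------------------------------------

def test_base_offer_daily_vegan_scores_100():
    menu = build_menu(lunch=[["vegan", "omni"]] * 7)
    assert base_offer(menu, Slot.lunch_main) == 100.0


def test_base_offer_six_of_seven_days_scores_0():
    menu = build_menu(lunch=[["vegan"]] * 6 + [["omni"]])
    assert base_offer(menu, Slot.lunch_main) == 0.0


def test_base_offer_a_la_carte_standing_vegan_counts_daily():
    menu = build_menu(lunch=[["vegan", "omni"]], style=MenuStyle.a_la_carte)
    assert base_offer(menu, Slot.lunch_main) == 100.0
    strict = ExtractionOptions(a_la_carte_always_available=False)
    assert base_offer(menu, Slot.lunch_main, strict) == 0.0


def test_base_offer_missing_when_slot_empty():
    menu = build_menu(lunch=[["vegan"]] * 7)  # no dinner section at all
    assert base_offer(menu, Slot.dinner_main) is None


# --- percentage indicators --------------------------------------------------

def test_percent_vegan_quarter_of_mains():
    """7 vegan of 28 lunch mains → 25.0 (one vegan among four mains daily)."""
    menu = build_menu(lunch=[["vegan", "omni", "omni", "omni"]] * 7)
    assert percent_class_mains(menu, Slot.lunch_main, "vegan") == 25.0


def test_percent_vegetarian_includes_vegan():
    menu = build_menu(lunch=[["vegan", "veg", "omni", "omni"]] * 7)
    assert percent_class_mains(menu, Slot.lunch_main, "vegan") == 25.0
    assert percent_class_mains(menu, Slot.lunch_main, "vegetarian") == 50.0


@pytest.mark.parametrize("specs, vegan_pct", [
    ([["vegan"]] * 7, 100.0),
    ([["omni", "omni"]] * 7, 0.0),
])
def test_percent_vegan_extremes(specs, vegan_pct):
    menu = build_menu(lunch=specs)
    assert percent_class_mains(menu, Slot.lunch_main, "vegan") == vegan_pct


def test_percent_missing_without_mains():
    menu = build_menu(lunch=[["omni"]] * 7)
    assert percent_class_mains(menu, Slot.dinner_main, "vegan") is None


# --- ruminant indicator -----------------------------------------------------

def test_ruminant_free_slot_scores_100_under_both_mappings():
    menu = build_menu(lunch=[["vegan", "omni", "omni"]] * 7)
    assert ruminant_indicator(menu, Slot.lunch_main, "clamped") == 100.0
    assert ruminant_indicator(menu, Slot.lunch_main, "identity") == 100.0


def test_one_third_ruminant_scores_exactly_zero_clamped():
    menu = build_menu(lunch=[["rum", "omni", "omni"]] * 7)
    assert ruminant_indicator(menu, Slot.lunch_main, "clamped") == 0.0
    assert ruminant_indicator(menu, Slot.lunch_main, "identity") == pytest.approx(200 / 3)


def test_one_of_nine_ruminant_clamped():
    """r = 88.89 → 3r − 200 = 66.67 under the clamp."""
    menu = build_menu(lunch=[["rum"] + ["omni"] * 8])
    assert ruminant_indicator(menu, Slot.lunch_main, "clamped") == pytest.approx(200 / 3)


def test_clamped_never_exceeds_identity():
    """Enumerate all compositions up to 12 mains on a one-day menu."""
    for n in range(1, 13):
        for k in range(n + 1):
            menu = build_menu(lunch=[["rum"] * k + ["omni"] * (n - k)])
            clamped = ruminant_indicator(menu, Slot.lunch_main, "clamped")
            identity = ruminant_indicator(menu, Slot.lunch_main, "identity")
            assert clamped <= identity + 1e-12
            if k == 0:
                assert clamped == identity == 100.0


# --- smaller meals ----------------------------------------------------------

def test_smaller_meal_percents_counts_vegan_within_vegetarian():
    """10 smaller meals, 2 vegan + 3 vegetarian → (20, 50)."""
    menu = build_menu(lunch=[["omni"]] * 7,
                      smaller=["vegan"] * 2 + ["veg"] * 3 + ["omni"] * 5)
    assert smaller_meal_percents(menu) == (20.0, 50.0)


def test_smaller_meals_missing_when_unassessable():
    menu = build_menu(lunch=[["omni"]] * 7,
                      smaller_meals_status=SmallerMealsStatus.ward_based_unassessable)
    assert smaller_meal_percents(menu) == (None, None)


def test_all_vegan_smaller_meals():
    menu = build_menu(lunch=[["omni"]] * 7, smaller=["vegan"] * 3)
    assert smaller_meal_percents(menu) == (100.0, 100.0)


# --- presentation indicators ------------------------------------------------

@pytest.mark.parametrize("menu_flag, expected", [
    (EnvironmentalMessaging.yes, 100.0),
    (EnvironmentalMessaging.partial, 50.0),
    (EnvironmentalMessaging.no, 0.0),
    (EnvironmentalMessaging.unknown, None),
])
def test_environmental_descriptor_menu_level(menu_flag, expected):
    menu = build_menu(lunch=[["omni"]] * 7, environmental_messaging=menu_flag)
    assert environmental_descriptor_indicator(menu) == expected


def test_environmental_descriptor_item_level_is_partial():
    menu = build_menu(lunch=[["omni"]] * 7,
                      environmental_messaging=EnvironmentalMessaging.unknown)
    flagged = menu.items[0].model_copy(update={
        "label_flags": menu.items[0].label_flags.model_copy(
            update={"environmental_messaging": EnvironmentalMessaging.yes})})
    menu = menu.model_copy(update={"items": (flagged,) + menu.items[1:]})
    assert environmental_descriptor_indicator(menu) == 50.0


def test_positioning_requires_vegan_first_in_every_section():
    everywhere = build_menu(lunch=[["vegan", "omni"]] * 7, dinner=[["vegan", "omni"]] * 7)
    assert positioning_indicator(everywhere) == 100.0
    lunch_only = build_menu(lunch=[["vegan", "omni"]] * 7, dinner=[["omni", "vegan"]] * 7)
    assert positioning_indicator(lunch_only) == 0.0
    no_vegan = build_menu(lunch=[["omni"]] * 7)
    assert positioning_indicator(no_vegan) == 0.0


@pytest.mark.parametrize("labelled, total, positive, negative", [
    (0, 10, 0.0, 100.0),      # no use
    (1, 10, 50.0, 50.0),      # 10 %: sometimes
    (2, 10, 50.0, 50.0),      # exactly 20 %: still the sometimes band
    (3, 10, 100.0, 0.0),      # 30 %: regular use
    (10, 10, 100.0, 0.0),
])
def test_label_bands(labelled, total, positive, negative):
    pos_specs = ["vegan+pos"] * labelled + ["vegan"] * (total - labelled)
    neg_specs = ["vegan+neg"] * labelled + ["vegan"] * (total - labelled)
    pos_menu = build_menu(lunch=[["omni"]] * 7, smaller=pos_specs)
    neg_menu = build_menu(lunch=[["omni"]] * 7, smaller=neg_specs)
    assert label_use_indicator(pos_menu, "positive") == positive
    assert label_use_indicator(neg_menu, "negative") == negative


def test_label_indicator_missing_without_plant_dishes():
    menu = build_menu(lunch=[["omni"]] * 7, smaller=["omni"] * 3)
    assert label_use_indicator(menu, "positive") is None
    assert label_use_indicator(menu, "negative") is None


# --- assembly ---------------------------------------------------------------

def test_extract_propagates_smaller_meal_missingness():
    menu = build_menu(lunch=[["vegan", "omni"]] * 7, dinner=[["vegan", "omni"]] * 7,
                      smaller_meals_status=SmallerMealsStatus.not_listed)
    iv = extract_indicators(menu)
    values = iv.as_dict()
    assert values["pct_vegan_smaller"] is None
    assert values["pct_vegetarian_smaller"] is None
    missing = [k for k, v in values.items() if v is None]
    assert missing == ["pct_vegan_smaller", "pct_vegetarian_smaller"]


def test_all_vegan_perfect_nudging_menu_scores_100_everywhere():
    menu = build_menu(
        lunch=[["vegan+pos"]] * 7, dinner=[["vegan+pos"]] * 7,
        smaller=["vegan"] * 4,
        environmental_messaging=EnvironmentalMessaging.yes,
    )
    assert all(v == 100.0 for v in extract_indicators(menu).as_dict().values())


def test_vegan_percentage_never_exceeds_vegetarian():
    from plantforward.classify import annotate_menu
    from plantforward.synthetic import generate_cohort

    for sm in generate_cohort(20, seed=99):
        menu = annotate_menu(sm.menu)
        for slot in (Slot.lunch_main, Slot.dinner_main):
            vg = percent_class_mains(menu, slot, "vegan")
            veg = percent_class_mains(menu, slot, "vegetarian")
            if vg is not None:
                assert vg <= veg


def test_indicator_vector_rejects_out_of_range():
    with pytest.raises(ValueError):
        IndicatorVector(pct_vegan_lunch=120.0)
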