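"""Subscore/final-score aggregation, missing-data rules, end-to-end scoring."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from plantforward.indicators import INDICATOR_GROUPS, IndicatorVector
from plantforward.model import EnvironmentalMessaging
from plantforward.scoring import (
    DEFAULT_SCHEME,
    WeightScheme,
    available_weight_fraction,
    final_score,
    load_weight_scheme,
    round_half_away,
    score_menu,
    subscore,
)

from conftest import build_menu, oracle_final, oracle_subscore, random_indicator_vector


def _main_vector(**overrides):
    base = dict(
        base_offer_lunch=100.0, base_offer_dinner=100.0,
        pct_vegan_lunch=50.0, pct_vegan_dinner=50.0,
        pct_vegetarian_lunch=100.0, pct_vegetarian_dinner=100.0,
        ruminant_free_lunch=100.0, ruminant_free_dinner=100.0,
    )
    base.update(overrides)
    return IndicatorVector(**base)


def test_main_meals_subscore_hand_computed():
    """(0.5·100·2 + 1·50·2 + 0.5·100·2 + 0.5·100·2) / 5 = 80."""
    assert subscore(_main_vector(), "main_meals") == pytest.approx(80.0)


def test_smaller_meals_subscore_hand_computed():
    iv = IndicatorVector(pct_vegan_smaller=50.0, pct_vegetarian_smaller=100.0)
    assert subscore(iv, "smaller_meals") == pytest.approx(200 / 3)


def test_presentation_subscore_missing_below_half_weight():
    """posD and posit missing leaves weight 1 of 3 — below the bar."""
    iv = IndicatorVector(positive_labels=100.0, no_negative_labels=100.0)
    assert available_weight_fraction(iv, "menu_presentation") == pytest.approx(1 / 3)
    assert subscore(iv, "menu_presentation") is None


def test_presentation_subscore_computed_at_exactly_half_weight():
    """The availability threshold is inclusive: exactly half is enough."""
    iv = IndicatorVector(env_descriptors=100.0, positive_labels=0.0)
    assert available_weight_fraction(iv, "menu_presentation") == pytest.approx(0.5)
    assert subscore(iv, "menu_presentation") == pytest.approx(100 * 1.0 / 1.5)


def test_final_score_hand_computed():
    assert final_score({"main_meals": 100.0, "smaller_meals": 100.0,
                        "menu_presentation": 100.0}) == 100.0
    got = final_score({"main_meals": 80.0, "smaller_meals": 200 / 3,
                       "menu_presentation": 0.0})
    assert round_half_away(got, 1) == 51.1


def test_final_score_renormalizes_over_present_subscores():
    subs = {"main_meals": 80.0, "smaller_meals": None, "menu_presentation": 30.0}
    assert final_score(subs) == pytest.approx((3 * 80 + 2 * 30) / 5)
    assert final_score(subs, renormalize=False) is None
    assert final_score({g: None for g in INDICATOR_GROUPS}) is None


def test_subscore_and_final_match_bruteforce_oracle(rng):
    for _ in range(300):
        iv = random_indicator_vector(rng)
        subs = {}
        for group, names in INDICATOR_GROUPS.items():
            expected = oracle_subscore(iv.as_dict(), DEFAULT_SCHEME.indicator_weights,
                                       names, DEFAULT_SCHEME.availability_threshold)
            got = subscore(iv, group)
            assert (got is None) == (expected is None)
            if expected is not None:
                assert got == pytest.approx(expected, abs=1e-9)
            subs[group] = got
        expected_final = oracle_final(subs, DEFAULT_SCHEME.final_weights)
        got_final = final_score(subs)
        if expected_final is None:
            assert got_final is None
        else:
            assert got_final == pytest.approx(expected_final, abs=1e-9)


@given(st.floats(min_value=0.0, max_value=100.0),
       st.integers(min_value=0, max_value=2 ** 14 - 1))
def test_degenerate_conservation(c, missing_mask):
    """If every present indicator equals c, all computable scores equal c."""
    from plantforward.indicators import INDICATOR_NAMES

    values = {
        name: (None if (missing_mask >> i) & 1 else c)
        for i, name in enumerate(INDICATOR_NAMES)
    }
    iv = IndicatorVector(**values)
    subs = {g: subscore(iv, g) for g in INDICATOR_GROUPS}
    for v in subs.values():
        if v is not None:
            assert v == pytest.approx(c)
    fv = final_score(subs)
    if fv is not None:
        assert fv == pytest.approx(c)


@given(st.floats(min_value=1e-3, max_value=1e3))
def test_weight_scaling_invariance(factor):
    """Scaling one group's weights by a constant leaves its subscore fixed."""
    iv = IndicatorVector(pct_vegan_smaller=37.0, pct_vegetarian_smaller=81.0)
    weights = dict(DEFAULT_SCHEME.indicator_weights)
    for name in INDICATOR_GROUPS["smaller_meals"]:
        weights[name] *= factor
    scaled = WeightScheme(indicator_weights=weights)
    assert subscore(iv, "smaller_meals", scaled) == pytest.approx(
        subscore(iv, "smaller_meals"))


def test_scores_stay_in_bounds(rng):
    for _ in range(500):
        iv = random_indicator_vector(rng, p_missing=float(rng.uniform(0, 0.9)))
        subs = {g: subscore(iv, g) for g in INDICATOR_GROUPS}
        for v in list(subs.values()) + [final_score(subs)]:
            if v is not None:
                assert 0.0 <= v <= 100.0


def test_weight_scheme_validation():
    with pytest.raises(ValueError):
        WeightScheme(indicator_weights={**DEFAULT_SCHEME.indicator_weights,
                                        "pct_vegan_lunch": 0.0})
    with pytest.raises(ValueError):
        WeightScheme(final_weights={"main_meals": 3.0})
    with pytest.raises(ValueError):
        WeightScheme(availability_threshold=0.0)


def test_weight_scheme_file_round_trip(tmp_path):
    path = tmp_path / "scheme.yaml"
    path.write_text("final_weights: {main_meals: 4, smaller_meals: 1, menu_presentation: 1}\n"
                    "availability_threshold: 0.75\n")
    scheme = load_weight_scheme(path)
    assert scheme.final_weights["main_meals"] == 4.0
    assert scheme.availability_threshold == 0.75
    assert scheme.indicator_weights == DEFAULT_SCHEME.indicator_weights


@pytest.mark.parametrize("x, ndigits, expected", [
    (0.5, 0, 1.0), (1.5, 0, 2.0), (-0.5, 0, -1.0),
    (51.111, 0, 51.0), (51.15, 1, 51.2), (460 / 9, 1, 51.1),
])
def test_round_half_away(x, ndigits, expected):
    assert round_half_away(x, ndigits) == expected


def test_score_menu_perfect_menu_scores_100():
    menu = build_menu(
        lunch=[["vegan+pos"]] * 7, dinner=[["vegan+pos"]] * 7,
        smaller=["vegan"] * 4,
        environmental_messaging=EnvironmentalMessaging.yes,
    )
    report = score_menu(menu)
    assert report.final == 100.0
    assert all(v == 100.0 for v in report.subscores.values())


def test_score_menu_worst_menu_scores_0():
    menu = build_menu(
        lunch=[["rum", "rum", "omni"]] * 7, dinner=[["rum", "omni"]] * 7,
        smaller=["omni"] * 4,
        environmental_messaging=EnvironmentalMessaging.no,
    )
    report = score_menu(menu)
    assert report.final == 0.0
    # no plant dishes: both label indicators missing, yet presentation still
    # carries 2/3 of its weight and computes
    assert report.available_weight_fraction["menu_presentation"] == pytest.approx(2 / 3)


def test_score_report_serialization(tmp_path, worked_example):
    report = score_menu(worked_example.menu)
    path = tmp_path / "report.json"
    report.to_json(path)
    import json

    payload = json.loads(path.read_text())
    assert payload["rounded"]["final"] == 51.0
    row = report.flat_row()
    assert row["final"] == pytest.approx(460 / 9)
    assert row["pct_vegan_lunch"] == 50.0
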