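"""Cohort analytics: ranking, distributions, provider comparison, prevalence."""

import numpy as np
import pytest

from plantforward.cohort import (
    alternatives_prevalence,
    distribution_summary,
    group_comparison,
    processed_meat_prevalence,
    rank_cohort,
    reports_frame,
)
from plantforward.indicators import IndicatorVector
from plantforward.model import Provider
from plantforward.scoring import DEFAULT_SCHEME, ScoreReport, score_menu

from conftest import build_menu


def _report(hospital_id, final, main=50.0, provider=Provider.in_house):
    subs = {"main_meals": main, "smaller_meals": 50.0, "menu_presentation": 50.0}
    return ScoreReport(
        hospital_id=hospital_id, trust_abbrev=hospital_id[:3], provider=provider,
        indicators=IndicatorVector(pct_vegan_lunch=final),
        subscores=subs, final=final,
        available_weight_fraction={g: 1.0 for g in subs},
    )


def test_ranking_sorts_by_final_descending():
    reports = [_report("A", 38.0), _report("B", 9.0), _report("C", 20.0)]
    table = rank_cohort(reports).table
    assert list(table["final"]) == [38.0, 20.0, 9.0]
    assert list(table["rank"]) == [1, 2, 3]


def test_ranking_tie_break_on_main_meals_then_id():
    reports = [_report("B", 20.0, main=60.0), _report("A", 20.0, main=80.0),
               _report("C", 20.0, main=60.0)]
    table = rank_cohort(reports).table
    assert list(table["hospital_id"]) == ["A", "B", "C"]


def test_single_report_summary_degenerates_to_its_values():
    cs = rank_cohort([_report("A", 33.0)])
    assert cs.summary.loc["min", "final"] == 33.0
    assert cs.summary.loc["mean", "final"] == 33.0
    assert cs.summary.loc["max", "final"] == 33.0


def test_rank_empty_cohort_raises():
    with pytest.raises(ValueError):
        rank_cohort([])


def test_histogram_half_open_bins():
    """Finals {9, 15, 20, 38} with width 10: 20 falls in the 20–30 bin."""
    reports = [_report(s, v) for s, v in zip("ABCD", [9.0, 15.0, 20.0, 38.0])]
    hist = distribution_summary(reports, bin_width=10)["final"]
    assert list(hist.counts[:4]) == [1, 1, 1, 1]
    assert hist.counts.sum() == 4
    # the boundary value 20 lands in the 20–30 bin, not 10–20
    assert hist.edges[2] == 20.0 and hist.counts[2] == 1
    assert hist.n_missing == 0


def test_histogram_top_bin_is_closed():
    reports = [_report(s, 100.0) for s in "AB"]
    hist = distribution_summary(reports, bin_width=10)["final"]
    assert hist.counts[-1] == 2
    assert hist.counts.sum() == 2


def test_histogram_reports_missing_separately():
    reports = [_report("A", 10.0)]
    broken = ScoreReport(
        hospital_id="B", trust_abbrev="B", provider=Provider.in_house,
        indicators=IndicatorVector(),
        subscores={g: None for g in DEFAULT_SCHEME.groups}, final=None,
        available_weight_fraction={g: 0.0 for g in DEFAULT_SCHEME.groups},
    )
    hist = distribution_summary(reports + [broken], bin_width=20)["final"]
    assert hist.counts.sum() == 1
    assert hist.n_missing == 1


def test_histogram_counts_sum_matches_non_missing(rng):
    from plantforward.synthetic import generate_cohort

    reports = [score_menu(sm.menu) for sm in generate_cohort(24, seed=8)]
    for col, hist in distribution_summary(reports, bin_width=5).items():
        assert hist.counts.sum() + hist.n_missing == len(reports)


def test_bin_width_must_divide_100():
    with pytest.raises(ValueError):
        distribution_summary([_report("A", 10.0)], bin_width=30)


def test_group_comparison_means_and_unknown_exclusion():
    reports = [
        _report("A", 10.0, provider=Provider.in_house),
        _report("B", 22.0, provider=Provider.in_house),
        _report("C", 30.0, provider=Provider.contracted),
        _report("D", 99.0, provider=Provider.unknown),
    ]
    means = group_comparison(reports)
    assert means.loc["in_house", "final"] == pytest.approx(16.0)
    assert means.loc["contracted", "final"] == pytest.approx(30.0)
    assert "unknown" not in means.index
    assert means["n"].sum() == 3


def test_cohort_mean_reconstructs_from_group_means():
    reports = [
        _report("A", 10.0, provider=Provider.in_house),
        _report("B", 22.0, provider=Provider.in_house),
        _report("C", 30.0, provider=Provider.contracted),
    ]
    means = group_comparison(reports)
    weighted = (means["final"] * means["n"]).sum() / means["n"].sum()
    assert weighted == pytest.approx(reports_frame(reports)["final"].mean())


def test_processed_meat_prevalence_by_category():
    with_sausage = build_menu(lunch=[["proc:sausage", "omni"]] * 7)
    without = build_menu(lunch=[["omni", "omni"]] * 7, hospital_id="B")
    prev = processed_meat_prevalence([with_sausage, without])
    assert prev.by_category["sausage"] == 0.5
    assert prev.by_category["ham"] == 0.0
    assert prev.mean_items == pytest.approx(3.5)
    assert (prev.min_items, prev.max_items) == (0, 7)


def test_processed_meat_every_day_requires_all_seven_days():
    six_days = build_menu(lunch=[["proc:ham"]] * 6 + [["omni"]])
    seven_days = build_menu(lunch=[["proc:ham"]] * 7, hospital_id="B")
    prev = processed_meat_prevalence([six_days, seven_days])
    assert prev.every_day_fraction == 0.5


def test_processed_meat_standing_smaller_item_covers_every_day():
    menu = build_menu(lunch=[["omni"]] * 7, smaller=["proc:ham", "vegan"])
    assert processed_meat_prevalence([menu]).every_day_fraction == 1.0


def test_prevalence_invariant_to_menu_order(rng):
    from plantforward.synthetic import generate_cohort

    menus = [sm.menu for sm in generate_cohort(12, seed=4)]
    forward = processed_meat_prevalence(menus)
    backward = processed_meat_prevalence(list(reversed(menus)))
    assert forward == backward


def test_alternatives_prevalence_extremes_and_fraction():
    none = build_menu(lunch=[["omni"]] * 7)
    prev = alternatives_prevalence([none])
    assert (prev.dairy_alternative_fraction, prev.meat_alternative_fraction) == (0.0, 0.0)

    flagged = none.model_copy(update={"items": tuple(
        it.model_copy(update={"is_meat_alternative": True, "is_dairy_alternative": True})
        for it in none.items)})
    prev = alternatives_prevalence([flagged])
    assert (prev.dairy_alternative_fraction, prev.meat_alternative_fraction) == (1.0, 1.0)

    cohort = [flagged] * 26 + [none] * 10
    assert alternatives_prevalence(cohort).meat_alternative_fraction == pytest.approx(
        0.722, abs=5e-4)


def test_cohort_summary_csv_layout(tmp_path):
    reports = [_report(s, v) for s, v in zip("ABC", [30.0, 20.0, 10.0])]
    cs = rank_cohort(reports)
    path = tmp_path / "cohort.csv"
    cs.to_csv(path)
    lines = path.read_text().splitlines()
    assert lines[1].startswith("min")
    assert lines[2].startswith("mean")
    assert lines[3].startswith("max")
    assert len(lines) == 1 + 3 + 3
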