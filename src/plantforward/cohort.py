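"""Descriptive analytics over a cohort of scored menus.

Rankings, score distributions, provider comparisons, and prevalence of
processed meat and of plant-based meat/dairy alternatives.  Statistical
treatment is deliberately descriptive: means are computed over non-missing
values only (consistent with the scoring engine's exclusion rule), and no
inferential statistics are attempted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .classify import DEFAULT_LEXICON, Lexicon, annotate_menu
from .indicators import INDICATOR_NAMES
from .model import (
    MAIN_SLOTS,
    Menu,
    MenuStyle,
    ProcessedMeatCategory,
    Provider,
    truncate_to_first_week,
)
from .scoring import GROUP_NAMES, ScoreReport

__all__ = [
    "SCORE_COLUMNS",
    "CohortSummary",
    "Histogram",
    "ProcessedMeatPrevalence",
    "AlternativesPrevalence",
    "reports_frame",
    "rank_cohort",
    "distribution_summary",
    "group_comparison",
    "processed_meat_prevalence",
    "alternatives_prevalence",
    "base_offer_attainment",
    "plot_distributions",
    "plot_group_comparison",
    "plot_processed_meat",
]

#: Score columns in reporting order: final, the three subscores, then the
#: 14 indicators.
SCORE_COLUMNS: tuple[str, ...] = ("final",) + GROUP_NAMES + INDICATOR_NAMES

_ID_COLUMNS = ("hospital_id", "trust_abbrev", "provider")


def reports_frame(reports: Sequence[ScoreReport]) -> pd.DataFrame:
    """One row per report; missing scores become NaN."""
    rows = []
    for r in reports:
        row: dict = {
            "hospital_id": r.hospital_id,
            "trust_abbrev": r.trust_abbrev,
            "provider": r.provider.value,
            "final": np.nan if r.final is None else r.final,
        }
        for g in GROUP_NAMES:
            v = r.subscores.get(g)
            row[g] = np.nan if v is None else v
        for name, v in r.indicators.as_dict().items():
            row[name] = np.nan if v is None else v
        rows.append(row)
    return pd.DataFrame(rows, columns=list(_ID_COLUMNS) + list(SCORE_COLUMNS))


@dataclass(frozen=True)
class CohortSummary:
    """Ranked per-hospital score table plus per-column min/mean/max rows."""

    table: pd.DataFrame
    summary: pd.DataFrame

    def to_csv(self, path: str | Path) -> None:
        """Summary rows (min/mean/max) first, then the ranked hospitals,
        mirroring the published table layout."""
        path = Path(path)
        summary = self.summary.reset_index().rename(columns={"index": "statistic"})
        table = self.table.copy()
        table.insert(0, "statistic", "")
        combined = pd.concat([summary, table], ignore_index=True)
        combined.to_csv(path, index=False)


def rank_cohort(reports: Sequence[ScoreReport]) -> CohortSummary:
    """Rank hospitals from highest to lowest final score.

    Ties are broken by the main-meals subscore, then by hospital identifier;
    hospitals with a missing final score sort last.  The summary frame
    carries min/mean/max per score column over non-missing entries.
    """
    if not reports:
        raise ValueError("cannot rank an empty cohort")
    df = reports_frame(reports)
    df = df.sort_values(
        by=["final", "main_meals", "hospital_id"],
        ascending=[False, False, True],
        na_position="last",
        kind="mergesort",
    ).reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    scores = df[list(SCORE_COLUMNS)]
    summary = pd.DataFrame(
        {"min": scores.min(), "mean": scores.mean(), "max": scores.max()}
    ).T
    return CohortSummary(table=df, summary=summary)


@dataclass(frozen=True)
class Histogram:
    """Counts per half-open bin [k·w, (k+1)·w) with the top bin closed at
    100; missing values are excluded and counted separately."""

    edges: np.ndarray
    counts: np.ndarray
    n_missing: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_left": self.edges[:-1],
            "bin_right": self.edges[1:],
            "count": self.counts,
        })


def distribution_summary(
    reports: Sequence[ScoreReport],
    bin_width: float = 10.0,
    columns: Sequence[str] = ("final",) + GROUP_NAMES,
) -> Dict[str, Histogram]:
    """Histogram of each score column over the cohort."""
    n_bins = 100.0 / bin_width
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError(f"bin width {bin_width} must divide 100")
    edges = np.linspace(0.0, 100.0, int(round(n_bins)) + 1)
    df = reports_frame(reports)
    out: Dict[str, Histogram] = {}
    for col in columns:
        values = df[col].dropna().to_numpy()
        counts, _ = np.histogram(values, bins=edges)
        out[col] = Histogram(edges=edges, counts=counts,
                             n_missing=int(df[col].isna().sum()))
    return out


def group_comparison(reports: Sequence[ScoreReport], key: str = "provider") -> pd.DataFrame:
    """Per-provider means of the final score, subscores and indicators.

    Hospitals with an unknown provider are excluded; empty groups are
    omitted.  Means are over non-missing values.
    """
    df = reports_frame(reports)
    if key == "provider":
        df = df[df["provider"] != Provider.unknown.value]
    groups = df.groupby(key, observed=True)[list(SCORE_COLUMNS)].mean()
    groups.insert(0, "n", df.groupby(key, observed=True).size())
    return groups


def _assessed(menu: Menu, lexicon: Lexicon) -> Menu:
    if menu.style is MenuStyle.cyclical:
        menu = truncate_to_first_week(menu)
    return annotate_menu(menu, lexicon)


@dataclass(frozen=True)
class ProcessedMeatPrevalence:
    """Cohort-level processed-meat descriptives over main meals."""

    by_category: Dict[str, float]
    every_day_fraction: float
    mean_items: float
    min_items: int
    max_items: int
    n_menus: int

    def to_dict(self) -> dict:
        return {
            "by_category": dict(self.by_category),
            "every_day_fraction": self.every_day_fraction,
            "mean_items": self.mean_items,
            "min_items": self.min_items,
            "max_items": self.max_items,
            "n_menus": self.n_menus,
        }


def processed_meat_prevalence(
    menus: Sequence[Menu], lexicon: Lexicon = DEFAULT_LEXICON
) -> ProcessedMeatPrevalence:
    """Processed meat on main meals across the cohort.

    Per category: the fraction of menus with at least one main containing
    it.  ``every_day_fraction`` is the share of menus offering at least one
    processed-meat *dish* (main or smaller) on every assessed day — a
    day-less item, such as a standing smaller-meals list or any item of an
    à-la-carte menu, is available daily and covers every day.  Item counts
    are per-menu counts of processed-meat mains over the assessed (first)
    week.
    """
    if not menus:
        raise ValueError("need at least one menu")
    cat_hits = {cat: 0 for cat in ProcessedMeatCategory}
    every_day = 0
    counts = []
    for menu in menus:
        menu = _assessed(menu, lexicon)
        mains = menu.mains()
        processed = [it for it in mains if it.processed_meat]
        counts.append(len(processed))
        present = set()
        for it in processed:
            present.update(it.processed_meat)
        for cat in present:
            cat_hits[cat] += 1
        any_dish = [it for it in menu.items if it.processed_meat]
        if any(it.day is None for it in any_dish):
            every_day += 1
        else:
            days_with = {it.day for it in any_dish}
            if set(range(1, 8)) <= days_with:
                every_day += 1
    n = len(menus)
    return ProcessedMeatPrevalence(
        by_category={cat.value: cat_hits[cat] / n for cat in ProcessedMeatCategory},
        every_day_fraction=every_day / n,
        mean_items=float(np.mean(counts)),
        min_items=int(min(counts)),
        max_items=int(max(counts)),
        n_menus=n,
    )


@dataclass(frozen=True)
class AlternativesPrevalence:
    """Fractions of menus offering plant-based dairy / meat alternatives."""

    dairy_alternative_fraction: float
    meat_alternative_fraction: float
    n_menus: int

    def to_dict(self) -> dict:
        return {
            "dairy_alternative_fraction": self.dairy_alternative_fraction,
            "meat_alternative_fraction": self.meat_alternative_fraction,
            "n_menus": self.n_menus,
        }


def alternatives_prevalence(
    menus: Sequence[Menu], lexicon: Lexicon = DEFAULT_LEXICON
) -> AlternativesPrevalence:
    """Fraction of menus with ≥1 dairy-alternative item (excluding milk
    alternatives) and with ≥1 meat-alternative main across lunch and dinner."""
    if not menus:
        raise ValueError("need at least one menu")
    dairy = meat = 0
    for menu in menus:
        menu = _assessed(menu, lexicon)
        if any(it.is_dairy_alternative for it in menu.items):
            dairy += 1
        if any(it.is_meat_alternative for it in menu.mains()):
            meat += 1
    n = len(menus)
    return AlternativesPrevalence(
        dairy_alternative_fraction=dairy / n,
        meat_alternative_fraction=meat / n,
        n_menus=n,
    )


def base_offer_attainment(reports: Sequence[ScoreReport]) -> Dict[str, float]:
    """Fraction of menus attaining the daily vegan base offer per slot
    (over menus where the indicator is present)."""
    out: Dict[str, float] = {}
    for name in ("base_offer_lunch", "base_offer_dinner"):
        values = [r.indicators.as_dict()[name] for r in reports]
        present = [v for v in values if v is not None]
        out[name] = float(np.mean([v == 100.0 for v in present])) if present else float("nan")
    return out


# ---------------------------------------------------------------------------
# Figures (optional; mirrors the published figure layouts)


def plot_distributions(reports: Sequence[ScoreReport], path: str | Path,
                       bin_width: float = 10.0) -> None:
    """Histogram panel of the final score and the three subscores."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    hists = distribution_summary(reports, bin_width=bin_width)
    fig, axes = plt.subplots(2, 2, figsize=(9, 6), sharey=True)
    for ax, (col, hist) in zip(axes.ravel(), hists.items()):
        ax.bar(hist.edges[:-1], hist.counts, width=np.diff(hist.edges),
               align="edge", edgecolor="white", color="#3a7d44")
        ax.set_title(col.replace("_", " "))
        ax.set_xlabel("score")
        ax.set_ylabel("menus")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_group_comparison(reports: Sequence[ScoreReport], path: str | Path) -> None:
    """Grouped bars of mean final score and subscores per provider."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    means = group_comparison(reports)[["final", *GROUP_NAMES]]
    ax = means.plot.bar(figsize=(8, 5), rot=0)
    ax.set_ylabel("mean score")
    ax.set_xlabel("catering provider")
    fig = ax.get_figure()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_processed_meat(prevalence: ProcessedMeatPrevalence, path: str | Path) -> None:
    """Bar chart of the proportion of menus serving each processed meat."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cats = list(prevalence.by_category)
    fracs = [100 * prevalence.by_category[c] for c in cats]
    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.bar(cats, fracs, color="#8c3b3b")
    ax.set_ylabel("% of menus")
    ax.set_ylim(0, 100)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
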