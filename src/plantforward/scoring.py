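"""Weighted aggregation of indicators into subscores and the final score.

Each of the three indicator groups (main meals, smaller meals, menu
presentation) yields a subscore between 0 and 100 as the weighted mean of
its *present* indicators.  A missing indicator is excluded from the
calculation, and the subscore itself is only computed when at least half of
the group's information — measured by the sum of the attributed weights —
is available.  The final score is the weighted mean of the subscores with
weights 3 (main meals), 1 (smaller meals) and 2 (menu presentation); by
default the weights are renormalized over the present subscores, mirroring
the within-group exclusion rule (a strict mode that propagates any missing
subscore to a missing final score is available).

Default indicator weights:

====================== ======  ========================== ======
main meals (total 5)           smaller meals (total 3)
---------------------- ------  -------------------------- ------
base offer lunch          0.5  vegan smaller %               2
base offer dinner         0.5  vegetarian smaller %          1
vegan % lunch             1    **menu presentation (3)**
vegan % dinner            1    environmental descriptors     1
vegetarian % lunch        0.5  vegan positioned first        1
vegetarian % dinner       0.5  positive labels               0.5
ruminant-free lunch       0.5  no negative labels            0.5
ruminant-free dinner      0.5
====================== ======  ========================== ======

The positive- and negative-label indicators deliberately carry 0.5 each so
that the labelling dimension totals weight 1.  Scoring is fully
deterministic; reported scores are rounded to the nearest integer (half away
from zero) for display while internal arithmetic keeps full precision.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Optional

import yaml

from .classify import DEFAULT_LEXICON, Lexicon, annotate_menu
from .indicators import (
    INDICATOR_GROUPS,
    INDICATOR_NAMES,
    ExtractionOptions,
    IndicatorVector,
    extract_indicators,
)
from .model import (
    Menu,
    MenuStyle,
    MenuValidationError,
    Provider,
    truncate_to_first_week,
    validate_menu,
)

__all__ = [
    "WeightScheme",
    "DEFAULT_SCHEME",
    "ScoreReport",
    "GROUP_NAMES",
    "load_weight_scheme",
    "available_weight_fraction",
    "subscore",
    "final_score",
    "score_menu",
    "round_half_away",
]

GROUP_NAMES = tuple(INDICATOR_GROUPS)

_DEFAULT_WEIGHTS: Dict[str, float] = {
    "base_offer_lunch": 0.5, "base_offer_dinner": 0.5,
    "pct_vegan_lunch": 1.0, "pct_vegan_dinner": 1.0,
    "pct_vegetarian_lunch": 0.5, "pct_vegetarian_dinner": 0.5,
    "ruminant_free_lunch": 0.5, "ruminant_free_dinner": 0.5,
    "pct_vegan_smaller": 2.0, "pct_vegetarian_smaller": 1.0,
    "env_descriptors": 1.0, "vegan_first": 1.0,
    "positive_labels": 0.5, "no_negative_labels": 0.5,
}

_DEFAULT_FINAL_WEIGHTS: Dict[str, float] = {
    "main_meals": 3.0, "smaller_meals": 1.0, "menu_presentation": 2.0,
}


@dataclass(frozen=True)
class WeightScheme:
    """Indicator weights, subscore grouping, final weights, and the
    availability threshold (minimum fraction of a group's weight that must be
    present for the subscore to be computed; the default 0.5 is inclusive)."""

    indicator_weights: Dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_WEIGHTS))
    groups: Dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {g: tuple(names) for g, names in INDICATOR_GROUPS.items()})
    final_weights: Dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_FINAL_WEIGHTS))
    availability_threshold: float = 0.5

    def __post_init__(self) -> None:
        grouped = [name for names in self.groups.values() for name in names]
        if sorted(grouped) != sorted(set(grouped)):
            raise ValueError("an indicator appears in more than one group")
        if set(grouped) != set(self.indicator_weights):
            raise ValueError(
                "groups must partition exactly the weighted indicator set; "
                f"difference: {set(grouped) ^ set(self.indicator_weights)}")
        for name, w in self.indicator_weights.items():
            if not w > 0:
                raise ValueError(f"indicator weight {name} = {w} must be positive")
        if set(self.final_weights) != set(self.groups):
            raise ValueError("final_weights must cover exactly the groups")
        for g, w in self.final_weights.items():
            if not w > 0:
                raise ValueError(f"final weight {g} = {w} must be positive")
        if not (0.0 < self.availability_threshold <= 1.0):
            raise ValueError("availability_threshold must be in (0, 1]")

    def group_weight(self, group: str) -> float:
        return sum(self.indicator_weights[name] for name in self.groups[group])


DEFAULT_SCHEME = WeightScheme()


def load_weight_scheme(path: str | Path) -> WeightScheme:
    """Load a weight scheme from YAML/JSON; omitted fields keep defaults."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    payload = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    payload = payload or {}
    kwargs: dict = {}
    if "indicator_weights" in payload:
        kwargs["indicator_weights"] = {k: float(v) for k, v in payload["indicator_weights"].items()}
    if "groups" in payload:
        kwargs["groups"] = {g: tuple(names) for g, names in payload["groups"].items()}
    if "final_weights" in payload:
        kwargs["final_weights"] = {k: float(v) for k, v in payload["final_weights"].items()}
    if "availability_threshold" in payload:
        kwargs["availability_threshold"] = float(payload["availability_threshold"])
    return WeightScheme(**kwargs)


def available_weight_fraction(
    indicators: IndicatorVector, group: str, scheme: WeightScheme = DEFAULT_SCHEME
) -> float:
    """Fraction of the group's total weight carried by present indicators."""
    values = indicators.as_dict()
    present = sum(
        scheme.indicator_weights[name]
        for name in scheme.groups[group]
        if values[name] is not None
    )
    return present / scheme.group_weight(group)


def subscore(
    indicators: IndicatorVector, group: str, scheme: WeightScheme = DEFAULT_SCHEME
) -> Optional[float]:
    """Weighted mean of the group's present indicators, or missing.

    Missing indicators are excluded; the subscore is missing when the present
    indicators carry less than ``availability_threshold`` of the group's
    total weight (the threshold is inclusive: exactly half is enough).
    """
    values = indicators.as_dict()
    pairs = [
        (scheme.indicator_weights[name], values[name])
        for name in scheme.groups[group]
        if values[name] is not None
    ]
    total = scheme.group_weight(group)
    available = sum(w for w, _ in pairs)
    if available / total < scheme.availability_threshold:
        return None
    return sum(w * v for w, v in pairs) / available


def final_score(
    subscores: Mapping[str, Optional[float]],
    scheme: WeightScheme = DEFAULT_SCHEME,
    renormalize: bool = True,
) -> Optional[float]:
    """Weighted mean of subscores with the 3/1/2 final weights.

    With ``renormalize`` (default) the weights are renormalized over the
    present subscores; the final score is missing only when every subscore
    is.  With ``renormalize=False`` any missing subscore makes the final
    score missing.
    """
    pairs = [
        (scheme.final_weights[g], subscores.get(g))
        for g in scheme.groups
    ]
    present = [(w, v) for w, v in pairs if v is not None]
    if not present:
        return None
    if not renormalize and len(present) < len(pairs):
        return None
    return sum(w * v for w, v in present) / sum(w for w, _ in present)


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention for reported scores)."""
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass(frozen=True)
class ScoreReport:
    """Scores of one menu with full provenance.

    ``subscores`` and ``final`` keep full precision; :meth:`rounded` applies
    the integer reporting convention.  ``available_weight_fraction`` records,
    per group, how much of the group's weight was backed by data.
    """

    hospital_id: str
    trust_abbrev: str
    provider: Provider
    indicators: IndicatorVector
    subscores: Dict[str, Optional[float]]
    final: Optional[float]
    available_weight_fraction: Dict[str, float]

    def rounded(self, ndigits: int = 0) -> Dict[str, Optional[float]]:
        """Subscores and final score under the reporting rounding."""
        out: Dict[str, Optional[float]] = {
            g: (None if v is None else round_half_away(v, ndigits))
            for g, v in self.subscores.items()
        }
        out["final"] = None if self.final is None else round_half_away(self.final, ndigits)
        return out

    def to_dict(self) -> dict:
        return {
            "hospital_id": self.hospital_id,
            "trust_abbrev": self.trust_abbrev,
            "provider": self.provider.value,
            "indicators": self.indicators.as_dict(),
            "subscores": dict(self.subscores),
            "final": self.final,
            "available_weight_fraction": dict(self.available_weight_fraction),
            "rounded": self.rounded(),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), indent=2, ensure_ascii=False) + "\n",
            encoding="utf-8")

    def flat_row(self) -> Dict[str, object]:
        """One flat mapping (CSV row) of identity, indicators and scores."""
        row: Dict[str, object] = {
            "hospital_id": self.hospital_id,
            "trust_abbrev": self.trust_abbrev,
            "provider": self.provider.value,
        }
        row.update(self.indicators.as_dict())
        row.update(self.subscores)
        row["final"] = self.final
        return row


def score_menu(
    menu: Menu,
    lexicon: Optional[Lexicon] = DEFAULT_LEXICON,
    scheme: WeightScheme = DEFAULT_SCHEME,
    options: ExtractionOptions = ExtractionOptions(),
    renormalize_final: bool = True,
) -> ScoreReport:
    """Score one menu end to end.

    Validates, truncates cyclical menus to their first week, resolves any
    underived annotations from dish names (pass ``lexicon=None`` to require
    a pre-annotated menu), extracts the 14 indicators and aggregates them.  Raises
    :class:`~plantforward.model.MenuValidationError` on invariant breaches.
    """
    findings = [f for f in validate_menu(menu) if f.severity == "error"]
    if findings:
        raise MenuValidationError(findings, source=menu.hospital_id)
    if menu.style is MenuStyle.cyclical:
        menu = truncate_to_first_week(menu)
    if lexicon is not None:
        menu = annotate_menu(menu, lexicon)
    indicators = extract_indicators(menu, options=options)
    subs = {g: subscore(indicators, g, scheme) for g in scheme.groups}
    return ScoreReport(
        hospital_id=menu.hospital_id,
        trust_abbrev=menu.trust_abbrev,
        provider=menu.provider,
        indicators=indicators,
        subscores=subs,
        final=final_score(subs, scheme, renormalize=renormalize_final),
        available_weight_fraction={
            g: available_weight_fraction(indicators, g, scheme) for g in scheme.groups
        },
    )
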