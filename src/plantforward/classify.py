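"""Deterministic, lexicon-driven dietary classification of menu text.

Real menu audits code each dish by hand; this module ships an editable
keyword lexicon that reproduces that coding for the short dish names typical
of hospital menus.  Matching is case-insensitive and whole-word: text is
lowercased, hyphens and slashes become spaces, punctuation is stripped, and
multi-word terms match as contiguous phrases.  This avoids substring false
hits ("hamper" does not contain the token "ham").

File-supplied annotations always take precedence over derived ones
(:func:`annotate_menu` only fills fields that are ``None``/unknown).

Two conventions worth noting:

* The token ``vegetarian`` sits in ``animal_product_terms``: a dish a menu
  prints as "Vegetarian …" (rather than vegan) conventionally contains dairy
  or egg, so the tag itself marks the dish as vegetarian-not-vegan.
* ``corned beef`` is matched as a phrase before the bare processed-meat
  categories so its tokens are not double-counted, while
  :func:`detect_ruminant` still fires on the ``beef`` token — corned beef is
  both ruminant and processed.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Dict, FrozenSet, Optional

import yaml
from pydantic import BaseModel, ConfigDict, model_validator

from .model import (
    DietClass,
    LabelFlags,
    MealItem,
    Menu,
    ProcessedMeatCategory,
)

__all__ = [
    "Lexicon",
    "DEFAULT_LEXICON",
    "load_lexicon",
    "classify_diet",
    "detect_ruminant",
    "detect_processed_meat",
    "detect_negative_label",
    "detect_positive_label",
    "annotate_item",
    "annotate_menu",
]

_TOKEN_RE = re.compile(r"[a-z0-9]+")


def _tokens(text: str) -> tuple[str, ...]:
    """Normalize text to lowercase word tokens (hyphens/slashes split words)."""
    return tuple(_TOKEN_RE.findall(text.lower().replace("-", " ").replace("/", " ")))


def _phrase(term: str) -> tuple[str, ...]:
    return _tokens(term)


def _find_phrase(tokens: tuple[str, ...], phrase: tuple[str, ...],
                 blocked: Optional[set[int]] = None) -> Optional[range]:
    """First occurrence of *phrase* as a contiguous token run, skipping blocked indices."""
    k = len(phrase)
    if k == 0:
        return None
    for i in range(len(tokens) - k + 1):
        span = range(i, i + k)
        if blocked and any(j in blocked for j in span):
            continue
        if tuple(tokens[i:i + k]) == phrase:
            return span
    return None


def _match_any(tokens: tuple[str, ...], terms: FrozenSet[str]) -> bool:
    return any(_find_phrase(tokens, _phrase(t)) is not None for t in terms)


class Lexicon(BaseModel):
    """Term sets driving dietary classification and label detection.

    Invariants: ruminant terms and all processed-meat terms must be included
    in ``meat_fish_terms`` (so any dish carrying them classifies as
    omnivorous), and the positive and negative label vocabularies must be
    disjoint.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    ruminant_terms: FrozenSet[str] = frozenset({"beef", "lamb", "goat"})
    processed_meat_terms: Dict[ProcessedMeatCategory, FrozenSet[str]] = {
        ProcessedMeatCategory.ham: frozenset({"ham", "gammon"}),
        ProcessedMeatCategory.bacon: frozenset({"bacon"}),
        ProcessedMeatCategory.sausage: frozenset({"sausage", "sausages"}),
        ProcessedMeatCategory.corned_beef: frozenset({"corned beef"}),
        ProcessedMeatCategory.other: frozenset(
            {"salami", "pepperoni", "chorizo", "pastrami", "hot dog"}),
    }
    meat_fish_terms: FrozenSet[str] = frozenset({
        "beef", "lamb", "goat", "mutton", "chicken", "turkey", "duck", "pork",
        "ham", "gammon", "bacon", "sausage", "sausages", "corned beef",
        "salami", "pepperoni", "chorizo", "pastrami", "hot dog", "meatball",
        "meatballs", "steak", "liver", "fish", "salmon", "tuna", "cod",
        "haddock", "plaice", "mackerel", "sardine", "prawn", "prawns",
        "shrimp", "crab",
    })
    animal_product_terms: FrozenSet[str] = frozenset({
        "cheese", "cheddar", "mozzarella", "halloumi", "feta", "paneer",
        "milk", "cream", "butter", "egg", "eggs", "omelette", "quiche",
        "yogurt", "yoghurt", "custard", "mayonnaise", "honey", "vegetarian",
    })
    negative_label_terms: FrozenSet[str] = frozenset({"vegetarian", "vegan", "meat-free"})
    positive_label_terms: FrozenSet[str] = frozenset(
        {"plant-based", "plant-rich", "plant-based protein", "plant-powered"})

    @model_validator(mode="after")
    def _check_invariants(self) -> "Lexicon":
        if not self.ruminant_terms <= self.meat_fish_terms:
            missing = sorted(self.ruminant_terms - self.meat_fish_terms)
            raise ValueError(f"ruminant_terms must be a subset of meat_fish_terms; missing {missing}")
        for cat, terms in self.processed_meat_terms.items():
            if not terms <= self.meat_fish_terms:
                missing = sorted(terms - self.meat_fish_terms)
                raise ValueError(
                    f"processed_meat_terms[{cat.value}] must be a subset of "
                    f"meat_fish_terms; missing {missing}")
        overlap = {_phrase(t) for t in self.negative_label_terms} & {
            _phrase(t) for t in self.positive_label_terms}
        if overlap:
            raise ValueError(f"negative and positive label terms overlap: {sorted(overlap)}")
        return self


DEFAULT_LEXICON = Lexicon()


def load_lexicon(path: str | Path) -> Lexicon:
    """Load a lexicon from a YAML or JSON file (partial overrides allowed)."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    payload = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    return Lexicon.model_validate(payload or {})


def classify_diet(name: str, lexicon: Lexicon = DEFAULT_LEXICON) -> DietClass:
    """Classify a dish name as vegan, vegetarian-not-vegan, or omnivorous.

    Omnivorous iff any meat/fish term matches; otherwise vegetarian iff any
    animal-product (dairy/egg/honey) term matches; otherwise vegan.
    """
    if not name:
        raise ValueError("dish name must be non-empty")
    toks = _tokens(name)
    if _match_any(toks, lexicon.meat_fish_terms):
        return DietClass.omnivorous
    if _match_any(toks, lexicon.animal_product_terms):
        return DietClass.vegetarian_not_vegan
    return DietClass.vegan


def detect_ruminant(name: str, lexicon: Lexicon = DEFAULT_LEXICON) -> bool:
    """True iff the dish name contains a beef/lamb/goat term."""
    if not name:
        raise ValueError("dish name must be non-empty")
    return _match_any(_tokens(name), lexicon.ruminant_terms)


def detect_processed_meat(
    name: str, lexicon: Lexicon = DEFAULT_LEXICON
) -> FrozenSet[ProcessedMeatCategory]:
    """Every processed-meat category whose terms match the dish name.

    Multi-token phrases are matched first and consume their tokens, so
    "corned beef" does not additionally feed a bare-token match.
    """
    if not name:
        raise ValueError("dish name must be non-empty")
    toks = _tokens(name)
    consumed: set[int] = set()
    found: set[ProcessedMeatCategory] = set()
    # longest phrases first so compound names are claimed before single tokens
    ordered: list[tuple[ProcessedMeatCategory, tuple[str, ...]]] = sorted(
        ((cat, _phrase(t)) for cat, terms in lexicon.processed_meat_terms.items() for t in terms),
        key=lambda pair: -len(pair[1]),
    )
    for cat, phrase in ordered:
        span = _find_phrase(toks, phrase, blocked=consumed)
        if span is not None:
            found.add(cat)
            consumed.update(span)
    return frozenset(found)


def detect_negative_label(label_text: str, lexicon: Lexicon = DEFAULT_LEXICON) -> bool:
    """True iff the printed name/label carries an explicit diet tag
    ('vegetarian', 'vegan', 'meat-free')."""
    return _match_any(_tokens(label_text or ""), lexicon.negative_label_terms)


def detect_positive_label(label_text: str, lexicon: Lexicon = DEFAULT_LEXICON) -> bool:
    """True iff the printed name/label uses appeal-broadening plant-forward
    language ('plant-rich', 'plant-based protein', ...)."""
    return _match_any(_tokens(label_text or ""), lexicon.positive_label_terms)


def annotate_item(item: MealItem, lexicon: Lexicon = DEFAULT_LEXICON) -> MealItem:
    """Fill any underived (None) dietary annotations from the dish name.

    File-supplied values take precedence and are never overwritten.
    """
    updates: dict = {}
    if item.diet_class is None:
        updates["diet_class"] = classify_diet(item.name, lexicon)
    if item.contains_ruminant is None:
        updates["contains_ruminant"] = detect_ruminant(item.name, lexicon)
    if item.processed_meat is None:
        updates["processed_meat"] = detect_processed_meat(item.name, lexicon)
    flags = item.label_flags
    flag_updates: dict = {}
    if flags.explicit_diet_label_present is None:
        flag_updates["explicit_diet_label_present"] = detect_negative_label(item.name, lexicon)
    if flags.positive_label_present is None:
        flag_updates["positive_label_present"] = detect_positive_label(item.name, lexicon)
    if flag_updates:
        updates["label_flags"] = flags.model_copy(update=flag_updates)
    if not updates:
        return item
    return item.model_copy(update=updates)


def annotate_menu(menu: Menu, lexicon: Lexicon = DEFAULT_LEXICON) -> Menu:
    """Return a menu with all item annotations resolved (idempotent)."""
    return menu.model_copy(
        update={"items": tuple(annotate_item(it, lexicon) for it in menu.items)})
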