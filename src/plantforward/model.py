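"""Menu and meal-item domain model, with JSON/CSV readers and writers.

A :class:`Menu` is one hospital's standard in-patient offering: an ordered
collection of :class:`MealItem` records across lunch mains, dinner mains and
smaller meals (sandwiches, soups, jacket potatoes, salads and lighter-appetite
options).  Cyclical menus repeat on a 1–4 week cycle and only the first week
is assessed; à la carte menus are standing menus and are assessed in full.
Starters and desserts are out of scope and have no slot.

Two on-disk representations are supported:

* **JSON** (canonical): one object holding the menu-level fields plus an
  ``items`` array.  The formal schema is available from
  :func:`menu_json_schema`.
* **CSV** (flat dialect): one row per meal item (UTF-8, comma separated,
  header row, set-valued fields pipe-delimited, ``""`` = unknown/underived,
  ``"-"`` = empty set) together with a ``<stem>.meta.json`` sidecar carrying
  the menu-level fields.

Dietary annotations (``diet_class``, ``contains_ruminant``, ``processed_meat``
and the label flags) may be supplied in the file — emulating manual coding of
real menus — or left null to be derived from the dish name by
:mod:`plantforward.classify`.  File-supplied codes always take precedence.
"""

from __future__ import annotations

import csv
import enum
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, FrozenSet, Iterable, Optional

from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_serializer

__all__ = [
    "Slot",
    "MAIN_SLOTS",
    "DietClass",
    "ProcessedMeatCategory",
    "EnvironmentalMessaging",
    "Provider",
    "MenuStyle",
    "SmallerMealsStatus",
    "LabelFlags",
    "MealItem",
    "Menu",
    "Finding",
    "MenuError",
    "MenuFormatError",
    "MenuValidationError",
    "EmptyMenuError",
    "read_menu",
    "write_menu",
    "validate_menu",
    "truncate_to_first_week",
    "menu_json_schema",
]


class Slot(str, enum.Enum):
    """Meal slot of an item."""

    lunch_main = "lunch_main"
    dinner_main = "dinner_main"
    smaller = "smaller"


#: The two main-meal slots assessed for the main-meals indicator group.
MAIN_SLOTS = (Slot.lunch_main, Slot.dinner_main)


class DietClass(str, enum.Enum):
    """Dietary class of a dish; vegan dishes are a subset of vegetarian ones."""

    vegan = "vegan"
    vegetarian_not_vegan = "vegetarian_not_vegan"
    omnivorous = "omnivorous"


class ProcessedMeatCategory(str, enum.Enum):
    """Processed-meat categories tracked for prevalence analytics."""

    ham = "ham"
    bacon = "bacon"
    sausage = "sausage"
    corned_beef = "corned_beef"
    other = "other"


class EnvironmentalMessaging(str, enum.Enum):
    """Presence of environmental-impact messaging (menu-wide or per item)."""

    yes = "yes"
    partial = "partial"
    no = "no"
    unknown = "unknown"


class Provider(str, enum.Enum):
    """Catering provider of the hospital."""

    in_house = "in_house"
    contracted = "contracted"
    mixed = "mixed"
    unknown = "unknown"


class MenuStyle(str, enum.Enum):
    cyclical = "cyclical"
    a_la_carte = "a_la_carte"


class SmallerMealsStatus(str, enum.Enum):
    """Whether smaller meals appear on the standard menu.

    ``ward_based_unassessable`` covers hospitals whose smaller meals are a
    daily ward-based selection that a menu audit cannot assess; ``not_listed``
    covers menus with no smaller-meal section at all.  Either way the
    smaller-meal indicators are missing, not zero.
    """

    listed = "listed"
    ward_based_unassessable = "ward_based_unassessable"
    not_listed = "not_listed"


class LabelFlags(BaseModel):
    """Label/nudging flags of one item; ``None`` means not yet derived."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    explicit_diet_label_present: Optional[bool] = None
    positive_label_present: Optional[bool] = None
    environmental_messaging: EnvironmentalMessaging = EnvironmentalMessaging.unknown


class MealItem(BaseModel):
    """One menu entry.

    ``day`` is 1-based and absent for à-la-carte items (and optionally for a
    standing smaller-meals list repeated daily on a cyclical menu).
    ``position`` is the 1-based listing order within the item's (day, slot)
    section — position 1 is what a patient reads first.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    name: str = Field(min_length=1)
    slot: Slot
    day: Optional[int] = Field(default=None, ge=1)
    position: int = Field(ge=1)
    diet_class: Optional[DietClass] = None
    contains_ruminant: Optional[bool] = None
    processed_meat: Optional[FrozenSet[ProcessedMeatCategory]] = None
    label_flags: LabelFlags = Field(default_factory=LabelFlags)
    is_meat_alternative: bool = False
    is_dairy_alternative: bool = False

    @field_serializer("processed_meat")
    def _sorted_processed(self, v: Optional[FrozenSet[ProcessedMeatCategory]]):
        # sorted list keeps serialized output deterministic across runs
        if v is None:
            return None
        return sorted(c.value for c in v)

    @property
    def is_plant_based(self) -> bool:
        """True for vegan or vegetarian dishes (requires a resolved class)."""
        return self.diet_class in (DietClass.vegan, DietClass.vegetarian_not_vegan)


class Menu(BaseModel):
    """A hospital's standard in-patient menu plus identity metadata."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    hospital_id: str = Field(min_length=1)
    trust_abbrev: str = ""
    provider: Provider = Provider.unknown
    style: MenuStyle = MenuStyle.cyclical
    n_weeks: Optional[int] = Field(default=None, ge=1)
    environmental_messaging: EnvironmentalMessaging = EnvironmentalMessaging.unknown
    smaller_meals_status: SmallerMealsStatus = SmallerMealsStatus.listed
    items: tuple[MealItem, ...] = ()

    def mains(self, slot: Optional[Slot] = None) -> list[MealItem]:
        """Main-slot items, optionally restricted to one slot."""
        slots = MAIN_SLOTS if slot is None else (slot,)
        return [it for it in self.items if it.slot in slots]

    def smaller_items(self) -> list[MealItem]:
        return [it for it in self.items if it.slot is Slot.smaller]

    def sections(self, slots: Iterable[Slot] = MAIN_SLOTS) -> dict[tuple, list[MealItem]]:
        """Items grouped by (day, slot) section, each sorted by position."""
        slots = tuple(slots)
        out: dict[tuple, list[MealItem]] = {}
        for it in self.items:
            if it.slot in slots:
                out.setdefault((it.day, it.slot), []).append(it)
        for sec in out.values():
            sec.sort(key=lambda it: it.position)
        return out


@dataclass(frozen=True)
class Finding:
    """One validation finding; ``severity`` is ``"error"`` or ``"warning"``."""

    severity: str
    code: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.severity}] {self.code}: {self.message}"


class MenuError(Exception):
    """Base class for menu I/O and validation errors."""


class MenuFormatError(MenuError):
    """The file does not conform to the menu schema."""


class MenuValidationError(MenuError):
    """A structurally parsable menu violates domain invariants."""

    def __init__(self, findings: list[Finding], source: Optional[str] = None):
        self.findings = findings
        self.source = source
        where = f" in {source}" if source else ""
        detail = "; ".join(str(f) for f in findings if f.severity == "error")
        super().__init__(f"invalid menu{where}: {detail}")


class EmptyMenuError(MenuError):
    """A cyclical menu has no assessable (day 1–7) items."""


def validate_menu(menu: Menu) -> list[Finding]:
    """Check the domain invariants of a menu.

    Returns a list of findings (empty iff the menu is fully well formed).
    A missing or unassessable smaller-meals section is a *warning* — the
    pipeline handles it as missing data — while invariant breaches are
    *errors*.
    """
    findings: list[Finding] = []

    for i, it in enumerate(menu.items):
        ident = f"item {i} ({it.name!r}, {it.slot.value}, day={it.day}, pos={it.position})"
        if it.diet_class in (DietClass.vegan, DietClass.vegetarian_not_vegan):
            if it.contains_ruminant:
                findings.append(Finding(
                    "error", "plant_dish_with_ruminant",
                    f"{ident}: diet_class={it.diet_class.value} but contains_ruminant is true"))
            if it.processed_meat:
                findings.append(Finding(
                    "error", "plant_dish_with_processed_meat",
                    f"{ident}: diet_class={it.diet_class.value} but processed_meat="
                    f"{sorted(c.value for c in it.processed_meat)}"))
        if menu.style is MenuStyle.a_la_carte and it.day is not None:
            findings.append(Finding(
                "error", "a_la_carte_day",
                f"{ident}: day values must be absent on an a la carte menu"))
        if menu.style is MenuStyle.cyclical and it.slot in MAIN_SLOTS and it.day is None:
            findings.append(Finding(
                "error", "cyclical_main_without_day",
                f"{ident}: every main-slot item on a cyclical menu needs a day"))

    if menu.style is MenuStyle.cyclical:
        n_weeks = menu.n_weeks or 1
        for it in menu.items:
            if it.day is not None and it.day > 7 * n_weeks:
                findings.append(Finding(
                    "error", "day_beyond_cycle",
                    f"item {it.name!r} has day {it.day} beyond the {n_weeks}-week cycle"))

    # positions unique and contiguous from 1 within each (day, slot) section
    for (day, slot), sec in menu.sections(slots=tuple(Slot)).items():
        positions = sorted(it.position for it in sec)
        if positions != list(range(1, len(sec) + 1)):
            findings.append(Finding(
                "error", "bad_positions",
                f"section (day={day}, slot={slot.value}) has positions {positions}; "
                f"expected contiguous 1..{len(sec)}"))

    smaller = menu.smaller_items()
    if menu.smaller_meals_status is not SmallerMealsStatus.listed and smaller:
        findings.append(Finding(
            "error", "smaller_status_contradiction",
            f"smaller_meals_status={menu.smaller_meals_status.value} but "
            f"{len(smaller)} smaller items are present"))
    if menu.smaller_meals_status is SmallerMealsStatus.not_listed:
        findings.append(Finding(
            "warning", "smaller_meals_not_listed",
            "no smaller meals listed on the standard menu; "
            "smaller-meal indicators will be missing"))
    elif menu.smaller_meals_status is SmallerMealsStatus.ward_based_unassessable:
        findings.append(Finding(
            "warning", "smaller_meals_ward_based",
            "smaller meals offered as a ward-based selection; not assessable from the menu"))
    elif not smaller:
        findings.append(Finding(
            "warning", "smaller_meals_empty",
            "smaller_meals_status is 'listed' but no smaller items are present"))

    return findings


def truncate_to_first_week(menu: Menu) -> Menu:
    """Restrict a cyclical menu to its first week (days 1–7).

    À la carte menus pass through unchanged.  Day-less items on a cyclical
    menu (a standing smaller-meals list repeated daily) are retained.
    Idempotent.
    """
    if menu.style is MenuStyle.a_la_carte:
        return menu
    kept = tuple(it for it in menu.items if it.day is None or 1 <= it.day <= 7)
    if not any(it.day is not None and 1 <= it.day <= 7 for it in menu.items):
        raise EmptyMenuError(
            f"menu {menu.hospital_id!r}: cyclical menu has no items within days 1-7")
    return menu.model_copy(update={"items": kept, "n_weeks": 1})


# ---------------------------------------------------------------------------
# I/O


def menu_json_schema() -> dict:
    """The formal JSON schema of the canonical menu file format."""
    return Menu.model_json_schema()


_CSV_COLUMNS = [
    "name", "slot", "day", "position", "diet_class", "contains_ruminant",
    "processed_meat", "explicit_diet_label_present", "positive_label_present",
    "environmental_messaging", "is_meat_alternative", "is_dairy_alternative",
]

_META_FIELDS = [
    "hospital_id", "trust_abbrev", "provider", "style", "n_weeks",
    "environmental_messaging", "smaller_meals_status",
]


def _bool_out(v: Optional[bool]) -> str:
    return "" if v is None else ("true" if v else "false")


def _bool_in(s: str, where: str) -> Optional[bool]:
    s = s.strip().lower()
    if s == "":
        return None
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise MenuFormatError(f"{where}: cannot parse boolean {s!r}")


def _item_to_row(it: MealItem) -> dict[str, str]:
    if it.processed_meat is None:
        pm = ""
    elif not it.processed_meat:
        pm = "-"
    else:
        pm = "|".join(sorted(c.value for c in it.processed_meat))
    return {
        "name": it.name,
        "slot": it.slot.value,
        "day": "" if it.day is None else str(it.day),
        "position": str(it.position),
        "diet_class": "" if it.diet_class is None else it.diet_class.value,
        "contains_ruminant": _bool_out(it.contains_ruminant),
        "processed_meat": pm,
        "explicit_diet_label_present": _bool_out(it.label_flags.explicit_diet_label_present),
        "positive_label_present": _bool_out(it.label_flags.positive_label_present),
        "environmental_messaging": it.label_flags.environmental_messaging.value,
        "is_meat_alternative": _bool_out(it.is_meat_alternative),
        "is_dairy_alternative": _bool_out(it.is_dairy_alternative),
    }


def _row_to_item(row: dict[str, str], where: str) -> dict[str, Any]:
    extra = set(row) - set(_CSV_COLUMNS)
    if extra:
        raise MenuFormatError(f"{where}: unknown columns {sorted(extra)}")
    pm_raw = (row.get("processed_meat") or "").strip()
    if pm_raw == "":
        pm: Any = None
    elif pm_raw == "-":
        pm = []
    else:
        pm = [t.strip() for t in pm_raw.split("|") if t.strip()]
    return {
        "name": row.get("name", ""),
        "slot": row.get("slot", ""),
        "day": None if not (row.get("day") or "").strip() else int(row["day"]),
        "position": int(row.get("position") or 0),
        "diet_class": (row.get("diet_class") or "").strip() or None,
        "contains_ruminant": _bool_in(row.get("contains_ruminant", ""), where),
        "processed_meat": pm,
        "label_flags": {
            "explicit_diet_label_present": _bool_in(row.get("explicit_diet_label_present", ""), where),
            "positive_label_present": _bool_in(row.get("positive_label_present", ""), where),
            "environmental_messaging": (row.get("environmental_messaging") or "unknown").strip(),
        },
        "is_meat_alternative": _bool_in(row.get("is_meat_alternative", "false"), where) or False,
        "is_dairy_alternative": _bool_in(row.get("is_dairy_alternative", "false"), where) or False,
    }


def _meta_path(csv_path: Path) -> Path:
    return csv_path.with_name(csv_path.stem + ".meta.json")


def _format_of(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower()
    if suffix == ".json":
        return "json"
    if suffix == ".csv":
        return "csv"
    raise MenuFormatError(f"{path}: cannot infer format from suffix {suffix!r}")


def read_menu(path: str | Path, format: Optional[str] = None) -> Menu:
    """Read and validate a menu file (JSON canonical form or CSV dialect).

    Raises :class:`MenuFormatError` on schema violations (naming the
    offending record and field) and :class:`MenuValidationError` when the
    parsed menu breaches a domain invariant.
    """
    path = Path(path)
    fmt = _format_of(path, format)
    try:
        if fmt == "json":
            payload = json.loads(path.read_text(encoding="utf-8"))
        elif fmt == "csv":
            meta_path = _meta_path(path)
            if not meta_path.exists():
                raise MenuFormatError(f"{path}: missing sidecar {meta_path.name}")
            payload = json.loads(meta_path.read_text(encoding="utf-8"))
            if "items" in payload:
                raise MenuFormatError(f"{meta_path}: sidecar must not carry items")
            with path.open(newline="", encoding="utf-8") as fh:
                reader = csv.DictReader(fh)
                payload["items"] = [
                    _row_to_item(row, f"{path.name} row {i + 2}")
                    for i, row in enumerate(reader)
                ]
        else:
            raise MenuFormatError(f"unknown format {fmt!r}")
    except (json.JSONDecodeError, ValueError) as exc:
        raise MenuFormatError(f"{path}: {exc}") from exc

    try:
        menu = Menu.model_validate(payload)
    except ValidationError as exc:
        details = "; ".join(
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}" for err in exc.errors()
        )
        raise MenuFormatError(f"{path}: {details}") from exc

    findings = validate_menu(menu)
    errors = [f for f in findings if f.severity == "error"]
    if errors:
        raise MenuValidationError(errors, source=str(path))
    return menu


def write_menu(menu: Menu, path: str | Path, format: Optional[str] = None) -> None:
    """Write a menu in the canonical JSON form or the flat CSV dialect."""
    path = Path(path)
    fmt = _format_of(path, format)
    if fmt == "json":
        path.write_text(
            json.dumps(menu.model_dump(mode="json"), indent=2, ensure_ascii=False) + "\n",
            encoding="utf-8",
        )
    elif fmt == "csv":
        meta = menu.model_dump(mode="json", include=set(_META_FIELDS))
        _meta_path(path).write_text(
            json.dumps(meta, indent=2, ensure_ascii=False) + "\n", encoding="utf-8")
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=_CSV_COLUMNS)
            writer.writeheader()
            for it in menu.items:
                writer.writerow(_item_to_row(it))
    else:
        raise MenuFormatError(f"unknown format {fmt!r}")
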