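"""Data model and I/O for food-composition tables, recipes, and food records.

The in-memory model mirrors an augmented food-composition table: each food
carries protein content (g/100 g), an amino-acid profile in mg per g protein,
a single digestibility fraction applied to all amino acids, and a plant or
animal origin flag. Profiles are stored per gram of protein (the unit of
reference requirement patterns) so they are portion-independent; the absolute
intake of an amino acid from a portion is

    mass_g x protein_g_per_100g / 100 x aa_mg_per_g_protein        [mg]

Foods without amino-acid data (composition tables typically only profile
foods above ~1% protein) are loaded with ``has_aa_data=False`` and an
all-zero profile: they still count toward protein and energy totals, but are
surfaced in score diagnostics rather than silently imputed.
"""

from __future__ import annotations

import json
import logging
from decimal import Decimal, InvalidOperation
from enum import Enum
from pathlib import Path
from typing import Iterator, Literal

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .aminoacids import CANONICAL_ORDER, AminoAcidVector, EAAKey

__all__ = [
    "FoodItem",
    "FoodTable",
    "Portion",
    "MealMoment",
    "MAIN_MEALS",
    "FoodRecordEntry",
    "FoodTableError",
    "UnknownFoodError",
    "load_food_table",
    "save_food_table",
    "load_records",
    "save_records",
    "load_persons",
    "validate_records",
    "group_records",
]

logger = logging.getLogger(__name__)

#: CSV column order for food tables; amino-acid columns are mg per g protein.
FOOD_TABLE_COLUMNS = [
    "id",
    "name",
    "protein_g_per_100g",
    "energy_kcal_per_100g",
    "origin",
    "digestibility_pct",
    *[k.value for k in CANONICAL_ORDER],
]

RECORD_COLUMNS = ["person_id", "day", "meal_moment", "food_id", "mass_g"]


class FoodTableError(ValueError):
    """Malformed food table, record, or recipe input."""


class UnknownFoodError(KeyError):
    """A portion references a food id absent from the table."""


# Digestibility is stored internally as a fraction but serialized as a
# percentage. The conversion goes through Decimal so that save -> load
# reproduces the fraction bit-for-bit (a plain x*100/100 can lose a ulp).
def _pct_to_fraction(raw: object) -> float:
    try:
        pct = Decimal(str(raw))
    except InvalidOperation:
        raise ValueError(f"digestibility_pct is not numeric: {raw!r}") from None
    if not 0 <= pct <= 100:
        raise ValueError(f"digestibility_pct must be in [0, 100], got {pct}")
    return float(pct / 100)


def _fraction_to_pct_str(fraction: float) -> str:
    return str(Decimal(repr(fraction)) * 100)


class FoodItem(BaseModel):
    """One food: protein and energy density, AA profile, digestibility, origin."""

    model_config = ConfigDict(frozen=True, arbitrary_types_allowed=True)

    id: str
    name: str
    protein_g_per_100g: float = Field(ge=0)
    aa_mg_per_g_protein: AminoAcidVector
    digestibility: float = Field(ge=0, le=1)
    origin: Literal["plant", "animal"]
    energy_kcal_per_100g: float = Field(default=0.0, ge=0)
    has_aa_data: bool = True

    def model_post_init(self, __context) -> None:
        if not self.has_aa_data and not self.aa_mg_per_g_protein.is_zero():
            raise ValueError(
                f"food {self.id!r}: has_aa_data=False requires an all-zero profile"
            )


class FoodTable:
    """Collection of :class:`FoodItem` keyed by unique id.

    Lookup of an unknown id raises :class:`UnknownFoodError`; it is never a
    silent zero.
    """

    def __init__(
        self,
        items: list[FoodItem] | None = None,
        source: str = "",
        version: str = "",
    ) -> None:
        self._items: dict[str, FoodItem] = {}
        self.source = source
        self.version = version
        for item in items or []:
            self.add(item)

    def add(self, item: FoodItem) -> None:
        if item.id in self._items:
            raise FoodTableError(f"duplicate food id {item.id!r}")
        self._items[item.id] = item

    def __getitem__(self, food_id: str) -> FoodItem:
        try:
            return self._items[food_id]
        except KeyError:
            raise UnknownFoodError(
                f"unknown food id {food_id!r} (table has {len(self)} items)"
            ) from None

    def __contains__(self, food_id: str) -> bool:
        return food_id in self._items

    def __len__(self) -> int:
        return len(self._items)

    def __iter__(self) -> Iterator[FoodItem]:
        # deterministic: canonical order is sorted id
        return iter(sorted(self._items.values(), key=lambda it: it.id))

    def ids(self) -> list[str]:
        return sorted(self._items)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view in the documented CSV schema (digestibility in %)."""
        rows = []
        for item in self:
            row: dict[str, object] = {
                "id": item.id,
                "name": item.name,
                "protein_g_per_100g": item.protein_g_per_100g,
                "energy_kcal_per_100g": item.energy_kcal_per_100g,
                "origin": item.origin,
                "digestibility_pct": _fraction_to_pct_str(item.digestibility),
            }
            profile = item.aa_mg_per_g_protein.as_dict()
            for key in CANONICAL_ORDER:
                row[key.value] = profile[key] if item.has_aa_data else ""
            rows.append(row)
        return pd.DataFrame(rows, columns=FOOD_TABLE_COLUMNS)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FoodTable):
            return NotImplemented
        return self._items == other._items


class Portion(BaseModel):
    """A consumed mass of one food."""

    model_config = ConfigDict(frozen=True)

    food_id: str
    mass_g: float = Field(ge=0)


class MealMoment(str, Enum):
    BEFORE_BREAKFAST = "before_breakfast"
    BREAKFAST = "breakfast"
    LUNCH = "lunch"
    DINNER = "dinner"
    SNACK = "snack"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: The three main meals of the day; snacks and pre-breakfast are inspected
#: separately, not scored by default.
MAIN_MEALS: tuple[MealMoment, ...] = (
    MealMoment.BREAKFAST,
    MealMoment.LUNCH,
    MealMoment.DINNER,
)

_MOMENT_ORDER = {m: i for i, m in enumerate(MealMoment)}


class FoodRecordEntry(BaseModel):
    """One line of a food record: a portion eaten at a meal moment on a day."""

    model_config = ConfigDict(frozen=True)

    person_id: str
    day: int = Field(ge=1)
    meal_moment: MealMoment
    portion: Portion


# ----------------------------------------------------------------------
# Food-table I/O
# ----------------------------------------------------------------------

def _parse_food_row(row: dict, where: str) -> FoodItem:
    def _field(name: str) -> object:
        if name not in row or pd.isna(row[name]) or row[name] == "":
            raise FoodTableError(f"{where}: missing required field {name!r}")
        return row[name]

    food_id = str(_field("id"))
    name = str(_field("name"))
    try:
        protein = float(_field("protein_g_per_100g"))
    except (TypeError, ValueError):
        raise FoodTableError(f"{where}: protein_g_per_100g is not numeric") from None
    energy_raw = row.get("energy_kcal_per_100g")
    energy = 0.0 if energy_raw is None or pd.isna(energy_raw) else float(energy_raw)
    origin = str(_field("origin")).strip().lower()
    if origin not in ("plant", "animal"):
        raise FoodTableError(f"{where}: origin must be 'plant' or 'animal', got {origin!r}")
    try:
        digestibility = _pct_to_fraction(_field("digestibility_pct"))
    except ValueError as exc:
        raise FoodTableError(f"{where}: {exc}") from None

    aa_values: dict[EAAKey, float] = {}
    any_aa = False
    for key in CANONICAL_ORDER:
        raw = row.get(key.value)
        if raw is None or (isinstance(raw, float) and pd.isna(raw)) or raw == "":
            aa_values[key] = 0.0
            continue
        try:
            value = float(raw)
        except (TypeError, ValueError):
            raise FoodTableError(f"{where}: column {key.value!r} is not numeric") from None
        if value < 0:
            raise FoodTableError(f"{where}: column {key.value!r} is negative")
        aa_values[key] = value
        any_aa = True

    try:
        return FoodItem(
            id=food_id,
            name=name,
            protein_g_per_100g=protein,
            energy_kcal_per_100g=energy,
            origin=origin,  # type: ignore[arg-type]
            digestibility=digestibility,
            aa_mg_per_g_protein=AminoAcidVector.from_mapping(aa_values),
            has_aa_data=any_aa,
        )
    except ValueError as exc:
        raise FoodTableError(f"{where}: {exc}") from None


def load_food_table(
    path: str | Path, dialect: Literal["csv", "json"] | None = None
) -> FoodTable:
    """Load a food-composition table from CSV or JSON.

    The CSV schema is ``FOOD_TABLE_COLUMNS`` (digestibility as a percentage,
    converted once here to a fraction). Foods whose amino-acid cells are all
    empty load with ``has_aa_data=False``. Unknown columns are ignored with a
    warning. Malformed rows raise :class:`FoodTableError` naming the row and
    field.
    """
    path = Path(path)
    if dialect is None:
        dialect = "json" if path.suffix.lower() == ".json" else "csv"

    if dialect == "json":
        payload = json.loads(path.read_text())
        meta = payload.get("metadata", {})
        table = FoodTable(
            source=str(meta.get("source", "")), version=str(meta.get("version", ""))
        )
        for i, row in enumerate(payload.get("foods", [])):
            table.add(_parse_food_row(dict(row), f"{path.name} food #{i + 1}"))
        return table

    df = pd.read_csv(path, dtype={"id": str, "name": str}, float_precision="round_trip")
    unknown = [c for c in df.columns if c not in FOOD_TABLE_COLUMNS]
    if unknown:
        logger.warning("ignoring unknown food-table columns: %s", ", ".join(unknown))
    missing = [
        c
        for c in ("id", "name", "protein_g_per_100g", "origin", "digestibility_pct")
        if c not in df.columns
    ]
    if missing and len(df) > 0:
        raise FoodTableError(f"{path.name}: missing required columns: {missing}")
    table = FoodTable(source=path.name)
    for i, row in enumerate(df.to_dict("records")):
        table.add(_parse_food_row(row, f"{path.name} row {i + 2}"))  # 1-based + header
    return table


def save_food_table(
    table: FoodTable, path: str | Path, dialect: Literal["csv", "json"] | None = None
) -> None:
    """Write a table in the documented schema; full float precision."""
    path = Path(path)
    if dialect is None:
        dialect = "json" if path.suffix.lower() == ".json" else "csv"
    if dialect == "json":
        foods = []
        for item in table:
            record: dict[str, object] = {
                "id": item.id,
                "name": item.name,
                "protein_g_per_100g": item.protein_g_per_100g,
                "energy_kcal_per_100g": item.energy_kcal_per_100g,
                "origin": item.origin,
                "digestibility_pct": _fraction_to_pct_str(item.digestibility),
            }
            if item.has_aa_data:
                record.update(
                    {k.value: v for k, v in item.aa_mg_per_g_protein.as_dict().items()}
                )
            foods.append(record)
        payload = {
            "metadata": {"source": table.source, "version": table.version},
            "foods": foods,
        }
        path.write_text(json.dumps(payload, indent=1))
    else:
        table.to_frame().to_csv(path, index=False, float_format=None)


# ----------------------------------------------------------------------
# Record I/O
# ----------------------------------------------------------------------

def _record_sort_key(entry: FoodRecordEntry) -> tuple:
    return (
        entry.person_id,
        entry.day,
        _MOMENT_ORDER[entry.meal_moment],
        entry.portion.food_id,
        entry.portion.mass_g,
    )


def load_records(path: str | Path) -> list[FoodRecordEntry]:
    """Load per-person food records (CSV: person_id,day,meal_moment,food_id,mass_g).

    Entries come back deterministically sorted by (person, day, moment).
    Unknown meal-moment strings raise an error listing the allowed values.
    """
    path = Path(path)
    df = pd.read_csv(
        path, dtype={"person_id": str, "food_id": str}, float_precision="round_trip"
    )
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing and len(df) > 0:
        raise FoodTableError(f"{path.name}: missing required columns: {missing}")
    entries: list[FoodRecordEntry] = []
    allowed = ", ".join(m.value for m in MealMoment)
    for i, row in enumerate(df.to_dict("records")):
        where = f"{path.name} row {i + 2}"
        raw_moment = str(row["meal_moment"]).strip().lower()
        try:
            moment = MealMoment(raw_moment)
        except ValueError:
            raise FoodTableError(
                f"{where}: unknown meal moment {raw_moment!r}; allowed: {allowed}"
            ) from None
        try:
            entries.append(
                FoodRecordEntry(
                    person_id=str(row["person_id"]),
                    day=int(row["day"]),
                    meal_moment=moment,
                    portion=Portion(
                        food_id=str(row["food_id"]), mass_g=float(row["mass_g"])
                    ),
                )
            )
        except (ValueError, TypeError) as exc:
            raise FoodTableError(f"{where}: {exc}") from None
    return sorted(entries, key=_record_sort_key)


def save_records(entries: list[FoodRecordEntry], path: str | Path) -> None:
    rows = [
        {
            "person_id": e.person_id,
            "day": e.day,
            "meal_moment": e.meal_moment.value,
            "food_id": e.portion.food_id,
            "mass_g": e.portion.mass_g,
        }
        for e in sorted(entries, key=_record_sort_key)
    ]
    pd.DataFrame(rows, columns=RECORD_COLUMNS).to_csv(path, index=False)


def load_persons(path: str | Path) -> list:
    """Load person profiles (CSV: person_id,body_weight_kg)."""
    from .requirements import PersonProfile

    df = pd.read_csv(path, dtype={"person_id": str}, float_precision="round_trip")
    missing = [c for c in ("person_id", "body_weight_kg") if c not in df.columns]
    if missing and len(df) > 0:
        raise FoodTableError(f"{Path(path).name}: missing required columns: {missing}")
    persons = []
    for i, row in enumerate(df.to_dict("records")):
        try:
            persons.append(
                PersonProfile(
                    person_id=str(row["person_id"]),
                    body_weight_kg=float(row["body_weight_kg"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise FoodTableError(f"{Path(path).name} row {i + 2}: {exc}") from None
    return sorted(persons, key=lambda p: p.person_id)


def validate_records(entries: list[FoodRecordEntry], table: FoodTable) -> None:
    """Check referential integrity of records against a food table."""
    unknown = sorted({e.portion.food_id for e in entries if e.portion.food_id not in table})
    if unknown:
        raise UnknownFoodError(f"records reference unknown food ids: {unknown}")


def group_records(
    entries: list[FoodRecordEntry],
) -> dict[tuple[str, int, MealMoment], list[Portion]]:
    """Group record entries into meals keyed by (person, day, moment).

    Keys and portions come out in deterministic sorted order regardless of
    input order.
    """
    grouped: dict[tuple[str, int, MealMoment], list[Portion]] = {}
    for entry in sorted(entries, key=_record_sort_key):
        key = (entry.person_id, entry.day, entry.meal_moment)
        grouped.setdefault(key, []).append(entry.portion)
    return grouped
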