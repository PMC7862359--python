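"""Cattle-register tables: animals, movements, snapshot semantics.

The register emulates a national animal identification and movement
database: one row per animal (identity, sex, breed, parent breeds, birth
date, one residency interval in its herd) and one row per movement
(animal, date, source herd, destination).  Three snapshot dates within a
single study year define herd membership for the demographic variables.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import pandas as pd

__all__ = [
    "BreedType",
    "Sex",
    "DestinationKind",
    "AnimalRecord",
    "MovementRecord",
    "Registry",
    "RegistryError",
    "DAIRY_BREEDS",
    "BEEF_BREEDS",
    "classify_breed_type",
    "read_registry",
    "write_registry",
    "validate_registry",
]

#: Dairy breeds recognised for parent-based breed typing (ICBF convention).
DAIRY_BREEDS = frozenset(
    {
        "Ayrshire",
        "Brown Swiss",
        "Holstein/Friesian",
        "Jersey",
        "Normande",
        "Norwegian Red",
    }
)

#: Beef breeds recognised for parent-based breed typing.
BEEF_BREEDS = frozenset(
    {
        "Angus",
        "Aubrac",
        "Blonde d'Aquitaine",
        "Belgian Blue",
        "Belted Galloway",
        "Bazadais",
        "Charolais",
        "Dexter",
        "Galloway",
        "Hereford",
        "Highland",
        "Irish Maol/Droimeann",
        "Kerry",
        "Longhorn",
        "Limousin",
        "Marchigiana",
        "Montbeliarde",
        "MRI/MRY",
        "Piedmontese",
        "Partenaise",
        "Rotbunte",
        "Romagnola",
        "Salers",
        "Shorthorn",
        "Simmental",
    }
)


class BreedType(str, Enum):
    DAIRY = "dairy"
    BEEF = "beef"
    CROSS = "cross"
    OTHER = "other"


class Sex(str, Enum):
    FEMALE = "female"
    MALE = "male"


class DestinationKind(str, Enum):
    HERD = "herd"
    SLAUGHTER = "slaughter"
    EXPORT = "export"


#: Terminal destination codes used when a movement leaves the herd network.
TERMINAL_CODES = {DestinationKind.SLAUGHTER: "SLAUGHTER", DestinationKind.EXPORT: "EXPORT"}


class RegistryError(ValueError):
    """Raised when register tables cannot be loaded or fail validation."""


@dataclass(frozen=True)
class AnimalRecord:
    """One animal and its single residency interval in its herd.

    ``herd_exit_date`` of ``None`` means the residency is still open at
    the end of the study year.  ``has_calved_by_sep1`` records whether
    the animal had ever calved by the September snapshot.
    """

    animal_id: str
    herd_id: str
    sex: Sex
    breed: str
    dam_breed: str | None
    sire_breed: str | None
    birth_date: dt.date
    has_calved_by_sep1: bool
    herd_entry_date: dt.date
    herd_exit_date: dt.date | None = None


@dataclass(frozen=True)
class MovementRecord:
    """One animal movement: out of ``source_herd`` on ``date``.

    ``destination_id`` is a herd id for herd-to-herd moves, otherwise a
    terminal code (slaughterhouse or export point).
    """

    animal_id: str
    date: dt.date
    source_herd: str
    destination_id: str
    destination_kind: DestinationKind


@dataclass
class Registry:
    """A validated register: animal table, movement table, snapshot dates."""

    animals: list[AnimalRecord]
    movements: list[MovementRecord]
    study_year: int = 2017
    snapshot_dates: tuple[dt.date, dt.date, dt.date] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.snapshot_dates is None:
            y = self.study_year
            self.snapshot_dates = (dt.date(y, 1, 1), dt.date(y, 5, 1), dt.date(y, 9, 1))

    # -- convenience accessors -------------------------------------------------

    def herd_ids(self) -> list[str]:
        return sorted({a.herd_id for a in self.animals})

    def animals_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "animal_id": [a.animal_id for a in self.animals],
                "herd_id": [a.herd_id for a in self.animals],
                "sex": [a.sex.value for a in self.animals],
                "breed": [a.breed for a in self.animals],
                "dam_breed": [a.dam_breed for a in self.animals],
                "sire_breed": [a.sire_breed for a in self.animals],
                "birth_date": [a.birth_date for a in self.animals],
                "has_calved_by_sep1": [a.has_calved_by_sep1 for a in self.animals],
                "herd_entry_date": [a.herd_entry_date for a in self.animals],
                "herd_exit_date": [a.herd_exit_date for a in self.animals],
            }
        )

    def movements_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "animal_id": [m.animal_id for m in self.movements],
                "date": [m.date for m in self.movements],
                "source_herd": [m.source_herd for m in self.movements],
                "destination_id": [m.destination_id for m in self.movements],
                "destination_kind": [m.destination_kind.value for m in self.movements],
            }
        )


def classify_breed_type(dam_breed: str | None, sire_breed: str | None) -> BreedType:
    """Assign an animal's breed type from its dam and sire breeds.

    dairy if both parents are on the dairy list; beef if both are on the
    beef list; cross if one parent is dairy and the other beef; other if
    either parent is missing or not on either list.
    """
    if not dam_breed or not sire_breed:
        return BreedType.OTHER
    dam_dairy, dam_beef = dam_breed in DAIRY_BREEDS, dam_breed in BEEF_BREEDS
    sire_dairy, sire_beef = sire_breed in DAIRY_BREEDS, sire_breed in BEEF_BREEDS
    if dam_dairy and sire_dairy:
        return BreedType.DAIRY
    if dam_beef and sire_beef:
        return BreedType.BEEF
    if (dam_dairy and sire_beef) or (dam_beef and sire_dairy):
        return BreedType.CROSS
    return BreedType.OTHER


# -- CSV dialect ---------------------------------------------------------------

ANIMAL_COLUMNS = [
    "animal_id",
    "herd_id",
    "sex",
    "breed",
    "dam_breed",
    "sire_breed",
    "birth_date",
    "has_calved_by_sep1",
    "herd_entry_date",
    "herd_exit_date",
]
MOVEMENT_COLUMNS = ["animal_id", "date", "source_herd", "destination_id", "destination_kind"]


def _parse_date(value, row: int, column: str, errors: list[str]) -> dt.date | None:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    try:
        return dt.date.fromisoformat(str(value))
    except ValueError:
        errors.append(f"row {row}: column {column!r}: unparseable date {value!r}")
        return None


def read_registry(
    animal_table: str | Path,
    movement_table: str | Path,
    study_year: int = 2017,
    snapshot_dates: tuple[dt.date, dt.date, dt.date] | None = None,
) -> Registry:
    """Load and validate a register from its two CSV tables.

    Raises :class:`RegistryError` naming the offending rows on missing
    columns, unparseable dates, duplicate animal ids or invariant
    violations.
    """
    adf = pd.read_csv(animal_table, dtype=str, keep_default_na=False)
    mdf = pd.read_csv(movement_table, dtype=str, keep_default_na=False)

    missing = [c for c in ANIMAL_COLUMNS if c not in adf.columns]
    missing += [c for c in MOVEMENT_COLUMNS if c not in mdf.columns]
    if missing:
        raise RegistryError(f"missing columns: {missing}")

    errors: list[str] = []
    dupes = adf.animal_id[adf.animal_id.duplicated()].unique().tolist()
    if dupes:
        raise RegistryError(f"duplicate animal_id values: {dupes}")

    animals: list[AnimalRecord] = []
    for i, row in enumerate(adf.itertuples(index=False)):
        birth = _parse_date(row.birth_date, i, "birth_date", errors)
        entry = _parse_date(row.herd_entry_date, i, "herd_entry_date", errors)
        exit_ = _parse_date(row.herd_exit_date, i, "herd_exit_date", errors)
        try:
            sex = Sex(row.sex)
        except ValueError:
            errors.append(f"row {i}: unknown sex {row.sex!r}")
            continue
        if birth is None or entry is None:
            continue
        animals.append(
            AnimalRecord(
                animal_id=row.animal_id,
                herd_id=row.herd_id,
                sex=sex,
                breed=row.breed,
                dam_breed=row.dam_breed or None,
                sire_breed=row.sire_breed or None,
                birth_date=birth,
                has_calved_by_sep1=str(row.has_calved_by_sep1).lower() in {"true", "1", "yes"},
                herd_entry_date=entry,
                herd_exit_date=exit_,
            )
        )

    movements: list[MovementRecord] = []
    for i, row in enumerate(mdf.itertuples(index=False)):
        date = _parse_date(row.date, i, "date", errors)
        try:
            kind = DestinationKind(row.destination_kind)
        except ValueError:
            errors.append(f"movement row {i}: unknown destination_kind {row.destination_kind!r}")
            continue
        if date is None:
            continue
        movements.append(
            MovementRecord(
                animal_id=row.animal_id,
                date=date,
                source_herd=row.source_herd,
                destination_id=row.destination_id,
                destination_kind=kind,
            )
        )

    if errors:
        raise RegistryError("register load failed:\n" + "\n".join(errors))

    registry = Registry(animals=animals, movements=movements, study_year=study_year)
    if snapshot_dates is not None:
        registry.snapshot_dates = snapshot_dates
    violations = validate_registry(registry)
    if violations:
        raise RegistryError("register validation failed:\n" + "\n".join(violations))
    return registry


def write_registry(registry: Registry, animal_table: str | Path, movement_table: str | Path) -> None:
    """Write the register back to its two CSV tables (ISO-8601 dates)."""
    adf = registry.animals_frame()
    for col in ("birth_date", "herd_entry_date", "herd_exit_date"):
        adf[col] = adf[col].map(lambda d: d.isoformat() if d is not None else "")
    adf.to_csv(animal_table, index=False)
    mdf = registry.movements_frame()
    mdf["date"] = mdf["date"].map(lambda d: d.isoformat())
    mdf.to_csv(movement_table, index=False)


def validate_registry(registry: Registry) -> list[str]:
    """Check every register invariant; return one message per violation.

    Checked: date ordering per animal, calved-implies-female, unique
    animal ids, movement animal ids known, movement dates inside the
    study year, terminal codes on slaughter/export moves, snapshot dates
    strictly increasing.
    """
    violations: list[str] = []
    seen: set[str] = set()
    for a in registry.animals:
        if a.animal_id in seen:
            violations.append(f"{a.animal_id}: duplicate_animal_id")
        seen.add(a.animal_id)
        if a.birth_date > a.herd_entry_date:
            violations.append(f"{a.animal_id}: birth_after_entry")
        if a.herd_exit_date is not None and a.herd_entry_date > a.herd_exit_date:
            violations.append(f"{a.animal_id}: exit_before_entry")
        if a.has_calved_by_sep1 and a.sex is not Sex.FEMALE:
            violations.append(f"{a.animal_id}: calved_male")

    year = registry.study_year
    for m in registry.movements:
        if m.animal_id not in seen:
            violations.append(f"movement {m.animal_id}@{m.date}: unknown_animal")
        if m.date.year != year:
            violations.append(f"movement {m.animal_id}@{m.date}: outside_study_year")
        if m.destination_kind is not DestinationKind.HERD:
            if m.destination_id != TERMINAL_CODES[m.destination_kind]:
                violations.append(f"movement {m.animal_id}@{m.date}: terminal_code_mismatch")

    d1, d2, d3 = registry.snapshot_dates
    if not (d1 < d2 < d3):
        violations.append("registry: snapshot_dates_not_increasing")
    return violations


def is_member(animal: AnimalRecord, date: dt.date) -> bool:
    """Half-open residency: entered on or before ``date``, not yet exited.

    An animal that exits on ``date`` is no longer a member that day; an
    animal that enters on ``date`` is.  This avoids double counting an
    animal in two herds on a movement day.
    """
    if animal.herd_entry_date > date:
        return False
    return animal.herd_exit_date is None or animal.herd_exit_date > date
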