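"""Shared fixtures: a tiny hand-built register and a generated one."""

from __future__ import annotations

import datetime as dt

import pytest

from herdtyper.features import compute_all_features
from herdtyper.registry import (
    AnimalRecord,
    DestinationKind,
    MovementRecord,
    Registry,
    Sex,
)
from herdtyper.synth import GeneratorConfig, generate_registry

YEAR = 2017


def animal(
    aid: str,
    herd: str = "H1",
    sex: Sex = Sex.FEMALE,
    parents: tuple[str, str] = ("Holstein/Friesian", "Holstein/Friesian"),
    birth: dt.date = dt.date(2014, 3, 1),
    calved: bool = False,
    entry: dt.date | None = None,
    exit: dt.date | None = None,
) -> AnimalRecord:
    return AnimalRecord(
        animal_id=aid,
        herd_id=herd,
        sex=sex,
        breed=parents[0],
        dam_breed=parents[0],
        sire_breed=parents[1],
        birth_date=birth,
        has_calved_by_sep1=calved,
        herd_entry_date=entry or birth,
        herd_exit_date=exit,
    )


def move(
    aid: str,
    date: dt.date,
    source: str,
    dest: str,
    kind: DestinationKind = DestinationKind.HERD,
) -> MovementRecord:
    return MovementRecord(
        animal_id=aid, date=date, source_herd=source, destination_id=dest, destination_kind=kind
    )


@pytest.fixture(scope="session")
def small_registry() -> tuple[Registry, dict[str, str]]:
    """Three herds of each archetype; enough for structural checks."""
    return generate_registry(GeneratorConfig(herds_per_type=3, seed=11))


@pytest.fixture(scope="session")
def small_features(small_registry):
    registry, labels = small_registry
    return compute_all_features(registry), labels
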