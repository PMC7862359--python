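"""Herd-level feature engineering: the nine management variables.

Every herd is summarised by nine proportions derived from the register:

==========================  ====================================================
pFemaleAnimals              females / herd size at the May snapshot
pDairyBreed                 dairy-bred animals / herd size (May)
pCrossBreed                 dairy-beef crosses / herd size (May)
pCalvedAnimals              ever-calved animals / herd size at the September
                            snapshot
pMalesBetween1and2Years     males aged [1, 2) years / all animals aged [1, 2)
                            years (May)
pAnimalsLess30Days          purchased animals resold in under 30 days / all
                            out-moves of the year
pOutMovesToSL               out-moves to slaughter / maximum herd size (the
                            largest of the three snapshot sizes)
pOutMovesToBirthHerd        out-moves returning an animal to its birth herd /
                            all out-moves
pInMovesToBirthHerd         in-moves returning an animal to its birth herd /
                            all in-moves
==========================  ====================================================

Zero denominators yield 0 and are flagged so downstream consumers always
receive complete vectors.  An animal's birth herd is reconstructed from
its movement chain: the source herd of its first movement of the year,
or its residency herd if it never moved.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from enum import Enum

import pandas as pd

from .registry import BreedType, DestinationKind, Registry, Sex, classify_breed_type, is_member

__all__ = [
    "FEATURE_NAMES",
    "HerdFeatures",
    "InitialClass",
    "snapshot_members",
    "compute_features",
    "compute_all_features",
    "features_frame",
    "initial_classification",
    "BREEDING_THRESHOLD",
    "DAIRY_THRESHOLD",
    "BEEF_THRESHOLD",
    "SHORT_STAY_DAYS",
]

logger = logging.getLogger(__name__)

FEATURE_NAMES = [
    "pFemaleAnimals",
    "pDairyBreed",
    "pCrossBreed",
    "pCalvedAnimals",
    "pMalesBetween1and2Years",
    "pAnimalsLess30Days",
    "pOutMovesToSL",
    "pOutMovesToBirthHerd",
    "pInMovesToBirthHerd",
]

#: A herd is a breeding enterprise if at least 25% of its September
#: animals have ever calved (ICBF convention).
BREEDING_THRESHOLD = 0.25
#: Breeding herds with at least 70% dairy animals are dairy ...
DAIRY_THRESHOLD = 0.70
#: ... with under 30% dairy animals are beef; the rest are mixed.
BEEF_THRESHOLD = 0.30
#: Purchased animals resold strictly within this many days count as
#: dealer throughput.
SHORT_STAY_DAYS = 30

#: Age band for the youngstock variable: [1, 2) years as completed days.
YEARLING_MIN_DAYS = 365
YEARLING_MAX_DAYS = 730


class InitialClass(str, Enum):
    DAIRY = "dairy"
    BEEF = "beef"
    MIXED = "mixed"
    UNKNOWN = "unknown"


@dataclass
class HerdFeatures:
    herd_id: str
    herd_size_jan: int
    herd_size_may: int
    herd_size_sep: int
    maximum_herd_size: int
    n_out_moves: int
    n_in_moves: int
    pFemaleAnimals: float
    pDairyBreed: float
    pCrossBreed: float
    pCalvedAnimals: float
    pMalesBetween1and2Years: float
    pAnimalsLess30Days: float
    pOutMovesToSL: float
    pOutMovesToBirthHerd: float
    pInMovesToBirthHerd: float
    zero_denominator_flags: list[str] = field(default_factory=list)

    def vector(self) -> list[float]:
        return [getattr(self, name) for name in FEATURE_NAMES]

    def as_dict(self) -> dict:
        d = {
            "herd_id": self.herd_id,
            "herd_size_jan": self.herd_size_jan,
            "herd_size_may": self.herd_size_may,
            "herd_size_sep": self.herd_size_sep,
            "maximum_herd_size": self.maximum_herd_size,
            "n_out_moves": self.n_out_moves,
            "n_in_moves": self.n_in_moves,
        }
        d.update({name: getattr(self, name) for name in FEATURE_NAMES})
        return d


def snapshot_members(registry: Registry, herd_id: str, date: dt.date) -> set[str]:
    """Animal ids resident in ``herd_id`` on ``date`` (half-open interval)."""
    return {
        a.animal_id
        for a in registry.animals
        if a.herd_id == herd_id and is_member(a, date)
    }


def _birth_herds(registry: Registry) -> dict[str, str]:
    """Birth herd per animal: source of its first movement, else its herd."""
    birth = {a.animal_id: a.herd_id for a in registry.animals}
    first_move: dict[str, tuple[dt.date, str]] = {}
    for m in registry.movements:
        cur = first_move.get(m.animal_id)
        if cur is None or m.date < cur[0]:
            first_move[m.animal_id] = (m.date, m.source_herd)
    for animal_id, (_, source) in first_move.items():
        birth[animal_id] = source
    return birth


def _ratio(numerator: float, denominator: float, herd_id: str, name: str, flags: list[str]) -> float:
    if denominator == 0:
        flags.append(name)
        logger.warning("herd %s: zero denominator for %s; using 0", herd_id, name)
        return 0.0
    return numerator / denominator


def compute_features(registry: Registry, herd_id: str) -> HerdFeatures:
    """Compute the nine herd-level variables for one herd."""
    birth = _birth_herds(registry)
    herd_animals = [a for a in registry.animals if a.herd_id == herd_id]
    out_moves = [m for m in registry.movements if m.source_herd == herd_id]
    in_moves = [
        m
        for m in registry.movements
        if m.destination_kind is DestinationKind.HERD and m.destination_id == herd_id
    ]
    return _compute(herd_id, herd_animals, out_moves, in_moves, registry.snapshot_dates, birth)


def compute_all_features(registry: Registry) -> dict[str, HerdFeatures]:
    """Compute features for every herd in the animal table.

    Equivalent to :func:`compute_features` per herd, with the grouping
    work done once.
    """
    birth = _birth_herds(registry)
    animals_by_herd: dict[str, list] = {}
    for a in registry.animals:
        animals_by_herd.setdefault(a.herd_id, []).append(a)
    out_by_herd: dict[str, list] = {}
    in_by_herd: dict[str, list] = {}
    for m in registry.movements:
        out_by_herd.setdefault(m.source_herd, []).append(m)
        if m.destination_kind is DestinationKind.HERD:
            in_by_herd.setdefault(m.destination_id, []).append(m)
    return {
        h: _compute(
            h,
            animals_by_herd[h],
            out_by_herd.get(h, []),
            in_by_herd.get(h, []),
            registry.snapshot_dates,
            birth,
        )
        for h in registry.herd_ids()
    }


def _compute(
    herd_id: str,
    herd_animals: list,
    out_moves: list,
    in_moves: list,
    snapshot_dates,
    birth: dict[str, str],
) -> HerdFeatures:
    jan, may, sep = snapshot_dates

    jan_members = [a for a in herd_animals if is_member(a, jan)]
    may_members = [a for a in herd_animals if is_member(a, may)]
    sep_members = [a for a in herd_animals if is_member(a, sep)]
    size_jan, size_may, size_sep = len(jan_members), len(may_members), len(sep_members)
    max_size = max(size_jan, size_may, size_sep)

    flags: list[str] = []

    n_female = sum(1 for a in may_members if a.sex is Sex.FEMALE)
    breed_types = [classify_breed_type(a.dam_breed, a.sire_breed) for a in may_members]
    n_dairy = sum(1 for b in breed_types if b is BreedType.DAIRY)
    n_cross = sum(1 for b in breed_types if b is BreedType.CROSS)
    n_calved = sum(1 for a in sep_members if a.has_calved_by_sep1)

    def age_days(a) -> int:
        return (may - a.birth_date).days

    yearlings = [a for a in may_members if YEARLING_MIN_DAYS <= age_days(a) < YEARLING_MAX_DAYS]
    n_yearling_males = sum(1 for a in yearlings if a.sex is Sex.MALE)

    n_out, n_in = len(out_moves), len(in_moves)

    n_out_sl = sum(1 for m in out_moves if m.destination_kind is DestinationKind.SLAUGHTER)
    n_out_birth = sum(
        1
        for m in out_moves
        if m.destination_kind is DestinationKind.HERD
        and m.destination_id == birth.get(m.animal_id)
    )
    n_in_birth = sum(1 for m in in_moves if herd_id == birth.get(m.animal_id))

    # Dealer throughput: an animal purchased during the year (an in-move
    # into this herd) and moved out again strictly under 30 days later.
    first_in: dict[str, dt.date] = {}
    for m in in_moves:
        if m.animal_id not in first_in or m.date < first_in[m.animal_id]:
            first_in[m.animal_id] = m.date
    n_short = 0
    for animal_id, date_in in first_in.items():
        exits = [m.date for m in out_moves if m.animal_id == animal_id and m.date >= date_in]
        if exits and (min(exits) - date_in).days < SHORT_STAY_DAYS:
            n_short += 1

    return HerdFeatures(
        herd_id=herd_id,
        herd_size_jan=size_jan,
        herd_size_may=size_may,
        herd_size_sep=size_sep,
        maximum_herd_size=max_size,
        n_out_moves=n_out,
        n_in_moves=n_in,
        pFemaleAnimals=_ratio(n_female, size_may, herd_id, "pFemaleAnimals", flags),
        pDairyBreed=_ratio(n_dairy, size_may, herd_id, "pDairyBreed", flags),
        pCrossBreed=_ratio(n_cross, size_may, herd_id, "pCrossBreed", flags),
        pCalvedAnimals=_ratio(n_calved, size_sep, herd_id, "pCalvedAnimals", flags),
        pMalesBetween1and2Years=_ratio(
            n_yearling_males, len(yearlings), herd_id, "pMalesBetween1and2Years", flags
        ),
        pAnimalsLess30Days=_ratio(n_short, n_out, herd_id, "pAnimalsLess30Days", flags),
        pOutMovesToSL=_ratio(n_out_sl, max_size, herd_id, "pOutMovesToSL", flags),
        pOutMovesToBirthHerd=_ratio(n_out_birth, n_out, herd_id, "pOutMovesToBirthHerd", flags),
        pInMovesToBirthHerd=_ratio(n_in_birth, n_in, herd_id, "pInMovesToBirthHerd", flags),
        zero_denominator_flags=flags,
    )


def features_frame(features: dict[str, HerdFeatures] | list[HerdFeatures]) -> pd.DataFrame:
    """Tabulate per-herd features, one row per herd."""
    if isinstance(features, dict):
        features = list(features.values())
    return pd.DataFrame([f.as_dict() for f in features])


def initial_classification(features: HerdFeatures) -> InitialClass:
    """Seed dairy/beef/mixed/unknown split from calving and breed shares.

    Non-breeding herds (under 25% ever-calved by September) are left
    unknown; breeding herds are dairy at >= 70% dairy animals, beef at
    < 30%, and mixed in between.
    """
    if features.pCalvedAnimals < BREEDING_THRESHOLD:
        return InitialClass.UNKNOWN
    if features.pDairyBreed >= DAIRY_THRESHOLD:
        return InitialClass.DAIRY
    if features.pDairyBreed < BEEF_THRESHOLD:
        return InitialClass.BEEF
    return InitialClass.MIXED
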