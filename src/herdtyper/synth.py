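"""Synthetic cattle-register generator with labelled herd archetypes.

Real national registers are confidential, so every downstream stage is
exercised on synthetic registers whose herds carry the management
signature of one of the 17 herd types: dairy systems (D, DnR-C, DnR-nC,
DRm), suckler beef systems (BP, BSW, BSY, BSY-nR, BSB), mixed herds (M),
stores and contract rearers (Sdm, Sbm, Sbf, Sbmx, Rdf), fatteners (F)
and traders (T).

Each archetype is a set of nominal herd-level fractions (sex, breed,
calving, age structure, movement mix).  Herd composition is built by
deterministic rounding of those fractions at the drawn herd size, so the
empirical feature vector of a generated herd sits close to its nominal
vector; randomness enters through herd sizes, ages, dates and the
assignment shuffles.  Counterpart herds (trade partners, contract
rearers) are emitted minimally and labelled ``counterpart`` so they do
not enter recovery statistics.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np

from .features import HerdFeatures
from .registry import (
    AnimalRecord,
    DestinationKind,
    MovementRecord,
    Registry,
    Sex,
)

__all__ = [
    "ArchetypeSpec",
    "GeneratorConfig",
    "default_archetypes",
    "generate_herd",
    "generate_registry",
    "COUNTERPART_LABEL",
]

COUNTERPART_LABEL = "counterpart"

_DAIRY_PARENTS = ("Holstein/Friesian", "Holstein/Friesian")
_BEEF_PARENTS = ("Charolais", "Limousin")
_CROSS_PARENTS = ("Holstein/Friesian", "Angus")  # dairy dam, beef sire


@dataclass(frozen=True)
class ArchetypeSpec:
    """Generative parameters for one herd type.

    The first block are the nominal values of the nine herd variables
    the classifier reads (fractions of the May herd, or of yearly
    moves).  The second block shapes age structure and trade volume:
    ``yearling_fraction``/``calf_fraction`` partition the May herd into
    age bands and ``out_rate``/``in_rate`` set yearly out- and in-moves
    as a multiple of herd size.
    """

    herd_type: str
    herd_size_range: tuple[int, int]
    female_fraction: float
    dairy_fraction: float
    cross_fraction: float
    calved_fraction: float
    male_1to2_fraction: float
    slaughter_out_fraction: float
    birth_herd_out_fraction: float
    birth_herd_in_fraction: float
    short_stay_fraction: float
    yearling_fraction: float = 0.20
    calf_fraction: float = 0.15
    out_rate: float = 0.40
    in_rate: float = 0.10
    short_stay_days: tuple[int, int] = (5, 26)  # dealer stay, half-open draw

    def validate(self) -> None:
        lo, hi = self.herd_size_range
        if not (0 < lo <= hi):
            raise ValueError(f"{self.herd_type}: empty herd size range")
        props = {
            "female_fraction": self.female_fraction,
            "dairy_fraction": self.dairy_fraction,
            "cross_fraction": self.cross_fraction,
            "calved_fraction": self.calved_fraction,
            "male_1to2_fraction": self.male_1to2_fraction,
            "slaughter_out_fraction": self.slaughter_out_fraction,
            "birth_herd_out_fraction": self.birth_herd_out_fraction,
            "birth_herd_in_fraction": self.birth_herd_in_fraction,
            "short_stay_fraction": self.short_stay_fraction,
            "yearling_fraction": self.yearling_fraction,
            "calf_fraction": self.calf_fraction,
        }
        for name, value in props.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{self.herd_type}: {name}={value} outside [0, 1]")
        if self.dairy_fraction + self.cross_fraction > 1.0:
            raise ValueError(f"{self.herd_type}: dairy + cross fractions exceed 1")
        if self.yearling_fraction + self.calf_fraction > 1.0:
            raise ValueError(f"{self.herd_type}: age fractions exceed 1")
        # Movement budget must be non-negative at nominal rates.
        out_budget = self.out_rate - (
            self.slaughter_out_fraction
            + self.birth_herd_out_fraction * self.out_rate
            + self.birth_herd_in_fraction * self.in_rate
            + self.short_stay_fraction * self.out_rate
        )
        if out_budget < -1e-9:
            raise ValueError(f"{self.herd_type}: out-move budget over-committed")

    def expected_features(self) -> HerdFeatures:
        """The nominal nine-variable vector this archetype aims at."""
        return HerdFeatures(
            herd_id=self.herd_type,
            herd_size_jan=0,
            herd_size_may=0,
            herd_size_sep=0,
            maximum_herd_size=0,
            n_out_moves=0,
            n_in_moves=0,
            pFemaleAnimals=self.female_fraction,
            pDairyBreed=self.dairy_fraction,
            pCrossBreed=self.cross_fraction,
            pCalvedAnimals=self.calved_fraction,
            pMalesBetween1and2Years=self.male_1to2_fraction,
            pAnimalsLess30Days=self.short_stay_fraction,
            pOutMovesToSL=self.slaughter_out_fraction,
            pOutMovesToBirthHerd=self.birth_herd_out_fraction,
            pInMovesToBirthHerd=self.birth_herd_in_fraction,
        )


@dataclass
class GeneratorConfig:
    herds_per_type: int = 20
    seed: int = 0
    study_year: int = 2017
    archetype_overrides: dict[str, ArchetypeSpec] = field(default_factory=dict)


def default_archetypes() -> dict[str, ArchetypeSpec]:
    """Nominal parameters for the 17 herd types.

    Values are calibration constants placed centrally inside each
    type's region of the default classification tree; the underlying
    management signatures (which variable is high or low for which
    type) follow the qualitative type descriptions.
    """

    def spec(herd_type: str, size=(60, 140), **kw) -> ArchetypeSpec:
        s = ArchetypeSpec(herd_type=herd_type, herd_size_range=size, **kw)
        s.validate()
        return s

    specs = [
        # -- dairy group -------------------------------------------------------
        spec(
            "D",
            female_fraction=0.90, dairy_fraction=0.90, cross_fraction=0.05,
            calved_fraction=0.45, male_1to2_fraction=0.05,
            slaughter_out_fraction=0.10, birth_herd_out_fraction=0.0,
            birth_herd_in_fraction=0.0, short_stay_fraction=0.02,
            yearling_fraction=0.20, calf_fraction=0.15, out_rate=0.40, in_rate=0.10,
        ),
        spec(
            "DnR-C",
            female_fraction=0.95, dairy_fraction=0.90, cross_fraction=0.05,
            calved_fraction=0.78, male_1to2_fraction=0.05,
            slaughter_out_fraction=0.08, birth_herd_out_fraction=0.0,
            birth_herd_in_fraction=0.60, short_stay_fraction=0.02,
            yearling_fraction=0.05, calf_fraction=0.10, out_rate=0.50, in_rate=0.30,
        ),
        spec(
            "DnR-nC",
            female_fraction=0.95, dairy_fraction=0.90, cross_fraction=0.05,
            calved_fraction=0.78, male_1to2_fraction=0.05,
            slaughter_out_fraction=0.08, birth_herd_out_fraction=0.0,
            birth_herd_in_fraction=0.05, short_stay_fraction=0.02,
            yearling_fraction=0.05, calf_fraction=0.10, out_rate=0.50, in_rate=0.30,
        ),
        spec(
            "DRm",
            female_fraction=0.55, dairy_fraction=0.85, cross_fraction=0.10,
            calved_fraction=0.40, male_1to2_fraction=0.70,
            slaughter_out_fraction=0.15, birth_herd_out_fraction=0.0,
            birth_herd_in_fraction=0.0, short_stay_fraction=0.02,
            yearling_fraction=0.30, calf_fraction=0.10, out_rate=0.40, in_rate=0.10,
        ),
        # -- mixed -------------------------------------------------------------
        spec(
            "M",
            female_fraction=0.85, dairy_fraction=0.48, cross_fraction=0.42,
            calved_fraction=0.45, male_1to2_fraction=0.10,
            slaughter_out_fraction=0.10, birth_herd_out_fraction=0.0,
            birth_herd_in_fraction=0.0, short_stay_fraction=0.02,
            yearling_fraction=0.15, calf_fraction=0.15, out_rate=0.40, in_rate=0.10,
        ),
        # -- beef group --------------------------------------------------------
        spec(
            "BP",
            female_fraction=0.65, dairy_fraction=0.02, cross_fraction=0.04,
            calved_fraction=0.45, male_1to2_fraction=0.40,
            slaughter_out_fraction=0.15, birth_herd_out_fraction=0.0,
            birth_herd_in_fraction=0.0, short_stay_fraction=0.02,
            yearling_fraction=0.25, calf_fraction=0.15, out_rate=0.40, in_rate=0.10,
        ),
        spec(
            "BSB",
            female_fraction=0.55, dairy_fraction=0.02, cross_fraction=0.30,
            calved_fraction=0.35, male_1to2_fraction=0.50,
            slaughter_out_fraction=0.55, birth_herd_out_fraction=0.0,
            birth_herd_in_fraction=0.0, short_stay_fraction=0.02,
            yearling_fraction=0.30, calf_fraction=0.15, out_rate=0.70, in_rate=0.10,
        ),
        spec(
            "BSY",
            female_fraction=0.55, dairy_fraction=0.02, cross_fraction=0.30,
            calved_fraction=0.32, male_1to2_fraction=0.45,
            slaughter_out_fraction=0.08, birth_herd_out_fraction=0.0,
            birth_herd_in_fraction=0.0, short_stay_fraction=0.02,
            yearling_fraction=0.35, calf_fraction=0.15, out_rate=0.40, in_rate=0.10,
        ),
        spec(
            "BSY-nR",
            female_fraction=0.40, dairy_fraction=0.02, cross_fraction=0.30,
            calved_fraction=0.28, male_1to2_fraction=0.85,
            slaughter_out_fraction=0.08, birth_herd_out_fraction=0.0,
            birth_herd_in_fraction=0.0, short_stay_fraction=0.02,
            yearling_fraction=0.40, calf_fraction=0.10, out_rate=0.40, in_rate=0.15,
        ),
        spec(
            "BSW",
            female_fraction=0.70, dairy_fraction=0.02, cross_fraction=0.30,
            calved_fraction=0.45, male_1to2_fraction=0.05,
            slaughter_out_fraction=0.08, birth_herd_out_fraction=0.0,
            birth_herd_in_fraction=0.0, short_stay_fraction=0.02,
            yearling_fraction=0.12, calf_fraction=0.25, out_rate=0.50, in_rate=0.05,
        ),
        # -- store / rearing group ---------------------------------------------
        spec(
            "Sdm",
            female_fraction=0.10, dairy_fraction=0.80, cross_fraction=0.15,
            calved_fraction=0.02, male_1to2_fraction=0.90,
            slaughter_out_fraction=0.10, birth_herd_out_fraction=0.03,
            birth_herd_in_fraction=0.0, short_stay_fraction=0.03,
            yearling_fraction=0.55, calf_fraction=0.20, out_rate=0.60, in_rate=0.60,
        ),
        spec(
            "Sbm",
            female_fraction=0.10, dairy_fraction=0.10, cross_fraction=0.25,
            calved_fraction=0.02, male_1to2_fraction=0.90,
            slaughter_out_fraction=0.10, birth_herd_out_fraction=0.03,
            birth_herd_in_fraction=0.0, short_stay_fraction=0.03,
            yearling_fraction=0.55, calf_fraction=0.15, out_rate=0.60, in_rate=0.60,
        ),
        spec(
            "Sbf",
            female_fraction=0.90, dairy_fraction=0.10, cross_fraction=0.25,
            calved_fraction=0.03, male_1to2_fraction=0.10,
            slaughter_out_fraction=0.10, birth_herd_out_fraction=0.03,
            birth_herd_in_fraction=0.0, short_stay_fraction=0.03,
            yearling_fraction=0.55, calf_fraction=0.15, out_rate=0.60, in_rate=0.60,
        ),
        spec(
            "Sbmx",
            female_fraction=0.50, dairy_fraction=0.10, cross_fraction=0.25,
            calved_fraction=0.02, male_1to2_fraction=0.50,
            slaughter_out_fraction=0.10, birth_herd_out_fraction=0.03,
            birth_herd_in_fraction=0.0, short_stay_fraction=0.03,
            yearling_fraction=0.55, calf_fraction=0.15, out_rate=0.60, in_rate=0.60,
        ),
        spec(
            "Rdf",
            female_fraction=0.95, dairy_fraction=0.90, cross_fraction=0.05,
            calved_fraction=0.03, male_1to2_fraction=0.03,
            slaughter_out_fraction=0.03, birth_herd_out_fraction=0.70,
            birth_herd_in_fraction=0.0, short_stay_fraction=0.02,
            yearling_fraction=0.60, calf_fraction=0.05, out_rate=0.50, in_rate=0.50,
        ),
        # -- fattening and trading ---------------------------------------------
        spec(
            "F",
            size=(100, 200),
            female_fraction=0.45, dairy_fraction=0.25, cross_fraction=0.30,
            calved_fraction=0.03, male_1to2_fraction=0.55,
            slaughter_out_fraction=0.80, birth_herd_out_fraction=0.0,
            birth_herd_in_fraction=0.0, short_stay_fraction=0.03,
            yearling_fraction=0.50, calf_fraction=0.05, out_rate=1.00, in_rate=0.90,
        ),
        spec(
            "T",
            size=(80, 160),
            female_fraction=0.50, dairy_fraction=0.30, cross_fraction=0.30,
            calved_fraction=0.05, male_1to2_fraction=0.50,
            slaughter_out_fraction=0.05, birth_herd_out_fraction=0.0,
            birth_herd_in_fraction=0.0, short_stay_fraction=0.80,
            yearling_fraction=0.40, calf_fraction=0.05, out_rate=2.00, in_rate=2.00,
        ),
    ]
    return {s.herd_type: s for s in specs}


# -- per-herd generation -------------------------------------------------------


def _date(year: int, rng: np.random.Generator, start: tuple[int, int], end: tuple[int, int]) -> dt.date:
    """Uniform date in [start, end] (month, day tuples) of ``year``."""
    d0 = dt.date(year, *start)
    d1 = dt.date(year, *end)
    return d0 + dt.timedelta(days=int(rng.integers(0, (d1 - d0).days + 1)))


def _parents(kind: str) -> tuple[str, str, str]:
    """(own breed, dam breed, sire breed) for a breed-type kind."""
    if kind == "dairy":
        dam, sire = _DAIRY_PARENTS
        return "Holstein/Friesian", dam, sire
    if kind == "cross":
        dam, sire = _CROSS_PARENTS
        return "Angus X", dam, sire
    dam, sire = _BEEF_PARENTS
    return "Charolais", dam, sire


def generate_herd(
    spec: ArchetypeSpec,
    herd_id: str,
    rng: np.random.Generator,
    study_year: int = 2017,
) -> tuple[list[AnimalRecord], list[MovementRecord]]:
    """Generate one herd's animals and movements for the study year.

    Besides the primary herd's residents and transients, rows for the
    two counterpart herds (``{herd_id}-CP1``: trade/contract partner;
    ``{herd_id}-CP2``: sales destination) are emitted so that both
    birth-herd movement variables are computable.
    """
    spec.validate()
    year = study_year
    may1 = dt.date(year, 5, 1)
    cp1, cp2 = f"{herd_id}-CP1", f"{herd_id}-CP2"
    lo, hi = spec.herd_size_range
    n = int(rng.integers(lo, hi + 1))

    n_out = round(spec.out_rate * n)
    n_in = round(spec.in_rate * n)
    n_sl = round(spec.slaughter_out_fraction * n)
    n_contract = min(round(spec.birth_herd_out_fraction * n_out), n)
    n_return = round(spec.birth_herd_in_fraction * n_in)
    n_short = round(spec.short_stay_fraction * n_out)
    n_generic_out = n_out - n_sl - n_contract - n_return - n_short
    n_generic_in = n_in - n_contract - n_return - n_short
    if n_generic_out < 0 or n_generic_in < 0:
        raise ValueError(f"{spec.herd_type}: movement budget infeasible at n={n}")

    animals: list[AnimalRecord] = []
    movements: list[MovementRecord] = []
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"{herd_id}-A{counter:05d}"

    # ---- May-member composition by deterministic rounding --------------------
    n_yearling = round(spec.yearling_fraction * n)
    n_year_rest = max(0, n_yearling - n_contract)
    n_calf = min(round(spec.calf_fraction * n), n - n_contract - n_year_rest)
    n_adult = n - n_contract - n_year_rest - n_calf

    year_males = min(round(spec.male_1to2_fraction * max(n_yearling, 1)), n_year_rest)
    n_female_target = round(spec.female_fraction * n)
    year_rest_females = n_year_rest - year_males
    rem_females = max(0, n_female_target - n_contract - year_rest_females)
    adult_females = min(n_adult, rem_females)
    calf_females = min(n_calf, rem_females - adult_females)
    n_calved = min(round(spec.calved_fraction * n), adult_females)

    # Breed mix over non-contract members (contract members are dairy).
    m = n - n_contract
    n_dairy_rest = min(m, max(0, round(spec.dairy_fraction * n) - n_contract))
    n_cross_rest = min(m - n_dairy_rest, round(spec.cross_fraction * n))
    breed_kinds = (
        ["dairy"] * n_dairy_rest
        + ["cross"] * n_cross_rest
        + ["beef"] * (m - n_dairy_rest - n_cross_rest)
    )
    rng.shuffle(breed_kinds)

    members: list[dict] = []

    # Contract-rearing members: young dairy females in from their birth
    # herd in February, back to it in November.
    for _ in range(n_contract):
        entry = _date(year, rng, (2, 1), (2, 25))
        exit_ = _date(year, rng, (11, 1), (11, 28))
        age = int(rng.integers(365, 500))
        members.append(
            dict(
                sex=Sex.FEMALE, kind="dairy", age=age, calved=False,
                entry=entry, exit=exit_, contract=True,
            )
        )

    # Remaining members: yearlings, calves born in spring, adults.
    sexes = (
        [Sex.MALE] * year_males + [Sex.FEMALE] * year_rest_females  # yearlings
        + [Sex.FEMALE] * adult_females + [Sex.MALE] * (n_adult - adult_females)  # adults
        + [Sex.FEMALE] * calf_females + [Sex.MALE] * (n_calf - calf_females)  # calves
    )
    ages = (
        [int(rng.integers(365, 730)) for _ in range(n_year_rest)]
        + [int(rng.integers(1100, 2900)) for _ in range(n_adult)]
        + [int(rng.integers(31, 89)) for _ in range(n_calf)]
    )
    calved_flags = (
        [False] * n_year_rest
        + [True] * n_calved + [False] * (n_adult - n_calved)
        + [False] * n_calf
    )
    for sex, age, calved, kind in zip(sexes, ages, calved_flags, breed_kinds):
        members.append(
            dict(sex=sex, kind=kind, age=age, calved=calved, entry=None, exit=None, contract=False)
        )

    # ---- exits of resident members (after the September snapshot) ------------
    non_contract = [mm for mm in members if not mm["contract"]]
    rng.shuffle(non_contract)
    if n_sl + n_generic_out > len(non_contract):
        raise ValueError(f"{spec.herd_type}: more member exits than members at n={n}")
    for mm in non_contract[:n_sl]:
        mm["exit"] = _date(year, rng, (10, 1), (12, 20))
        mm["exit_to"] = ("SLAUGHTER", DestinationKind.SLAUGHTER)
    for mm in non_contract[n_sl : n_sl + n_generic_out]:
        mm["exit"] = _date(year, rng, (10, 1), (12, 20))
        mm["exit_to"] = (cp2, DestinationKind.HERD)

    for mm in members:
        birth = may1 - dt.timedelta(days=mm["age"])
        entry = mm["entry"] if mm["entry"] is not None else birth
        aid = next_id()
        own, dam, sire = _parents(mm["kind"])
        animals.append(
            AnimalRecord(
                animal_id=aid, herd_id=herd_id, sex=mm["sex"], breed=own,
                dam_breed=dam, sire_breed=sire, birth_date=birth,
                has_calved_by_sep1=mm["calved"], herd_entry_date=entry,
                herd_exit_date=mm["exit"],
            )
        )
        if mm["contract"]:
            movements.append(MovementRecord(aid, mm["entry"], cp1, herd_id, DestinationKind.HERD))
            movements.append(MovementRecord(aid, mm["exit"], herd_id, cp1, DestinationKind.HERD))
        elif mm["exit"] is not None:
            dest, kind = mm["exit_to"]
            movements.append(MovementRecord(aid, mm["exit"], herd_id, dest, kind))

    # ---- short-stay (dealer) throughput: in and out within 30 days ------------
    for _ in range(n_short):
        entry = _date(year, rng, (6, 1), (7, 10))
        stay = int(rng.integers(*spec.short_stay_days))
        exit_ = entry + dt.timedelta(days=stay)
        aid = next_id()
        sex = Sex.FEMALE if rng.random() < spec.female_fraction else Sex.MALE
        own, dam, sire = _parents("cross" if rng.random() < 0.5 else "beef")
        birth = entry - dt.timedelta(days=int(rng.integers(200, 900)))
        animals.append(
            AnimalRecord(aid, herd_id, sex, own, dam, sire, birth, False, entry, exit_)
        )
        movements.append(MovementRecord(aid, entry, cp1, herd_id, DestinationKind.HERD))
        movements.append(MovementRecord(aid, exit_, herd_id, "EXPORT", DestinationKind.EXPORT))

    # ---- generic purchases arriving after the September snapshot --------------
    for _ in range(n_generic_in):
        entry = _date(year, rng, (9, 15), (10, 31))
        aid = next_id()
        sex = Sex.FEMALE if rng.random() < spec.female_fraction else Sex.MALE
        own, dam, sire = _parents("beef" if rng.random() < 0.5 else "cross")
        birth = entry - dt.timedelta(days=int(rng.integers(200, 900)))
        animals.append(AnimalRecord(aid, herd_id, sex, own, dam, sire, birth, False, entry, None))
        movements.append(MovementRecord(aid, entry, cp1, herd_id, DestinationKind.HERD))

    # ---- off-site reared heifers returning to this, their birth, herd ---------
    # They reside at the contract partner (CP1) between the two legs.
    for _ in range(n_return):
        out_leg = _date(year, rng, (2, 1), (2, 25))
        in_leg = _date(year, rng, (11, 1), (11, 28))
        aid = next_id()
        own, dam, sire = _parents("dairy")
        birth = out_leg - dt.timedelta(days=int(rng.integers(30, 90)))
        animals.append(
            AnimalRecord(aid, cp1, Sex.FEMALE, own, dam, sire, birth, False, out_leg, in_leg)
        )
        movements.append(MovementRecord(aid, out_leg, herd_id, cp1, DestinationKind.HERD))
        movements.append(MovementRecord(aid, in_leg, cp1, herd_id, DestinationKind.HERD))

    # ---- minimal counterpart residents ----------------------------------------
    for cp in (cp1, cp2):
        for j in range(4):
            aid = f"{cp}-A{j:02d}"
            own, dam, sire = _parents("dairy" if j % 2 == 0 else "beef")
            birth = may1 - dt.timedelta(days=int(rng.integers(1100, 2900)))
            animals.append(
                AnimalRecord(aid, cp, Sex.FEMALE, own, dam, sire, birth, j < 2, birth, None)
            )

    return animals, movements


def generate_registry(config: GeneratorConfig) -> tuple[Registry, dict[str, str]]:
    """Generate a full labelled register.

    Returns the registry and a mapping herd_id -> truth label, where
    primary herds carry their archetype's herd type and counterpart
    herds the label ``counterpart``.
    """
    archetypes = default_archetypes()
    archetypes.update(config.archetype_overrides)
    animals: list[AnimalRecord] = []
    movements: list[MovementRecord] = []
    labels: dict[str, str] = {}

    herd_index = 0
    for herd_type in sorted(archetypes):
        spec = archetypes[herd_type]
        for i in range(config.herds_per_type):
            herd_id = f"{herd_type}-{i:03d}"
            rng = np.random.default_rng([config.seed % (2**31), herd_index])
            a, m = generate_herd(spec, herd_id, rng, config.study_year)
            animals.extend(a)
            movements.extend(m)
            labels[herd_id] = spec.herd_type
            labels[f"{herd_id}-CP1"] = COUNTERPART_LABEL
            labels[f"{herd_id}-CP2"] = COUNTERPART_LABEL
            herd_index += 1

    registry = Registry(animals=animals, movements=movements, study_year=config.study_year)
    return registry, labels
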