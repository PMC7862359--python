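"""Herd-level variables: snapshot membership, the nine quotients, the
initial breeding/dairy/beef/mixed split."""

from __future__ import annotations

import datetime as dt

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from herdtyper.features import (
    HerdFeatures,
    InitialClass,
    compute_all_features,
    compute_features,
    initial_classification,
    snapshot_members,
)
from herdtyper.registry import (
    BreedType,
    DestinationKind,
    Registry,
    Sex,
    classify_breed_type,
    is_member,
)

from .conftest import animal, move

MAY = dt.date(2017, 5, 1)


# -- snapshot membership -------------------------------------------------------


def residency_days_oracle(a, date: dt.date) -> bool:
    """Brute force: enumerate the residency days and test membership."""
    end = a.herd_exit_date or dt.date(2018, 12, 31)
    day = a.herd_entry_date
    days = set()
    while day < end:
        days.add(day)
        day += dt.timedelta(days=1)
    return date in days


@pytest.mark.parametrize(
    "entry, exit, member_on_may1",
    [
        (dt.date(2017, 1, 10), None, True),  # entered before, never left
        (dt.date(2017, 1, 10), dt.date(2017, 4, 30), False),  # exited April 30
        (dt.date(2017, 5, 1), None, True),  # entering on the snapshot day
        (dt.date(2017, 5, 1), dt.date(2017, 5, 1), False),  # same-day in and out
        (dt.date(2017, 5, 2), None, False),  # entered the day after
        (dt.date(2017, 4, 1), dt.date(2017, 5, 2), True),  # exits the day after
    ],
)
def test_snapshot_membership_boundaries(entry, exit, member_on_may1):
    """Half-open residency agrees with day-by-day enumeration."""
    a = animal("A1", birth=dt.date(2016, 1, 1), entry=entry, exit=exit)
    registry = Registry(animals=[a], movements=[])
    members = snapshot_members(registry, "H1", MAY)
    assert (("A1" in members) is member_on_may1)
    assert is_member(a, MAY) == residency_days_oracle(a, MAY) == member_on_may1


def test_unknown_herd_has_no_members():
    registry = Registry(animals=[animal("A1")], movements=[])
    assert snapshot_members(registry, "NOPE", MAY) == set()


# -- the nine quotients on a hand-built herd -----------------------------------


def _fixture_herd() -> Registry:
    """Herd H1: sizes 8 (Jan), 10 (May), 9 (Sep); constructed counts.

    May members: 6 female / 10; 4 slaughter out-moves; 12 out-moves in
    total of which 3 return animals to their birth herd.
    """
    animals = []
    dairy = ("Holstein/Friesian", "Holstein/Friesian")
    beef = ("Charolais", "Limousin")
    # 8 animals present all year (entered before Jan 1).
    for i in range(8):
        animals.append(
            animal(
                f"R{i}",
                sex=Sex.FEMALE if i < 5 else Sex.MALE,
                parents=dairy if i < 4 else beef,
                birth=dt.date(2014, 3, 1),
                calved=i < 3,
            )
        )
    # 2 spring arrivals: present in May; one leaves before September.
    animals.append(
        animal(
            "S0", sex=Sex.FEMALE, parents=dairy,
            birth=dt.date(2016, 2, 1), entry=dt.date(2017, 3, 1),
        )
    )
    animals.append(
        animal(
            "S1", sex=Sex.MALE, parents=beef,
            birth=dt.date(2016, 2, 1), entry=dt.date(2017, 3, 1),
            exit=dt.date(2017, 8, 1),
        )
    )
    movements = []
    # 4 out-moves to slaughter, late in the year.
    for i in range(4):
        movements.append(
            move(f"R{i}", dt.date(2017, 10, 2 + i), "H1", "SLAUGHTER", DestinationKind.SLAUGHTER)
        )
    # 3 out-moves returning animals to their birth herd B1 (two-leg trips
    # within the year: arrived from B1 first).
    for i, aid in enumerate(["X0", "X1", "X2"]):
        animals.append(
            animal(
                aid, herd="H1", sex=Sex.FEMALE, parents=dairy,
                birth=dt.date(2016, 6, 1),
                entry=dt.date(2017, 6, 1), exit=dt.date(2017, 8, 1),
            )
        )
        movements.append(move(aid, dt.date(2017, 6, 1), "B1", "H1"))
        movements.append(move(aid, dt.date(2017, 8, 1), "H1", "B1"))
    # 5 more non-returning out-moves to make 12 out-moves in total.
    movements.append(move("S1", dt.date(2017, 8, 1), "H1", "H9"))
    for i in range(4, 8):
        movements.append(move(f"R{i}", dt.date(2017, 11, 1 + i), "H1", "H9"))
    # B1 and H9 need at least one animal row for a valid register.
    animals.append(animal("B1A", herd="B1", birth=dt.date(2013, 1, 1)))
    animals.append(animal("H9A", herd="H9", birth=dt.date(2013, 1, 1)))
    return Registry(animals=animals, movements=movements)


def test_fixture_quotients_match_hand_counts():
    registry = _fixture_herd()
    f = compute_features(registry, "H1")
    assert (f.herd_size_jan, f.herd_size_may, f.herd_size_sep) == (8, 10, 9)
    assert f.maximum_herd_size == 10
    assert f.pFemaleAnimals == pytest.approx(6 / 10)
    assert f.pOutMovesToSL == pytest.approx(4 / 10)
    assert f.n_out_moves == 12
    assert f.pOutMovesToBirthHerd == pytest.approx(3 / 12)
    assert f.pDairyBreed == pytest.approx(5 / 10)
    assert f.pCalvedAnimals == pytest.approx(3 / 9)


def test_fixture_quotients_match_brute_force_recount():
    """An independent movement-scan recount agrees exactly."""
    registry = _fixture_herd()
    f = compute_features(registry, "H1")

    # Independent recount, straight from the record lists.
    herd = [a for a in registry.animals if a.herd_id == "H1"]
    may = [a for a in herd if a.herd_entry_date <= MAY and (a.herd_exit_date is None or a.herd_exit_date > MAY)]
    outs = [m for m in registry.movements if m.source_herd == "H1"]
    ins = [m for m in registry.movements if m.destination_id == "H1" and m.destination_kind is DestinationKind.HERD]

    first_move: dict[str, object] = {}
    for m in sorted(registry.movements, key=lambda m: m.date):
        first_move.setdefault(m.animal_id, m)
    own_herd = {a.animal_id: a.herd_id for a in registry.animals}

    def birth_herd(aid: str) -> str:
        return first_move[aid].source_herd if aid in first_move else own_herd[aid]

    assert f.pOutMovesToBirthHerd == pytest.approx(
        sum(
            m.destination_kind is DestinationKind.HERD and m.destination_id == birth_herd(m.animal_id)
            for m in outs
        )
        / len(outs)
    )
    assert f.pInMovesToBirthHerd == pytest.approx(
        sum(birth_herd(m.animal_id) == "H1" for m in ins) / len(ins)
    )
    assert f.pFemaleAnimals == pytest.approx(sum(a.sex is Sex.FEMALE for a in may) / len(may))
    assert f.pCrossBreed == pytest.approx(
        sum(classify_breed_type(a.dam_breed, a.sire_breed) is BreedType.CROSS for a in may) / len(may)
    )


def test_short_stay_counts_only_sub30_day_purchases():
    """The three 61-day visitors do not count; a 10-day visitor does."""
    registry = _fixture_herd()
    f = compute_features(registry, "H1")
    assert f.pAnimalsLess30Days == 0.0

    registry.animals.append(
        animal(
            "Q1", herd="H1", sex=Sex.MALE,
            parents=("Charolais", "Limousin"), birth=dt.date(2016, 6, 1),
            entry=dt.date(2017, 6, 10), exit=dt.date(2017, 6, 20),
        )
    )
    registry.movements.append(move("Q1", dt.date(2017, 6, 10), "H9", "H1"))
    registry.movements.append(move("Q1", dt.date(2017, 6, 20), "H1", "H9"))
    f2 = compute_features(registry, "H1")
    assert f2.pAnimalsLess30Days == pytest.approx(1 / 13)


def test_zero_denominators_yield_zero_with_flags():
    registry = Registry(
        animals=[animal("A1", birth=dt.date(2014, 1, 1))], movements=[]
    )
    f = compute_features(registry, "H1")
    assert f.pAnimalsLess30Days == 0.0
    assert f.pMalesBetween1and2Years == 0.0
    assert "pMalesBetween1and2Years" in f.zero_denominator_flags
    assert "n/a" not in f.zero_denominator_flags


def test_features_agree_with_recount_on_generated_registry(small_registry):
    """Spot-check generated herds against per-herd recomputation."""
    registry, labels = small_registry
    all_feats = compute_all_features(registry)
    some = [h for h in sorted(labels) if labels[h] != "counterpart"][::23][:6]
    for h in some:
        assert compute_features(registry, h) == all_feats[h]


# -- initial classification ----------------------------------------------------


def _feat(calved: float, dairy: float) -> HerdFeatures:
    return HerdFeatures(
        herd_id="H", herd_size_jan=1, herd_size_may=1, herd_size_sep=1,
        maximum_herd_size=1, n_out_moves=0, n_in_moves=0,
        pFemaleAnimals=0.5, pDairyBreed=dairy, pCrossBreed=0.0,
        pCalvedAnimals=calved, pMalesBetween1and2Years=0.0,
        pAnimalsLess30Days=0.0, pOutMovesToSL=0.0,
        pOutMovesToBirthHerd=0.0, pInMovesToBirthHerd=0.0,
    )


@pytest.mark.parametrize(
    "calved, dairy, expected",
    [
        (0.24, 0.9, InitialClass.UNKNOWN),
        (0.25, 0.9, InitialClass.DAIRY),  # >= at the breeding boundary
        (0.40, 0.70, InitialClass.DAIRY),  # >= at the dairy boundary
        (0.40, 0.699, InitialClass.MIXED),
        (0.40, 0.50, InitialClass.MIXED),
        (0.40, 0.299, InitialClass.BEEF),
        (0.40, 0.30, InitialClass.MIXED),  # 0.30 is not "< 30%"
    ],
)
def test_initial_classification_boundaries(calved, dairy, expected):
    assert initial_classification(_feat(calved, dairy)) is expected


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    calved=st.floats(0.25, 1.0),
    dairy_low=st.floats(0.0, 1.0),
    bump=st.floats(0.0, 1.0),
)
def test_raising_dairy_share_never_moves_dairy_toward_beef(calved, dairy_low, bump):
    """Monotonicity of the breeding split in the dairy proportion."""
    order = [InitialClass.BEEF, InitialClass.MIXED, InitialClass.DAIRY]
    lo = initial_classification(_feat(calved, dairy_low))
    hi = initial_classification(_feat(calved, min(1.0, dairy_low + bump)))
    assert order.index(hi) >= order.index(lo)
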