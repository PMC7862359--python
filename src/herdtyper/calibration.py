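"""Behavioural recovery of classification thresholds from synthetic herds.

Each recovery builds a one-parameter family of synthetic herds, varying a
single archetype fraction, classifies each herd end-to-end (register ->
features -> tree), and bisects for the point where the assigned class
flips.  The recovered boundary is reported in feature space: the value of
the discriminating variable of the first herd on the passing side.  This
confirms that the printed decision thresholds (25% breeding, 70% dairy,
30% beef, 0.5 direct-to-slaughter, the 30-day dealer window) really are
the operative boundaries of the full pipeline, not just constants in a
table.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Callable

import numpy as np

from .features import HerdFeatures, compute_features
from .registry import Registry
from .synth import default_archetypes, generate_herd
from .tree import MAIN_GROUPS, DecisionTree, build_default_tree, classify_herd

__all__ = [
    "classify_family_herd",
    "recover_feature_threshold",
    "recover_dealer_window",
]

FAMILY_HERD_SIZE = 400


def classify_family_herd(
    base_type: str,
    seed: int,
    tree: DecisionTree | None = None,
    **overrides,
) -> tuple[str, HerdFeatures]:
    """Generate one herd from a modified archetype and classify it."""
    spec = replace(
        default_archetypes()[base_type],
        herd_size_range=(FAMILY_HERD_SIZE, FAMILY_HERD_SIZE),
        **overrides,
    )
    animals, movements = generate_herd(spec, "FAM", np.random.default_rng(seed))
    registry = Registry(animals=animals, movements=movements)
    features = compute_features(registry, "FAM")
    label, _ = classify_herd(tree or build_default_tree(), features)
    return label, features


def recover_feature_threshold(
    base_type: str,
    parameter: str,
    feature_name: str,
    passes: Callable[[str], bool],
    lo: float,
    hi: float,
    seed: int = 0,
    tol: float = 1e-3,
) -> float:
    """Bisect a single-archetype-parameter herd family for the class flip.

    ``passes(label)`` must be False at ``lo`` and True at ``hi`` and
    monotone in between.  Returns the discriminating feature's value for
    the first herd on the passing side — the operative boundary.
    """
    tree = build_default_tree()

    def ok(x: float) -> bool:
        label, _ = classify_family_herd(base_type, seed, tree, **{parameter: x})
        return passes(label)

    if ok(lo) or not ok(hi):
        raise ValueError(f"family [{lo}, {hi}] does not bracket a class flip")
    while hi - lo > tol:
        mid = (lo + hi) / 2
        if ok(mid):
            hi = mid
        else:
            lo = mid
    _, features = classify_family_herd(base_type, seed, tree, **{parameter: hi})
    return float(getattr(features, feature_name))


def recover_dealer_window(seed: int = 0, lo: int = 5, hi: int = 60) -> int:
    """Smallest dealer stay length (days) at which a trader herd stops
    classifying as trading: residencies of this length no longer count
    as short stays."""
    tree = build_default_tree()

    def trader(s: int) -> bool:
        label, _ = classify_family_herd("T", seed, tree, short_stay_days=(s, s + 1))
        return label == "T"

    if not trader(lo) or trader(hi):
        raise ValueError("stay-length family does not bracket the flip")
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if trader(mid):
            lo = mid
        else:
            hi = mid
    return hi


def recover_printed_thresholds(seed: int = 0) -> dict[str, float]:
    """All five behaviourally recovered boundaries in one sweep."""
    breeding = recover_feature_threshold(
        "D", "calved_fraction", "pCalvedAnimals",
        lambda label: MAIN_GROUPS[label] in {"dairy", "beef", "mixed"},
        lo=0.05, hi=0.60, seed=seed,
    )
    dairy = recover_feature_threshold(
        "D", "dairy_fraction", "pDairyBreed",
        lambda label: MAIN_GROUPS[label] == "dairy",
        lo=0.40, hi=0.95, seed=seed,
    )
    beef = recover_feature_threshold(
        "D", "dairy_fraction", "pDairyBreed",
        lambda label: MAIN_GROUPS[label] != "beef",
        lo=0.05, hi=0.60, seed=seed,
    )
    slaughter = recover_feature_threshold(
        "F", "slaughter_out_fraction", "pOutMovesToSL",
        lambda label: label == "F",
        lo=0.10, hi=0.90, seed=seed,
    )
    return {
        "breeding": breeding,
        "dairy": dairy,
        "beef": beef,
        "slaughter": slaughter,
        "dealer_window_days": recover_dealer_window(seed=seed),
    }
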