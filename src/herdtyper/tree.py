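"""The 17-type herd classification tree and its threshold sensitivity.

The classifier is a fixed decision tree over the nine herd variables:
13 decisions (10 binary, 3 ternary) ending in 17 leaf herd types across
six main groups (dairy, beef, mixed, store/rearing, fattening, trading).
Five thresholds are fixed by the underlying classification conventions
(25% breeding, 70%/30% dairy/beef, 50% direct-to-slaughter, the 30-day
dealer window inside pAnimalsLess30Days); the remaining thresholds are
configuration constants chosen midway between the management signatures
the tree separates, and can be edited via the YAML serialization.

All comparisons use >= at the stated boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import yaml

from .features import FEATURE_NAMES, HerdFeatures

__all__ = [
    "HERD_TYPES",
    "MAIN_GROUPS",
    "DEFAULT_THRESHOLDS",
    "DecisionNode",
    "Leaf",
    "DecisionTree",
    "SensitivityBand",
    "build_default_tree",
    "classify_herd",
    "tree_stats",
    "threshold_sensitivity",
    "save_tree",
    "load_tree",
]

#: The 17 herd types and their main group.
MAIN_GROUPS: dict[str, str] = {
    "D": "dairy",
    "DnR-C": "dairy",
    "DnR-nC": "dairy",
    "DRm": "dairy",
    "BP": "beef",
    "BSW": "beef",
    "BSY": "beef",
    "BSY-nR": "beef",
    "BSB": "beef",
    "M": "mixed",
    "Sdm": "store/rearing",
    "Sbm": "store/rearing",
    "Sbf": "store/rearing",
    "Sbmx": "store/rearing",
    "Rdf": "store/rearing",
    "F": "fattening",
    "T": "trading",
}
HERD_TYPES = list(MAIN_GROUPS)

#: Default decision thresholds.  The first five are fixed conventions;
#: the rest are configurable calibration constants (see module docstring).
DEFAULT_THRESHOLDS: dict[str, float | tuple[float, float]] = {
    "D1_breeding": 0.25,
    "D2_dairy_beef": (0.30, 0.70),
    "D3_dairy_males": 0.30,
    "D4_calved_high": 0.60,
    "D5_contract_in": 0.30,
    "D6_cross": 0.15,
    "D7_beef_slaughter": 0.35,
    "D8_beef_males": (0.20, 0.65),
    "D9_short_stay": 0.50,
    "D10_slaughter": 0.50,
    "D11_birth_out": 0.30,
    "D12_store_dairy": 0.60,
    "D13_store_sex": (0.35, 0.65),
}


@dataclass(frozen=True)
class Leaf:
    herd_type: str

    @property
    def main_group(self) -> str:
        return MAIN_GROUPS[self.herd_type]


@dataclass
class DecisionNode:
    """One split on one variable.

    Binary nodes hold one threshold and two children ``(below, at_or_above)``;
    ternary nodes hold two ordered thresholds and three children
    ``(below_low, middle, at_or_above_high)``.
    """

    node_id: str
    variable: str
    thresholds: tuple[float, ...]
    children: tuple["DecisionNode | Leaf", ...]

    def __post_init__(self) -> None:
        if self.variable not in FEATURE_NAMES:
            raise ValueError(f"{self.node_id}: unknown variable {self.variable}")
        if len(self.thresholds) not in (1, 2):
            raise ValueError(f"{self.node_id}: need 1 or 2 thresholds")
        if len(self.children) != len(self.thresholds) + 1:
            raise ValueError(f"{self.node_id}: children/threshold mismatch")
        if len(self.thresholds) == 2 and not self.thresholds[0] < self.thresholds[1]:
            raise ValueError(f"{self.node_id}: ternary thresholds must increase")

    @property
    def is_ternary(self) -> bool:
        return len(self.thresholds) == 2

    def branch(self, value: float) -> int:
        """Index of the child the value falls into (>= at boundaries)."""
        if len(self.thresholds) == 1:
            return 1 if value >= self.thresholds[0] else 0
        low, high = self.thresholds
        if value >= high:
            return 2
        if value >= low:
            return 1
        return 0


@dataclass
class DecisionTree:
    root: DecisionNode

    def nodes(self) -> list[DecisionNode]:
        out: list[DecisionNode] = []

        def walk(n) -> None:
            if isinstance(n, DecisionNode):
                out.append(n)
                for c in n.children:
                    walk(c)

        walk(self.root)
        return out

    def leaves(self) -> list[Leaf]:
        out: list[Leaf] = []

        def walk(n) -> None:
            if isinstance(n, Leaf):
                out.append(n)
            else:
                for c in n.children:
                    walk(c)

        walk(self.root)
        return out

    def node(self, node_id: str) -> DecisionNode:
        for n in self.nodes():
            if n.node_id == node_id:
                return n
        raise KeyError(node_id)


@dataclass
class SensitivityBand:
    """How far a threshold can move before 10% of herds change class."""

    node_id: str
    threshold: float
    low: float | None
    high: float | None
    fraction: float
    n_herds: int
    n_reassigned: int
    open_low: bool = False
    open_high: bool = False


def build_default_tree(thresholds: dict | None = None) -> DecisionTree:
    """The canonical 13-decision, 17-leaf classification tree.

    ``thresholds`` overrides entries of :data:`DEFAULT_THRESHOLDS`.
    """
    t = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        t.update(thresholds)

    def b(key: str) -> tuple[float]:
        return (float(t[key]),)

    def tern(key: str) -> tuple[float, float]:
        lo, hi = t[key]
        return (float(lo), float(hi))

    # Dairy subtree: male rearing first, then calved share, then the
    # contract-rearing return signal.
    d5 = DecisionNode(
        "D5", "pInMovesToBirthHerd", b("D5_contract_in"), (Leaf("DnR-nC"), Leaf("DnR-C"))
    )
    d4 = DecisionNode("D4", "pCalvedAnimals", b("D4_calved_high"), (Leaf("D"), d5))
    d3 = DecisionNode("D3", "pMalesBetween1and2Years", b("D3_dairy_males"), (d4, Leaf("DRm")))

    # Beef subtree: pedigree herds split off on cross-breds, finishers on
    # slaughter share, the suckler systems on male youngstock share.
    d8 = DecisionNode(
        "D8",
        "pMalesBetween1and2Years",
        tern("D8_beef_males"),
        (Leaf("BSW"), Leaf("BSY"), Leaf("BSY-nR")),
    )
    d7 = DecisionNode("D7", "pOutMovesToSL", b("D7_beef_slaughter"), (d8, Leaf("BSB")))
    d6 = DecisionNode("D6", "pCrossBreed", b("D6_cross"), (Leaf("BP"), d7))

    # Breeding herds: dairy / mixed / beef on the dairy-bred share.
    d2 = DecisionNode("D2", "pDairyBreed", tern("D2_dairy_beef"), (d6, Leaf("M"), d3))

    # Non-breeding herds: traders, fatteners, contract rearers, stores.
    d13 = DecisionNode(
        "D13", "pFemaleAnimals", tern("D13_store_sex"), (Leaf("Sbm"), Leaf("Sbmx"), Leaf("Sbf"))
    )
    d12 = DecisionNode("D12", "pDairyBreed", b("D12_store_dairy"), (d13, Leaf("Sdm")))
    d11 = DecisionNode("D11", "pOutMovesToBirthHerd", b("D11_birth_out"), (d12, Leaf("Rdf")))
    d10 = DecisionNode("D10", "pOutMovesToSL", b("D10_slaughter"), (d11, Leaf("F")))
    d9 = DecisionNode("D9", "pAnimalsLess30Days", b("D9_short_stay"), (d10, Leaf("T")))

    d1 = DecisionNode("D1", "pCalvedAnimals", b("D1_breeding"), (d9, d2))
    return DecisionTree(root=d1)


def classify_herd(
    tree: DecisionTree, features: HerdFeatures
) -> tuple[str, list[tuple[str, str, float, int]]]:
    """Walk the tree for one herd.

    Returns the leaf herd type and the decision path as a list of
    ``(node_id, variable, value, branch_index)`` tuples.
    """
    path: list[tuple[str, str, float, int]] = []
    node: DecisionNode | Leaf = tree.root
    while isinstance(node, DecisionNode):
        value = float(getattr(features, node.variable))
        branch = node.branch(value)
        path.append((node.node_id, node.variable, value, branch))
        node = node.children[branch]
    return node.herd_type, path


def tree_stats(tree: DecisionTree) -> dict[str, int]:
    nodes = tree.nodes()
    leaves = tree.leaves()

    def depth(n) -> int:
        if isinstance(n, Leaf):
            return 0
        return 1 + max(depth(c) for c in n.children)

    return {
        "n_leaves": len(leaves),
        "n_decisions": len(nodes),
        "n_binary": sum(1 for n in nodes if not n.is_ternary),
        "n_ternary": sum(1 for n in nodes if n.is_ternary),
        "n_variables": len({n.variable for n in nodes}),
        "max_depth": depth(tree.root),
    }


def herds_at_node(
    tree: DecisionTree, node_id: str, features: list[HerdFeatures]
) -> list[HerdFeatures]:
    """Herds whose decision path passes through ``node_id``."""
    out = []
    for f in features:
        _, path = classify_herd(tree, f)
        if any(step[0] == node_id for step in path):
            out.append(f)
    return out


def threshold_sensitivity(
    tree: DecisionTree,
    node_id: str,
    features: list[HerdFeatures],
    fraction: float = 0.10,
    threshold_index: int = 0,
) -> SensitivityBand:
    """Band within which a node threshold reassigns at most ``fraction``.

    Among herds reaching the node, each band endpoint is the variable
    value of the (⌈fraction·n⌉+1)-th herd counted outward from the
    threshold on that side: moving the threshold strictly inside the
    band reassigns at most ⌈fraction·n⌉ herds across the boundary.  A
    side with too few herds yields an open-ended bound, flagged.
    """
    node = tree.node(node_id)
    threshold = node.thresholds[threshold_index]
    at_node = herds_at_node(tree, node_id, features)
    if not at_node:
        raise ValueError(f"no herds reach node {node_id}")
    values = sorted(float(getattr(f, node.variable)) for f in at_node)
    n = len(values)

    if fraction == 0:
        return SensitivityBand(node_id, threshold, threshold, threshold, 0.0, n, 0)

    k = math.ceil(fraction * n)
    below = sorted((v for v in values if v < threshold), reverse=True)
    above = sorted(v for v in values if v >= threshold)

    # Ties at equal values are included together: the endpoint sits at the
    # first value whose crossing would exceed k reassignments.
    low, open_low = (below[k], False) if len(below) > k else (None, True)
    high, open_high = (above[k], False) if len(above) > k else (None, True)
    return SensitivityBand(
        node_id=node_id,
        threshold=threshold,
        low=low,
        high=high,
        fraction=fraction,
        n_herds=n,
        n_reassigned=k,
        open_low=open_low,
        open_high=open_high,
    )


# -- plain-text serialization so experts can edit thresholds -------------------


def _node_to_dict(n: DecisionNode | Leaf):
    if isinstance(n, Leaf):
        return {"leaf": n.herd_type}
    return {
        "node_id": n.node_id,
        "variable": n.variable,
        "thresholds": list(n.thresholds),
        "children": [_node_to_dict(c) for c in n.children],
    }


def _node_from_dict(d) -> DecisionNode | Leaf:
    if "leaf" in d:
        return Leaf(d["leaf"])
    return DecisionNode(
        node_id=d["node_id"],
        variable=d["variable"],
        thresholds=tuple(float(x) for x in d["thresholds"]),
        children=tuple(_node_from_dict(c) for c in d["children"]),
    )


def save_tree(tree: DecisionTree, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_node_to_dict(tree.root), sort_keys=False))


def load_tree(path: str | Path) -> DecisionTree:
    return DecisionTree(root=_node_from_dict(yaml.safe_load(Path(path).read_text())))
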