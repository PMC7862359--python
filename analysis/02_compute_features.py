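"""Aggregate the register to herd level.

Computes the nine herd variables (sex, breed and calving composition at
the snapshots; youngstock, dealer-throughput and transport shares) for
every herd in results/register/, applies the initial breeding-based
dairy/beef/mixed/unknown split, and writes results/features.csv.
"""

from __future__ import annotations

from pathlib import Path

from herdtyper.features import compute_all_features, features_frame, initial_classification
from herdtyper.registry import read_registry

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    register = RESULTS / "register"
    registry = read_registry(register / "animals.csv", register / "movements.csv")
    feats = compute_all_features(registry)
    df = features_frame(feats).sort_values("herd_id").reset_index(drop=True)
    df["initial_class"] = [initial_classification(feats[h]).value for h in df.herd_id]
    df.to_csv(RESULTS / "features.csv", index=False, float_format="%.6f")

    print(f"featurized {len(df)} herds -> {RESULTS / 'features.csv'}")
    print("initial classification (breeding >= 25% calved; dairy >= 70%, beef < 30% dairy-bred):")
    print(df.initial_class.value_counts().to_string())
    flagged = sum(bool(f.zero_denominator_flags) for f in feats.values())
    print(f"{flagged} herds had at least one zero-denominator variable (flagged, set to 0)")


if __name__ == "__main__":
    main()
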