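"""Staged rule extraction with supervised self-organising maps.

Replays the visual rule-extraction procedure on the synthetic register:
a supervised map trained on (pDairyBreed, pCalvedAnimals) isolates the
unclassified non-breeding herds in the low-calved region; adding
pOutMovesToSL splits that region bimodally, and the antimode of the
slaughter-share histogram suggests the 0.5 fattener/store boundary.
Artifacts go to results/walkthrough/.
"""

from __future__ import annotations

import argparse
from pathlib import Path

from herdtyper.pipeline import PipelineConfig, run_walkthrough

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    result = run_walkthrough(
        PipelineConfig(
            herds_per_type=10,
            seed=args.seed,
            epochs=20,
            grid_shape=(10, 10),
            out_dir=str(RESULTS / "walkthrough"),
        )
    )
    centers = (result.histogram_edges[:-1] + result.histogram_edges[1:]) / 2
    low = int(result.histogram_counts[centers < 0.5].sum())
    high = int(result.histogram_counts[centers >= 0.5].sum())
    print("stage 1 (2 variables): mean calved share")
    print(f"  non-breeding map region : {result.unknown_region_mean_calved:.3f}")
    print(f"  rest of the map         : {result.other_region_mean_calved:.3f}")
    print("stage 2 (+ pOutMovesToSL): slaughter-share histogram over the grey region")
    print(f"  mass below 0.5 = {low} herds (stores/rearers/traders), above = {high} (fatteners)")
    print(f"  antimode-suggested threshold = {result.suggested_threshold:.3f}")
    print(f"stage 3 retrained with classes {sorted(result.stage3_model.classes)}")


if __name__ == "__main__":
    main()
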