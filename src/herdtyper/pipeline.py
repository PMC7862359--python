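"""End-to-end orchestration: generate/ingest, featurize, train, classify.

``run_pipeline`` freezes the full analysis into one reproducible run:
synthetic register (or CSV ingest) -> nine herd variables -> initial
breeding/dairy/beef/mixed split -> supervised map -> component planes ->
decision-tree classification -> report.  ``run_walkthrough`` replays the
staged rule-extraction exercise on two, then three variables, in which
the slaughter-share histogram over the non-breeding map region exposes
the fattener/store split at 0.5.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .features import (
    FEATURE_NAMES,
    compute_all_features,
    features_frame,
    initial_classification,
)
from .registry import Registry, read_registry, write_registry
from .som import (
    BDKModel,
    InputSet,
    TrainingSchedule,
    component_plane,
    fit_normalizer,
    map_records,
    region_histogram,
    train_bdk,
)
from .synth import COUNTERPART_LABEL, GeneratorConfig, generate_registry
from .tree import (
    SensitivityBand,
    build_default_tree,
    classify_herd,
    load_tree,
    save_tree,
    threshold_sensitivity,
    tree_stats,
)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "run_walkthrough"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    input_mode: str = "synthetic"  # "synthetic" | "files"
    herds_per_type: int = 20
    seed: int = 0
    study_year: int = 2017
    animals_csv: str | None = None
    movements_csv: str | None = None
    truth_labels_csv: str | None = None
    tree_file: str | None = None
    grid_shape: tuple[int, int] = (12, 12)
    epochs: int = 30
    out_dir: str = "run"
    render_planes: bool = False

    def as_dict(self) -> dict:
        return {
            "input_mode": self.input_mode,
            "herds_per_type": self.herds_per_type,
            "seed": self.seed,
            "study_year": self.study_year,
            "animals_csv": self.animals_csv,
            "movements_csv": self.movements_csv,
            "truth_labels_csv": self.truth_labels_csv,
            "tree_file": self.tree_file,
            "grid_shape": list(self.grid_shape),
            "epochs": self.epochs,
            "render_planes": self.render_planes,
        }


@dataclass
class RunReport:
    counts_per_type: dict[str, int]
    counts_per_group: dict[str, int]
    n_classified: int
    tree_stats: dict[str, int]
    bdk_resubstitution_accuracy: float
    label_recovery: float | None
    sensitivity_bands: dict[str, dict]
    provenance: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "counts_per_type": self.counts_per_type,
            "counts_per_group": self.counts_per_group,
            "n_classified": self.n_classified,
            "tree_stats": self.tree_stats,
            "bdk_resubstitution_accuracy": self.bdk_resubstitution_accuracy,
            "label_recovery": self.label_recovery,
            "sensitivity_bands": self.sensitivity_bands,
            "provenance": self.provenance,
        }


def _band_dict(band: SensitivityBand) -> dict:
    return {
        "threshold": band.threshold,
        "low": band.low,
        "high": band.high,
        "open_low": band.open_low,
        "open_high": band.open_high,
        "n_herds": band.n_herds,
        "n_reassigned": band.n_reassigned,
    }


def _load_inputs(config: PipelineConfig) -> tuple[Registry, dict[str, str] | None]:
    if config.input_mode == "synthetic":
        gen = GeneratorConfig(
            herds_per_type=config.herds_per_type,
            seed=config.seed,
            study_year=config.study_year,
        )
        return generate_registry(gen)
    if config.input_mode != "files":
        raise ValueError(f"unknown input mode {config.input_mode!r}")
    if not (config.animals_csv and config.movements_csv):
        raise ValueError("files mode requires animals_csv and movements_csv")
    registry = read_registry(config.animals_csv, config.movements_csv, config.study_year)
    labels = None
    if config.truth_labels_csv:
        df = pd.read_csv(config.truth_labels_csv, dtype=str)
        labels = dict(zip(df.herd_id, df.herd_type))
    return registry, labels


def _stage(name: str, t0: float) -> float:
    t1 = time.perf_counter()
    logger.info("stage %-14s %6.2fs", name, t1 - t0)
    return t1


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run the full analysis; write artifacts under ``config.out_dir``.

    Outputs: animals/movements/truth_labels (synthetic mode),
    features.csv, classified.csv, the tree YAML, component-plane
    matrices, report.json and a manifest.  Identical config and seed
    give identical outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()

    registry, truth = _load_inputs(config)
    if config.input_mode == "synthetic":
        write_registry(registry, out / "animals.csv", out / "movements.csv")
        pd.DataFrame(
            sorted(truth.items()), columns=["herd_id", "herd_type"]
        ).to_csv(out / "truth_labels.csv", index=False)
    t0 = _stage("inputs", t0)

    feats = compute_all_features(registry)
    fdf = features_frame(feats).sort_values("herd_id").reset_index(drop=True)
    fdf["initial_class"] = [
        initial_classification(feats[h]).value for h in fdf.herd_id
    ]
    fdf.to_csv(out / "features.csv", index=False, float_format="%.6f")
    t0 = _stage("featurize", t0)

    tree = load_tree(config.tree_file) if config.tree_file else build_default_tree()
    save_tree(tree, out / "tree.yaml")
    rows = []
    for h in fdf.herd_id:
        herd_type, path = classify_herd(tree, feats[h])
        rows.append(
            {
                "herd_id": h,
                "herd_type": herd_type,
                "path": ">".join(step[0] for step in path),
            }
        )
    cdf = pd.DataFrame(rows)
    if truth is not None:
        cdf["truth"] = [truth.get(h, "") for h in cdf.herd_id]
    cdf.to_csv(out / "classified.csv", index=False)
    t0 = _stage("classify", t0)

    # Supervised map on the nine variables, labelled by the tree classes.
    X = fdf[FEATURE_NAMES].to_numpy(float)
    norm = fit_normalizer(X, tuple(FEATURE_NAMES))
    input_set = InputSet(
        records=norm.apply(X), ids=list(fdf.herd_id), labels=list(cdf.herd_type)
    )
    schedule = TrainingSchedule(epochs=config.epochs, seed=config.seed)
    model = train_bdk(input_set, schedule, config.grid_shape, normalizer=norm)
    predicted = model.predict(input_set.records)
    resub = float(np.mean([p == t for p, t in zip(predicted, cdf.herd_type)]))
    model_dir = out / "model"
    model_dir.mkdir(exist_ok=True)
    for i, name in enumerate(FEATURE_NAMES):
        np.savetxt(model_dir / f"plane_{name}.csv", component_plane(model.grid, i), delimiter=",")
    if config.render_planes:
        _render_planes(model, model_dir)
    t0 = _stage("train-bdk", t0)

    feat_list = list(feats.values())
    bands: dict[str, dict] = {}
    for node in tree.nodes():
        for ti in range(len(node.thresholds)):
            key = node.node_id if len(node.thresholds) == 1 else f"{node.node_id}[{ti}]"
            try:
                band = threshold_sensitivity(tree, node.node_id, feat_list, 0.10, ti)
            except ValueError:
                continue
            bands[key] = _band_dict(band)
    t0 = _stage("sensitivity", t0)

    counts = cdf.herd_type.value_counts().to_dict()
    from .tree import MAIN_GROUPS

    group_counts: dict[str, int] = {}
    for herd_type, c in counts.items():
        group_counts[MAIN_GROUPS[herd_type]] = group_counts.get(MAIN_GROUPS[herd_type], 0) + c

    recovery = None
    if truth is not None:
        primary = cdf[cdf.get("truth", "").ne("") & (cdf.truth != COUNTERPART_LABEL)]
        if len(primary):
            recovery = float((primary.herd_type == primary.truth).mean())

    config_hash = hashlib.sha256(
        json.dumps(config.as_dict(), sort_keys=True).encode()
    ).hexdigest()[:16]
    report = RunReport(
        counts_per_type=counts,
        counts_per_group=group_counts,
        n_classified=len(cdf),
        tree_stats=tree_stats(tree),
        bdk_resubstitution_accuracy=resub,
        label_recovery=recovery,
        sensitivity_bands=bands,
        provenance={
            "config": config.as_dict(),
            "config_hash": config_hash,
            "seed": config.seed,
            "version": __version__,
        },
    )
    (out / "report.json").write_text(json.dumps(report.as_dict(), indent=2, sort_keys=True))
    (out / "manifest.json").write_text(
        json.dumps(
            {
                "artifacts": sorted(p.name for p in out.iterdir() if p.is_file()),
                "config_hash": config_hash,
            },
            indent=2,
        )
    )
    return report


def _render_planes(model: BDKModel, out_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for i, name in enumerate(FEATURE_NAMES):
        fig, ax = plt.subplots(figsize=(4, 4))
        # Red-high / blue-low colour convention for component planes.
        im = ax.imshow(component_plane(model.grid, i), cmap="RdYlBu_r")
        ax.set_title(name)
        fig.colorbar(im, ax=ax)
        fig.savefig(out_dir / f"plane_{name}.png", dpi=100, bbox_inches="tight")
        plt.close(fig)


def _antimode(counts: np.ndarray, centers: np.ndarray) -> float:
    """Centre of the sparsest stretch between the two histogram modes.

    Finds the dominant mode, the largest mode on the other side of the
    histogram, and returns the middle of the minimal-count run strictly
    between them.
    """
    m1 = int(np.argmax(counts))
    rest = np.array(
        [c if abs(i - m1) > 2 else -1 for i, c in enumerate(counts)]
    )
    m2 = int(np.argmax(rest))
    lo, hi = sorted((m1, m2))
    if hi - lo < 2:
        return float(centers[(lo + hi) // 2])
    between = counts[lo + 1 : hi]
    minimal = np.flatnonzero(between == between.min()) + lo + 1
    return float(centers[minimal[len(minimal) // 2]])


# -- staged rule-extraction walkthrough ---------------------------------------


@dataclass
class WalkthroughResult:
    unknown_region_mean_calved: float
    other_region_mean_calved: float
    histogram_counts: np.ndarray
    histogram_edges: np.ndarray
    suggested_threshold: float
    stage3_model: BDKModel


def run_walkthrough(
    config: PipelineConfig,
) -> WalkthroughResult:
    """Replay the staged rule-extraction exercise.

    Stage 1 trains a supervised map on (pDairyBreed, pCalvedAnimals)
    with the initial breeding-based labels: the unclassified herds
    gather in the low-calved region.  Stage 2 adds pOutMovesToSL; the
    histogram of that raw variable over the unclassified region is
    bimodal, and its antimode suggests the 0.5 fattener/store boundary.
    Stage 3 retrains with fatteners and stores split out.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    registry, _ = _load_inputs(config)
    feats = compute_all_features(registry)
    herd_ids = sorted(feats)
    initial = {h: initial_classification(feats[h]).value for h in herd_ids}

    def bdk_for(variables: list[str], labels: dict[str, str], seed_offset: int) -> tuple[BDKModel, InputSet]:
        X = np.array([[getattr(feats[h], v) for v in variables] for h in herd_ids])
        norm = fit_normalizer(X, tuple(variables))
        iset = InputSet(norm.apply(X), ids=herd_ids, labels=[labels[h] for h in herd_ids])
        schedule = TrainingSchedule(epochs=config.epochs, seed=config.seed + seed_offset)
        return train_bdk(iset, schedule, config.grid_shape, normalizer=norm), iset

    # Stage 1: two variables, initial labels.  The "grey region" of the
    # map is the set of pixels on which the unclassified (non-breeding)
    # herds are represented.
    model1, iset1 = bdk_for(["pDairyBreed", "pCalvedAnimals"], initial, 1)
    assign1 = map_records(model1.grid, iset1)
    grey1 = {assign1[h] for h in herd_ids if initial[h] == "unknown"}
    calved = {h: feats[h].pCalvedAnimals for h in herd_ids}
    in_unknown = [h for h, node in assign1.items() if node in grey1]
    in_other = [h for h in herd_ids if h not in set(in_unknown)]
    mean_unknown = float(np.mean([calved[h] for h in in_unknown])) if in_unknown else float("nan")
    mean_other = float(np.mean([calved[h] for h in in_other])) if in_other else float("nan")

    # Stage 2: add the slaughter share; histogram over the grey region.
    model2, iset2 = bdk_for(["pDairyBreed", "pCalvedAnimals", "pOutMovesToSL"], initial, 2)
    assign2 = map_records(model2.grid, iset2)
    unknown_nodes = {assign2[h] for h in herd_ids if initial[h] == "unknown"}
    sl_raw = {h: feats[h].pOutMovesToSL for h in herd_ids}
    counts, edges = region_histogram(
        assign2, unknown_nodes, sl_raw, bins=20, value_range=(0.0, 1.0)
    )
    centers = (edges[:-1] + edges[1:]) / 2
    suggested = _antimode(counts, centers)

    # Stage 3: split the unclassified herds on the suggested boundary.
    relabelled = {
        h: (
            ("F" if sl_raw[h] >= suggested else "S/R")
            if initial[h] == "unknown"
            else initial[h]
        )
        for h in herd_ids
    }
    model3, _ = bdk_for(["pDairyBreed", "pCalvedAnimals", "pOutMovesToSL"], relabelled, 3)

    np.savetxt(out / "walkthrough_histogram.csv", np.column_stack([centers, counts]), delimiter=",")
    summary = {
        "unknown_region_mean_calved": mean_unknown,
        "other_region_mean_calved": mean_other,
        "suggested_threshold": suggested,
        "stage3_classes": model3.classes,
    }
    (out / "walkthrough.json").write_text(json.dumps(summary, indent=2))
    return WalkthroughResult(
        unknown_region_mean_calved=mean_unknown,
        other_region_mean_calved=mean_other,
        histogram_counts=counts,
        histogram_edges=edges,
        suggested_threshold=suggested,
        stage3_model=model3,
    )
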