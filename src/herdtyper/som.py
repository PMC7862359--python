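"""Self-organising maps and supervised bi-directional Kohonen training.

A SOM projects K normalised records of N variables onto an X-by-Y grid
of weight vectors.  Training repeatedly presents each record in random
order: the node whose weight vector is nearest in Euclidean distance
(the best matching unit, BMU) and its grid neighbourhood are pulled
toward the record,

    w_xy  <-  w_xy + alpha * beta_xy * (z - w_xy),

with a Gaussian neighbourhood beta_xy = exp(-d^2 / (2 sigma^2)) over
grid-coordinate distance d to the BMU.  The learning rate alpha and the
spread sigma shrink geometrically after every epoch.

The supervised variant trains a second, class-weight grid alongside the
feature grid.  Early in training the BMU search is driven by the class
part, late in training by the feature part (the mixing weight moves
linearly from class to feature across epochs), so class structure
organises the map before features refine it.  Per-node class vectors
stay on the probability simplex; their argmax labels the map's class
regions.

Component planes (the grid coloured by one de-normalised variable) and
region histograms (the raw distribution of one variable over records
mapping into a node subset) are the instruments used to read
classification rules off a trained map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "NormalizationParams",
    "TrainingSchedule",
    "SOMGrid",
    "BDKModel",
    "InputSet",
    "fit_normalizer",
    "find_bmu",
    "update_weights",
    "train_som",
    "train_bdk",
    "component_plane",
    "map_records",
    "region_histogram",
    "quantization_error",
]


@dataclass(frozen=True)
class NormalizationParams:
    """Per-variable mean and standard deviation (population convention)."""

    mean: np.ndarray
    std: np.ndarray
    names: tuple[str, ...] | None = None

    def apply(self, records: np.ndarray) -> np.ndarray:
        return (np.asarray(records, dtype=float) - self.mean) / self.std

    def invert(self, records: np.ndarray) -> np.ndarray:
        return np.asarray(records, dtype=float) * self.std + self.mean


def fit_normalizer(records: np.ndarray, names: tuple[str, ...] | None = None) -> NormalizationParams:
    """Fit a z-score transform so each variable has mean 0, variance 1.

    Uses the population (1/K) variance.  A constant variable cannot be
    scaled and is rejected by name.
    """
    X = np.asarray(records, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 records to fit a normalizer")
    mean = X.mean(axis=0)
    std = X.std(axis=0)  # population convention
    constant = np.flatnonzero(std == 0)
    if constant.size:
        labels = [names[i] if names else f"var{i}" for i in constant]
        raise ValueError(f"constant variables cannot be normalised: {labels}")
    return NormalizationParams(mean=mean, std=std, names=names)


@dataclass(frozen=True)
class TrainingSchedule:
    epochs: int = 50
    alpha0: float = 0.5
    alpha_decay: float = 0.95
    sigma0: float | None = None  # default: half the larger grid dimension
    sigma_decay: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha0 <= 1:
            raise ValueError("alpha0 must be in (0, 1]")
        if not (0 < self.alpha_decay <= 1 and 0 < self.sigma_decay <= 1):
            raise ValueError("decay factors must be in (0, 1]")
        if self.sigma0 is not None and self.sigma0 <= 0:
            raise ValueError("sigma0 must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be positive")


@dataclass
class SOMGrid:
    """Trained map: weights of shape (X, Y, N) plus training metadata."""

    weights: np.ndarray
    normalizer: NormalizationParams | None = None
    epochs_run: int = 0
    final_alpha: float = 0.0
    final_sigma: float = 0.0

    @property
    def shape(self) -> tuple[int, int]:
        return self.weights.shape[0], self.weights.shape[1]

    @property
    def n_variables(self) -> int:
        return self.weights.shape[2]


@dataclass
class InputSet:
    """K normalised records with identifiers and optional class labels."""

    records: np.ndarray
    ids: list[str]
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.records = np.asarray(self.records, dtype=float)
        if self.records.ndim != 2:
            raise ValueError("records must be a K x N matrix")
        if len(self.ids) != self.records.shape[0]:
            raise ValueError("ids length mismatch")
        if self.labels is not None and len(self.labels) != self.records.shape[0]:
            raise ValueError("labels length mismatch")


@dataclass
class BDKModel:
    """Supervised map: feature grid plus per-node class-weight vectors."""

    grid: SOMGrid
    class_weights: np.ndarray  # (X, Y, C), rows on the simplex
    classes: list[str]

    def node_labels(self) -> np.ndarray:
        """Majority (argmax class-weight) label index per node."""
        return self.class_weights.argmax(axis=2)

    def predict(self, records: np.ndarray) -> list[str]:
        """Label of the feature-BMU's class region, per record."""
        labels = self.node_labels()
        out = []
        for z in np.asarray(records, dtype=float):
            x, y = find_bmu(self.grid, z)
            out.append(self.classes[labels[x, y]])
        return out


def find_bmu(grid: SOMGrid, z: np.ndarray) -> tuple[int, int]:
    """Best matching unit: node with minimum Euclidean distance to ``z``.

    Ties break to the smallest (x, y) in row-major order.
    """
    d2 = ((grid.weights - np.asarray(z, dtype=float)) ** 2).sum(axis=2)
    flat = int(np.argmin(d2))  # argmin returns first minimum: row-major tie-break
    return flat // grid.shape[1], flat % grid.shape[1]


def _neighbourhood(shape: tuple[int, int], bmu: tuple[int, int], sigma: float) -> np.ndarray:
    """Gaussian factor beta_xy over grid coordinates; 1 at the BMU."""
    xs = np.arange(shape[0])[:, None]
    ys = np.arange(shape[1])[None, :]
    d2 = (xs - bmu[0]) ** 2 + (ys - bmu[1]) ** 2
    return np.exp(-d2 / (2.0 * sigma**2))


def update_weights(
    grid: SOMGrid, z: np.ndarray, bmu: tuple[int, int], alpha: float, sigma: float
) -> None:
    """Pull every node toward ``z`` by alpha * beta_xy, in place."""
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must be in [0, 1]")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    beta = _neighbourhood(grid.shape, bmu, sigma)
    grid.weights += alpha * beta[:, :, None] * (np.asarray(z, dtype=float) - grid.weights)


def _init_grid(
    shape: tuple[int, int], n_vars: int, rng: np.random.Generator,
    normalizer: NormalizationParams | None,
) -> SOMGrid:
    weights = rng.uniform(-1.0, 1.0, size=(shape[0], shape[1], n_vars))
    return SOMGrid(weights=weights, normalizer=normalizer)


def train_som(
    input_set: InputSet,
    schedule: TrainingSchedule,
    grid_shape: tuple[int, int] = (20, 20),
    normalizer: NormalizationParams | None = None,
) -> SOMGrid:
    """Train an unsupervised map.

    Per epoch the records are visited in a fresh seeded permutation;
    each presentation moves the BMU's neighbourhood toward the record.
    alpha and sigma decay geometrically between epochs.  Deterministic
    under a fixed schedule seed.
    """
    X = input_set.records
    K, N = X.shape
    if K < 1:
        raise ValueError("need at least one record")
    rng = np.random.default_rng(schedule.seed)
    grid = _init_grid(grid_shape, N, rng, normalizer)
    alpha = schedule.alpha0
    sigma = schedule.sigma0 if schedule.sigma0 is not None else max(grid_shape) / 2.0
    for _ in range(schedule.epochs):
        for k in rng.permutation(K):
            z = X[k]
            bmu = find_bmu(grid, z)
            update_weights(grid, z, bmu, alpha, sigma)
        alpha *= schedule.alpha_decay
        sigma *= schedule.sigma_decay
    grid.epochs_run = schedule.epochs
    grid.final_alpha = alpha
    grid.final_sigma = sigma
    return grid


def train_bdk(
    input_set: InputSet,
    schedule: TrainingSchedule,
    grid_shape: tuple[int, int] = (20, 20),
    normalizer: NormalizationParams | None = None,
) -> BDKModel:
    """Train a supervised (bi-directional) map on labelled records.

    The BMU search minimises a convex mix of squared distances on the
    class one-hot part and the feature part; at epoch t of T the class
    part carries weight 1 - t/T and the feature part t/T, so labels
    drive the organisation early and features late.  Both grids are
    updated with the same Gaussian neighbourhood.
    """
    if input_set.labels is None or any(l is None for l in input_set.labels):
        raise ValueError("every record must carry a class label")
    X = input_set.records
    K, N = X.shape
    classes = sorted(set(input_set.labels))
    C = len(classes)
    onehot = np.zeros((K, C))
    for i, label in enumerate(input_set.labels):
        onehot[i, classes.index(label)] = 1.0

    rng = np.random.default_rng(schedule.seed)
    grid = _init_grid(grid_shape, N, rng, normalizer)
    # Class weights start near-uniform on the simplex; the jitter breaks
    # the total tie in the first, purely class-driven, BMU searches.
    cw = np.full((grid_shape[0], grid_shape[1], C), 1.0 / C)
    cw += rng.uniform(0, 0.01, size=cw.shape)
    cw /= cw.sum(axis=2, keepdims=True)

    alpha = schedule.alpha0
    sigma = schedule.sigma0 if schedule.sigma0 is not None else max(grid_shape) / 2.0
    T = schedule.epochs
    for t in range(T):
        w_feat = t / T
        w_class = 1.0 - w_feat
        for k in rng.permutation(K):
            z, c = X[k], onehot[k]
            d2 = w_feat * ((grid.weights - z) ** 2).sum(axis=2)
            d2 += w_class * ((cw - c) ** 2).sum(axis=2)
            flat = int(np.argmin(d2))
            bmu = (flat // grid_shape[1], flat % grid_shape[1])
            beta = _neighbourhood(grid_shape, bmu, sigma)
            grid.weights += alpha * beta[:, :, None] * (z - grid.weights)
            cw += alpha * beta[:, :, None] * (c - cw)
        alpha *= schedule.alpha_decay
        sigma *= schedule.sigma_decay
    grid.epochs_run = T
    grid.final_alpha = alpha
    grid.final_sigma = sigma
    # Convex updates toward one-hots keep rows on the simplex; renormalise
    # only to absorb floating-point drift.
    cw = np.clip(cw, 0.0, None)
    cw /= cw.sum(axis=2, keepdims=True)
    return BDKModel(grid=grid, class_weights=cw, classes=classes)


def component_plane(grid: SOMGrid, variable: int) -> np.ndarray:
    """The (X, Y) matrix of de-normalised weight values of one variable."""
    if not 0 <= variable < grid.n_variables:
        raise IndexError(f"variable index {variable} out of range")
    plane = grid.weights[:, :, variable]
    if grid.normalizer is not None:
        plane = plane * grid.normalizer.std[variable] + grid.normalizer.mean[variable]
    return plane


def map_records(grid: SOMGrid, input_set: InputSet) -> dict[str, tuple[int, int]]:
    """Assign each record to its BMU; deterministic on a trained grid."""
    return {rid: find_bmu(grid, z) for rid, z in zip(input_set.ids, input_set.records)}


def region_histogram(
    assignments: dict[str, tuple[int, int]],
    node_subset: set[tuple[int, int]],
    raw_values: dict[str, float],
    bins: int | np.ndarray = 20,
    value_range: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of a raw variable over records whose BMU is in a region.

    Returns (counts, bin_edges).  An empty region yields all-zero counts.
    """
    values = [raw_values[rid] for rid, node in assignments.items() if node in node_subset]
    if not values:
        edges = np.histogram_bin_edges([], bins=bins, range=value_range or (0.0, 1.0))
        return np.zeros(len(edges) - 1, dtype=int), edges
    counts, edges = np.histogram(values, bins=bins, range=value_range)
    return counts, edges


def quantization_error(grid: SOMGrid, records: np.ndarray) -> float:
    """Mean Euclidean distance of records to their BMU weight vector."""
    X = np.asarray(records, dtype=float)
    total = 0.0
    for z in X:
        x, y = find_bmu(grid, z)
        total += float(np.linalg.norm(grid.weights[x, y] - z))
    return total / len(X)
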