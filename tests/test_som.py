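"""Map engine: normaliser, BMU search, neighbourhood update, training,
supervised maps, component planes and region histograms."""

from __future__ import annotations

import numpy as np
import pytest

from herdtyper.som import (
    InputSet,
    SOMGrid,
    TrainingSchedule,
    component_plane,
    find_bmu,
    fit_normalizer,
    map_records,
    quantization_error,
    region_histogram,
    train_bdk,
    train_som,
    update_weights,
)


# -- normaliser ----------------------------------------------------------------


def test_two_point_zscore():
    params = fit_normalizer(np.array([[0.0], [1.0]]))
    assert params.mean[0] == pytest.approx(0.5)
    transformed = params.apply(np.array([[0.0], [1.0]]))
    assert transformed.ravel() == pytest.approx([-1.0, 1.0])


def test_normalizer_inverts_and_centres():
    rng = np.random.default_rng(4)
    X = rng.normal(3, 2, size=(40, 5))
    params = fit_normalizer(X)
    Z = params.apply(X)
    assert np.abs(Z.mean(axis=0)).max() < 1e-10
    assert Z.std(axis=0) == pytest.approx(np.ones(5))
    assert np.abs(params.invert(Z) - X).max() < 1e-12


def test_constant_variable_rejected_by_name():
    X = np.column_stack([np.arange(5.0), np.ones(5)])
    with pytest.raises(ValueError, match="var1"):
        fit_normalizer(X)
    with pytest.raises(ValueError, match="flat"):
        fit_normalizer(X, names=("ok", "flat"))


# -- BMU search ----------------------------------------------------------------


def bmu_oracle(grid: SOMGrid, z: np.ndarray) -> tuple[int, int]:
    """Exhaustive search over every node, in row-major order."""
    best, best_d = None, np.inf
    for x in range(grid.shape[0]):
        for y in range(grid.shape[1]):
            d = float(np.linalg.norm(grid.weights[x, y] - z))
            if d < best_d:
                best, best_d = (x, y), d
    return best


def test_bmu_matches_exhaustive_oracle_on_100_random_instances():
    rng = np.random.default_rng(7)
    grid = SOMGrid(weights=rng.normal(size=(6, 6, 4)))
    for _ in range(100):
        z = rng.normal(size=4)
        assert find_bmu(grid, z) == bmu_oracle(grid, z)


def test_bmu_exact_hit_and_tie_break():
    grid = SOMGrid(weights=np.array([[[0.0, 0.0], [1.0, 1.0]]]))  # 1x2 grid
    assert find_bmu(grid, np.array([0.9, 0.9])) == (0, 1)
    assert find_bmu(grid, np.array([0.0, 0.0])) == (0, 0)
    # Equidistant input: first node in row-major order wins.
    assert find_bmu(grid, np.array([0.5, 0.5])) == (0, 0)


# -- weight update -------------------------------------------------------------


def test_update_alpha_one_sets_bmu_to_record():
    rng = np.random.default_rng(1)
    grid = SOMGrid(weights=rng.normal(size=(4, 4, 3)))
    z = rng.normal(size=3)
    bmu = find_bmu(grid, z)
    update_weights(grid, z, bmu, alpha=1.0, sigma=0.8)
    assert grid.weights[bmu] == pytest.approx(z)


def test_update_alpha_zero_is_identity():
    rng = np.random.default_rng(2)
    grid = SOMGrid(weights=rng.normal(size=(4, 4, 3)))
    before = grid.weights.copy()
    update_weights(grid, np.zeros(3), (1, 1), alpha=0.0, sigma=1.0)
    assert np.array_equal(grid.weights, before)


def test_half_width_of_gaussian_neighbourhood():
    """A node at grid distance sigma*sqrt(2 ln 2) moves half as far as
    the BMU (closed form of the Gaussian factor).  Choose sigma so that
    an integer grid offset sits exactly at that distance."""
    offset = 3
    sigma = offset / np.sqrt(2 * np.log(2.0))
    grid = SOMGrid(weights=np.zeros((1, 8, 1)))
    z = np.array([1.0])
    update_weights(grid, z, (0, 0), alpha=0.5, sigma=sigma)
    bmu_move = grid.weights[0, 0, 0]
    far_move = grid.weights[0, offset, 0]
    assert far_move == pytest.approx(bmu_move / 2)


def test_update_contracts_every_node_toward_record():
    rng = np.random.default_rng(3)
    grid = SOMGrid(weights=rng.normal(size=(5, 5, 4)))
    z = rng.normal(size=4)
    pre = np.linalg.norm(grid.weights - z, axis=2)
    update_weights(grid, z, find_bmu(grid, z), alpha=0.7, sigma=2.0)
    post = np.linalg.norm(grid.weights - z, axis=2)
    assert (post <= pre + 1e-12).all()


# -- training ------------------------------------------------------------------


def test_single_record_attracts_whole_map():
    """With one record, slow annealing contracts every node onto it."""
    z = np.array([0.3, -0.7])
    iset = InputSet(records=z[None, :], ids=["only"])
    schedule = TrainingSchedule(
        epochs=150, alpha0=0.9, alpha_decay=0.99, sigma0=4.0, sigma_decay=0.99, seed=5
    )
    grid = train_som(iset, schedule, grid_shape=(4, 4))
    assert np.abs(grid.weights - z).max() < 1e-3


def _two_cluster_set(seed: int = 9, k: int = 30) -> InputSet:
    rng = np.random.default_rng(seed)
    a = rng.normal([-2, -2], 0.2, size=(k, 2))
    b = rng.normal([2, 2], 0.2, size=(k, 2))
    X = np.vstack([a, b])
    ids = [f"a{i}" for i in range(k)] + [f"b{i}" for i in range(k)]
    labels = ["A"] * k + ["B"] * k
    return InputSet(records=X, ids=ids, labels=labels)


def test_quantization_error_decreases_with_training():
    iset = _two_cluster_set()
    schedule = TrainingSchedule(epochs=30, seed=6)
    rng = np.random.default_rng(schedule.seed)
    init = SOMGrid(weights=rng.uniform(-1, 1, size=(6, 6, 2)))
    qe_init = quantization_error(init, iset.records)
    trained = train_som(iset, schedule, grid_shape=(6, 6))
    qe_trained = quantization_error(trained, iset.records)
    assert qe_trained < qe_init


def _connected(nodes: set[tuple[int, int]]) -> bool:
    if not nodes:
        return False
    seen = {next(iter(nodes))}
    frontier = list(seen)
    while frontier:
        x, y = frontier.pop()
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                nb = (x + dx, y + dy)
                if nb in nodes and nb not in seen:
                    seen.add(nb)
                    frontier.append(nb)
    return seen == nodes


def test_two_clusters_occupy_disjoint_connected_regions():
    iset = _two_cluster_set()
    grid = train_som(iset, TrainingSchedule(epochs=40, seed=8), grid_shape=(6, 6))
    assign = map_records(grid, iset)
    nodes_a = {node for rid, node in assign.items() if rid.startswith("a")}
    nodes_b = {node for rid, node in assign.items() if rid.startswith("b")}
    assert nodes_a and nodes_b
    assert not nodes_a & nodes_b
    assert _connected(nodes_a) and _connected(nodes_b)


def test_training_is_deterministic_under_fixed_seed():
    iset = _two_cluster_set()
    s = TrainingSchedule(epochs=10, seed=12)
    g1 = train_som(iset, s, grid_shape=(5, 5))
    g2 = train_som(iset, s, grid_shape=(5, 5))
    assert np.array_equal(g1.weights, g2.weights)
    m1 = train_bdk(iset, s, grid_shape=(5, 5))
    m2 = train_bdk(iset, s, grid_shape=(5, 5))
    assert np.array_equal(m1.grid.weights, m2.grid.weights)
    assert np.array_equal(m1.class_weights, m2.class_weights)


def test_training_ignores_record_identity():
    iset = _two_cluster_set()
    renamed = InputSet(
        records=iset.records, ids=[f"x{i}" for i in range(len(iset.ids))], labels=iset.labels
    )
    s = TrainingSchedule(epochs=10, seed=13)
    assert np.array_equal(
        train_som(iset, s, (5, 5)).weights, train_som(renamed, s, (5, 5)).weights
    )


# -- supervised maps -----------------------------------------------------------


def test_bdk_separates_two_classes():
    iset = _two_cluster_set()
    model = train_bdk(iset, TrainingSchedule(epochs=40, seed=21), grid_shape=(6, 6))
    predicted = model.predict(iset.records)
    accuracy = np.mean([p == t for p, t in zip(predicted, iset.labels)])
    assert accuracy >= 0.95
    # Majority labels form two contiguous regions.
    labels = model.node_labels()
    for c in range(len(model.classes)):
        region = {(x, y) for x in range(6) for y in range(6) if labels[x, y] == c}
        assert _connected(region)
    # Class-weight vectors stay on the probability simplex.
    assert (model.class_weights >= 0).all()
    assert model.class_weights.sum(axis=2) == pytest.approx(np.ones((6, 6)))


def test_bdk_single_class_labels_every_node():
    iset = _two_cluster_set()
    mono = InputSet(records=iset.records, ids=iset.ids, labels=["A"] * len(iset.ids))
    model = train_bdk(mono, TrainingSchedule(epochs=10, seed=2), grid_shape=(4, 4))
    assert model.classes == ["A"]
    assert (model.node_labels() == 0).all()


def test_bdk_requires_labels():
    iset = _two_cluster_set()
    unlabelled = InputSet(records=iset.records, ids=iset.ids)
    with pytest.raises(ValueError, match="label"):
        train_bdk(unlabelled, TrainingSchedule(epochs=2, seed=0), (4, 4))


# -- instrumentation -----------------------------------------------------------


def test_component_planes_denormalise_weights():
    iset = _two_cluster_set()
    norm = fit_normalizer(iset.records)
    normalised = InputSet(records=norm.apply(iset.records), ids=iset.ids)
    grid = train_som(normalised, TrainingSchedule(epochs=20, seed=3), (5, 5), normalizer=norm)
    planes = [component_plane(grid, i) for i in range(grid.n_variables)]
    assert len(planes) == 2
    for i, plane in enumerate(planes):
        assert plane == pytest.approx(grid.weights[:, :, i] * norm.std[i] + norm.mean[i])
        # De-normalised plane lies within the raw data range plus slack.
        lo, hi = iset.records[:, i].min(), iset.records[:, i].max()
        span = hi - lo
        assert plane.min() > lo - 0.5 * span and plane.max() < hi + 0.5 * span
    with pytest.raises(IndexError):
        component_plane(grid, 2)


def test_map_records_matches_bmu_and_conserves_counts():
    iset = _two_cluster_set()
    grid = train_som(iset, TrainingSchedule(epochs=5, seed=4), (5, 5))
    assign = map_records(grid, iset)
    assert len(assign) == len(iset.ids)
    for rid, z in zip(iset.ids, iset.records):
        assert assign[rid] == find_bmu(grid, z)
    # Identical records share a node.
    twin = InputSet(records=np.vstack([iset.records[0], iset.records[0]]), ids=["t1", "t2"])
    twin_assign = map_records(grid, twin)
    assert twin_assign["t1"] == twin_assign["t2"]


def test_region_histograms_are_additive_and_localised():
    # Half the records at 0.1, half at 0.9.
    values = {f"r{i}": (0.1 if i < 20 else 0.9) for i in range(40)}
    assignments = {f"r{i}": ((0, 0) if i < 20 else (1, 1)) for i in range(40)}
    all_nodes = {(0, 0), (1, 1)}
    counts_all, edges = region_histogram(assignments, all_nodes, values, bins=10, value_range=(0, 1))
    assert counts_all.sum() == 40

    c_low, _ = region_histogram(assignments, {(0, 0)}, values, bins=10, value_range=(0, 1))
    c_high, _ = region_histogram(assignments, {(1, 1)}, values, bins=10, value_range=(0, 1))
    assert np.array_equal(c_low + c_high, counts_all)
    # The 0.9-cluster's region shows a single right mode.
    centers = (edges[:-1] + edges[1:]) / 2
    assert c_high[centers > 0.5].sum() == 20 and c_high[centers < 0.5].sum() == 0

    empty, _ = region_histogram(assignments, {(3, 3)}, values, bins=10, value_range=(0, 1))
    assert empty.sum() == 0
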