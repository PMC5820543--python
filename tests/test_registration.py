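import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bloomcount.registration import (Cluster, RegistrationConfig, RegPoint,
                                     bloom_count_per_plot,
                                     constrained_distance, register_blooms,
                                     weighted_distance)
from bloomcount.scene_io import PlotBoundary
from bloomcount.simulation import SimConfig, generate_sim_data


def _cluster(points, classes):
    pts = np.asarray(points, float)
    return Cluster(members=tuple(range(len(pts))), center=pts.mean(axis=0),
                   classes=frozenset(classes))


def test_weighted_distance_identity_and_elevation_weight():
    assert weighted_distance((1, 2, 3), (1, 2, 3)) == 0.0
    assert weighted_distance((0, 0, 0), (0, 0, 2), w=0.5) == pytest.approx(1.0)


@settings(derandomize=True, max_examples=50, deadline=None)
@given(st.lists(st.floats(-10, 10), min_size=6, max_size=6))
def test_weighted_distance_w1_is_euclidean(vals):
    a, b = np.asarray(vals[:3]), np.asarray(vals[3:])
    assert weighted_distance(a, b, w=1.0) == pytest.approx(
        float(np.linalg.norm(a - b)), abs=1e-12)


def test_constrained_distance_rules():
    ci = _cluster([[0, 0, 0]], ["IMG_3"])
    cj = _cluster([[1, 0, 0]], ["IMG_3"])
    ck = _cluster([[1, 0, 0]], ["IMG_5"])
    assert constrained_distance(ci, cj) == float("inf")
    assert constrained_distance(ci, ck) == pytest.approx(1.0)


def test_constrained_distance_symmetric():
    rng = np.random.default_rng(0)
    for _ in range(20):
        ca = _cluster(rng.normal(size=(2, 3)), ["a", "b"])
        cb = _cluster(rng.normal(size=(3, 3)), rng.choice(["a", "c", "d", "e"],
                                                          3, replace=False))
        assert constrained_distance(ca, cb) == constrained_distance(cb, ca)


def test_cluster_rejects_duplicate_classes():
    with pytest.raises(ValueError):
        Cluster(members=(0, 1), center=np.zeros(3), classes=frozenset(["a"]))


# ------------------------------------------------------------- merge loop

def _register(coords, classes, lam, w=1.0):
    pts = [RegPoint(np.asarray(c, float), k) for c, k in zip(coords, classes)]
    return register_blooms(pts, RegistrationConfig(merge_threshold=lam,
                                                   elevation_weight=w))


def test_single_point_is_one_cluster():
    z, clusters = _register([[0, 0, 0]], ["a"], 1.0)
    assert len(clusters) == 1 and list(z) == [0]


def test_same_class_never_merges_even_at_zero_distance():
    z, clusters = _register([[0, 0, 0], [0, 0, 0]], ["a", "a"], 1.0)
    assert len(clusters) == 2


@pytest.mark.parametrize("lam,expected", [(0.6, 1), (0.5, 2), (0.4, 2)])
def test_strict_merge_threshold(lam, expected):
    z, clusters = _register([[0, 0, 0], [0.5, 0, 0]], ["a", "b"], lam)
    assert len(clusters) == expected


def test_empty_input_rejected():
    with pytest.raises(ValueError):
        register_blooms([], RegistrationConfig(merge_threshold=1.0))


def test_zero_noise_duplicates_recovered_exactly():
    cfg = SimConfig(points_per_class=60, sigma=1e-12, rng_seed=5)
    data = generate_sim_data(cfg)
    z, clusters = _register(data.observations, data.classes, lam=0.5)
    assert len(clusters) == len(np.unique(data.truth))
    # identical partitions
    for c in clusters.values():
        assert len(set(data.truth[list(c.members)])) == 1


def _invariants(points, classes, z, clusters, lam, w):
    # partition: every point in exactly one cluster
    members = [i for c in clusters.values() for i in c.members]
    assert sorted(members) == list(range(len(points)))
    for cid, c in clusters.items():
        # cannot-link: one detection per source image per cluster
        assert len(c.classes) == len(c.members)
        assert np.allclose(c.center,
                           np.asarray(points)[list(c.members)].mean(axis=0))
        assert all(z[i] == cid for i in c.members)
    # lambda-separation at convergence
    ids = sorted(clusters)
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            d = constrained_distance(clusters[ids[a]], clusters[ids[b]], w)
            assert d >= lam


@pytest.mark.parametrize("seed", range(5))
def test_invariants_on_noisy_artificial_data(seed):
    cfg = SimConfig(points_per_class=40, sigma=0.3, rng_seed=seed)
    data = generate_sim_data(cfg)
    lam = 2 * cfg.sigma
    z, clusters = _register(data.observations, data.classes, lam)
    _invariants(data.observations, data.classes, z, clusters, lam, w=1.0)


# ------------------------------------------------- greedy-trace oracle

def _replay_reference(coords, classes, lam, w):
    """Literal pure-python replay of the merging loop: singletons,
    index-ordered passes, stale centers within a pass, strict threshold,
    lowest-index tie break, center recomputation at pass end."""
    n = len(coords)
    z = list(range(n))
    centers = {i: np.asarray(coords[i], float) for i in range(n)}

    def wdist(a, b):
        d = a - b
        return float(np.sqrt(d[0] ** 2 + d[1] ** 2 + (w * d[2]) ** 2))

    while True:
        merged = False
        for i in range(n):
            mem_i = [k for k in range(n) if z[k] == i]
            if not mem_i:
                continue
            ei = {classes[k] for k in mem_i}
            best_d, best_j = None, None
            for j in range(n):
                if j == i:
                    continue
                mem_j = [k for k in range(n) if z[k] == j]
                if not mem_j:
                    continue
                if ei & {classes[k] for k in mem_j}:
                    continue
                d = wdist(centers[i], centers[j])
                if best_d is None or d < best_d:
                    best_d, best_j = d, j
            if best_d is not None and best_d < lam:
                for k in mem_i:
                    z[k] = best_j
                merged = True
        for j in range(n):
            mem = [k for k in range(n) if z[k] == j]
            if mem:
                centers[j] = np.mean([coords[k] for k in mem], axis=0)
        if not merged:
            return z


@pytest.mark.parametrize("seed", range(30))
def test_matches_literal_replay_on_small_instances(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 11))
    coords = rng.uniform(0, 2, (n, 3))
    classes = [int(c) for c in rng.integers(0, 4, n)]
    lam = float(rng.uniform(0.3, 1.5))
    w = float(rng.choice([0.5, 1.0]))
    z, _ = _register(coords, classes, lam, w)
    ref = _replay_reference(coords, classes, lam, w)
    assert list(z) == ref


# ------------------------------------------------------------- counting

def _square(pid, cx, cy, half=0.75):
    return PlotBoundary(pid, np.array([
        [cx - half, cy - half, 0], [cx + half, cy - half, 0],
        [cx + half, cy + half, 0], [cx - half, cy + half, 0]], float))


def _singleton(idx, xyz):
    return {idx: _cluster([xyz], [f"i{idx}"])}


def test_counts_per_plot():
    plots = [_square("A", 0, 0), _square("B", 2, 0)]
    clusters = {i: _cluster([[0.1 * i, 0.1, 0.5]], [f"i{i}"]) for i in range(3)}
    counts, outside = bloom_count_per_plot(clusters, plots)
    assert counts == {"A": 3, "B": 0} and outside == []


def test_cluster_on_shared_edge_goes_to_first_plot():
    plots = [_square("A", 0, 0), _square("B", 1.5, 0)]  # shared edge x=0.75
    counts, _ = bloom_count_per_plot(_singleton(0, [0.75, 0.0, 0.3]), plots)
    assert counts == {"A": 1, "B": 0}
    counts, _ = bloom_count_per_plot(_singleton(0, [0.75, 0.0, 0.3]), plots[::-1])
    assert counts == {"B": 1, "A": 0}


def test_empty_clusters_all_zero_and_outside_reported():
    plots = [_square("A", 0, 0)]
    counts, outside = bloom_count_per_plot({}, plots)
    assert counts == {"A": 0}
    counts, outside = bloom_count_per_plot(_singleton(7, [9, 9, 0]), plots)
    assert counts == {"A": 0} and outside == [7]


def test_overlapping_plots_rejected():
    with pytest.raises(ValueError):
        bloom_count_per_plot({}, [_square("A", 0, 0), _square("B", 0.5, 0)])
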