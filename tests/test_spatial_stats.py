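import numpy as np
import pytest
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist, pdist, squareform

from igquant.core_model import ClusterRecord, NNDResult
from igquant.spatial_stats import (
    InsufficientParticlesError,
    area_count_correlation,
    cluster_area,
    cluster_threshold,
    density,
    inter_cluster_distances,
    nnd,
    ripley_k,
    single_linkage_clusters,
)

from conftest import make_particles


# ---------------------------------------------------------------------------
# nearest-neighbour distances


def test_intra_nnd_three_points():
    particles = make_particles([(0, 0), (0, 30), (100, 0)])
    result = nnd(particles, "intra", 10, 10)
    assert sorted(result.distances_nm.tolist()) == [30.0, 30.0, 100.0]
    assert result.mean_nm == pytest.approx(160.0 / 3.0)


def test_inter_nnd_directional():
    b = make_particles([(0, 5), (300, 0)], cls=5, prefix="b")
    a = make_particles([(0, 0), (100, 0)], cls=10, prefix="a")
    result = nnd(a + b, "inter", 5, 10)
    assert sorted(result.distances_nm.tolist()) == [5.0, 200.0]
    assert result.mean_nm == pytest.approx(102.5)


def test_intra_nnd_single_particle_is_an_error():
    with pytest.raises(InsufficientParticlesError):
        nnd(make_particles([(0, 0)]), "intra", 10, 10)


def test_inter_nnd_missing_class_is_an_error():
    with pytest.raises(InsufficientParticlesError):
        nnd(make_particles([(0, 0), (5, 5)], cls=10), "inter", 5, 10)


def test_nnd_matches_brute_force_on_random_patterns(rng):
    for _ in range(20):
        xy10 = rng.uniform(0, 500, (int(rng.integers(2, 40)), 2))
        xy5 = rng.uniform(0, 500, (int(rng.integers(1, 40)), 2))
        particles = make_particles(xy10, cls=10) + make_particles(xy5, cls=5, prefix="q")
        d_intra = nnd(particles, "intra", 10, 10).distances_nm
        full = squareform(pdist(xy10)) + np.diag(np.full(len(xy10), np.inf))
        assert d_intra == pytest.approx(full.min(axis=1))
        d_inter = nnd(particles, "inter", 5, 10).distances_nm
        assert d_inter == pytest.approx(cdist(xy5, xy10).min(axis=1))


# ---------------------------------------------------------------------------
# clustering threshold


def _nnd_result(values):
    arr = np.asarray(values, float)
    return NNDResult("intra", 10, 10, arr, float(arr.mean()))


def test_threshold_mean_plus_2sd():
    thr = cluster_threshold(_nnd_result([10, 10, 15, 75]))
    sd = np.std([10, 10, 15, 75], ddof=1)
    assert thr == pytest.approx(27.5 + 2 * sd)
    assert thr == pytest.approx(91.01, abs=0.005)


def test_threshold_constant_distances():
    assert cluster_threshold(_nnd_result([20, 20, 20])) == pytest.approx(20.0)


def test_threshold_alternative_rules():
    res = _nnd_result([10, 10, 15, 75])
    assert cluster_threshold(res, rule="mean") == pytest.approx(27.5)
    sd = np.std([10, 10, 15, 75], ddof=1)
    assert cluster_threshold(res, rule="mean_plus_1sd") == pytest.approx(27.5 + sd)
    assert cluster_threshold(res, rule="fixed", fixed_nm=40.0) == 40.0


# ---------------------------------------------------------------------------
# single-linkage clustering


SIX_POINTS = [(0, 0), (0, 15), (0, 30), (300, 0), (300, 10), (500, 500)]


def test_single_linkage_example_min_size_three():
    clusters = single_linkage_clusters(make_particles(SIX_POINTS), 20.0, 3)
    assert len(clusters) == 1
    assert sorted(clusters[0].member_ids) == ["p0", "p1", "p2"]


def test_single_linkage_example_min_size_two():
    clusters = single_linkage_clusters(make_particles(SIX_POINTS), 20.0, 2)
    assert sorted(c.n_particles for c in clusters) == [2, 3]


def test_single_linkage_empty_input():
    assert single_linkage_clusters([], 20.0, 3) == []


def _brute_force_partition(xy, threshold):
    """Connected components of the <=threshold graph, via scipy csgraph."""
    n = len(xy)
    d = squareform(pdist(xy))
    ii, jj = np.nonzero(d <= threshold)
    graph = coo_matrix((np.ones_like(ii), (ii, jj)), shape=(n, n))
    _, labels = connected_components(graph, directed=False)
    return labels


def test_single_linkage_equals_connected_components(rng):
    for _ in range(50):
        n = int(rng.integers(2, 80))
        xy = rng.uniform(0, 400, (n, 2))
        threshold = float(rng.uniform(10, 120))
        particles = make_particles(xy)
        clusters = single_linkage_clusters(particles, threshold, 1)
        got = {frozenset(c.member_ids) for c in clusters}
        labels = _brute_force_partition(xy, threshold)
        want = {
            frozenset(f"p{i}" for i in np.flatnonzero(labels == lab))
            for lab in np.unique(labels)
        }
        assert got == want


def test_single_linkage_invariant_to_order_and_rigid_motion(rng):
    xy = rng.uniform(0, 300, (40, 2))
    particles = make_particles(xy)
    base = {frozenset(c.member_ids) for c in single_linkage_clusters(particles, 50.0, 3)}

    perm = rng.permutation(40)
    shuffled = [particles[i] for i in perm]
    assert {frozenset(c.member_ids) for c in single_linkage_clusters(shuffled, 50.0, 3)} == base

    theta = 0.7
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    moved = (xy @ rot.T) + [1000.0, 2000.0]
    transformed = make_particles(moved)
    assert {frozenset(c.member_ids) for c in single_linkage_clusters(transformed, 50.0, 3)} == base


def test_threshold_hierarchy_is_monotone(rng):
    """Clusters at a smaller threshold refine clusters at a larger one."""
    xy = rng.uniform(0, 400, (60, 2))
    particles = make_particles(xy)
    for t1, t2 in [(20, 40), (40, 80), (25, 26)]:
        fine = single_linkage_clusters(particles, t1, 1)
        coarse = single_linkage_clusters(particles, t2, 1)
        coarse_sets = [set(c.member_ids) for c in coarse]
        for c in fine:
            assert sum(set(c.member_ids) <= cs for cs in coarse_sets) == 1


# ---------------------------------------------------------------------------
# cluster geometry


def test_cluster_area_examples():
    assert cluster_area(np.array([(0, 0), (100, 0), (0, 100)])) == pytest.approx(5000.0)
    assert cluster_area(np.array([(0, 0), (10, 0), (20, 0)])) == 0.0
    square = np.array([(0, 0), (100, 0), (100, 100), (0, 100)])
    assert cluster_area(square) == pytest.approx(10000.0)


def test_cluster_area_matches_shapely_hull_oracle(rng):
    from shapely.geometry import MultiPoint

    for _ in range(300):
        n = int(rng.integers(3, 40))
        xy = rng.uniform(0, 200, (n, 2))
        assert cluster_area(xy) == pytest.approx(MultiPoint(xy.tolist()).convex_hull.area, abs=1e-6)


def _cluster_from(xy, cls=10):
    xy = np.asarray(xy, float)
    return ClusterRecord(
        member_ids=[f"m{i}" for i in range(len(xy))],
        size_class=cls,
        n_particles=len(xy),
        hull_area_nm2=cluster_area(xy),
        centroid_nm=(float(xy[:, 0].mean()), float(xy[:, 1].mean())),
        member_xy=xy,
    )


def test_inter_cluster_distance_symmetric_pair():
    a = _cluster_from([(0, 0), (0, 10), (10, 0)])
    b = _cluster_from([(60, 0), (60, 10), (70, 0)])  # closest members 50 apart
    both = [a, b]
    assert inter_cluster_distances(both, both).tolist() == [50.0, 50.0]


def test_inter_cluster_distance_coincident_point_is_zero():
    a = _cluster_from([(0, 0), (0, 10), (10, 0)])
    b = _cluster_from([(0, 0), (50, 50), (80, 80)])
    assert inter_cluster_distances([a], [b])[0] == 0.0


def test_single_cluster_has_no_neighbour():
    a = _cluster_from([(0, 0), (0, 10), (10, 0)])
    with pytest.raises(InsufficientParticlesError):
        inter_cluster_distances([a], [a])


def test_centroid_metric_differs_from_min_member():
    a = _cluster_from([(0, 0), (0, 10), (10, 0)])
    b = _cluster_from([(60, 0), (60, 10), (70, 0)])
    d_min = inter_cluster_distances([a], [b], metric="min_member")[0]
    d_cen = inter_cluster_distances([a], [b], metric="centroid")[0]
    assert d_min == 50.0 and d_cen > d_min


# ---------------------------------------------------------------------------
# density


def test_density_count_over_area(square_roi):
    square_roi.polygon = [(0, 0), (632.456, 0), (632.456, 632.456), (0, 632.456)]
    square_roi.area_um2 = None
    square_roi.__post_init__()
    assert square_roi.area_um2 == pytest.approx(0.4, rel=1e-3)
    coords = [(50 + 25 * i, 50 + 20 * i) for i in range(20)]
    rec = density(make_particles(coords), square_roi, 10, image_id="img")
    assert rec.density_per_um2 == pytest.approx(20 / square_roi.area_um2)


def test_density_zero_particles(square_roi):
    rec = density([], square_roi, 10)
    assert rec.n_particles == 0 and rec.density_per_um2 == 0.0


def test_density_excludes_outside_particles(square_roi):
    inside = make_particles([(10, 10), (500, 500), (999, 999)])
    outside = make_particles([(1500, 1500), (-5, 50)], prefix="o")
    rec = density(inside + outside, square_roi, 10)
    assert rec.n_particles == 3 and rec.density_per_um2 == pytest.approx(3.0)


def test_density_zero_area_roi_is_error(square_roi):
    square_roi.area_um2 = 0.0
    with pytest.raises(ValueError, match="zero area"):
        density([], square_roi, 10)


# ---------------------------------------------------------------------------
# Ripley's K


def test_ripley_k_small_r_no_pairs(square_roi):
    xy = np.array([(0.0, 0.0), (10.0, 0.0)])
    curve = ripley_k(xy, square_roi, [5.0])
    assert curve.k_values[0] == 0.0


def test_ripley_k_all_pairs_equals_area(square_roi):
    xy = np.array([(0.0, 0.0), (10.0, 0.0)])
    curve = ripley_k(xy, square_roi, [15.0])
    # A/(n(n-1)) * 2 ordered pairs = A
    assert curve.k_values[0] == pytest.approx(1e6)


def test_ripley_k_monotone_in_r(square_roi, rng):
    xy = rng.uniform(0, 1000, (50, 2))
    curve = ripley_k(xy, square_roi, [10.0, 50.0, 100.0, 200.0])
    assert np.all(np.diff(curve.k_values) >= 0)


def test_toroidal_requires_period(square_roi):
    xy = np.array([(0.0, 0.0), (10.0, 0.0), (20.0, 20.0)])
    with pytest.raises(ValueError, match="period"):
        ripley_k(xy, square_roi, [10.0], estimator="toroidal")


# ---------------------------------------------------------------------------
# correlation


def test_area_count_correlation_proportional_is_one():
    clusters = [
        _cluster_from(np.array([(0, 0), (0, s * 10), (s * 10, 0)]) + 200 * i)
        for i, s in enumerate([1, 2, 3, 4], start=1)
    ]
    for c, n in zip(clusters, [3, 6, 9, 12]):
        c.n_particles = n
        c.hull_area_nm2 = 100.0 * n  # exactly proportional
    r, p = area_count_correlation(clusters)
    assert r == pytest.approx(1.0)


def test_area_count_correlation_constant_counts_is_error():
    clusters = [_cluster_from([(0, 0), (0, 10 * i), (10 * i, 0)]) for i in range(1, 5)]
    for c in clusters:
        c.n_particles = 3
    with pytest.raises(ValueError, match="variance"):
        area_count_correlation(clusters)
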