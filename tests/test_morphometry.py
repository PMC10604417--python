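"""Point clouds, DBSCAN grain isolation, surfaces, boxes, ordering."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from spikect import morphometry as mm
from spikect import phantom as ph
from spikect.volume_io import BinaryVolume

from conftest import small_grain_spec


def _bv(mask, P=85.0):
    return BinaryVolume(mask.astype(np.uint8), P)


# ---------------------------------------------------------------------------
# volume_to_pointcloud
# ---------------------------------------------------------------------------

def test_single_voxel_cloud():
    m = np.zeros((10, 10, 10))
    m[5, 6, 7] = 1
    pts = mm.volume_to_pointcloud(_bv(m))
    assert pts.shape == (1, 3)
    assert pts[0].tolist() == [5, 6, 7]


def test_cube_point_count():
    pts = mm.volume_to_pointcloud(_bv(np.ones((10, 10, 10))))
    assert pts.shape == (1000, 3)


def test_empty_foreground_rejected():
    with pytest.raises(ValueError, match="no spike"):
        mm.volume_to_pointcloud(_bv(np.zeros((4, 4, 4))))


def test_phantom_cloud_size_matches_truth():
    spec = small_grain_spec(seed=6, volume_dims=(80, 64, 64), grain_count=4)
    _, truth = ph.generate_phantom(spec)
    pts = mm.volume_to_pointcloud(_bv(truth.label_volume > 0))
    assert pts.shape[0] == int(np.count_nonzero(truth.label_volume))


# ---------------------------------------------------------------------------
# extract_surface_points
# ---------------------------------------------------------------------------

def test_cube_shell_is_all_but_center():
    m = np.zeros((5, 5, 5))
    m[1:4, 1:4, 1:4] = 1
    pts = np.argwhere(m > 0)
    shell = mm.extract_surface_points(m, pts)
    assert shell.shape[0] == 26
    assert [2, 2, 2] not in shell.tolist()


def test_single_voxel_is_its_own_shell():
    m = np.zeros((3, 3, 3))
    m[1, 1, 1] = 1
    shell = mm.extract_surface_points(m, np.argwhere(m > 0))
    assert shell.tolist() == [[1, 1, 1]]


def test_sphere_shell_has_no_interior_point():
    g = np.arange(-22, 23)
    Z, Y, X = np.meshgrid(g, g, g, indexing="ij")
    inside = Z ** 2 + Y ** 2 + X ** 2 <= 20 ** 2
    occ = inside.astype(np.uint8)
    pts = np.argwhere(occ)
    shell = mm.extract_surface_points(occ, pts)
    # every shell point has at least one 6-neighbour outside the sphere
    for p in shell[::37]:
        nb_all_fg = all(
            occ[tuple(np.clip(p + d, 0, occ.shape[0] - 1))]
            for d in np.vstack([np.eye(3, dtype=int), -np.eye(3, dtype=int)])
        )
        assert not nb_all_fg


# ---------------------------------------------------------------------------
# cluster_grains vs an independent density-connectivity oracle
# ---------------------------------------------------------------------------

def dbscan_oracle(points, eps, min_points):
    """BFS over the eps-neighbourhood graph with the same core rule:
    a point is core iff its eps-ball holds >= min_points points (itself
    included); clusters grow from cores in point order; border points join
    the earliest cluster that reaches them."""
    tree = cKDTree(points)
    neigh = tree.query_ball_point(points, eps)
    core = np.array([len(n) >= min_points for n in neigh])
    labels = -np.ones(len(points), dtype=int)
    cid = 0
    for i in range(len(points)):
        if labels[i] != -1 or not core[i]:
            continue
        labels[i] = cid
        queue = [i]
        while queue:
            j = queue.pop()
            if not core[j]:
                continue
            for k in neigh[j]:
                if labels[k] == -1:
                    labels[k] = cid
                    queue.append(k)
        cid += 1
    return labels


def _random_cloud(rng):
    """Clumpy random cloud: a few Gaussian blobs plus sparse noise."""
    parts = []
    for _ in range(rng.integers(2, 5)):
        center = rng.uniform(0, 60, 3)
        parts.append(rng.normal(center, rng.uniform(1.0, 3.0), (rng.integers(50, 400), 3)))
    parts.append(rng.uniform(0, 60, (rng.integers(10, 60), 3)))
    pts = np.concatenate(parts)[:2000]
    return np.unique(np.round(pts, 3), axis=0)


@pytest.mark.parametrize("trial", range(5))
def test_clustering_matches_bfs_oracle(trial):
    rng = np.random.default_rng(300 + trial)
    pts = _random_cloud(rng)
    eps = float(rng.uniform(1.5, 4.0))
    min_points = int(rng.integers(3, 10))
    cfg = mm.ClusterConfig(eps=eps, min_points=min_points, min_cluster_voxels=1)
    clusters, debris = mm.cluster_grains(pts, cfg)
    labels = dbscan_oracle(pts, eps, min_points)
    oracle_clusters = [pts[labels == c] for c in range(labels.max() + 1)]
    assert len(clusters) == len(oracle_clusters)
    for got, exp in zip(clusters, oracle_clusters):
        assert {tuple(p) for p in got} == {tuple(p) for p in exp}
    assert {tuple(p) for p in debris} == {tuple(p) for p in pts[labels == -1]}


def test_two_separated_blobs_make_two_grains():
    m = np.zeros((40, 16, 16))
    m[2:7, 2:7, 2:7] = 1
    m[27:32, 2:7, 2:7] = 1
    clusters, debris = mm.cluster_grains(
        mm.volume_to_pointcloud(_bv(m)),
        mm.ClusterConfig(eps=4, min_points=10, min_cluster_voxels=50))
    assert len(clusters) == 2
    assert debris.shape[0] == 0


def test_single_blob_is_one_grain():
    m = np.zeros((12, 12, 12))
    m[2:9, 2:9, 2:9] = 1
    clusters, _ = mm.cluster_grains(mm.volume_to_pointcloud(_bv(m)),
                                    mm.ClusterConfig())
    assert len(clusters) == 1


def test_cluster_size_conservation():
    rng = np.random.default_rng(17)
    pts = _random_cloud(rng)
    cfg = mm.ClusterConfig(eps=2.0, min_points=6, min_cluster_voxels=30)
    clusters, debris = mm.cluster_grains(pts, cfg)
    assert sum(c.shape[0] for c in clusters) + debris.shape[0] == pts.shape[0]


def test_no_grains_after_filtering_raises():
    pts = np.array([[0, 0, 0], [50, 50, 50], [90, 0, 0]], float)
    with pytest.raises(ValueError, match="adjust eps"):
        mm.cluster_grains(pts, mm.ClusterConfig(eps=1.0, min_points=3))


# ---------------------------------------------------------------------------
# grain_volume / grain_surface
# ---------------------------------------------------------------------------

def test_volume_unit_identity():
    assert mm.grain_volume(1000, 100.0) == pytest.approx(1.0)
    assert mm.grain_volume(0, 100.0) == 0.0


def test_volume_surface_pixel_size_scaling():
    """V scales as P^3 and S as P^2 under a pure pixel-size change."""
    m = np.zeros((12, 12, 12))
    m[2:9, 3:8, 3:9] = 1
    pts = np.argwhere(m > 0).astype(float)
    shell = mm.extract_surface_points(m, pts)
    _, _, s1 = mm.grain_surface(shell, 1e6, 50.0)
    _, _, s2 = mm.grain_surface(shell, 1e6, 100.0)
    assert s2 / s1 == pytest.approx(4.0, rel=1e-12)
    assert mm.grain_volume(343, 100.0) / mm.grain_volume(343, 50.0) == pytest.approx(8.0)


def test_cube_surface_equals_hull_area():
    g = np.arange(10)
    zz, yy, xx = np.meshgrid(g, g, g, indexing="ij")
    pts = np.stack([zz.ravel(), yy.ravel(), xx.ravel()], 1).astype(float)
    _, m, s = mm.grain_surface(pts, alpha=1e6, pixel_size_um=100.0)
    assert s == pytest.approx(6 * (9 * 0.1) ** 2, rel=5e-3)
    assert m == pytest.approx(mm.convex_hull_area(pts), rel=1e-9)


def test_collinear_points_are_degenerate():
    with pytest.raises(ValueError, match="degenerate"):
        mm.grain_surface(np.array([[0, 0, 0], [1, 1, 1], [2, 2, 2]], float),
                         12.0, 100.0)


def test_alpha_shape_tracks_concavity():
    """Two separated cubes: a large alpha bridges them (hull), a small
    alpha returns both cube surfaces, so the small-alpha area is larger."""
    g = np.arange(6)
    zz, yy, xx = np.meshgrid(g, g, g, indexing="ij")
    cube = np.stack([zz.ravel(), yy.ravel(), xx.ravel()], 1).astype(float)
    two = np.concatenate([cube, cube + [30, 0, 0]])
    _, _, a_small = mm.grain_surface(two, alpha=4.0, pixel_size_um=100.0)
    _, _, a_large = mm.grain_surface(two, alpha=1e6, pixel_size_um=100.0)
    assert a_small > 2 * 0.9 * (6 * (5 * 0.1) ** 2)  # ~both cube hulls
    assert a_large < a_small


# ---------------------------------------------------------------------------
# grain_obb
# ---------------------------------------------------------------------------

def test_obb_axis_aligned_box_exact():
    zz, yy, xx = np.meshgrid(np.arange(50), np.arange(20), np.arange(10),
                             indexing="ij")
    pts = np.stack([zz.ravel(), yy.ravel(), xx.ravel()], 1).astype(float)
    assert mm.grain_obb(pts, 100.0) == pytest.approx((5.0, 2.0, 1.0))


def test_obb_rotation_invariance():
    zz, yy, xx = np.meshgrid(np.arange(50), np.arange(20), np.arange(10),
                             indexing="ij")
    pts = np.stack([zz.ravel(), yy.ravel(), xx.ravel()], 1).astype(float)
    th = np.deg2rad(30)
    R = np.array([[1, 0, 0],
                  [0, np.cos(th), -np.sin(th)],
                  [0, np.sin(th), np.cos(th)]])
    dims = mm.grain_obb(pts @ R.T, 100.0)
    assert dims == pytest.approx((5.0, 2.0, 1.0), rel=0.03)


def test_obb_sorted_and_single_point_rejected():
    rng = np.random.default_rng(5)
    pts = rng.normal(0, 5, (200, 3))
    l, w, t = mm.grain_obb(pts, 80.0)
    assert l >= w >= t > 0
    with pytest.raises(ValueError):
        mm.grain_obb(pts[:1], 80.0)


# ---------------------------------------------------------------------------
# ordering / spike traits / profiles
# ---------------------------------------------------------------------------

def test_order_along_axis():
    cents = np.array([[90, 0, 0], [10, 0, 0], [50, 0, 0]], float)
    idx = mm.order_grains(cents, np.array([1.0, 0, 0]))
    assert idx.tolist() == [3, 1, 2]


def test_order_tie_break_is_deterministic():
    cents = np.array([[10, 5, 9], [10, 5, 2], [10, 1, 7]], float)
    idx1 = mm.order_grains(cents, np.array([1.0, 0, 0]))
    idx2 = mm.order_grains(cents, np.array([1.0, 0, 0]))
    assert idx1.tolist() == idx2.tolist() == [3, 2, 1]


def test_phantom_order_matches_construction():
    spec = small_grain_spec(seed=13, volume_dims=(120, 64, 64), grain_count=8)
    _, truth = ph.generate_phantom(spec)
    spike = mm.analyze_spike(_bv(truth.label_volume > 0, spec.pixel_size_um))
    # grains sorted by position must ascend in construction z
    cz = [g.centroid[0] for g in spike.grains]
    assert cz == sorted(cz)
    assert [g.position_index for g in spike.grains] == list(range(1, 9))


def test_spike_totals_are_sums():
    spec = small_grain_spec(seed=14, volume_dims=(120, 64, 64), grain_count=8)
    _, truth = ph.generate_phantom(spec)
    spike = mm.analyze_spike(_bv(truth.label_volume > 0, spec.pixel_size_um))
    assert spike.grain_count == len(spike.grains) == 8
    assert spike.total_grain_volume_mm3 == pytest.approx(
        sum(g.volume_mm3 for g in spike.grains))
    assert spike.total_grain_surface_mm2 == pytest.approx(
        sum(g.surface_mm2 for g in spike.grains))


def test_single_grain_spike_length_equals_grain_length():
    m = np.zeros((40, 20, 20))
    m[5:30, 8:13, 8:12] = 1
    spike = mm.analyze_spike(_bv(m, 100.0))
    assert spike.grain_count == 1
    assert spike.spike_length_mm == pytest.approx(spike.grains[0].length_mm)


def test_rotation_robustness_of_traits():
    """Rotating the volume 90 degrees about the spike axis changes traits
    by < 1%."""
    spec = small_grain_spec(seed=15, volume_dims=(120, 64, 64), grain_count=8)
    _, truth = ph.generate_phantom(spec)
    mask = (truth.label_volume > 0).astype(np.uint8)
    s1 = mm.analyze_spike(_bv(mask, spec.pixel_size_um))
    s2 = mm.analyze_spike(_bv(np.rot90(mask, axes=(1, 2)).copy(), spec.pixel_size_um))
    assert s2.grain_count == s1.grain_count
    assert s2.spike_length_mm == pytest.approx(s1.spike_length_mm, rel=0.01)
    assert s2.total_grain_volume_mm3 == pytest.approx(s1.total_grain_volume_mm3,
                                                      rel=0.01)
    assert s2.total_grain_surface_mm2 == pytest.approx(s1.total_grain_surface_mm2,
                                                       rel=0.01)


def test_profile_of_single_spike_is_its_sequence():
    spec = small_grain_spec(seed=16, volume_dims=(120, 64, 64), grain_count=8)
    _, truth = ph.generate_phantom(spec)
    spike = mm.analyze_spike(_bv(truth.label_volume > 0, spec.pixel_size_um))
    prof = mm.positional_profile([spike], "volume_mm3")
    assert prof["position"].tolist() == [g.position_index for g in spike.grains]
    assert prof["mean"].tolist() == pytest.approx(
        [g.volume_mm3 for g in spike.grains])
    assert (prof["n_spikes"] == 1).all()


def test_profile_of_identical_spikes_equals_either():
    spec = small_grain_spec(seed=16, volume_dims=(120, 64, 64), grain_count=8)
    _, truth = ph.generate_phantom(spec)
    spike = mm.analyze_spike(_bv(truth.label_volume > 0, spec.pixel_size_um))
    prof1 = mm.positional_profile([spike], "length_mm")
    prof2 = mm.positional_profile([spike, spike], "length_mm")
    assert prof2["mean"].tolist() == pytest.approx(prof1["mean"].tolist())
    assert (prof2["n_spikes"] == 2).all()


def test_unknown_trait_rejected():
    with pytest.raises(ValueError, match="unknown trait"):
        mm.positional_profile([], "mass_kg")


def test_export_labeled_cloud_writes_ply(tmp_path):
    clusters = [np.argwhere(np.ones((3, 3, 3))).astype(float),
                np.argwhere(np.ones((2, 2, 2))).astype(float) + 20]
    out = mm.export_labeled_cloud(clusters, tmp_path / "c.ply", seed=1)
    assert out.exists() and out.stat().st_size > 0
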