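import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from orchardscan import (
    KdTreeIndex,
    PointCloud,
    RotationSpec,
    kd_range_query,
    radius_outlier_removal,
    transform_coordinates,
    voxel_downsample,
)
from orchardscan.preprocess import inverse_transform_coordinates, statistical_outlier_removal


class TestRotation:
    def test_z_rotation_quarter_turn(self):
        cloud = PointCloud([[1.0, 0.0, 0.0]])
        out = transform_coordinates(cloud, RotationSpec(theta_deg=90, phi_deg=0))
        assert np.allclose(out.points, [[0, 1, 0]], atol=1e-12)

    def test_clockwise_y_quarter_turn_sends_x_to_z(self):
        cloud = PointCloud([[1.0, 0.0, 0.0]])
        out = transform_coordinates(cloud, RotationSpec(theta_deg=0, phi_deg=90))
        assert np.allclose(out.points, [[0, 0, 1]], atol=1e-12)

    def test_counterclockwise_flag_flips_y_convention(self):
        cloud = PointCloud([[1.0, 0.0, 0.0]])
        out = transform_coordinates(
            cloud, RotationSpec(theta_deg=0, phi_deg=90, clockwise_y=False)
        )
        assert np.allclose(out.points, [[0, 0, -1]], atol=1e-12)

    def test_zero_angles_identity(self, random_cloud):
        out = transform_coordinates(random_cloud, RotationSpec(0, 0))
        assert np.allclose(out.points, random_cloud.points, atol=0)

    @settings(max_examples=50, deadline=None)
    @given(theta=st.floats(-360, 360), phi=st.floats(-360, 360))
    def test_matrices_orthonormal_det_one(self, theta, phi):
        m = RotationSpec(theta, phi).matrix()
        assert np.allclose(m.T @ m, np.eye(3), atol=1e-12)
        assert np.isclose(np.linalg.det(m), 1.0, atol=1e-12)

    def test_pairwise_distances_preserved(self, random_cloud):
        out = transform_coordinates(random_cloud, RotationSpec(37.0, 101.5))
        d_in = np.linalg.norm(random_cloud.points[:50, None] - random_cloud.points[None, :50], axis=-1)
        d_out = np.linalg.norm(out.points[:50, None] - out.points[None, :50], axis=-1)
        assert np.max(np.abs(d_in - d_out)) < 1e-9

    def test_inverse_round_trip(self, random_cloud):
        spec = RotationSpec(90, 90)
        back = inverse_transform_coordinates(transform_coordinates(random_cloud, spec), spec)
        assert np.max(np.abs(back.points - random_cloud.points)) <= 1e-9


class TestRadiusOutlierRemoval:
    def test_isolated_point_removed(self, rng):
        dense = rng.normal(0, 1e-4, (50, 3))
        cloud = PointCloud(np.vstack([dense, [[1.0, 0, 0]]]))
        kept, removed = radius_outlier_removal(cloud, min_neighbors=32, radius=0.01)
        assert len(kept) == 50
        assert removed.sum() == 1 and removed[-1]

    def test_small_cloud_entirely_removed(self, rng):
        cloud = PointCloud(rng.uniform(0, 1, (10, 3)))
        kept, removed = radius_outlier_removal(cloud, min_neighbors=32, radius=10.0)
        assert len(kept) == 0 and removed.all()

    def test_neighbor_count_excludes_self(self):
        # two coincident points each have exactly 1 *other* neighbor
        cloud = PointCloud([[0, 0, 0], [0, 0, 0]])
        kept, _ = radius_outlier_removal(cloud, min_neighbors=1, radius=0.1)
        assert len(kept) == 2
        kept, _ = radius_outlier_removal(cloud, min_neighbors=2, radius=0.1)
        assert len(kept) == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 1, (500, 3))
        cloud = PointCloud(pts)
        kept, removed = radius_outlier_removal(cloud, min_neighbors=5, radius=0.1)
        dist = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        counts = (dist <= 0.1).sum(axis=1) - 1  # exclude self
        expected_removed = counts < 5
        assert np.array_equal(removed, expected_removed)
        assert np.array_equal(kept.points, pts[~expected_removed])

    def test_empty_cloud_passes_through(self):
        cloud = PointCloud(np.zeros((0, 3)))
        kept, removed = radius_outlier_removal(cloud)
        assert len(kept) == 0 and removed.shape == (0,)

    def test_decisions_are_simultaneous(self):
        # a chain where sequential removal would cascade but simultaneous
        # evaluation keeps the interior: pairs at spacing 0.09 < radius
        pts = np.array([[0.0, 0, 0], [0.09, 0, 0], [0.18, 0, 0], [0.27, 0, 0]])
        kept, removed = radius_outlier_removal(PointCloud(pts), min_neighbors=2, radius=0.1)
        # ends have 1 neighbor, middles have 2 (on the original cloud)
        assert list(removed) == [True, False, False, True]


class TestVoxelDownsample:
    def test_single_cell_centroid(self):
        pts = np.array([[0.001, 0.001, 0.001], [0.002, 0.003, 0.001],
                        [0.003, 0.002, 0.004], [0.004, 0.004, 0.002]])
        out = voxel_downsample(PointCloud(pts), voxel=0.01)
        assert len(out) == 1
        assert np.allclose(out.points[0], pts.mean(axis=0))

    def test_two_cells(self):
        cloud = PointCloud([[0.005, 0, 0], [0.015, 0, 0]])
        assert len(voxel_downsample(cloud, voxel=0.01)) == 2

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_hashing_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(-1, 1, (1000, 3))
        out = voxel_downsample(PointCloud(pts), voxel=0.05)
        cells = {}
        for p in pts:
            cells.setdefault(tuple(np.floor(p / 0.05).astype(int)), []).append(p)
        assert len(out) == len(cells)
        expected = np.array(sorted(np.mean(v, axis=0).tolist() for v in cells.values()))
        got = np.array(sorted(out.points.tolist()))
        assert np.allclose(got, expected, atol=1e-12)

    def test_output_never_larger(self, random_cloud):
        for voxel in (0.01, 0.1, 1.0, 100.0):
            assert len(voxel_downsample(random_cloud, voxel)) <= len(random_cloud)

    def test_invalid_voxel(self, random_cloud):
        with pytest.raises(ValueError):
            voxel_downsample(random_cloud, 0.0)


class TestStatisticalOutlierRemoval:
    def test_straggler_removed_body_kept(self, rng):
        body = rng.uniform(0, 1, (300, 3))
        cloud = PointCloud(np.vstack([body, [[5.0, 5.0, 5.0]]]))
        kept, removed = statistical_outlier_removal(cloud, k_neighbors=10, std_ratio=2.0)
        assert removed[-1]
        assert removed[:-1].sum() < 30  # body essentially intact


class TestKdRangeQuery:
    def test_unit_cube_corner(self):
        corners = np.array([[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)], float)
        idx = kd_range_query(PointCloud(corners), [0, 0, 0], [0.5, 0.5, 0.5])
        assert list(idx) == [0]

    def test_universal_box(self, random_cloud):
        idx = kd_range_query(random_cloud, [-10] * 3, [10] * 3)
        assert np.array_equal(idx, np.arange(len(random_cloud)))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_linear_scan(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 1, (300, 3))
        lo = rng.uniform(0, 0.5, 3)
        hi = lo + rng.uniform(0.05, 0.5, 3)
        idx = kd_range_query(PointCloud(pts), lo, hi)
        expected = np.flatnonzero(np.all((pts >= lo) & (pts <= hi), axis=1))
        assert np.array_equal(idx, expected)

    def test_degenerate_box_raises(self, random_cloud):
        index = KdTreeIndex(random_cloud)
        with pytest.raises(ValueError, match="degenerate"):
            index.range_query([1, 0, 0], [0, 1, 1])

    def test_boundary_inclusive(self):
        cloud = PointCloud([[0.5, 0.5, 0.5]])
        assert list(kd_range_query(cloud, [0.5, 0.5, 0.5], [0.5, 0.5, 0.5])) == [0]
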