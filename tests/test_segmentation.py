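import numpy as np
import pytest

from orchardscan import (
    LABEL_GROUND,
    LABEL_OUTLIER,
    PointCloud,
    SegmentationError,
    cluster_trees,
    crop_roi,
    dbscan,
    fit_ground_plane,
    remove_ground,
)
from orchardscan.segmentation import dbscan_1d, ground_seed_indices


def brute_force_dbscan(points, eps, min_pts):
    """Independent O(n^2) DBSCAN with the same first-visited-core tie-break."""
    from collections import deque

    points = np.asarray(points, float)
    if points.ndim == 1:
        points = points[:, None]
    n = len(points)
    dist = np.linalg.norm(points[:, None] - points[None, :], axis=-1)
    neighbors = [np.flatnonzero(dist[i] <= eps) for i in range(n)]
    core = np.array([len(nb) >= min_pts for nb in neighbors])
    labels = np.full(n, -1)
    cluster = 0
    for start in range(n):
        if labels[start] != -1 or not core[start]:
            continue
        labels[start] = cluster
        queue = deque([start])
        while queue:
            p = queue.popleft()
            for q in neighbors[p]:
                if labels[q] == -1:
                    labels[q] = cluster
                    if core[q]:
                        queue.append(q)
        cluster += 1
    return labels


class TestGroundPlane:
    def test_horizontal_plane_exact(self, rng):
        ground = np.column_stack([rng.uniform(0, 10, 200), rng.uniform(0, 10, 200), np.zeros(200)])
        canopy = rng.uniform(0, 10, (5, 3)) + [0, 0, 2.0]
        plane = fit_ground_plane(PointCloud(np.vstack([ground, canopy])), 0.02, 500, seed=3)
        assert np.allclose(np.abs(plane.normal), [0, 0, 1], atol=1e-6)
        assert len(plane.inliers) >= 200

    def test_sloped_plane_recovered(self, rng):
        x = rng.uniform(0, 10, 300)
        y = rng.uniform(0, 10, 300)
        pts = np.column_stack([x, y, 0.1 * x])
        plane = fit_ground_plane(PointCloud(pts), 0.02, 500, seed=3)
        expected = np.array([-0.1, 0, 1]) / np.linalg.norm([-0.1, 0, 1])
        assert np.allclose(plane.normal, expected, atol=1e-6)

    def test_too_few_points_raises(self):
        with pytest.raises(SegmentationError):
            fit_ground_plane(PointCloud([[0, 0, 0], [1, 1, 1]]), 0.05, 10, seed=0)

    def test_collinear_points_raise(self):
        pts = np.column_stack([np.arange(10.0), np.zeros(10), np.zeros(10)])
        with pytest.raises(SegmentationError):
            fit_ground_plane(PointCloud(pts), 0.05, 50, seed=0)

    def test_seeded_reproducibility(self, rng):
        pts = rng.uniform(0, 5, (500, 3)) * [1, 1, 0.05]
        a = fit_ground_plane(PointCloud(pts), 0.03, 100, seed=9)
        b = fit_ground_plane(PointCloud(pts), 0.03, 100, seed=9)
        assert np.array_equal(a.normal, b.normal) and a.d == b.d

    def test_inlier_count_monotone_in_threshold(self, rng):
        pts = rng.uniform(0, 5, (500, 3)) * [1, 1, 0.2]
        counts = [
            len(fit_ground_plane(PointCloud(pts), thr, 200, seed=2).inliers)
            for thr in (0.02, 0.05, 0.1, 0.3)
        ]
        assert counts == sorted(counts)


class TestRemoveGround:
    def test_noiseless_orchard_keeps_exactly_tree_points(self, small_orchard):
        _, cloud, _, labels = small_orchard
        plane = fit_ground_plane(
            PointCloud(cloud.points[labels == LABEL_GROUND]), 1e-9, 200, seed=0
        )
        kept = remove_ground(cloud, plane)
        expected = cloud.points[labels >= 0]
        assert len(kept) == len(expected)
        assert np.allclose(np.sort(kept.points, axis=0), np.sort(expected, axis=0))

    def test_all_ground_gives_empty(self, rng):
        pts = np.column_stack([rng.uniform(0, 5, (100, 2)), np.zeros(100)])
        plane = fit_ground_plane(PointCloud(pts), 0.02, 200, seed=0)
        assert len(remove_ground(PointCloud(pts), plane)) == 0

    def test_noisy_orchard_misclassification_below_one_percent(self, noisy_orchard):
        _, cloud, _, labels = noisy_orchard
        plane = fit_ground_plane(
            cloud.select(ground_seed_indices(cloud, 0.5)), 0.05, 500, seed=1
        )
        kept_mask = plane.signed_distance(cloud.points) > plane.threshold
        ground = labels == LABEL_GROUND
        assert (kept_mask & ground).sum() / ground.sum() < 0.01


class TestCropRoi:
    def test_exactly_in_box(self, rng):
        pts = rng.uniform(0, 1, (300, 3))
        out = crop_roi(PointCloud(pts), [0.2, 0.2, 0.2], [0.7, 0.7, 0.7])
        expected = pts[np.all((pts >= 0.2) & (pts <= 0.7), axis=1)]
        assert np.allclose(np.sort(out.points, axis=0), np.sort(expected, axis=0))

    def test_degenerate_box(self, random_cloud):
        with pytest.raises(ValueError):
            crop_roi(random_cloud, [1, 1, 1], [0, 0, 0])


class TestDbscan:
    def test_two_separated_blobs(self, rng):
        a = rng.normal(0, 0.1, (20, 2))
        b = rng.normal(0, 0.1, (20, 2)) + [3.0, 0]
        labels = dbscan(np.vstack([a, b]), eps=0.5, min_pts=4)
        assert set(labels) == {0, 1}
        assert len(set(labels[:20])) == 1 and len(set(labels[20:])) == 1

    def test_isolated_point_is_noise(self, rng):
        pts = np.vstack([rng.normal(0, 0.05, (30, 2)), [[10.0, 10.0]]])
        labels = dbscan(pts, eps=0.5, min_pts=4)
        assert labels[-1] == -1

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 2, (200, 2))
        mine = dbscan(pts, eps=0.2, min_pts=5)
        oracle = brute_force_dbscan(pts, eps=0.2, min_pts=5)
        assert np.array_equal(mine, oracle)

    def test_order_invariance_up_to_relabeling(self, rng):
        pts = rng.uniform(0, 2, (150, 2))
        perm = rng.permutation(len(pts))
        a = dbscan(pts, 0.25, 5)
        b = dbscan(pts[perm], 0.25, 5)[np.argsort(perm)]
        # identical partitions (core tie-breaks may renumber clusters)
        assert np.array_equal(a == -1, b == -1)
        for lab in set(a[a >= 0]):
            members = a == lab
            assert len(set(b[members])) == 1

    def test_sklearn_agrees_on_core_partition(self, rng):
        from sklearn.cluster import DBSCAN as SkDBSCAN

        pts = rng.uniform(0, 2, (300, 2))
        mine = dbscan(pts, 0.2, 5)
        sk = SkDBSCAN(eps=0.2, min_samples=5).fit(pts)
        core = np.zeros(len(pts), bool)
        core[sk.core_sample_indices_] = True
        assert np.array_equal(mine[core] == -1, sk.labels_[core] == -1)
        for lab in set(mine[core]):
            members = core & (mine == lab)
            assert len(set(sk.labels_[members])) == 1


class TestDbscan1d:
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_generic_dbscan_on_scalars(self, seed):
        rng = np.random.default_rng(seed)
        vals = np.concatenate([
            rng.uniform(0, 1, 60), rng.uniform(3, 4, 60), rng.uniform(8, 8.2, 5)
        ])
        fast = dbscan_1d(vals, eps=0.3, min_pts=5)
        ref = brute_force_dbscan(vals, eps=0.3, min_pts=5)
        assert np.array_equal(fast == -1, ref == -1)
        for lab in set(ref[ref >= 0]):
            assert len(set(fast[ref == lab])) == 1

    def test_sparse_bridge_does_not_merge(self):
        left = np.linspace(0, 1, 100)
        right = np.linspace(3, 4, 100)
        bridge = np.array([1.8, 2.2])  # isolated stragglers between groups
        labels = dbscan_1d(np.concatenate([left, right, bridge]), eps=0.5, min_pts=5)
        assert labels[0] != labels[150]
        assert set(labels[-2:]) == {-1}


class TestGroundSeeds:
    def test_seeds_are_per_cell_minima(self, rng):
        pts = rng.uniform(0, 2, (500, 3))
        idx = ground_seed_indices(PointCloud(pts), cell=0.5)
        cells = np.floor(pts[:, :2] / 0.5).astype(int)
        for i in idx:
            same = np.all(cells == cells[i], axis=1)
            assert pts[i, 2] == pts[same, 2].min()


class TestClusterTrees:
    def test_noiseless_2x3_matches_generator_labels(self, small_orchard):
        _, cloud, truth, labels = small_orchard
        canopy = cloud.select(labels >= 0)
        true_tree = labels[labels >= 0]
        result = cluster_trees(canopy, eps=0.4, min_pts=10)
        assert result.n_clusters == 6
        assert sorted(result.tree_of_cluster.values()) == sorted(
            t.tree_id for t in truth.trees
        )
        # every cluster maps one-to-one onto a generating tree
        for lab, tid in result.tree_of_cluster.items():
            members = result.labels == lab
            gen = np.bincount(true_tree[members]).argmax()
            rec = truth.trees[gen]
            assert rec.tree_id == tid

    def test_single_tree(self, rng):
        pts = rng.normal(0, 0.3, (500, 3)) + [0, 0, 2]
        result = cluster_trees(PointCloud(pts), eps=0.4, min_pts=10)
        assert result.n_clusters == 1
        assert list(result.row_of_cluster.values()) == [0]

    def test_noisy_orchard_assignment_accuracy(self, noisy_orchard):
        _, cloud, truth, labels = noisy_orchard
        canopy = cloud.select(labels >= 0)
        true_tree = labels[labels >= 0]
        result = cluster_trees(canopy, eps=0.4, min_pts=10)
        assert result.n_clusters == 12
        # map each cluster to its majority generating tree, then score
        correct = 0
        for lab in result.tree_of_cluster:
            members = result.labels == lab
            majority = np.bincount(true_tree[members]).argmax()
            correct += (true_tree[members] == majority).sum()
        assert correct / len(true_tree) >= 0.95

    def test_empty_failure_is_informative(self, rng):
        sparse = PointCloud(rng.uniform(0, 100, (30, 3)))
        with pytest.raises(SegmentationError, match="eps"):
            cluster_trees(sparse, eps=0.01, min_pts=10)
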