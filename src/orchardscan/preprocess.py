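"""Coordinate correction and point-cloud cleaning.

The sensor is operated with its scan frame rotated relative to the
orchard frame (X along rows, Y across rows, Z up), so raw clouds are
reoriented by a two-phase rotation: counterclockwise about Z by theta,
then about Y by phi using the clockwise sign convention (−sin phi in the
first row of the Y matrix). Cleaning is radius outlier removal (drop
points with too few neighbors inside a ball) followed by voxel-grid
downsampling (one centroid per occupied cube).

The default filter parameters (32 neighbors within 0.01 m; 0.01 m
voxels) are calibrated for dense field scans from a ~300k points/s
sensor; sparser clouds need proportionally looser values, which every
entry point exposes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .cloud import PointCloud


@dataclass(frozen=True)
class RotationSpec:
    """Two-phase reorientation: Z by ``theta_deg`` CCW, then Y by ``phi_deg``.

    ``clockwise_y=True`` uses the sign convention with −sin(phi) in the
    first row of the Y matrix (a clockwise rotation when looking along
    +Y); False gives the standard counterclockwise convention.
    """

    theta_deg: float = 90.0
    phi_deg: float = 90.0
    clockwise_y: bool = True

    def rz(self) -> np.ndarray:
        t = np.deg2rad(self.theta_deg)
        c, s = np.cos(t), np.sin(t)
        return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])

    def ry(self) -> np.ndarray:
        p = np.deg2rad(self.phi_deg)
        c, s = np.cos(p), np.sin(p)
        if self.clockwise_y:
            return np.array([[c, 0.0, -s], [0.0, 1.0, 0.0], [s, 0.0, c]])
        return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])

    def matrix(self) -> np.ndarray:
        """Combined rotation applied to column vectors: Ry @ Rz."""
        return self.ry() @ self.rz()


def transform_coordinates(cloud: PointCloud, spec: RotationSpec) -> PointCloud:
    """Apply the two-phase rotation to every point; lengths are preserved."""
    cloud.require_nonempty("transform_coordinates")
    rotated = cloud.points @ spec.matrix().T
    return PointCloud(rotated, intensity=cloud.intensity, frame_id=cloud.frame_id)


def inverse_transform_coordinates(cloud: PointCloud, spec: RotationSpec) -> PointCloud:
    """Exact inverse of :func:`transform_coordinates` (rotation transpose)."""
    cloud.require_nonempty("inverse_transform_coordinates")
    rotated = cloud.points @ spec.matrix()
    return PointCloud(rotated, intensity=cloud.intensity, frame_id=cloud.frame_id)


def radius_outlier_removal(
    cloud: PointCloud, min_neighbors: int = 32, radius: float = 0.01
) -> tuple[PointCloud, np.ndarray]:
    """Drop points with fewer than ``min_neighbors`` other points within ``radius``.

    Decisions are simultaneous: neighbor counts are computed on the
    original cloud, never on a partially filtered one, so the result is
    independent of point order. The query point itself is not counted as
    its own neighbor. Returns (filtered cloud, boolean removed-mask).
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    if min_neighbors < 1:
        raise ValueError("min_neighbors must be >= 1")
    n = len(cloud)
    if n == 0:
        return cloud, np.zeros(0, dtype=bool)
    tree = cKDTree(cloud.points)
    # counts include the point itself, hence the +1 in the threshold
    counts = tree.query_ball_point(cloud.points, r=radius, return_length=True)
    removed = counts < min_neighbors + 1
    return cloud.select(~removed), removed


def statistical_outlier_removal(
    cloud: PointCloud, k_neighbors: int = 20, std_ratio: float = 2.0
) -> tuple[PointCloud, np.ndarray]:
    """Drop points whose mean distance to their k nearest neighbors is anomalous.

    A point is removed when its mean k-NN distance exceeds the cloud-wide
    mean by more than ``std_ratio`` standard deviations. Complements the
    radius filter on sparse clouds where near-surface stragglers keep
    just enough neighbors to pass it. Off by default in the pipeline.
    """
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    n = len(cloud)
    if n <= k_neighbors:
        return cloud, np.zeros(n, dtype=bool)
    tree = cKDTree(cloud.points)
    dists, _ = tree.query(cloud.points, k=k_neighbors + 1)
    mean_d = dists[:, 1:].mean(axis=1)  # skip self at distance 0
    cutoff = mean_d.mean() + std_ratio * mean_d.std()
    removed = mean_d > cutoff
    return cloud.select(~removed), removed


def voxel_downsample(cloud: PointCloud, voxel: float = 0.01) -> PointCloud:
    """Replace the points of each occupied voxel with their centroid.

    The grid is axis-aligned with edge length ``voxel`` and anchored at
    the coordinate origin. Output order follows lexicographic voxel index.
    """
    if voxel <= 0:
        raise ValueError("voxel must be > 0")
    if len(cloud) == 0:
        return cloud
    idx = np.floor(cloud.points / voxel).astype(np.int64)
    _, inverse, counts = np.unique(idx, axis=0, return_inverse=True, return_counts=True)
    sums = np.zeros((len(counts), 3))
    np.add.at(sums, inverse, cloud.points)
    centroids = sums / counts[:, None]
    return PointCloud(centroids, frame_id=cloud.frame_id)


class KdTreeIndex:
    """Spatial index for axis-aligned range queries over a fixed cloud.

    Backed by a balanced k-d partition (split axes cycling X, Y, Z);
    queries return exactly the indices inside the closed box.
    """

    def __init__(self, cloud: PointCloud, leafsize: int = 16):
        self._points = cloud.points
        self._tree = cKDTree(self._points, leafsize=leafsize, balanced_tree=True)

    def range_query(self, lo, hi) -> np.ndarray:
        """Indices of points with lo <= p <= hi on every axis (sorted)."""
        lo = np.asarray(lo, dtype=float)
        hi = np.asarray(hi, dtype=float)
        if lo.shape != (3,) or hi.shape != (3,):
            raise ValueError("box corners must be 3-vectors")
        if np.any(lo > hi):
            raise ValueError(f"degenerate box: min {lo} exceeds max {hi}")
        center = (lo + hi) / 2.0
        # Chebyshev ball of the half-extent max = circumscribing box; then exact filter
        r = float(np.max((hi - lo) / 2.0))
        candidates = np.asarray(self._tree.query_ball_point(center, r=r, p=np.inf), dtype=np.int64)
        if candidates.size == 0:
            return candidates
        pts = self._points[candidates]
        inside = np.all((pts >= lo) & (pts <= hi), axis=1)
        return np.sort(candidates[inside])


def kd_range_query(cloud: PointCloud, lo, hi) -> np.ndarray:
    """One-shot axis-aligned range query (builds a transient index)."""
    return KdTreeIndex(cloud).range_query(lo, hi)
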