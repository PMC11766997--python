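"""Ground-plane removal and clustering of the cloud into rows and trees.

The ground is fit with RANSAC (3-point candidate planes, inlier count at
a distance threshold, least-squares refit on the winning inlier set) and
removed by keeping only points above it. Individual trees are then found
by density clustering in the x-y plane: a first pass on y separates the
rows, a second pass inside each row separates the trees.

DBSCAN is implemented here with a fixed, documented tie-break — a border
point reachable from several clusters joins the cluster whose core point
visits it first, with visitation order fixed by sorted point index — so
that results are exactly reproducible and order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .cloud import PointCloud
from .preprocess import KdTreeIndex


class SegmentationError(RuntimeError):
    pass


@dataclass
class PlaneModel:
    """Plane a*x + b*y + c*z + d = 0 with unit normal (a, b, c)."""

    normal: np.ndarray
    d: float
    threshold: float
    inliers: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return points @ self.normal + self.d


def _plane_from_three(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray):
    n = np.cross(p1 - p0, p2 - p0)
    norm = np.linalg.norm(n)
    if norm < 1e-12:
        return None
    n = n / norm
    return n, -float(n @ p0)


def _lsq_plane(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Total-least-squares plane through a point set (smallest SVD direction)."""
    centroid = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - centroid, full_matrices=False)
    normal = vt[-1]
    return normal, -float(normal @ centroid)


def fit_ground_plane(
    cloud: PointCloud,
    dist_threshold: float = 0.05,
    n_iterations: int = 1000,
    seed: int | None = 0,
) -> PlaneModel:
    """RANSAC plane fit; the returned normal points toward +Z.

    Draws ``n_iterations`` random 3-point candidate planes, keeps the one
    with the most points within ``dist_threshold``, then refits by total
    least squares on that inlier set and recomputes the inliers.
    """
    pts = cloud.points
    if len(pts) < 3:
        raise SegmentationError("plane fit needs at least 3 points")
    rng = np.random.default_rng(seed)
    best_count = -1
    best = None
    for _ in range(n_iterations):
        i, j, k = rng.choice(len(pts), size=3, replace=False)
        cand = _plane_from_three(pts[i], pts[j], pts[k])
        if cand is None:
            continue
        normal, d = cand
        count = int(np.count_nonzero(np.abs(pts @ normal + d) <= dist_threshold))
        if count > best_count:
            best_count = count
            best = (normal, d)
    if best is None:
        raise SegmentationError("all RANSAC samples were collinear; degenerate cloud")
    normal, d = best
    inliers = np.flatnonzero(np.abs(pts @ normal + d) <= dist_threshold)
    if len(inliers) >= 3:
        normal, d = _lsq_plane(pts[inliers])
        inliers = np.flatnonzero(np.abs(pts @ normal + d) <= dist_threshold)
    if normal[2] < 0:  # orient upward so "above the plane" is unambiguous
        normal, d = -normal, -d
    return PlaneModel(normal=normal, d=d, threshold=dist_threshold, inliers=inliers)


def ground_seed_indices(cloud: PointCloud, cell: float = 0.5) -> np.ndarray:
    """Indices of the lowest point in each x-y grid cell.

    Wherever the ground is visible at all, the per-cell minimum is a
    ground return, so these seeds give RANSAC a candidate set dominated
    by ground even when ground points are a small minority of the scene.
    """
    if cell <= 0:
        raise ValueError("cell must be > 0")
    cloud.require_nonempty("ground_seed_indices")
    keys = np.floor(cloud.points[:, :2] / cell).astype(np.int64)
    order = np.lexsort((cloud.z, keys[:, 1], keys[:, 0]))
    sorted_keys = keys[order]
    first = np.ones(len(order), dtype=bool)
    first[1:] = np.any(np.diff(sorted_keys, axis=0) != 0, axis=1)
    return np.sort(order[first])


def remove_ground(cloud: PointCloud, plane: PlaneModel) -> PointCloud:
    """Keep points strictly above the plane by more than its threshold."""
    keep = plane.signed_distance(cloud.points) > plane.threshold
    return cloud.select(keep)


def crop_roi(cloud: PointCloud, lo, hi) -> PointCloud:
    """Axis-aligned region-of-interest crop via the k-d index."""
    idx = KdTreeIndex(cloud).range_query(lo, hi)
    return cloud.select(idx)


@dataclass
class ClusterLabels:
    """Per-point integer labels; −1 is noise."""

    labels: np.ndarray
    tree_of_cluster: dict[int, str] = field(default_factory=dict)
    row_of_cluster: dict[int, int] = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return int(len(set(self.labels[self.labels >= 0])))


def dbscan(points: np.ndarray, eps: float, min_pts: int) -> np.ndarray:
    """Density-based clustering; returns labels with −1 = noise.

    A core point has at least ``min_pts`` points (itself included) within
    ``eps``. Clusters are grown breadth-first from the lowest-index
    unvisited core point, so border points always join the first cluster
    that reaches them and labels do not depend on input order beyond the
    stable index sort applied internally.
    """
    if eps <= 0:
        raise ValueError("eps must be > 0")
    if min_pts < 1:
        raise ValueError("min_pts must be >= 1")
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    n = len(points)
    labels = np.full(n, -1, dtype=np.int64)
    if n == 0:
        return labels
    tree = cKDTree(points)
    counts = tree.query_ball_point(points, r=eps, return_length=True)
    core = counts >= min_pts
    core_idx = np.flatnonzero(core)
    if len(core_idx) == 0:
        return labels
    # clusters are the connected components of the core points; a border
    # point joins the earliest-grown cluster among its core neighbors, which
    # is exactly what breadth-first growth from the lowest-index unvisited
    # core point produces
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components
    from sklearn.neighbors import NearestNeighbors

    core_tree = cKDTree(points[core_idx])
    pairs = core_tree.query_pairs(r=eps, output_type="ndarray")
    m = len(core_idx)
    graph = coo_matrix(
        (np.ones(len(pairs), dtype=np.int8), (pairs[:, 0], pairs[:, 1])), shape=(m, m)
    ).tocsr()
    # the pair graph is upper-triangular; weak connectivity treats it as undirected
    _, comp = connected_components(graph, directed=True, connection="weak")
    # renumber components in order of their lowest core index
    _, first = np.unique(comp, return_index=True)
    renumber = np.empty(comp.max() + 1, dtype=np.int64)
    renumber[comp[np.sort(first)]] = np.arange(len(first))
    core_labels = renumber[comp]
    labels[core_idx] = core_labels
    non_core = np.flatnonzero(~core)
    if len(non_core):
        nn = NearestNeighbors(radius=eps).fit(points[core_idx])
        neighborhoods = nn.radius_neighbors(points[non_core], return_distance=False)
        for i, nb in zip(non_core, neighborhoods):
            if len(nb):
                labels[i] = core_labels[nb].min()
    return labels


def _dbscan_xy_deduplicated(xy: np.ndarray, eps: float, min_pts: int) -> np.ndarray:
    """Tree-scale DBSCAN on the x-y projection via grid deduplication.

    Points are snapped to an eps/4 grid and clustering runs on the
    occupied cells, so memory stays bounded no matter how dense the
    cloud is; labels are broadcast back to the points. At tree scale a
    genuine canopy region occupies far more cells than ``min_pts``, so
    the cell-level core test matches the point-level one.
    """
    cell = eps / 4.0
    keys = np.floor(xy / cell).astype(np.int64)
    uniq, inverse = np.unique(keys, axis=0, return_inverse=True)
    centers = (uniq + 0.5) * cell
    cell_labels = dbscan(centers, eps=eps, min_pts=min(min_pts, max(1, len(uniq))))
    return cell_labels[inverse]


def cluster_trees(
    cloud: PointCloud,
    eps: float = 0.4,
    min_pts: int = 10,
    row_eps: float | None = None,
    strategy: str = "rows-then-trees",
) -> ClusterLabels:
    """Group a ground-free cloud into rows and individual trees.

    ``rows-then-trees`` (default) first runs 1-D density clustering on
    the y-coordinate alone to find rows (``row_eps`` defaults to
    ``eps``; keep it below half the clear gap between rows so isolated
    stragglers between rows cannot become core points), then clusters
    x-y within each row at tree scale. ``single-pass`` clusters x-y
    once. Trees are numbered by increasing centroid x within each row;
    rows by increasing centroid y.
    """
    cloud.require_nonempty("cluster_trees")
    xy = cloud.points[:, :2]
    labels = np.full(len(cloud), -1, dtype=np.int64)
    row_of: dict[int, int] = {}
    if strategy == "single-pass":
        flat = _dbscan_xy_deduplicated(xy, eps=eps, min_pts=min_pts)
        clusters = _order_clusters(xy, flat)
        for new, old in enumerate(clusters):
            labels[flat == old] = new
            row_of[new] = 0
    elif strategy == "rows-then-trees":
        row_eps = eps if row_eps is None else row_eps
        row_labels = dbscan_1d(cloud.points[:, 1], eps=row_eps, min_pts=min_pts)
        row_ids = sorted(
            set(row_labels[row_labels >= 0]),
            key=lambda r: cloud.points[row_labels == r, 1].mean(),
        )
        next_label = 0
        for row_idx, row in enumerate(row_ids):
            members = np.flatnonzero(row_labels == row)
            sub = _dbscan_xy_deduplicated(xy[members], eps=eps, min_pts=min_pts)
            for old in _order_clusters(xy[members], sub):
                labels[members[sub == old]] = next_label
                row_of[next_label] = row_idx
                next_label += 1
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    if not row_of:
        raise SegmentationError(
            "no clusters found; check eps/min_pts against the cloud density "
            f"(n={len(cloud)}, eps={eps}, min_pts={min_pts})"
        )
    tree_of = {}
    counters: dict[int, int] = {}
    for lab in sorted(row_of):
        r = row_of[lab]
        counters[r] = counters.get(r, 0) + 1
        tree_of[lab] = f"R{r + 1}T{counters[r]}"
    return ClusterLabels(labels=labels, tree_of_cluster=tree_of, row_of_cluster=row_of)


def dbscan_1d(values: np.ndarray, eps: float, min_pts: int) -> np.ndarray:
    """Exact DBSCAN on scalars in O(n log n) via sorting.

    Core points (≥ ``min_pts`` within ±eps, self included) chain into
    clusters when consecutive core values are within eps; non-core
    points join the cluster of the nearest core value within eps, else
    are noise. Sparse stragglers between two dense groups cannot bridge
    them, unlike a plain single-linkage gap cut.
    """
    values = np.asarray(values, dtype=float).ravel()
    n = len(values)
    labels = np.full(n, -1, dtype=np.int64)
    if n == 0:
        return labels
    order = np.argsort(values, kind="stable")
    v = values[order]
    counts = np.searchsorted(v, v + eps, side="right") - np.searchsorted(v, v - eps, side="left")
    core = counts >= min_pts
    core_pos = np.flatnonzero(core)
    if len(core_pos) == 0:
        return labels
    core_vals = v[core_pos]
    # new cluster whenever the gap between consecutive core values exceeds eps
    cluster_of_core = np.concatenate([[0], np.cumsum(np.diff(core_vals) > eps)])
    sorted_labels = np.full(n, -1, dtype=np.int64)
    sorted_labels[core_pos] = cluster_of_core
    non_core = np.flatnonzero(~core)
    if len(non_core) > 0:
        nearest = np.clip(np.searchsorted(core_vals, v[non_core]), 0, len(core_vals) - 1)
        prev = np.clip(nearest - 1, 0, len(core_vals) - 1)
        d_next = np.abs(core_vals[nearest] - v[non_core])
        d_prev = np.abs(core_vals[prev] - v[non_core])
        best = np.where(d_prev <= d_next, prev, nearest)
        dist = np.minimum(d_prev, d_next)
        reachable = dist <= eps
        sorted_labels[non_core[reachable]] = cluster_of_core[best[reachable]]
    labels[order] = sorted_labels
    return labels


def _order_clusters(xy: np.ndarray, labels: np.ndarray) -> list[int]:
    ids = sorted(set(labels[labels >= 0]))
    return sorted(ids, key=lambda c: xy[labels == c, 0].mean())
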