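"""Geometric feature extraction for individual trees.

Tree height is the z-range of the tree's cloud, Htree = Hmax − Hmin,
with Hmin normally a near-ground return at the base of the trunk.
Sensor canopy volume is the axis-aligned bounding box of the canopy
points, optionally with the cross-row (y) extent replaced by a
field-measured width, since a single-sided scan under-represents canopy
depth across the row. The manual comparator models the crown as an
ellipsoid from two perpendicular viewing positions:

    CV_m = (pi/6) * D1 * D2 * [(Ht1 − Hs1) + (Ht2 − Hs2)] / 2

where D1, D2 are crown diameters and Ht/Hs are canopy top/base heights
from each position (both terms treated symmetrically as canopy vertical
extents). Tree spacing and row spacing are planar (x-y) center-to-center
distances between consecutive cluster centroids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .cloud import PointCloud
from .segmentation import ClusterLabels


@dataclass
class BoundingBox:
    lo: np.ndarray
    hi: np.ndarray

    @property
    def extents(self) -> np.ndarray:
        return self.hi - self.lo

    @property
    def volume(self) -> float:
        return float(np.prod(self.extents))


@dataclass
class TreeMetrics:
    tree_id: str
    row_index: int
    h_max: float
    h_min: float
    height: float
    bbox: BoundingBox
    canopy_volume: float
    width_adjusted: bool
    centroid: np.ndarray
    n_points: int


@dataclass
class SpacingResult:
    """Consecutive center-to-center distances, per row and between rows."""

    tree_spacings: dict[int, np.ndarray]  # row index -> distances along the row
    row_spacings: np.ndarray              # consecutive row-centroid distances

    @property
    def all_tree_spacings(self) -> np.ndarray:
        if not self.tree_spacings:
            return np.zeros(0)
        return np.concatenate([self.tree_spacings[r] for r in sorted(self.tree_spacings)])


def tree_height(cloud: PointCloud) -> tuple[float, float, float]:
    """(Hmax, Hmin, Htree) with Htree = Hmax − Hmin."""
    cloud.require_nonempty("tree_height")
    h_max = float(cloud.z.max())
    h_min = float(cloud.z.min())
    return h_max, h_min, h_max - h_min


def bounding_box(cloud: PointCloud) -> BoundingBox:
    cloud.require_nonempty("bounding_box")
    box = BoundingBox(lo=cloud.points.min(axis=0), hi=cloud.points.max(axis=0))
    if np.any(box.extents == 0):
        warnings.warn("bounding box is flat (zero extent on some axis)", stacklevel=2)
    return box


def canopy_volume_bbox(
    cloud: PointCloud, measured_width: float | None = None
) -> tuple[float, bool]:
    """Bounding-box canopy volume; y-extent replaced by ``measured_width``.

    The replacement compensates for single-side scans that see only part
    of the cross-row canopy depth.
    """
    cloud.require_nonempty("canopy_volume_bbox")
    if measured_width is not None and measured_width <= 0:
        raise ValueError("measured_width must be > 0")
    box = bounding_box(cloud)
    ex, ey, ez = box.extents
    if measured_width is not None:
        ey = measured_width
    return float(ex * ey * ez), measured_width is not None


def manual_canopy_volume(
    d1: float, d2: float, ht1: float, hs1: float, ht2: float, hs2: float
) -> float:
    """Ellipsoid manual canopy volume from two-position field measurements."""
    if d1 < 0 or d2 < 0:
        raise ValueError("crown diameters must be >= 0")
    if ht1 < hs1 or ht2 < hs2:
        raise ValueError("canopy top must not be below canopy base (Ht >= Hs)")
    return (np.pi / 6.0) * d1 * d2 * 0.5 * ((ht1 - hs1) + (ht2 - hs2))


def centroid(points: np.ndarray) -> np.ndarray:
    """Arithmetic mean position of a point set."""
    points = np.asarray(points, dtype=float)
    if points.size == 0:
        raise ValueError("centroid of an empty point set is undefined")
    return points.mean(axis=0)


def spacing(
    tree_centroids: dict[int, list[np.ndarray]], mode: str = "row-centroid"
) -> SpacingResult:
    """Spacings from per-row ordered tree centroids (planar x-y distances).

    ``tree_centroids`` maps row index to centroids ordered along the row.
    Row spacing modes: ``row-centroid`` (default) measures between row
    mean centroids; ``tree-to-tree`` averages distances between opposite
    trees of consecutive rows, pairing by position in row.
    """
    if not tree_centroids:
        raise ValueError("spacing requires at least one row of centroids")
    tree_sp: dict[int, np.ndarray] = {}
    for row, cents in tree_centroids.items():
        c = np.asarray(cents, dtype=float)[:, :2]
        tree_sp[row] = np.linalg.norm(np.diff(c, axis=0), axis=1) if len(c) >= 2 else np.zeros(0)
    rows = sorted(tree_centroids)
    row_cents = [np.asarray(tree_centroids[r], dtype=float)[:, :2].mean(axis=0) for r in rows]
    if len(rows) < 2:
        row_sp = np.zeros(0)
    elif mode == "row-centroid":
        row_sp = np.linalg.norm(np.diff(np.asarray(row_cents), axis=0), axis=1)
    elif mode == "tree-to-tree":
        row_sp = []
        for a, b in zip(rows[:-1], rows[1:]):
            ca = np.asarray(tree_centroids[a], dtype=float)[:, :2]
            cb = np.asarray(tree_centroids[b], dtype=float)[:, :2]
            m = min(len(ca), len(cb))
            row_sp.append(np.linalg.norm(ca[:m] - cb[:m], axis=1).mean())
        row_sp = np.asarray(row_sp)
    else:
        raise ValueError(f"unknown row-spacing mode {mode!r}")
    return SpacingResult(tree_spacings=tree_sp, row_spacings=row_sp)


def _trim_vertical_stragglers(z: np.ndarray, max_gap: float) -> np.ndarray:
    """Keep-mask dropping points split from the main body by a z-gap > max_gap.

    Scans the sorted z-profile outward from the median; everything past
    the first oversized gap (above or below) is considered an erroneous
    return rather than canopy.
    """
    order = np.argsort(z, kind="stable")
    gaps = np.diff(z[order])
    med = len(z) // 2
    keep_sorted = np.ones(len(z), dtype=bool)
    above = np.flatnonzero(gaps[med:] > max_gap)
    if len(above):
        keep_sorted[med + above[0] + 1 :] = False
    below = np.flatnonzero(gaps[:med] > max_gap)
    if len(below):
        keep_sorted[: below[-1] + 1] = False
    keep = np.empty(len(z), dtype=bool)
    keep[order] = keep_sorted
    return keep


def _trim_unsupported_top(points: np.ndarray, min_support: int, radius: float) -> np.ndarray:
    """Keep-mask dropping apex returns not corroborated by nearby returns.

    Walking down from the highest point, a candidate apex is accepted
    only when at least ``min_support`` other points lie within
    ``radius`` of it; uncorroborated single returns floating above the
    canopy are erroneous points, not the tree top.
    """
    from scipy.spatial import cKDTree

    keep = np.ones(len(points), dtype=bool)
    tree = cKDTree(points)
    order = np.argsort(points[:, 2])[::-1]
    for idx in order[: max(20, min_support + 1)]:
        n_near = tree.query_ball_point(points[idx], r=radius, return_length=True) - 1
        if n_near >= min_support:
            break
        keep[idx] = False
    return keep


def measure_trees(
    full_cloud: PointCloud,
    canopy_cloud: PointCloud,
    clusters: ClusterLabels,
    canopy_floor: float = 0.3,
    measured_widths: dict[str, float] | None = None,
    footprint_margin: float = 0.1,
    max_z_gap: float | None = None,
    min_top_support: int = 0,
    top_support_radius: float = 0.12,
) -> list[TreeMetrics]:
    """Per-tree height, bounding box, canopy volume and centroid.

    ``canopy_cloud`` is the ground-free cloud the cluster labels refer
    to. Hmax is the top of the tree's own cluster; Hmin comes from
    ``full_cloud`` (ground returns included) restricted to the tree's
    x-y footprint grown by ``footprint_margin``, so it reflects the true
    near-ground base. The canopy bounding box excludes points below
    ``canopy_floor`` above the tree's own base.
    """
    if len(canopy_cloud) != len(clusters.labels):
        raise ValueError("cluster labels do not match the canopy cloud")
    measured_widths = measured_widths or {}
    out: list[TreeMetrics] = []
    for lab in sorted(clusters.tree_of_cluster):
        tree_id = clusters.tree_of_cluster[lab]
        sub = canopy_cloud.select(clusters.labels == lab)
        if max_z_gap is not None and len(sub) > 2:
            sub = sub.select(_trim_vertical_stragglers(sub.z, max_z_gap))
        if min_top_support > 0 and len(sub) > min_top_support:
            sub = sub.select(
                _trim_unsupported_top(sub.points, min_top_support, top_support_radius)
            )
        lo = sub.points[:, :2].min(axis=0) - footprint_margin
        hi = sub.points[:, :2].max(axis=0) + footprint_margin
        in_fp = np.all((full_cloud.points[:, :2] >= lo) & (full_cloud.points[:, :2] <= hi), axis=1)
        column = full_cloud.select(in_fp) if in_fp.any() else sub
        h_max = float(sub.z.max())
        h_min = min(float(column.z.min()), float(sub.z.min()))
        height = h_max - h_min
        canopy = sub.select(sub.z >= h_min + canopy_floor)
        if len(canopy) == 0:
            canopy = sub
        vol, adjusted = canopy_volume_bbox(canopy, measured_widths.get(tree_id))
        out.append(
            TreeMetrics(
                tree_id=tree_id,
                row_index=clusters.row_of_cluster[lab],
                h_max=h_max, h_min=h_min, height=height,
                bbox=bounding_box(canopy),
                canopy_volume=vol, width_adjusted=adjusted,
                centroid=centroid(sub.points),
                n_points=len(sub),
            )
        )
    return out


def spacing_from_metrics(metrics: list[TreeMetrics], mode: str = "row-centroid") -> SpacingResult:
    """Spacings from measured tree centroids grouped by row, ordered by x."""
    rows: dict[int, list[np.ndarray]] = {}
    for m in sorted(metrics, key=lambda m: (m.row_index, m.centroid[0])):
        rows.setdefault(m.row_index, []).append(m.centroid)
    return spacing(rows, mode=mode)
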