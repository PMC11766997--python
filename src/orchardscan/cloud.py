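"""Core in-memory containers for the pipeline.

Every stage of the pipeline consumes and produces a :class:`PointCloud`
holding Cartesian coordinates in meters, following the right-handed
convention used throughout: X along tree rows, Y across rows, Z up.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class EmptyCloudError(ValueError):
    """Raised when an operation requires a non-empty point cloud."""


class ValidationError(ValueError):
    """Raised when a record violates a domain invariant."""


@dataclass
class PointCloud:
    """A set of 3D points in meters, optionally with per-point intensity.

    Parameters
    ----------
    points
        Array of shape (n, 3), float64; columns are x, y, z in meters.
    intensity
        Optional per-point scalar, shape (n,).
    frame_id
        Optional acquisition-frame tag.
    """

    points: np.ndarray
    intensity: np.ndarray | None = None
    frame_id: str | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.size == 0:
            pts = pts.reshape(0, 3)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValidationError(f"points must have shape (n, 3), got {pts.shape}")
        if not np.all(np.isfinite(pts)):
            raise ValidationError("point coordinates must be finite")
        self.points = pts
        if self.intensity is not None:
            inten = np.asarray(self.intensity, dtype=np.float64)
            if inten.shape != (len(pts),):
                raise ValidationError("intensity length must match point count")
            self.intensity = inten

    def __len__(self) -> int:
        return len(self.points)

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.points[:, 2]

    def select(self, index: np.ndarray) -> "PointCloud":
        """Sub-cloud at a boolean mask or integer index array."""
        inten = self.intensity[index] if self.intensity is not None else None
        return PointCloud(self.points[index], intensity=inten, frame_id=self.frame_id)

    def require_nonempty(self, op: str = "operation") -> None:
        if len(self) == 0:
            raise EmptyCloudError(f"{op} requires a non-empty point cloud")


@dataclass
class TreeRecord:
    """Manual measurements for one tree.

    Ht/Hs pairs are the canopy top and canopy base heights read off a
    measuring post from two perpendicular viewing positions; D1/D2 are
    the crown diameters along the two directions.
    """

    tree_id: str
    measured_height: float
    d1: float
    d2: float
    ht1: float
    hs1: float
    ht2: float
    hs2: float
    row_index: int = 0
    position_in_row: int = 0

    def validate(self) -> None:
        if self.d1 < 0 or self.d2 < 0:
            raise ValidationError(f"tree {self.tree_id}: crown diameters must be >= 0")
        if not (self.ht1 >= self.hs1 >= 0):
            raise ValidationError(
                f"tree {self.tree_id}: requires Ht1 >= Hs1 >= 0 "
                f"(got Ht1={self.ht1}, Hs1={self.hs1})"
            )
        if not (self.ht2 >= self.hs2 >= 0):
            raise ValidationError(
                f"tree {self.tree_id}: requires Ht2 >= Hs2 >= 0 "
                f"(got Ht2={self.ht2}, Hs2={self.hs2})"
            )
        if self.measured_height < 0:
            raise ValidationError(f"tree {self.tree_id}: height must be >= 0")


@dataclass
class OrchardGroundTruth:
    """Per-tree manual measurements plus the planted orchard layout."""

    trees: list[TreeRecord]
    tree_spacing: float
    row_spacing: float
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.tree_spacing <= 0 or self.row_spacing <= 0:
            raise ValidationError("planted spacings must be > 0")
        ids = [t.tree_id for t in self.trees]
        if len(set(ids)) != len(ids):
            raise ValidationError("tree_id values must be unique")
        for t in self.trees:
            t.validate()

    def __len__(self) -> int:
        return len(self.trees)

    def tree(self, tree_id: str) -> TreeRecord:
        for t in self.trees:
            if t.tree_id == tree_id:
                return t
        raise KeyError(tree_id)
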