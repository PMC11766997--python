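"""Point-cloud and ground-truth file IO.

Supported cloud formats are the simple ASCII dialects that survive a
text-only toolchain: ASCII PCD, ASCII PLY and plain XYZ/CSV. Coordinates
are meters and are held as float64 in memory regardless of file precision.

Ground truth is a CSV with one row per tree; the schema is this
package's own (see README) since field protocols rarely fix one:

    tree_id,measured_height,D1,D2,Ht1,Hs1,Ht2,Hs2,row_index,position_in_row

plus a header-comment or sidecar-free convention for the planted layout:
``tree_spacing`` and ``row_spacing`` are passed as columns (constant per
orchard) or explicitly to :func:`read_ground_truth`.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .cloud import EmptyCloudError, OrchardGroundTruth, PointCloud, TreeRecord, ValidationError

logger = logging.getLogger(__name__)

FORMATS = ("pcd", "ply", "xyz-csv")


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".pcd":
        return "pcd"
    if suffix == ".ply":
        return "ply"
    if suffix in (".csv", ".xyz", ".txt"):
        return "xyz-csv"
    raise ValueError(f"cannot infer point-cloud format from suffix {suffix!r}")


def read_point_cloud(path: str | Path, fmt: str | None = None) -> PointCloud:
    """Read a point cloud from an ASCII PCD, ASCII PLY or XYZ/CSV file.

    Non-numeric or non-finite rows are dropped and their count logged.
    Raises ``EmptyCloudError`` if no valid point remains.
    """
    path = Path(path)
    fmt = fmt or _infer_format(path)
    if fmt not in FORMATS:
        raise ValueError(f"unsupported format {fmt!r}; expected one of {FORMATS}")
    if not path.exists():
        raise FileNotFoundError(path)

    if fmt == "pcd":
        rows = _read_pcd_rows(path)
    elif fmt == "ply":
        rows = _read_ply_rows(path)
    else:
        rows = path.read_text().splitlines()
        # tolerate an x,y,z header line
        if rows and rows[0].lower().lstrip().startswith(("x", '"x')):
            rows = rows[1:]

    pts, rejected = _parse_rows(rows)
    if rejected:
        logger.warning("%s: rejected %d malformed/non-finite rows", path.name, rejected)
    if len(pts) == 0:
        raise EmptyCloudError(f"{path}: no valid points")
    return PointCloud(pts)


def _parse_rows(rows: list[str]) -> tuple[np.ndarray, int]:
    pts: list[tuple[float, float, float]] = []
    rejected = 0
    for line in rows:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        try:
            x, y, z = float(parts[0]), float(parts[1]), float(parts[2])
        except (ValueError, IndexError):
            rejected += 1
            continue
        if not (np.isfinite(x) and np.isfinite(y) and np.isfinite(z)):
            rejected += 1
            continue
        pts.append((x, y, z))
    return np.asarray(pts, dtype=np.float64).reshape(-1, 3), rejected


def _read_pcd_rows(path: Path) -> list[str]:
    lines = path.read_text().splitlines()
    data_at = None
    for i, line in enumerate(lines):
        if line.startswith("DATA"):
            if "ascii" not in line:
                raise ValueError(f"{path}: only ASCII PCD is supported")
            data_at = i + 1
            break
    if data_at is None:
        raise ValueError(f"{path}: missing DATA header line; not a PCD file?")
    return lines[data_at:]


def _read_ply_rows(path: Path) -> list[str]:
    lines = path.read_text().splitlines()
    if not lines or not lines[0].strip().startswith("ply"):
        raise ValueError(f"{path}: missing 'ply' magic")
    n_vertices = None
    end = None
    for i, line in enumerate(lines):
        tokens = line.split()
        if tokens[:2] == ["element", "vertex"]:
            n_vertices = int(tokens[2])
        if line.strip() == "end_header":
            end = i + 1
            break
        if tokens[:1] == ["format"] and "ascii" not in line:
            raise ValueError(f"{path}: only ASCII PLY is supported")
    if end is None or n_vertices is None:
        raise ValueError(f"{path}: malformed PLY header")
    return lines[end : end + n_vertices]


def write_point_cloud(cloud: PointCloud, path: str | Path, fmt: str | None = None) -> Path:
    """Write a non-empty cloud; output re-reads to within 1e-6 m."""
    cloud.require_nonempty("write_point_cloud")
    path = Path(path)
    fmt = fmt or _infer_format(path)
    pts = cloud.points
    # %.8g keeps coordinates of orchard scale (|x| < 1e4 m) well inside 1e-6 m
    body = "\n".join(f"{p[0]:.10g} {p[1]:.10g} {p[2]:.10g}" for p in pts)
    if fmt == "pcd":
        header = (
            "# .PCD v0.7 - Point Cloud Data file format\n"
            "VERSION 0.7\nFIELDS x y z\nSIZE 4 4 4\nTYPE F F F\nCOUNT 1 1 1\n"
            f"WIDTH {len(pts)}\nHEIGHT 1\nVIEWPOINT 0 0 0 1 0 0 0\n"
            f"POINTS {len(pts)}\nDATA ascii\n"
        )
        path.write_text(header + body + "\n")
    elif fmt == "ply":
        header = (
            "ply\nformat ascii 1.0\n"
            f"element vertex {len(pts)}\n"
            "property double x\nproperty double y\nproperty double z\n"
            "end_header\n"
        )
        path.write_text(header + body + "\n")
    elif fmt == "xyz-csv":
        np.savetxt(path, pts, fmt="%.10g", delimiter=",", header="x,y,z", comments="")
    else:
        raise ValueError(f"unsupported format {fmt!r}")
    return path


GROUND_TRUTH_COLUMNS = [
    "tree_id", "measured_height", "D1", "D2", "Ht1", "Hs1", "Ht2", "Hs2",
    "row_index", "position_in_row",
]


def read_ground_truth(
    path: str | Path,
    tree_spacing: float | None = None,
    row_spacing: float | None = None,
) -> OrchardGroundTruth:
    """Read per-tree manual measurements from CSV.

    The planted spacings may be given as constant ``tree_spacing`` /
    ``row_spacing`` columns or passed explicitly (arguments win).
    """
    df = pd.read_csv(path)
    missing = [c for c in GROUND_TRUTH_COLUMNS[:8] if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing ground-truth columns {missing}")
    if tree_spacing is None:
        if "tree_spacing" not in df.columns:
            raise ValidationError(f"{path}: tree_spacing not in file nor given")
        tree_spacing = float(df["tree_spacing"].iloc[0])
    if row_spacing is None:
        if "row_spacing" not in df.columns:
            raise ValidationError(f"{path}: row_spacing not in file nor given")
        row_spacing = float(df["row_spacing"].iloc[0])
    trees = [
        TreeRecord(
            tree_id=str(r["tree_id"]),
            measured_height=float(r["measured_height"]),
            d1=float(r["D1"]), d2=float(r["D2"]),
            ht1=float(r["Ht1"]), hs1=float(r["Hs1"]),
            ht2=float(r["Ht2"]), hs2=float(r["Hs2"]),
            row_index=int(r.get("row_index", 0)),
            position_in_row=int(r.get("position_in_row", 0)),
        )
        for _, r in df.iterrows()
    ]
    return OrchardGroundTruth(trees, tree_spacing=tree_spacing, row_spacing=row_spacing)


def write_ground_truth(truth: OrchardGroundTruth, path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for t in truth.trees:
        rows.append(
            dict(
                tree_id=t.tree_id, measured_height=t.measured_height,
                D1=t.d1, D2=t.d2, Ht1=t.ht1, Hs1=t.hs1, Ht2=t.ht2, Hs2=t.hs2,
                row_index=t.row_index, position_in_row=t.position_in_row,
                tree_spacing=truth.tree_spacing, row_spacing=truth.row_spacing,
            )
        )
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
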