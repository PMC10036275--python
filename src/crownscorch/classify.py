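"""Burned/unburned crown classification from orthomosaic greenness.

Point-cloud colors inside crowns are too shadow-contaminated to classify on
directly, so each crown is classified from the orthomosaic instead: crown
points are thinned (low points and isolated noise removed), a detailed
concave hull is traced around what remains, orthomosaic pixels inside the
hull are extracted, and the crown is called burned when fewer than half of
those pixels have a positive Green Leaf Index.

GLI = (2G − R − B) / (2G + R + B): positive for green vegetation, negative
for brown/scorched material, zero for gray.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import shapely
from scipy.spatial import Delaunay, cKDTree
from shapely.geometry import MultiPoint, Polygon

from .cloud import ColoredPointCloud, RasterGrid
from .segmentation import CrownSegment

__all__ = [
    "gli",
    "CrownPixels",
    "BurnCall",
    "UnclassifiableTreeError",
    "refine_crown_points",
    "crown_hull",
    "extract_crown_pixels",
    "classify_burn",
]


class UnclassifiableTreeError(ValueError):
    """Raised when a crown has too few points or pixels to classify."""


def gli(r, g, b):
    """Green Leaf Index, in [-1, 1]; 0 where the denominator vanishes.

    Scale-invariant: gli(kR, kG, kB) == gli(R, G, B) for k > 0, so uniform
    shading (shadow) does not change its sign.
    """
    r = np.asarray(r, dtype=float)
    g = np.asarray(g, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(r < 0) or np.any(g < 0) or np.any(b < 0):
        raise ValueError("negative band values")
    num = 2 * g - r - b
    den = 2 * g + r + b
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return out if out.ndim else float(out)


@dataclass
class CrownPixels:
    """Orthomosaic pixels of one crown ("individual tree orthomosaic")."""

    tree_id: int
    colors: np.ndarray  # (n, 3)

    @property
    def count(self) -> int:
        return len(self.colors)


@dataclass
class BurnCall:
    """Burn classification of one crown."""

    tree_id: int
    positive_gli_fraction: float
    label: str  # "burned" | "unburned"


def refine_crown_points(
    segment: CrownSegment,
    height_percentile: float = 25.0,
    ivf_voxel: float = 0.5,
    percentile_of_max: bool = False,
) -> ColoredPointCloud:
    """Thin a crown's points before hull tracing.

    Drops points below the ``height_percentile`` of the segment's point-height
    distribution (linear-interpolation percentile; set ``percentile_of_max``
    to use that fraction of the maximum height instead), then applies an
    isolated-voxels filter: points whose ``ivf_voxel``-edge voxel has no
    occupied 26-neighborhood voxel are noise and removed.
    """
    pts = segment.points
    if pts is None or len(pts) < 4:
        raise UnclassifiableTreeError(
            f"tree {segment.tree_id}: fewer than 4 member points"
        )
    if percentile_of_max:
        cutoff = (height_percentile / 100.0) * pts.z.max()
    else:
        cutoff = np.percentile(pts.z, height_percentile)
    pts = pts.subset(pts.z >= cutoff)
    min_points = 3  # a triangle is the smallest hull-able crown

    if len(pts):
        vox = np.column_stack(
            [
                np.floor(pts.x / ivf_voxel).astype(int),
                np.floor(pts.y / ivf_voxel).astype(int),
                np.floor(pts.z / ivf_voxel).astype(int),
            ]
        )
        occupied = set(map(tuple, np.unique(vox, axis=0)))
        if len(occupied) == 1:
            occupied = set()  # a single-voxel crown carries no isolation signal
        offsets = [
            (dx, dy, dz)
            for dx in (-1, 0, 1)
            for dy in (-1, 0, 1)
            for dz in (-1, 0, 1)
            if (dx, dy, dz) != (0, 0, 0)
        ]
        isolated = {
            v
            for v in occupied
            if not any(
                (v[0] + dx, v[1] + dy, v[2] + dz) in occupied for dx, dy, dz in offsets
            )
        }
        if isolated:
            keep = np.array([tuple(v) not in isolated for v in vox])
            pts = pts.subset(keep)

    if len(pts) < min_points:
        raise UnclassifiableTreeError(
            f"tree {segment.tree_id}: fewer than {min_points} points after refinement"
        )
    return pts


def _triangulation_radii(xy: np.ndarray):
    try:
        tri = Delaunay(xy)
    except Exception:
        return None, None
    a, b, c = (xy[tri.simplices[:, i]] for i in range(3))
    la = np.linalg.norm(b - c, axis=1)
    lb = np.linalg.norm(a - c, axis=1)
    lc = np.linalg.norm(a - b, axis=1)
    s = (la + lb + lc) / 2
    area = np.sqrt(np.maximum(s * (s - la) * (s - lb) * (s - lc), 0))
    with np.errstate(divide="ignore", invalid="ignore"):
        circumradius = np.where(area > 0, la * lb * lc / (4 * area), np.inf)
    return tri.simplices, circumradius


def _alpha_shape(xy: np.ndarray, alpha: float) -> Polygon | None:
    """Union of Delaunay triangles with circumradius ≤ alpha."""
    simplices, circumradius = _triangulation_radii(xy)
    if simplices is None:
        return None
    keep = simplices[circumradius <= alpha]
    if len(keep) == 0:
        return None
    polys = shapely.polygons(xy[keep])
    merged = shapely.unary_union(polys)
    if merged.geom_type == "MultiPolygon":
        merged = max(merged.geoms, key=lambda g: g.area)
    return merged if merged.geom_type == "Polygon" else None


def crown_hull(points: ColoredPointCloud, alpha: float | None = None) -> Polygon:
    """Detailed concave hull of the crown in plan view.

    An alpha shape (union of Delaunay triangles with circumradius ≤ alpha).
    By default alpha adapts to the point spacing: starting from 3× the median
    planar nearest-neighbor distance it doubles until the shape holds at
    least 99% of the points, so locally sparse crown interiors do not punch
    spurious holes while uniformly dense point sets keep a detailed outline.
    Falls back to the convex hull when no alpha qualifies or the geometry is
    degenerate; collinear inputs yield a thinly buffered line with a warning.
    """
    xy = np.column_stack([points.x, points.y])
    xy_unique = np.unique(xy, axis=0)
    if len(xy_unique) < 4:
        hull = MultiPoint(xy_unique).convex_hull
        if hull.geom_type != "Polygon":
            warnings.warn("degenerate crown geometry; buffered fallback", stacklevel=2)
            hull = hull.buffer(0.05)
        return hull
    if alpha is None:
        dist, _ = cKDTree(xy_unique).query(xy_unique, k=2)
        candidates = 3.0 * np.median(dist[:, 1]) * 2.0 ** np.arange(6)
    else:
        candidates = [alpha]
    simplices, circumradius = _triangulation_radii(xy_unique)
    for a in candidates:
        if simplices is None:
            break
        keep = simplices[circumradius <= a]
        if len(keep) == 0:
            continue
        merged = shapely.unary_union(shapely.polygons(xy_unique[keep]))
        if merged.geom_type == "MultiPolygon":
            merged = max(merged.geoms, key=lambda g: g.area)
        if merged.geom_type != "Polygon" or merged.area == 0:
            continue
        inside = shapely.contains_xy(merged.buffer(1e-9), xy[:, 0], xy[:, 1])
        if inside.mean() >= 0.99:
            return merged
    hull = MultiPoint(xy_unique).convex_hull
    if hull.geom_type != "Polygon":
        warnings.warn("collinear crown points; buffered line polygon", stacklevel=2)
        hull = hull.buffer(0.05)
    return hull


def extract_crown_pixels(
    ortho: RasterGrid, hull: Polygon, tree_id: int = 0
) -> CrownPixels:
    """Pixels of the orthomosaic whose centers fall inside the hull."""
    if ortho.bands != 3:
        raise ValueError("orthomosaic must have 3 bands")
    minx, miny, maxx, maxy = hull.bounds
    r_hi, c_lo = ortho.cell_index(minx, miny)
    r_lo, c_hi = ortho.cell_index(maxx, maxy)
    r_lo, r_hi = max(r_lo, 0), min(r_hi, ortho.n_rows - 1)
    c_lo, c_hi = max(c_lo, 0), min(c_hi, ortho.n_cols - 1)
    if r_lo > r_hi or c_lo > c_hi:
        raise UnclassifiableTreeError(f"tree {tree_id}: hull outside orthomosaic")
    rows, cols = np.mgrid[r_lo : r_hi + 1, c_lo : c_hi + 1]
    cx, cy = ortho.cell_center(rows.ravel(), cols.ravel())
    inside = shapely.contains_xy(hull, cx, cy)
    if not inside.any():
        raise UnclassifiableTreeError(f"tree {tree_id}: no pixel centers in hull")
    colors = ortho.values[rows.ravel()[inside], cols.ravel()[inside]]
    return CrownPixels(tree_id=tree_id, colors=np.asarray(colors, dtype=int))


def classify_burn(pixels: CrownPixels, threshold: float = 0.5) -> BurnCall:
    """Call a crown burned when the positive-GLI pixel fraction is < threshold.

    A fraction exactly at the threshold is unburned; pixels with GLI exactly 0
    count as non-positive.
    """
    if pixels.count < 1:
        raise UnclassifiableTreeError(f"tree {pixels.tree_id}: no pixels")
    vals = gli(pixels.colors[:, 0], pixels.colors[:, 1], pixels.colors[:, 2])
    frac = float(np.mean(vals > 0))
    label = "burned" if frac < threshold else "unburned"
    return BurnCall(tree_id=pixels.tree_id, positive_gli_fraction=frac, label=label)
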