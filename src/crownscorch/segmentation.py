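"""Individual-tree detection and crown delineation on canopy height models.

The chain is the standard one for fine-resolution canopy rasters: rasterize
maximum point height into a 10-cm CHM, blur lightly with a Gaussian, find
treetops with a variable-radius local-maximum filter (window grows with tree
height following a crown-allometry rule), and flood the inverted CHM from the
treetops with a marker-controlled watershed so every canopy cell is assigned
to exactly one crown. Detected crowns are filtered by plot membership and
minimum area, then matched one-to-one to field stems to score recall and
precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from shapely.geometry import Polygon
from skimage.segmentation import watershed

from .cloud import ColoredPointCloud, RasterGrid

__all__ = [
    "TreeTop",
    "CrownSegment",
    "MatchReport",
    "build_chm",
    "smooth_chm",
    "detect_treetops",
    "watershed_labels",
    "segment_crowns",
    "filter_segments",
    "match_trees",
    "default_window",
]


@dataclass(frozen=True)
class TreeTop:
    """A detected treetop: planar position and CHM height at the maximum."""

    x: float
    y: float
    height: float


@dataclass
class CrownSegment:
    """One delineated crown: apex, traced boundary, and member points."""

    tree_id: int
    apex: TreeTop
    boundary: Polygon
    area: float
    point_indices: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    points: Optional[ColoredPointCloud] = None


@dataclass
class MatchReport:
    """Detected-crown vs field-stem assignment with detection scores."""

    pairs: list[tuple[int, int]]  # (segment tree_id, field tree_id)
    tp_count: int
    fn_count: int
    fp_count: int

    @property
    def recall(self) -> float:
        denom = self.tp_count + self.fn_count
        return self.tp_count / denom if denom else 0.0

    @property
    def precision(self) -> float:
        denom = self.tp_count + self.fp_count
        return self.tp_count / denom if denom else 0.0

    @classmethod
    def from_counts(cls, tp: int, fn: int, fp: int) -> "MatchReport":
        return cls(pairs=[], tp_count=tp, fn_count=fn, fp_count=fp)


def build_chm(cloud: ColoredPointCloud, cell: float = 0.10) -> RasterGrid:
    """Rasterize maximum point height per cell; empty cells are no-data."""
    if len(cloud) == 0:
        raise ValueError("cannot build a CHM from an empty cloud")
    if cell <= 0:
        raise ValueError("cell size must be positive")
    x0, y0 = cloud.x.min(), cloud.y.min()
    n_cols = max(int(np.floor((cloud.x.max() - x0) / cell)) + 1, 1)
    n_rows = max(int(np.floor((cloud.y.max() - y0) / cell)) + 1, 1)
    nodata = -9999.0
    values = np.full((n_rows, n_cols), nodata)
    grid = RasterGrid(values, x0, y0, cell, nodata=nodata)
    row, col = grid.cell_index(cloud.x, cloud.y)
    row, col = np.clip(row, 0, n_rows - 1), np.clip(col, 0, n_cols - 1)
    np.maximum.at(values, (row, col), cloud.z)
    return grid


def smooth_chm(chm: RasterGrid, sigma: float = 0.05) -> RasterGrid:
    """Gaussian-blur the CHM; ``sigma`` is in map units (meters).

    No-data cells are filled with 0 (ground) before filtering so the
    watershed later sees a complete surface.
    """
    values = np.where(chm.values == chm.nodata, 0.0, chm.values)
    if sigma <= 0:
        warnings.warn("non-positive sigma: CHM returned unsmoothed", stacklevel=2)
        return RasterGrid(values, chm.x0, chm.y0, chm.cell, nodata=chm.nodata)
    smoothed = ndimage.gaussian_filter(values, sigma=sigma / chm.cell)
    return RasterGrid(smoothed, chm.x0, chm.y0, chm.cell, nodata=chm.nodata)


def default_window(height: float) -> float:
    """Variable local-maximum window radius (m) as a function of tree height."""
    return max(0.6, 0.05 * height + 0.6)


def detect_treetops(
    chm_smooth: RasterGrid,
    min_height: float = 2.0,
    window_fn: Callable[[float], float] = default_window,
) -> list[TreeTop]:
    """Find treetops: cells that are the maximum of their height-dependent
    circular window and at least ``min_height`` tall.

    Equal-height plateau ties are broken toward the smaller (row, col), an
    arbitrary but deterministic rule.
    """
    values = chm_smooth.values
    # candidates: 3x3 local maxima (ties kept) above the height floor
    local_max = values >= ndimage.maximum_filter(values, size=3, mode="nearest")
    rows, cols = np.nonzero(local_max & (values >= min_height))
    tops: list[TreeTop] = []
    n_rows, n_cols = values.shape
    for r, c in zip(rows, cols):
        h = values[r, c]
        rad_cells = window_fn(h) / chm_smooth.cell
        ri = int(np.ceil(rad_cells))
        r0, r1 = max(r - ri, 0), min(r + ri + 1, n_rows)
        c0, c1 = max(c - ri, 0), min(c + ri + 1, n_cols)
        win = values[r0:r1, c0:c1]
        rr, cc = np.mgrid[r0:r1, c0:c1]
        in_circle = (rr - r) ** 2 + (cc - c) ** 2 <= rad_cells**2
        if np.any(win[in_circle] > h):
            continue
        ties = in_circle & (win == h)
        tie_rows, tie_cols = rr[ties], cc[ties]
        best = np.lexsort((tie_cols, tie_rows))[0]
        if (tie_rows[best], tie_cols[best]) != (r, c):
            continue
        x, y = chm_smooth.cell_center(r, c)
        tops.append(TreeTop(float(x), float(y), float(h)))
    return tops


def watershed_labels(
    chm_smooth: RasterGrid,
    tops: Sequence[TreeTop],
    min_height: float = 2.0,
) -> np.ndarray:
    """Marker-controlled watershed label map on the inverted CHM.

    Cells below ``min_height`` are masked out (label 0); every unmasked cell
    reachable from a marker gets exactly one crown label (1-based, in the
    order of ``tops``).
    """
    values = chm_smooth.values
    markers = np.zeros(values.shape, dtype=int)
    for i, top in enumerate(tops, start=1):
        r, c = chm_smooth.cell_index(top.x, top.y)
        if not (0 <= r < values.shape[0] and 0 <= c < values.shape[1]):
            warnings.warn(f"treetop {i} outside CHM extent; skipped", stacklevel=2)
            continue
        markers[r, c] = i
    mask = values >= min_height
    return watershed(-values, markers=markers, mask=mask)


def _label_polygon(labels: np.ndarray, lab: int, grid: RasterGrid) -> Polygon:
    rows, cols = np.nonzero(labels == lab)
    # shared edge arrays so adjacent boxes bit-match and the union dissolves
    x_edges = grid.x0 + np.arange(labels.shape[1] + 1) * grid.cell
    y_edges = grid.y0 + np.arange(labels.shape[0] + 1) * grid.cell
    iy = labels.shape[0] - rows - 1
    boxes = shapely.box(x_edges[cols], y_edges[iy], x_edges[cols + 1], y_edges[iy + 1])
    merged = shapely.unary_union(boxes)
    if merged.geom_type == "MultiPolygon":
        merged = max(merged.geoms, key=lambda g: g.area)
    return merged


def segment_crowns(
    chm_smooth: RasterGrid,
    tops: Sequence[TreeTop],
    cloud: Optional[ColoredPointCloud] = None,
    min_height: float = 2.0,
) -> list[CrownSegment]:
    """Delineate one crown per treetop and assign member points.

    Boundaries are traced from the watershed label map (union of member
    cells); member points are the cloud points whose plan-view cell carries
    the crown's label, which guarantees containment in the traced polygon.
    """
    if not tops:
        raise ValueError("segment_crowns requires at least one treetop")
    labels = watershed_labels(chm_smooth, tops, min_height=min_height)

    point_labels = None
    if cloud is not None and len(cloud):
        row, col = chm_smooth.cell_index(cloud.x, cloud.y)
        inside = (
            (row >= 0) & (row < labels.shape[0]) & (col >= 0) & (col < labels.shape[1])
        )
        point_labels = np.zeros(len(cloud), dtype=int)
        point_labels[inside] = labels[row[inside], col[inside]]

    segments: list[CrownSegment] = []
    for i, top in enumerate(tops, start=1):
        if not np.any(labels == i):
            continue
        poly = _label_polygon(labels, i, chm_smooth)
        seg = CrownSegment(tree_id=i, apex=top, boundary=poly, area=poly.area)
        if point_labels is not None:
            idx = np.nonzero(point_labels == i)[0]
            seg.point_indices = idx
            seg.points = cloud.subset(idx)
        segments.append(seg)
    return segments


def filter_segments(
    segments: Sequence[CrownSegment],
    plot_center: tuple[float, float] = (0.0, 0.0),
    plot_radius: float = 11.28,
    min_area: float = 0.3,
) -> list[CrownSegment]:
    """Keep crowns whose apex lies in the plot and whose area is ≥ min_area m²."""
    cx, cy = plot_center
    return [
        s
        for s in segments
        if np.hypot(s.apex.x - cx, s.apex.y - cy) <= plot_radius
        and s.area >= min_area
    ]


def match_trees(
    segments: Sequence[CrownSegment],
    field_stems: pd.DataFrame,
    max_dist: float = 2.0,
    height_tol: float = 0.3,
) -> MatchReport:
    """Greedy one-to-one matching of detected crowns to field stems.

    Candidate pairs are taken in ascending apex-to-stem distance; a pair is
    accepted iff the distance is ≤ ``max_dist`` and the apex height is within
    ``height_tol`` (fractional) of the field-measured total height. Unmatched
    stems count as false negatives, unmatched segments as false positives.

    ``field_stems`` needs columns tree_id, stem_x, stem_y, total_height.
    """
    if len(segments) == 0 or len(field_stems) == 0:
        return MatchReport(
            pairs=[], tp_count=0, fn_count=len(field_stems), fp_count=len(segments)
        )
    sx = field_stems["stem_x"].to_numpy(float)
    sy = field_stems["stem_y"].to_numpy(float)
    sh = field_stems["total_height"].to_numpy(float)
    sid = field_stems["tree_id"].to_numpy()

    cand = []
    for i, seg in enumerate(segments):
        d = np.hypot(seg.apex.x - sx, seg.apex.y - sy)
        ok = (d <= max_dist) & (np.abs(seg.apex.height - sh) <= height_tol * sh)
        for j in np.nonzero(ok)[0]:
            cand.append((d[j], i, j))
    cand.sort()

    used_seg: set[int] = set()
    used_stem: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _, i, j in cand:
        if i in used_seg or j in used_stem:
            continue
        used_seg.add(i)
        used_stem.add(j)
        pairs.append((segments[i].tree_id, sid[j]))
    tp = len(pairs)
    return MatchReport(
        pairs=pairs,
        tp_count=tp,
        fn_count=len(field_stems) - tp,
        fp_count=len(segments) - tp,
    )
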