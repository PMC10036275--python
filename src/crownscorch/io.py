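"""Reading and writing point clouds, rasters, and stem tables.

Point clouds move as LAS 1.2 (RGB point formats) or whitespace-delimited
``x y z r g b`` text; rasters as GeoTIFF (pixel-scale + tiepoint tags) via
tifffile; tables as CSV. Coordinates are planar meters throughout — no CRS
transformation is performed.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import tifffile

from ._las import read_las, write_las
from .cloud import ColoredPointCloud, RasterGrid

__all__ = [
    "read_point_cloud",
    "write_point_cloud",
    "read_raster",
    "write_raster",
]

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".las", ".laz"):
        return "las"
    return "text"


def read_point_cloud(path, format: str | None = None) -> ColoredPointCloud:
    """Load a colored point cloud from LAS or ``x y z r g b`` text.

    Color is required by the downstream method: files without RGB raise, and
    files whose RGB is all zero load with a "colorless" warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt == "las":
        cloud = read_las(path)
    elif fmt == "text":
        cloud = _read_text(path)
    else:
        raise ValueError(f"unknown point-cloud format {fmt!r}")
    if len(cloud) and cloud.colors.max() == 0:
        warnings.warn(f"{path}: colorless point cloud (RGB all zero)", stacklevel=2)
    return cloud


def _read_text(path: Path) -> ColoredPointCloud:
    try:
        data = np.loadtxt(path, ndmin=2)
    except ValueError:
        # re-scan to report the offending row
        with open(path) as fh:
            for i, line in enumerate(fh, start=1):
                parts = line.split()
                if not parts or line.lstrip().startswith("#"):
                    continue
                try:
                    vals = [float(p) for p in parts]
                except ValueError:
                    raise ValueError(f"{path}: malformed row {i}: {line.rstrip()!r}")
                if len(vals) != 6:
                    raise ValueError(
                        f"{path}: row {i} has {len(vals)} columns, expected 6 "
                        "(x y z r g b)"
                    )
        raise
    if data.size == 0:
        return ColoredPointCloud(*[np.empty(0)] * 3, *[np.empty(0, int)] * 3)
    if data.shape[1] < 6:
        raise ValueError(
            f"{path}: {data.shape[1]} columns, expected 6 (x y z r g b); "
            "RGB color is required"
        )
    rgb = data[:, 3:6]
    if np.any(rgb < 0):
        raise ValueError(f"{path}: negative color values")
    depth = 8 if rgb.max() <= 255 else 16
    return ColoredPointCloud(
        data[:, 0], data[:, 1], data[:, 2],
        rgb[:, 0].astype(int), rgb[:, 1].astype(int), rgb[:, 2].astype(int),
        bit_depth=depth,
    )


def write_point_cloud(cloud: ColoredPointCloud, path, format: str | None = None) -> None:
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "las":
        write_las(cloud, path)
    elif fmt == "text":
        data = np.column_stack(
            [cloud.x, cloud.y, cloud.z, cloud.r, cloud.g, cloud.b]
        )
        np.savetxt(path, data, fmt="%.3f %.3f %.3f %d %d %d")
    else:
        raise ValueError(f"unknown point-cloud format {fmt!r}")


def write_raster(grid: RasterGrid, path) -> None:
    """Write a RasterGrid as GeoTIFF (pixel scale + tiepoint at the NW corner)."""
    y_top = grid.y0 + grid.n_rows * grid.cell
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (grid.cell, grid.cell, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, grid.x0, y_top, 0.0)),
    ]
    values = grid.values
    if grid.bands == 1:
        values = values.astype(np.float32)
        extratags.append((_TAG_GDAL_NODATA, "s", 0, str(grid.nodata)))
        photometric = "minisblack"
    else:
        values = values.astype(np.uint8)
        photometric = "rgb"
    tifffile.imwrite(path, values, photometric=photometric, extratags=extratags)


def read_raster(path) -> RasterGrid:
    """Read a GeoTIFF written by :func:`write_raster` (or compatible)."""
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray()
        tags = page.tags
        if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
            raise ValueError(f"{path}: missing georeferencing tags")
        cell = float(tags[_TAG_PIXEL_SCALE].value[0])
        tie = tags[_TAG_TIEPOINT].value
        x0, y_top = float(tie[3]), float(tie[4])
        nodata = -9999.0
        if _TAG_GDAL_NODATA in tags:
            nodata = float(tags[_TAG_GDAL_NODATA].value)
    n_rows = values.shape[0]
    return RasterGrid(values, x0, y_top - n_rows * cell, cell, nodata=nodata)
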