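"""Point-cloud preprocessing: understory/ground removal and height normalization.

The assessment method operates on height-normalized clouds with everything
below breast-height-scale vegetation removed: points under 2 m above ground
carry ground litter, shrubs, and photogrammetric noise that would contaminate
crown profiles. Ground classification proper is expected upstream; a
grid-minimum normalizer is provided as a stand-in for clouds that arrive with
raw elevations.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .cloud import ColoredPointCloud

__all__ = ["preprocess", "normalize_by_grid_minimum"]

log = logging.getLogger(__name__)


def preprocess(cloud: ColoredPointCloud, min_height: float = 2.0) -> ColoredPointCloud:
    """Remove points below ``min_height`` above ground (strictly-less removal).

    Points exactly at the threshold are retained. Idempotent. An empty result
    (e.g. a plot with complete crown consumption) is a warning, not an error.
    """
    keep = cloud.z >= min_height
    removed = int((~keep).sum())
    log.info("preprocess: removed %d of %d points below %.2f m",
             removed, len(cloud), min_height)
    out = cloud.subset(keep)
    if len(out) == 0:
        warnings.warn(
            f"all {len(cloud)} points below {min_height} m; empty cloud returned",
            stacklevel=2,
        )
    return out


def normalize_by_grid_minimum(cloud: ColoredPointCloud, cell: float = 2.0) -> ColoredPointCloud:
    """Height-normalize by subtracting an interpolated per-cell minimum surface.

    The minimum z in each ``cell``-by-``cell`` tile estimates local ground;
    the tile minima are bilinearly interpolated at each point and subtracted,
    so the lowest points in each tile land near z = 0. A cell larger than the
    cloud extent degenerates to subtracting the global minimum.
    """
    if cell <= 0:
        raise ValueError("cell size must be positive")
    if len(cloud) == 0:
        return cloud
    x0, y0 = cloud.x.min(), cloud.y.min()
    n_cols = int(np.ceil((cloud.x.max() - x0) / cell))
    n_rows = int(np.ceil((cloud.y.max() - y0) / cell))
    if n_cols < 1 or n_rows < 1 or (n_cols == 1 and n_rows == 1):
        z = cloud.z - cloud.z.min()
        return ColoredPointCloud(cloud.x, cloud.y, z, cloud.r, cloud.g, cloud.b,
                                 bit_depth=cloud.bit_depth)

    col = np.clip(((cloud.x - x0) / cell).astype(int), 0, n_cols - 1)
    row = np.clip(((cloud.y - y0) / cell).astype(int), 0, n_rows - 1)
    minima = np.full((n_rows, n_cols), np.nan)
    np.fmin.at(minima, (row, col), cloud.z)
    # fill empty tiles from their nearest occupied tile
    if np.isnan(minima).any():
        from scipy.ndimage import distance_transform_edt

        idx = distance_transform_edt(
            np.isnan(minima), return_distances=False, return_indices=True
        )
        minima = minima[tuple(idx)]

    yc = y0 + (np.arange(n_rows) + 0.5) * cell
    xc = x0 + (np.arange(n_cols) + 0.5) * cell
    interp = RegularGridInterpolator(
        (yc, xc), minima, method="linear", bounds_error=False, fill_value=None
    )
    ground = interp(np.column_stack([cloud.y, cloud.x]))
    return ColoredPointCloud(
        cloud.x, cloud.y, cloud.z - ground, cloud.r, cloud.g, cloud.b,
        bit_depth=cloud.bit_depth,
    )
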