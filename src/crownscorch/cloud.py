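"""Core in-memory containers: colored point clouds and raster grids.

Coordinates are planar meters (a projected CRS is assumed; no reprojection is
performed). Heights ``z`` are meters above ground once a cloud has been
height-normalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ColoredPointCloud", "RasterGrid"]


@dataclass
class ColoredPointCloud:
    """Points with per-point 3-band color.

    Parameters
    ----------
    x, y : float arrays, m
        Planar coordinates.
    z : float array, m
        Height; above ground after normalization.
    r, g, b : integer arrays
        Color bands, all on the same declared bit depth.
    bit_depth : int
        Bits per color band (8 or 16).
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    r: np.ndarray
    g: np.ndarray
    b: np.ndarray
    bit_depth: int = 8

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        self.r = np.asarray(self.r)
        self.g = np.asarray(self.g)
        self.b = np.asarray(self.b)
        n = len(self.x)
        for name in ("y", "z", "r", "g", "b"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"field {name!r} has length != {n}")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        cmax = 2**self.bit_depth - 1
        for name in ("r", "g", "b"):
            band = getattr(self, name)
            if band.size and (band.min() < 0 or band.max() > cmax):
                raise ValueError(
                    f"color band {name!r} outside [0, {cmax}] for bit depth "
                    f"{self.bit_depth}"
                )

    def __len__(self) -> int:
        return len(self.x)

    @property
    def colors(self) -> np.ndarray:
        """(n, 3) color array."""
        return np.column_stack([self.r, self.g, self.b])

    def subset(self, mask_or_idx) -> "ColoredPointCloud":
        """Return the cloud restricted to a boolean mask or index array."""
        return ColoredPointCloud(
            self.x[mask_or_idx],
            self.y[mask_or_idx],
            self.z[mask_or_idx],
            self.r[mask_or_idx],
            self.g[mask_or_idx],
            self.b[mask_or_idx],
            bit_depth=self.bit_depth,
        )

    @staticmethod
    def concatenate(clouds: list["ColoredPointCloud"]) -> "ColoredPointCloud":
        if not clouds:
            return ColoredPointCloud(*[np.empty(0)] * 3, *[np.empty(0, int)] * 3)
        depth = clouds[0].bit_depth
        if any(c.bit_depth != depth for c in clouds):
            raise ValueError("cannot concatenate clouds of mixed bit depth")
        return ColoredPointCloud(
            *[np.concatenate([getattr(c, f) for c in clouds]) for f in "xyzrgb"],
            bit_depth=depth,
        )


@dataclass
class RasterGrid:
    """Georeferenced cell grid: a 1-band CHM (m) or 3-band color image.

    Grid convention: origin ``(x0, y0)`` is the min-x / min-y corner, row 0 is
    at max y, cells are half-open ``[x0 + j*cell, x0 + (j+1)*cell)``.
    """

    values: np.ndarray  # (rows, cols) or (rows, cols, 3)
    x0: float
    y0: float
    cell: float
    nodata: float = field(default=-9999.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.cell <= 0:
            raise ValueError("cell size must be positive")
        if self.values.ndim not in (2, 3) or (
            self.values.ndim == 3 and self.values.shape[2] != 3
        ):
            raise ValueError("values must be (rows, cols) or (rows, cols, 3)")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def bands(self) -> int:
        return 1 if self.values.ndim == 2 else 3

    def cell_index(self, x, y):
        """Row/col of the cells containing planar points (half-open cells)."""
        col = np.floor((np.asarray(x) - self.x0) / self.cell).astype(int)
        row = self.n_rows - 1 - np.floor((np.asarray(y) - self.y0) / self.cell).astype(int)
        return row, col

    def cell_center(self, row, col):
        """Planar coordinates of cell centers."""
        x = self.x0 + (np.asarray(col) + 0.5) * self.cell
        y = self.y0 + (self.n_rows - np.asarray(row) - 0.5) * self.cell
        return x, y

    def center_grids(self):
        """Full (rows, cols) arrays of cell-center x and y."""
        rows, cols = np.mgrid[0 : self.n_rows, 0 : self.n_cols]
        return self.cell_center(rows, cols)
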