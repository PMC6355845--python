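"""Georeferenced raster grids and terrain derivatives.

A :class:`RasterGrid` is a plain in-memory raster: a 2-D plane per band plus
planar metric georeferencing (UTM-like coordinates, origin at the upper-left
corner, row index increasing southward).  Pixel (r, c) covers the half-open
square ``[origin_x + c*cell, origin_x + (c+1)*cell) x
(origin_y - (r+1)*cell, origin_y - r*cell]``.

Terrain derivatives (slope, aspect, curvature) follow Horn's 3x3 finite
difference scheme, the convention used by mainstream GIS packages.  Depth is
stored in metres, negative below sea level, so the seabed surface is simply a
signed elevation plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

__all__ = ["RasterGrid", "slope_aspect", "curvature", "FLAT_SLOPE_DEG"]

#: slopes below this (degrees) are treated as flat: aspect is undefined there
FLAT_SLOPE_DEG = 1e-6


class ConfigurationError(ValueError):
    """Invalid parameters or grid configuration."""


class DataError(ValueError):
    """Malformed or inconsistent data content."""


@dataclass
class RasterGrid:
    """A georeferenced raster: ``values`` is (rows, cols) or (rows, cols, bands)."""

    values: np.ndarray
    origin_x: float = 0.0
    origin_y: float = 0.0
    cell_size: float = 1.0
    nodata: float | None = None
    band_names: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.cell_size <= 0:
            raise ConfigurationError(f"cell_size must be > 0, got {self.cell_size}")
        if self.values.ndim not in (2, 3):
            raise DataError(f"values must be 2-D or 3-D, got ndim={self.values.ndim}")
        if self.rows < 1 or self.cols < 1:
            raise DataError("raster must have at least one row and one column")
        if self.band_names and len(self.band_names) != self.n_bands:
            raise ConfigurationError(
                f"{len(self.band_names)} band names for {self.n_bands} bands"
            )

    # -- shape ------------------------------------------------------------
    @property
    def rows(self) -> int:
        return self.values.shape[0]

    @property
    def cols(self) -> int:
        return self.values.shape[1]

    @property
    def n_bands(self) -> int:
        return 1 if self.values.ndim == 2 else self.values.shape[2]

    def band(self, i: int) -> np.ndarray:
        return self.values if self.values.ndim == 2 else self.values[:, :, i]

    # -- georeferencing ----------------------------------------------------
    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) in world metres."""
        return (
            self.origin_x,
            self.origin_y - self.rows * self.cell_size,
            self.origin_x + self.cols * self.cell_size,
            self.origin_y,
        )

    def pixel_to_world(self, r, c):
        """World coordinates of pixel centres."""
        r = np.asarray(r, dtype=float)
        c = np.asarray(c, dtype=float)
        x = self.origin_x + (c + 0.5) * self.cell_size
        y = self.origin_y - (r + 0.5) * self.cell_size
        return x, y

    def world_to_pixel(self, x, y):
        """(row, col) indices of the pixels containing world points."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        c = np.floor((x - self.origin_x) / self.cell_size).astype(np.int64)
        r = np.floor((self.origin_y - y) / self.cell_size).astype(np.int64)
        return r, c

    def same_georeference(self, other: "RasterGrid", tol: float = 1e-9) -> bool:
        return (
            abs(self.origin_x - other.origin_x) <= tol
            and abs(self.origin_y - other.origin_y) <= tol
            and abs(self.cell_size - other.cell_size) <= tol
            and self.values.shape[:2] == other.values.shape[:2]
        )

    def with_values(self, values: np.ndarray, band_names=()) -> "RasterGrid":
        return replace(self, values=values, band_names=tuple(band_names))


# ---------------------------------------------------------------------------
# Horn terrain derivatives
# ---------------------------------------------------------------------------

_HORN_X = np.array([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]])
_HORN_Y = np.array([[1.0, 2.0, 1.0], [0.0, 0.0, 0.0], [-1.0, -2.0, -1.0]])


def _horn_gradients(depth: RasterGrid) -> tuple[np.ndarray, np.ndarray]:
    z = np.asarray(depth.values, dtype=float)
    if z.ndim != 2:
        raise DataError("terrain derivatives need a single-band depth raster")
    cell = depth.cell_size
    dzdx = ndimage.correlate(z, _HORN_X, mode="nearest") / (8.0 * cell)
    dzdy = ndimage.correlate(z, _HORN_Y, mode="nearest") / (8.0 * cell)
    return dzdx, dzdy


def slope_aspect(depth: RasterGrid) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Slope (deg), aspect (deg clockwise from north, downslope) and a flat mask.

    Aspect is the compass direction of steepest *descent*; cells flatter than
    ``FLAT_SLOPE_DEG`` are flagged flat and their aspect set to NaN.
    """
    dzdx, dzdy = _horn_gradients(depth)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    # steepest descent = -gradient; east component -dzdx, north component -dzdy
    aspect = np.degrees(np.arctan2(-dzdx, -dzdy)) % 360.0
    flat = slope < FLAT_SLOPE_DEG
    aspect = np.where(flat, np.nan, aspect)
    return slope, aspect, flat


def curvature(depth: RasterGrid) -> np.ndarray:
    """Total curvature as the Laplacian of depth, units 1/m."""
    z = np.asarray(depth.values, dtype=float)
    if z.ndim != 2:
        raise DataError("curvature needs a single-band depth raster")
    lap = ndimage.convolve(
        z, np.array([[0.0, 1.0, 0.0], [1.0, -4.0, 1.0], [0.0, 1.0, 0.0]]), mode="nearest"
    )
    return lap / (depth.cell_size**2)
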