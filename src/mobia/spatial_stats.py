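"""Post-classification spatial analysis of the classified object layer.

Zonation tables summarise per-class area, object counts and the share of
each class inside the mound boundary.  Getis-Ord Gi* hotspot analysis on a
fishnet grid locates significant concentrations of the small biogenic
classes (live coral, sponges); hotspot Z-scores are related to depth by a
Pearson correlation, and settlement orientation is summarised as a circular
histogram of flank aspect at object centroids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely import STRtree
from shapely.geometry import Polygon, box

from .grid import ConfigurationError, DataError, RasterGrid, slope_aspect

__all__ = [
    "HotspotField",
    "zonation_stats",
    "zonation_from_aggregates",
    "format_zonation",
    "hotspot_gi_star",
    "zscore_depth_scatter",
    "aspect_polar",
]

CONFIDENCE_Z = ((2.576, 99), (1.960, 95), (1.645, 90))


# ---------------------------------------------------------------------------
# zonation table (per-class area statistics)
# ---------------------------------------------------------------------------


def zonation_from_aggregates(per_class: pd.DataFrame) -> pd.DataFrame:
    """Derive the zonation table from per-class totals.

    ``per_class`` is indexed by class code with columns ``total_area`` (m2),
    ``n_objects`` and optionally ``mound_area`` (m2).  Percentages and mean
    object area are computed in full precision; a class whose mound area
    exceeds its total area is geometrically impossible and triggers a
    warning naming the class (such rows can occur when totals come from an
    external, rounded source).
    """
    req = {"total_area", "n_objects"}
    if not req.issubset(per_class.columns):
        raise ConfigurationError(f"per-class table needs columns {sorted(req)}")
    df = per_class.copy().astype(float)
    grand_total = df["total_area"].sum()
    if grand_total <= 0:
        raise DataError("total classified area must be positive")
    df["pct_total"] = 100.0 * df["total_area"] / grand_total
    df["mean_object_area"] = df["total_area"] / df["n_objects"]
    if "mound_area" in df.columns:
        bad = df.index[df["mound_area"] > df["total_area"] + 1e-9].tolist()
        if bad:
            warnings.warn(
                f"mound area exceeds class total for {bad}: geometrically "
                "impossible; percentages reported as given",
                stacklevel=2,
            )
        mound_total = df["mound_area"].sum()
        df["pct_mound"] = (
            100.0 * df["mound_area"] / mound_total if mound_total > 0 else 0.0
        )
    totals = {
        "total_area": grand_total,
        "n_objects": df["n_objects"].sum(),
        "pct_total": 100.0,
        "mean_object_area": grand_total / df["n_objects"].sum(),
    }
    if "mound_area" in df.columns:
        totals["mound_area"] = df["mound_area"].sum()
        totals["pct_mound"] = 100.0
    out = pd.concat([df, pd.DataFrame([totals], index=["TOTAL"])])
    out.index.name = "class"
    return out


def zonation_stats(objects: pd.DataFrame, mound: Polygon) -> pd.DataFrame:
    """Per-class zonation table from classified polygons.

    ``objects`` needs a ``class`` column and a ``geometry`` column of shapely
    polygons.  Mound membership is by geometric intersection area with the
    mound polygon.
    """
    if mound is None or mound.is_empty or not mound.is_valid:
        raise DataError("mound polygon is missing or invalid")
    rows = {}
    for oid, row in objects.iterrows():
        geom = row["geometry"]
        if geom is None or not geom.is_valid:
            raise DataError(f"invalid geometry for object {oid}")
    grouped = objects.groupby("class")
    for code, grp in grouped:
        areas = np.array([g.area for g in grp["geometry"]])
        inter = np.zeros(len(grp))
        for i, g in enumerate(grp["geometry"]):
            if g.intersects(mound):
                inter[i] = g.intersection(mound).area
        rows[code] = {
            "total_area": areas.sum(),
            "n_objects": len(grp),
            "mound_area": inter.sum(),
        }
    per_class = pd.DataFrame(rows).T
    table = zonation_from_aggregates(per_class)
    body = table.drop(index="TOTAL")
    if (body["mound_area"] > body["total_area"] + 1e-6).any():
        raise DataError("computed mound area exceeds class total area")
    return table


def format_zonation(table: pd.DataFrame) -> pd.DataFrame:
    """Presentation rounding (2 decimals), mirroring full-precision data."""
    out = table.copy()
    for c in out.columns:
        if c != "n_objects":
            out[c] = out[c].round(2)
    out["n_objects"] = out["n_objects"].astype(int)
    return out


# ---------------------------------------------------------------------------
# Getis-Ord Gi* hotspot field
# ---------------------------------------------------------------------------


@dataclass
class HotspotField:
    """Fishnet of class-area density with Gi* Z-scores and confidence bins."""

    origin_x: float
    origin_y: float  # upper-left corner (north-west)
    cell_size: float
    values: np.ndarray  # (ny, nx) target-class area per cell
    z: np.ndarray  # (ny, nx) Gi* Z-scores
    conf: np.ndarray  # (ny, nx) int: 0, 90, 95 or 99

    @property
    def shape(self):
        return self.values.shape

    def cell_polygon(self, r: int, c: int) -> Polygon:
        x0 = self.origin_x + c * self.cell_size
        y1 = self.origin_y - r * self.cell_size
        return box(x0, y1 - self.cell_size, x0 + self.cell_size, y1)

    def cell_centres(self):
        ny, nx = self.values.shape
        xs = self.origin_x + (np.arange(nx) + 0.5) * self.cell_size
        ys = self.origin_y - (np.arange(ny) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def to_frame(self) -> pd.DataFrame:
        xs, ys = self.cell_centres()
        return pd.DataFrame(
            {
                "x": xs.ravel(),
                "y": ys.ravel(),
                "value": self.values.ravel(),
                "z": self.z.ravel(),
                "conf": self.conf.ravel(),
            }
        )


def gi_star_grid(values: np.ndarray, band_cells: float) -> np.ndarray:
    """Gi* Z-scores on a regular grid with binary distance-band weights.

    Neighbours are the cells whose centre lies within ``band_cells`` cell
    widths (self included); statistics use all n grid cells.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise ConfigurationError("need at least 2 cells for Gi*")
    xbar = x.mean()
    s = np.sqrt((x**2).mean() - xbar**2)
    if s == 0:
        raise DataError("constant field: Gi* undefined (zero variance)")
    r = int(np.floor(band_cells))
    di, dj = np.mgrid[-r: r + 1, -r: r + 1]
    kernel = (di**2 + dj**2 <= band_cells**2).astype(float)
    wx = ndimage.convolve(x, kernel, mode="constant", cval=0.0)
    w1 = ndimage.convolve(np.ones_like(x), kernel, mode="constant", cval=0.0)
    w2 = w1  # binary weights: sum of squares equals the sum
    denom = s * np.sqrt((n * w2 - w1**2) / (n - 1))
    return (wx - xbar * w1) / denom


def hotspot_gi_star(
    objects: pd.DataFrame,
    target_class: str,
    cell_size: float = 1.0,
    band_distance: float = 3.0,
    extent: tuple[float, float, float, float] | None = None,
    mound_context: Polygon | None = None,
) -> HotspotField:
    """Gi* hotspot field of one class's area density over a fishnet.

    Cell value = summed target-class polygon area intersecting the cell.
    ``extent`` is (xmin, ymin, xmax, ymax); by default the bounds of all
    objects (or of the mound polygon if given, whichever is larger).
    """
    if cell_size <= 0:
        raise ConfigurationError("cell_size must be positive")
    if band_distance < cell_size:
        raise ConfigurationError("band_distance must be >= cell_size")
    geoms = list(objects["geometry"])
    if extent is None:
        xs0, ys0, xs1, ys1 = zip(*(g.bounds for g in geoms))
        xmin, ymin, xmax, ymax = min(xs0), min(ys0), max(xs1), max(ys1)
        if mound_context is not None:
            bx0, by0, bx1, by1 = mound_context.bounds
            xmin, ymin = min(xmin, bx0), min(ymin, by0)
            xmax, ymax = max(xmax, bx1), max(ymax, by1)
    else:
        xmin, ymin, xmax, ymax = extent
    nx = max(int(np.ceil((xmax - xmin) / cell_size)), 1)
    ny = max(int(np.ceil((ymax - ymin) / cell_size)), 1)
    origin_y = ymin + ny * cell_size

    cells = [
        box(
            xmin + c * cell_size,
            origin_y - (r + 1) * cell_size,
            xmin + (c + 1) * cell_size,
            origin_y - r * cell_size,
        )
        for r in range(ny)
        for c in range(nx)
    ]
    tree = STRtree(cells)
    values = np.zeros(ny * nx)
    sel = objects["class"] == target_class
    for g in objects.loc[sel, "geometry"]:
        for ci in tree.query(g):
            inter = g.intersection(cells[ci])
            if not inter.is_empty:
                values[ci] += inter.area
    values = values.reshape(ny, nx)
    z = gi_star_grid(values, band_distance / cell_size)
    conf = np.zeros_like(z, dtype=int)
    for thr, level in CONFIDENCE_Z:
        conf[(np.abs(z) >= thr) & (conf == 0)] = level
    return HotspotField(xmin, origin_y, cell_size, values, z, conf)


# ---------------------------------------------------------------------------
# relations to terrain
# ---------------------------------------------------------------------------


def zscore_depth_scatter(
    field: HotspotField, bathy: RasterGrid
) -> tuple[pd.DataFrame, float]:
    """(mean depth, Z) pairs per fishnet cell and their Pearson correlation."""
    ny, nx = field.shape
    # mean depth of the bathy cells whose centres fall in each fishnet cell
    br = np.arange(bathy.rows)
    bc = np.arange(bathy.cols)
    yb = bathy.origin_y - (br + 0.5) * bathy.cell_size
    xb = bathy.origin_x + (bc + 0.5) * bathy.cell_size
    fr = np.floor((field.origin_y - yb) / field.cell_size).astype(int)
    fc = np.floor((xb - field.origin_x) / field.cell_size).astype(int)
    ok_r = (fr >= 0) & (fr < ny)
    ok_c = (fc >= 0) & (fc < nx)
    rr, cc = np.meshgrid(fr, fc, indexing="ij")
    mask = np.outer(ok_r, ok_c)
    lin = rr[mask] * nx + cc[mask]
    depth = np.asarray(bathy.values, dtype=float)[mask]
    sums = np.bincount(lin, weights=depth, minlength=ny * nx)
    cnts = np.bincount(lin, minlength=ny * nx)
    has = cnts > 0
    valid = has & np.isfinite(field.z.ravel())
    if valid.sum() < 3:
        raise DataError("fewer than 3 overlapping cells: insufficient data")
    mean_depth = np.full(ny * nx, np.nan)
    mean_depth[has] = sums[has] / cnts[has]
    df = pd.DataFrame(
        {"mean_depth": mean_depth[valid], "z": field.z.ravel()[valid]}
    )
    r = float(np.corrcoef(df["mean_depth"], df["z"])[0, 1])
    return df, r


def aspect_polar(
    objects: pd.DataFrame,
    bathy: RasterGrid,
    classes: tuple[str, ...] = ("LCN", "SPG"),
    n_bins: int = 36,
) -> dict[str, pd.DataFrame]:
    """Circular histogram of flank aspect at target-object centroids.

    Returns, per class, a table with bin start angle, object count and
    area-weighted count; flat-flagged centroids are excluded and reported in
    the table attrs.
    """
    _, aspect, flat = slope_aspect(bathy)
    width = 360.0 / n_bins
    out = {}
    for code in classes:
        sel = objects[objects["class"] == code]
        if len(sel) == 0:
            warnings.warn(f"no objects of class {code} for polar histogram",
                          stacklevel=2)
        counts = np.zeros(n_bins)
        areas = np.zeros(n_bins)
        n_flat = 0
        for _, row in sel.iterrows():
            cen = row["geometry"].centroid
            r, c = bathy.world_to_pixel(cen.x, cen.y)
            r = int(np.clip(r, 0, bathy.rows - 1))
            c = int(np.clip(c, 0, bathy.cols - 1))
            if flat[r, c]:
                n_flat += 1
                continue
            b = int(aspect[r, c] // width) % n_bins
            counts[b] += 1
            areas[b] += row["geometry"].area
        df = pd.DataFrame(
            {"bin_start_deg": np.arange(n_bins) * width, "count": counts,
             "area": areas}
        )
        df.attrs["n_flat_excluded"] = n_flat
        out[code] = df
    return out
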