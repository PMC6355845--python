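"""Raster and vector I/O.

Rasters are GeoTIFFs: a plain TIFF carrying the standard georeferencing
tags (ModelPixelScale, ModelTiepoint, GDAL_NODATA) plus a JSON image
description with band names.  Files without georeferencing are rejected
explicitly rather than silently assuming a transform.  Vectors are GeoJSON
feature collections (shapely geometries + attribute dicts); polygon winding
is normalised to counter-clockwise shells on write.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import mapping, shape
from shapely.geometry.polygon import orient

from .grid import DataError, RasterGrid

__all__ = ["read_raster", "write_raster", "read_vector", "write_vector"]

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


def write_raster(grid: RasterGrid, path) -> None:
    """Write a RasterGrid as a georeferenced TIFF."""
    path = Path(path)
    desc = json.dumps(
        {"band_names": list(grid.band_names), "crs": "local-metric"}
    )
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (grid.cell_size, grid.cell_size, 0.0), True),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, grid.origin_x, grid.origin_y, 0.0), True),
    ]
    if grid.nodata is not None:
        extratags.append((_TAG_GDAL_NODATA, "s", 0, str(grid.nodata), True))
    photometric = "rgb" if (grid.values.ndim == 3 and grid.values.shape[2] == 3) else "minisblack"
    tifffile.imwrite(
        path,
        np.ascontiguousarray(grid.values),
        photometric=photometric,
        description=desc,
        extratags=extratags,
    )


def read_raster(path) -> RasterGrid:
    """Read a georeferenced TIFF; error if the georeferencing tags are absent."""
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        tags = page.tags
        if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
            raise DataError(f"{path}: no georeference (missing GeoTIFF tags)")
        scale = tags[_TAG_PIXEL_SCALE].value
        tie = tags[_TAG_TIEPOINT].value
        if abs(scale[0] - scale[1]) > 1e-12:
            raise DataError(f"{path}: non-square pixels are not supported")
        values = page.asarray()
        band_names: tuple = ()
        nodata = None
        desc = tags.get("ImageDescription")
        if desc is not None:
            try:
                meta = json.loads(desc.value)
                band_names = tuple(meta.get("band_names", ()))
            except (ValueError, TypeError):
                pass
        if _TAG_GDAL_NODATA in tags:
            nodata = float(tags[_TAG_GDAL_NODATA].value)
    # tiepoint maps raster (i, j) -> world (x, y); we write i = j = 0
    origin_x = tie[3] - tie[0] * scale[0]
    origin_y = tie[4] + tie[1] * scale[1]
    return RasterGrid(
        values,
        origin_x=float(origin_x),
        origin_y=float(origin_y),
        cell_size=float(scale[0]),
        nodata=nodata,
        band_names=band_names,
    )


# ---------------------------------------------------------------------------
# vectors (GeoJSON)
# ---------------------------------------------------------------------------


def _orient_geom(geom):
    if geom.geom_type == "Polygon":
        return orient(geom)
    if geom.geom_type == "MultiPolygon":
        from shapely.geometry import MultiPolygon

        return MultiPolygon([orient(p) for p in geom.geoms])
    return geom


def write_vector(objects: pd.DataFrame, path) -> None:
    """Write a GeoJSON FeatureCollection from a table with a geometry column."""
    path = Path(path)
    features = []
    attr_cols = [c for c in objects.columns if c != "geometry"]
    for oid, row in objects.iterrows():
        props = {}
        for c in attr_cols:
            v = row[c]
            if isinstance(v, (np.integer,)):
                v = int(v)
            elif isinstance(v, (np.floating,)):
                v = float(v)
            elif isinstance(v, (np.bool_,)):
                v = bool(v)
            props[c] = v
        props["_id"] = int(oid) if isinstance(oid, (int, np.integer)) else oid
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(_orient_geom(row["geometry"])),
                "properties": props,
            }
        )
    doc = {"type": "FeatureCollection", "features": features}
    path.write_text(json.dumps(doc))


def read_vector(path) -> pd.DataFrame:
    """Read a GeoJSON FeatureCollection into a table with a geometry column."""
    path = Path(path)
    doc = json.loads(path.read_text())
    if doc.get("type") != "FeatureCollection":
        raise DataError(f"{path}: not a GeoJSON FeatureCollection")
    records = []
    index = []
    for i, feat in enumerate(doc.get("features", [])):
        props = dict(feat.get("properties") or {})
        oid = props.pop("_id", i)
        geom = feat.get("geometry")
        if geom is None:
            raise DataError(f"{path}: feature {oid} has no geometry")
        props["geometry"] = shape(geom)
        records.append(props)
        index.append(oid)
    if not records:
        return pd.DataFrame(columns=["geometry"])
    return pd.DataFrame(records, index=index)
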