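"""Spatial statistics on the classified objects.

Per-model zonation tables, Gi* hotspot fields for LCN and SPG (with the
Z-score vs depth scatter) and the aspect polar histograms, plus the
reference-table zonation worked example.

Usage: python analysis/05_zonation_hotspots.py [--scene results/scene]
       [--segmentation results/segmentation]
       [--predictions results/classification/predictions.csv]
       [--outdir results/stats]
"""

import argparse
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from mobia.classification import MODEL_KINDS
from mobia.io import read_raster, read_vector, write_vector
from mobia.reference import load_reference_zonation
from mobia.spatial_stats import (
    aspect_polar,
    format_zonation,
    hotspot_gi_star,
    zonation_from_aggregates,
    zonation_stats,
    zscore_depth_scatter,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--scene", default="results/scene")
    ap.add_argument("--segmentation", default="results/segmentation")
    ap.add_argument("--predictions", default="results/classification/predictions.csv")
    ap.add_argument("--outdir", default="results/stats")
    ap.add_argument("--cell", type=float, default=1.0)
    ap.add_argument("--band", type=float, default=3.0)
    args = ap.parse_args()

    out = Path(args.outdir)
    out.mkdir(parents=True, exist_ok=True)

    # reference worked example (the survey's own table arithmetic)
    for method in ("DNN", "LR", "RF"):
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            table = zonation_from_aggregates(load_reference_zonation(method))
        format_zonation(table).to_csv(out / f"reference_zonation_{method}.csv")
        for w in caught:
            print(f"reference {method}: {w.message}")

    bathy = read_raster(Path(args.scene) / "bathy.tif")
    boundary = read_vector(Path(args.scene) / "boundary.geojson")["geometry"].iloc[0]
    polys = read_vector(Path(args.segmentation) / "segments.geojson")
    preds = pd.read_csv(args.predictions, index_col=0)

    for kind in MODEL_KINDS:
        classified = pd.DataFrame({
            "class": preds[f"class_{kind}"].to_numpy(),
            "geometry": polys["geometry"].to_numpy(),
        })
        format_zonation(zonation_stats(classified, boundary)).to_csv(
            out / f"zonation_{kind}.csv")

    primary = MODEL_KINDS[-1]
    classified = pd.DataFrame({
        "class": preds[f"class_{primary}"].to_numpy(),
        "geometry": polys["geometry"].to_numpy(),
    })
    for code in ("LCN", "SPG"):
        field = hotspot_gi_star(classified, code, args.cell, args.band,
                                extent=bathy.extent, mound_context=boundary)
        cells = field.to_frame()
        hot = cells[cells["conf"] > 0]
        geoms = [field.cell_polygon(int(r), int(c))
                 for r, c in zip(*np.unravel_index(hot.index, field.shape))]
        gdf = hot.reset_index(drop=True).drop(columns=["x", "y"])
        gdf["geometry"] = geoms
        write_vector(gdf, out / f"hotspot_{code}.geojson")
        scatter, r = zscore_depth_scatter(field, bathy)
        scatter.to_csv(out / f"zscatter_{code}.csv", index=False)
        (out / f"zscatter_{code}_r.json").write_text(
            json.dumps({"pearson_r": r}))
        print(f"{code}: {int((hot['conf'] == 99).sum())} cells at 99%, "
              f"Z-depth r = {r:.3f}")

    polar = aspect_polar(classified, bathy, ("LCN", "SPG"))
    pd.concat(polar, names=["class", "bin"]).to_csv(out / "polar.csv")
    print(f"written to {out}")


if __name__ == "__main__":
    main()
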