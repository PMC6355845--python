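"""Segment the mosaic, optionally running the ESP scale sweep first.

With --esp, sweeps the given scales, prints LV / ROC-LV and applies the
a-priori rule: the analysis scale is the local ROC-LV maximum with the
highest ROC-LV.  Without --esp, segments at --scale (default 150, the scale
the rule selected on the reference synthetic scene; see docs/methods.md).

Usage: python analysis/02_segment.py [--scene results/scene]
       [--outdir results/segmentation] [--scale 150] [--esp] [--scales 50:400:50]
"""

import argparse
from pathlib import Path

from mobia.io import read_raster, write_raster, write_vector
from mobia.segmentation import (
    SegmentationParams,
    esp_scale,
    segment,
    segments_to_polygons,
)

import pandas as pd


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--scene", default="results/scene")
    ap.add_argument("--outdir", default="results/segmentation")
    ap.add_argument("--scale", type=float, default=150.0)
    ap.add_argument("--esp", action="store_true",
                    help="run the ESP sweep and select the scale from it")
    ap.add_argument("--scales", default="50:400:50", help="start:stop:step")
    args = ap.parse_args()

    out = Path(args.outdir)
    out.mkdir(parents=True, exist_ok=True)
    mosaic = read_raster(Path(args.scene) / "mosaic.tif")

    scale = args.scale
    if args.esp:
        start, stop, step = (float(v) for v in args.scales.split(":"))
        scales = [start + i * step for i in range(int((stop - start) / step) + 1)]
        curve = esp_scale(mosaic, scales)
        curve.to_csv(out / "esp_curve.csv", index=False)
        print(curve.to_string(index=False))
        candidates = curve[curve["is_candidate"]]
        scale = float(candidates.loc[candidates["roc_lv"].idxmax(), "scale"])
        print(f"a-priori rule selects scale {scale:g}")

    segmap = segment(mosaic, SegmentationParams(scale=scale))
    write_raster(segmap.labels, out / "segments.tif")
    polys = segments_to_polygons(segmap)
    write_vector(
        pd.DataFrame({"geometry": [g for _, g in polys]},
                     index=[i for i, _ in polys]),
        out / "segments.geojson",
    )
    print(f"scale {scale:g}: {segmap.n_segments} segments -> {out}")


if __name__ == "__main__":
    main()
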