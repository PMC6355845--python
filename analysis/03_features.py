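"""Extract per-object features and majority ground-truth labels.

Usage: python analysis/03_features.py [--scene results/scene]
       [--segmentation results/segmentation] [--out results/features.csv]
"""

import argparse
from pathlib import Path

from mobia.classes import DEFAULT_SCHEME
from mobia.features import build_feature_table, segment_majority_class
from mobia.io import read_raster
from mobia.segmentation import SegmentationParams, segment


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--scene", default="results/scene")
    ap.add_argument("--segmentation", default="results/segmentation")
    ap.add_argument("--scale", type=float, default=150.0,
                    help="used to rebuild segment statistics from the mosaic")
    ap.add_argument("--out", default="results/features.csv")
    args = ap.parse_args()

    scene = Path(args.scene)
    mosaic = read_raster(scene / "mosaic.tif")
    bathy = read_raster(scene / "bathy.tif")
    backscatter = read_raster(scene / "backscatter.tif")
    class_map = read_raster(scene / "class_map.tif")

    # the label raster alone cannot recreate merge statistics, so the
    # (deterministic) segmentation is recomputed at the analysis scale
    segmap = segment(mosaic, SegmentationParams(scale=args.scale))
    labels = segment_majority_class(segmap, class_map, DEFAULT_SCHEME)
    table = build_feature_table(segmap, mosaic, bathy, backscatter, labels)

    out = Path(args.out)
    out.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(out)
    print(f"{len(table)} objects x {table.shape[1]} columns -> {out}")


if __name__ == "__main__":
    main()
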