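"""Generate the default synthetic mound scene.

Writes mosaic, bathymetry, backscatter, ground-truth class map and the
slope-break mound boundary to results/scene/.

Usage: python analysis/01_simulate.py [--seed 0] [--outdir results/scene]
"""

import argparse
from pathlib import Path

from mobia.classes import DEFAULT_SCHEME
from mobia.io import write_raster, write_vector
from mobia.pipeline import stage_seed
from mobia.synthetic import SceneSpec, generate_scene

import pandas as pd


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", default="results/scene")
    args = ap.parse_args()

    out = Path(args.outdir)
    out.mkdir(parents=True, exist_ok=True)
    spec = SceneSpec(seed=stage_seed(args.seed, "simulate"))
    scene = generate_scene(spec, DEFAULT_SCHEME)

    write_raster(scene.mosaic, out / "mosaic.tif")
    write_raster(scene.bathy, out / "bathy.tif")
    write_raster(scene.backscatter, out / "backscatter.tif")
    write_raster(scene.class_map, out / "class_map.tif")
    write_vector(
        pd.DataFrame({"geometry": [scene.boundary]}), out / "boundary.geojson"
    )
    print(f"scene written to {out} "
          f"({scene.mosaic.rows}x{scene.mosaic.cols} px mosaic, "
          f"boundary area {scene.boundary.area:.2f} m2)")


if __name__ == "__main__":
    main()
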