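"""End-to-end pipeline: simulate -> segment -> features -> classify -> stats.

A :class:`PipelineConfig` (YAML-serialisable, unknown keys rejected) drives
all stages; one global seed feeds a documented per-stage derivation
(``SeedSequence((seed, stage_id))``) so each stage is independently
reproducible and adding a stage never perturbs the others.  Each run writes
a manifest with the config hash, package versions and SHA-256 checksums of
every output, so two runs with equal config + seed can be compared
byte-for-byte.  With ``resume=True`` stages whose outputs already exist are
loaded instead of recomputed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classes import DEFAULT_SCHEME
from .classification import (
    evaluate,
    make_training_set,
    predict,
    split_train_test,
    train,
)
from .features import build_feature_table, segment_majority_class
from .grid import ConfigurationError
from .io import read_raster, write_raster, write_vector
from .segmentation import SegmentationParams, esp_scale, segment, segments_to_polygons
from .spatial_stats import (
    aspect_polar,
    format_zonation,
    hotspot_gi_star,
    zonation_stats,
    zscore_depth_scatter,
)
from .synthetic import SceneSpec, generate_scene, mound_boundary

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed"]

_STAGE_IDS = {
    "simulate": 0,
    "esp": 1,
    "segment": 2,
    "features": 3,
    "sample": 4,
    "split": 5,
    "train": 6,
    "stats": 7,
}


def stage_seed(global_seed: int, stage: str, extra: int = 0) -> int:
    """Derived per-stage seed, kept below 2**31."""
    ss = np.random.SeedSequence(entropy=int(global_seed),
                                spawn_key=(_STAGE_IDS[stage], extra))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "runs/default"
    simulate: bool = True
    scene: dict = field(default_factory=dict)  # SceneSpec overrides
    paths: dict = field(default_factory=dict)  # inputs when simulate is false
    # default analysis scale for the default scene, selected by the ESP
    # rate-of-change rule (docs/methods.md); the library-level
    # SegmentationParams default is independent of any particular scene
    segmentation: dict = field(default_factory=lambda: {"scale": 150.0})
    esp_scales: list = field(default_factory=list)  # empty = skip ESP
    per_class: int = 150
    train_fraction: float = 0.15
    # "pool": split the balanced sample (leaks duplicates when classes are
    # scarce); "all": stratified split of every labelled object; "balanced":
    # stratified split of every object, then the training side is resampled
    # to per_class rows per class (no train/test leakage)
    split_source: str = "balanced"
    models: list = field(default_factory=lambda: ["LR", "RF", "DNN"])
    hyper: dict = field(default_factory=dict)  # per model kind
    hotspot_classes: list = field(default_factory=lambda: ["LCN", "SPG"])
    hotspot_cell: float = 1.0
    hotspot_band: float = 3.0
    boundary_slope_deg: float = 10.0
    polar_bins: int = 36

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def config_hash(self) -> str:
        # outdir does not affect the computation, so it is excluded: the
        # same run written to two places hashes identically
        d = {k: v for k, v in self.to_dict().items() if k != "outdir"}
        return hashlib.sha256(
            yaml.safe_dump(d, sort_keys=True).encode()
        ).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, resume: bool = False) -> Path:
    """Execute the configured pipeline; returns the run directory."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    scheme = DEFAULT_SCHEME
    outputs: list[Path] = []

    def done(*names):
        return all((out / n).exists() for n in names)

    # -- simulate or load inputs -------------------------------------------
    stage = "simulate"
    try:
        if config.simulate:
            spec = SceneSpec(**{**config.scene, "seed": stage_seed(config.seed, "simulate")})
            raster_names = ["mosaic.tif", "bathy.tif", "backscatter.tif", "class_map.tif"]
            if resume and done(*raster_names, "boundary.geojson"):
                mosaic = read_raster(out / "mosaic.tif")
                bathy = read_raster(out / "bathy.tif")
                backscatter = read_raster(out / "backscatter.tif")
                class_map = read_raster(out / "class_map.tif")
                boundary = mound_boundary(bathy, config.boundary_slope_deg)
            else:
                scene = generate_scene(spec, scheme, config.boundary_slope_deg)
                mosaic, bathy = scene.mosaic, scene.bathy
                backscatter, class_map = scene.backscatter, scene.class_map
                boundary = scene.boundary
                write_raster(mosaic, out / "mosaic.tif")
                write_raster(bathy, out / "bathy.tif")
                write_raster(backscatter, out / "backscatter.tif")
                write_raster(class_map, out / "class_map.tif")
                write_vector(
                    pd.DataFrame({"geometry": [boundary]}), out / "boundary.geojson"
                )
                sidecar = {**dataclasses.asdict(spec)}
                sidecar.pop("styles", None)
                (out / "scene.yaml").write_text(yaml.safe_dump(sidecar, sort_keys=True))
            outputs += [out / n for n in raster_names] + [out / "boundary.geojson"]
        else:
            mosaic = read_raster(config.paths["mosaic"])
            bathy = read_raster(config.paths["bathy"])
            backscatter = (
                read_raster(config.paths["backscatter"])
                if config.paths.get("backscatter")
                else None
            )
            class_map = (
                read_raster(config.paths["class_map"])
                if config.paths.get("class_map")
                else None
            )
            boundary = mound_boundary(bathy, config.boundary_slope_deg)

        # -- optional ESP ----------------------------------------------------
        stage = "esp"
        if config.esp_scales:
            curve = esp_scale(mosaic, config.esp_scales,
                              SegmentationParams(**{"scale": 1, **config.segmentation})
                              if config.segmentation else None)
            pd.DataFrame(
                {"scale": curve.scales, "lv": curve.lv, "roc_lv": curve.roc_lv}
            ).to_csv(out / "esp.csv", index=False)
            outputs.append(out / "esp.csv")

        # -- segmentation ------------------------------------------------------
        stage = "segment"
        params = SegmentationParams(**config.segmentation)
        segmap = segment(mosaic, params)
        write_raster(segmap.labels, out / "segments.tif")
        outputs.append(out / "segments.tif")
        polys = segments_to_polygons(segmap)

        # -- features ----------------------------------------------------------
        stage = "features"
        labels = (
            segment_majority_class(segmap, class_map, scheme)
            if class_map is not None
            else None
        )
        table = build_feature_table(segmap, mosaic, bathy, backscatter, labels)
        table.to_csv(out / "features.csv")
        outputs.append(out / "features.csv")

        # -- sample, split, train, classify, evaluate --------------------------
        stage = "train"
        if labels is None:
            raise ConfigurationError("classification requires ground-truth labels")
        if config.split_source == "pool":
            pool = make_training_set(
                table, labels, config.per_class,
                stage_seed(config.seed, "sample"), scheme,
            )
            train_set, test_set = split_train_test(
                pool, config.train_fraction, stage_seed(config.seed, "split")
            )
        elif config.split_source in ("all", "balanced"):
            from .classification import LabelledSet
            from .features import FEATURE_COLUMNS

            keep = labels != scheme.excluded
            full = LabelledSet(
                np.asarray(table.index[keep]),
                table.loc[keep, FEATURE_COLUMNS].reset_index(drop=True),
                np.asarray(labels[keep]),
                scheme,
            )
            train_set, test_set = split_train_test(
                full, config.train_fraction, stage_seed(config.seed, "split")
            )
            if config.split_source == "balanced":
                rng = np.random.default_rng(stage_seed(config.seed, "sample"))
                picks = []
                scarce = []
                for code in scheme.codes:
                    idx = np.flatnonzero(train_set.labels == code)
                    if idx.size == 0:
                        raise ConfigurationError(
                            f"class {code} has no training objects"
                        )
                    if idx.size < config.per_class:
                        scarce.append(code)
                    picks.append(np.sort(rng.choice(
                        idx, size=config.per_class,
                        replace=idx.size < config.per_class,
                    )))
                if scarce:
                    warnings.warn(
                        f"classes {scarce} have fewer than {config.per_class} "
                        "training objects; resampled with replacement",
                        UserWarning, stacklevel=2,
                    )
                train_set = train_set.subset(np.concatenate(picks))
        else:
            raise ConfigurationError(
                "split_source must be 'pool', 'all' or 'balanced', got "
                f"{config.split_source!r}"
            )

        objects = pd.DataFrame(
            {"geometry": [g for _, g in polys]},
            index=pd.RangeIndex(len(polys), name="segment_id"),
        )
        objects["label"] = labels
        results = {}
        for kind in config.models:
            from .classification import MODEL_KINDS

            clf = train(
                kind, train_set, config.hyper.get(kind),
                stage_seed(config.seed, "train", MODEL_KINDS.index(kind)),
            )
            test_pred = predict(clf, test_set.features)
            cm, metrics = evaluate(np.asarray(test_pred.labels), test_set.labels, scheme)
            (out / f"metrics_{kind}.json").write_text(json.dumps(metrics.as_dict(), indent=2))
            cm.to_csv(out / f"confusion_{kind}.csv")
            outputs += [out / f"metrics_{kind}.json", out / f"confusion_{kind}.csv"]
            full_pred = predict(clf, table)
            objects[f"class_{kind}"] = full_pred.labels
            results[kind] = {"metrics": metrics, "confusion": cm, "pred": full_pred}

        write_vector(objects, out / "objects.geojson")
        outputs.append(out / "objects.geojson")

        # -- spatial statistics ------------------------------------------------
        stage = "stats"
        extent = mosaic.extent
        for kind in config.models:
            classified = objects.rename(columns={f"class_{kind}": "class"})[
                ["class", "geometry"]
            ]
            zon = zonation_stats(classified, boundary)
            format_zonation(zon).to_csv(out / f"zonation_{kind}.csv")
            outputs.append(out / f"zonation_{kind}.csv")
        primary = config.models[-1]
        classified = objects.rename(columns={f"class_{primary}": "class"})[
            ["class", "geometry"]
        ]
        for code in config.hotspot_classes:
            fld = hotspot_gi_star(
                classified, code, config.hotspot_cell, config.hotspot_band,
                extent=extent, mound_context=boundary,
            )
            cells = fld.to_frame()
            hot = cells[cells["conf"] > 0]
            geoms = [
                fld.cell_polygon(int(r), int(c))
                for r, c in zip(*np.unravel_index(hot.index, fld.shape))
            ]
            gdf = hot.reset_index(drop=True).drop(columns=["x", "y"])
            gdf["geometry"] = geoms
            write_vector(gdf, out / f"hotspot_{code}.geojson")
            scatter, r = zscore_depth_scatter(fld, bathy)
            scatter.to_csv(out / f"zscatter_{code}.csv", index=False)
            (out / f"zscatter_{code}_r.json").write_text(json.dumps({"pearson_r": r}))
            outputs += [
                out / f"hotspot_{code}.geojson",
                out / f"zscatter_{code}.csv",
                out / f"zscatter_{code}_r.json",
            ]
        polar = aspect_polar(classified, bathy, tuple(config.hotspot_classes),
                             config.polar_bins)
        polar_df = pd.concat(polar, names=["class", "bin"])
        polar_df.to_csv(out / "polar.csv")
        outputs.append(out / "polar.csv")
    except Exception as err:
        err.args = (f"[stage {stage}] {err}",) + err.args[1:] if err.args else (
            f"[stage {stage}]",
        )
        raise

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "checksums": {p.name: _sha256(p) for p in outputs if p.exists()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    config.to_yaml(out / "config.yaml")
    return out
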