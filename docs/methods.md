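# Methods

`mobia` implements a Marine Object-Based Image Analysis (MOBIA) pipeline for
facies mapping on cold-water coral mounds: a synthetic scene generator stands
in for a real photomosaic/multibeam survey, and the analysis chain segments
the mosaic into objects, describes each object with spectral / textural /
geometric / terrain features, classifies the objects with three supervised
models, and summarises the classified maps with zonation tables, Getis-Ord
Gi* hotspot fields, Z-score-depth correlation and aspect polar histograms.

## 1. Synthetic scene generator (`mobia.synthetic`)

One scene bundles four co-registered rasters and a boundary polygon:

- **Bathymetry** (0.25 m cells): a southward-deepening regional plane
  (`regional_slope`, default 0.04 m/m) plus an ovoid Gaussian mound
  (`mound_height` 4 m, sigma 2.5 m x 4 m, elongated north-south) and
  Gaussian noise (sd 0.02 m). Base depth −976 m.
- **Ground-truth class map** (8 mm cells) over eight classes: live coral
  framework (LCN), dead coral framework (DC), sponges (SPG), hemipelagic
  sediments (HEMS), the same with dropstones (HESDR), coral rubble (CRUB),
  pebbles (PEB) and an OTHER/shadow bucket that is generated but excluded
  from training and metrics. Zonation rules: the mound core is a DC/CRUB
  mixture; LCN patches are placed only where the flank aspect lies in the
  northern sector (±45°); SPG blobs sit near the summit and upper west
  flank; the off-mound background is HEMS/HESDR with PEB scattered
  preferentially south.
- **RGB mosaic** (8 mm cells): per-class mean colours around mid-grey
  (separation scaled by `contrast`, default 1.0) plus per-pixel noise and a
  broad illumination gradient.
- **Backscatter** (0.25 m cells): per-class acoustic levels (hard substrates
  brighter) with noise.
- **Mound boundary**: the largest closed region where slope exceeds a break
  angle (default 10°), mimicking a topographic-break delineation.

The default scene is 12 m x 16 m (1500 x 2000 mosaic pixels), which keeps
the two-orders-of-magnitude resolution gap between optical and acoustic
data at desk scale. Generator defaults are study conditions and are never
adjusted to make downstream checks pass.

## 2. Multiresolution segmentation (`mobia.segmentation`)

Bottom-up pairwise region merging on the 4-connected region adjacency
graph. The fusion cost of merging segments *a* and *b* is

    f = w_color * Δh_color + (1 − w_color) * (w_cmpct * Δh_cmpct
                                              + (1 − w_cmpct) * Δh_smooth)

where `Δh_color` is the area-weighted increase in per-band standard
deviation (band weights equal by default), and the shape terms use
perimeter-based compactness `l/√n` and bounding-box smoothness `l/b`.
A merge is allowed iff `f < scale²`. Merging proceeds in deterministic
mutual-best-fitting sweeps (a pair merges when each is the other's
cheapest neighbour), with ties broken by lower cost then lower neighbour
id; segment ids are the minimum member pixel linear index, relabelled to a
contiguous range at the end. Defaults: `color_weight` 0.9,
`compactness_weight` 0.5, `scale` 400.

### Scale selection (ESP)

`esp_scale` computes, per candidate scale, the local variance LV (mean over
segments of the segment's mean per-band standard deviation) and its rate of
change ROC-LV = 100·(LV_i − LV_{i−1})/LV_{i−1}; candidate scales are local
ROC-LV maxima. The package's a-priori selection rule — fixed before any
classification outcome was inspected — is: **the analysis scale is the
candidate with the highest ROC-LV**.

On the reference synthetic scene, sweeping scales 50..400 (step 50) gives

| scale | 50 | 100 | 150 | 200 | 250 | 300 | 350 | 400 |
|---|---|---|---|---|---|---|---|---|
| segments | 343 | 243 | 188 | 141 | 103 | 73 | 43 | 32 |
| LV | 6.37 | 7.28 | 8.66 | 9.98 | 10.96 | 12.02 | 13.99 | 16.10 |
| ROC-LV | — | 14.25 | **18.93** | 15.24 | 9.82 | 9.68 | 16.38 | 15.14 |

Local maxima sit at 150 and 350; the rule selects **150** (188 segments,
every class represented). Very coarse scales over-merge this scene — the
sponge patches sit on the rubble core with low colour contrast and are
absorbed into it — so the analysis scripts and the acceptance run use
scale 150, while the library default stays 400.

## 3. Object features (`mobia.features`)

21 canonical columns per object (`FEATURE_COLUMNS`), plus `label`, quality
flags and `border_length`:

- **Spectral**: per-band means `mean_red/green/blue` and `brightness` =
  sum of band means.
- **Texture** (GLCM): grey-level co-occurrence matrix on a global min-max
  quantisation to 32 levels of the backscatter grid (luminance fallback),
  symmetric, distance 1, averaged over the four offsets, restricted to
  pixel pairs inside the same object footprint. Reported: homogeneity
  Σ p/(1+(i−j)²), entropy −Σ p ln p (nats), GLCM mean Σ i·p. Objects too
  small on the coarse grid to yield a pair fall back to homogeneity 1 /
  entropy 0 and are flagged `glcm_single`.
- **Shape** (from the pixel-index covariance eigenvalues λ1 ≥ λ2 and the
  exposed-edge perimeter *e*): area, compactness e²/(4πn), roundness
  4πn/e², density √n/(1+√(λ1+λ2)), asymmetry 1−λ2/λ1, shape_index e/(4√n),
  border_index = e / perimeter of the oriented minimum bounding rectangle
  (rotating calipers, floored at 1), rectangular_fit / elliptic_fit against
  the moment-matched rectangle / ellipse, main_direction = λ1-eigenvector
  orientation clockwise from north folded to [0, 180).
- **Terrain** (Horn 3x3 on the bathymetry, evaluated over the bathy cells
  whose centres fall inside the object; centroid-cell fallback for
  slivers): mean_depth, slope (deg), aspect (deg clockwise from north,
  direction of steepest descent, circular mean across cells; cells flatter
  than 1e−6° are excluded and an object that is entirely flat is flagged
  `aspect_flat`), curvature (Laplacian / cell²).

Ground-truth object labels are the majority ground-truth class of the
object's pixels (ties to the lower class id).

## 4. Classification (`mobia.classification`)

Three scikit-learn models behind one interface: multinomial logistic
regression (L2, C=1), random forest (100 trees, √p features) and a
multilayer perceptron "DNN" (two 64-unit ReLU layers, adam, batch 32, up to
200 epochs). Features are standardised on the training set. Predicted
probabilities are reindexed to the full 7-class scheme (absent classes get
probability 0) and ties resolve to the first class in scheme order.

Split protocols (`split_source`):

- **pool**: sample 150 objects per class with replacement, then split
  15/85 stratified. This is the survey-style protocol; with few objects
  per class it duplicates rows across train and test, which inflates
  held-out scores. Kept for comparability, not used for acceptance.
- **all**: stratified split of all labelled objects.
- **balanced** (used by the analysis scripts and acceptance): stratified
  split of all labelled objects first, then only the training side is
  resampled to `per_class` rows per class (with replacement only when a
  class is scarce, with a warning). Balanced training, leak-free test set.

Metrics (implemented by hand, cross-checked against scikit-learn in the
tests): overall accuracy; average accuracy (mean one-vs-rest binary
accuracy); micro precision/recall (= overall accuracy for single-label
multiclass); macro precision/recall averaged over all 7 scheme classes
with zero-division counted as 0 and such classes reported in
`undefined_precision_classes`.

## 5. Spatial statistics (`mobia.spatial_stats`)

- **Zonation table**: per class, total area, object count, mean object
  area, % of total area, area inside the mound boundary (by polygon
  intersection, not centroid rule) and % of mound area, plus a TOTAL row.
  `zonation_from_aggregates` runs the same arithmetic from externally
  printed totals and warns on geometrically impossible rows (mound area
  exceeding class total) instead of hiding them.
- **Gi\* hotspots**: the classified polygons' target-class area is binned
  onto a fishnet (default 1 m cells over the scene extent); Gi* Z-scores
  use binary distance-band weights (default band 3 m, self included) and
  all fishnet cells as the population. Confidence bins 90/95/99% at
  |Z| > 1.645/1.960/2.576.
- **Z-score vs depth**: per fishnet cell, mean bathymetric depth of the
  bathy cells inside it against the cell's Z-score; Pearson r.
- **Aspect polar histograms**: circular histogram (default 36 bins) of the
  flank aspect at target-object centroids; flat cells are excluded and
  counted.

## 6. Pipeline, seeds and determinism (`mobia.pipeline`)

`run_pipeline(PipelineConfig)` chains simulate → segment → (optional ESP)
→ features → train/evaluate (LR, RF, DNN) → zonation/hotspot/polar
statistics, writing GeoTIFF/GeoJSON/CSV/JSON outputs plus a manifest with
SHA-256 checksums of every artefact and a hash of the config (output
directory excluded). Runs are bit-reproducible for a fixed config.

Every random draw is derived from the single global seed through
`numpy.random.SeedSequence(global_seed, spawn_key=(stage_id, extra))`,
reduced below 2³¹: the simulate / sample / split / train stages each get
an independent stream, and per-model train seeds use the model's index.
Changing one stage's seed therefore never perturbs another stage.

Problem sizes (scene dimensions, per-class sample counts, fishnet cell and
band sizes) are the package's own desk-scale choices; they are set in
`SceneSpec` and `PipelineConfig` defaults and recorded in each run's
`config.yaml`.

### Generator realism and limits

The generator reproduces the *structure* that the spatial statistics are
meant to detect (north-sector live coral, summit sponges, southward pebble
drift, a slope-break mound boundary) but is deliberately simple: colours
are Gaussian around class means, no occlusion/shadow geometry, no spatially
correlated mosaic noise, and the acoustic classes are separated more
cleanly than in real surveys. Accuracy numbers on synthetic scenes are
therefore upper bounds, not survey estimates.
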