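"""Seeded synthetic benthic scenes for a cold-water coral mound.

Generates co-registered rasters that emulate the statistical structure of a
reef-scale survey of a small, current-aligned, ovoid coral mound: a
bathymetry grid (metres, negative down), an RGB video-mosaic raster two
orders of magnitude finer, a backscatter intensity grid, a ground-truth
facies label raster and the mound-boundary polygon derived from the
topographic break.

The facies zonation encodes the field pattern the pipeline is meant to
recover: the mound core is coral rubble with dead-coral framework patches,
live coral colonies settle only on the north-facing flank, sponges cluster
near the summit and upper western flank, and the off-mound seabed is
hemipelagic sediment with dropstone patches and pebbles scattered
preferentially to the south.

Every output is a pure function of (spec, seed).  Sub-generators draw from
seeds derived as ``SeedSequence(seed, spawn_key=(stage,))`` with a fixed
stage table, so adding a raster type never perturbs earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely.geometry import Point, Polygon
from shapely.ops import unary_union
from skimage import measure

from .classes import DEFAULT_SCHEME, ClassScheme
from .grid import ConfigurationError, DataError, RasterGrid, slope_aspect

__all__ = [
    "ClassStyle",
    "SceneSpec",
    "Scene",
    "generate_bathymetry",
    "generate_class_map",
    "render_mosaic",
    "generate_backscatter",
    "mound_boundary",
    "generate_scene",
    "class_fractions",
    "EmptyBoundaryError",
]

_STAGE_SEEDS = {"bathy": 0, "class_map": 1, "mosaic": 2, "backscatter": 3}


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_STAGE_SEEDS[stage],))
    )


class EmptyBoundaryError(DataError):
    """No cell exceeds the slope threshold: no topographic break to trace."""


@dataclass(frozen=True)
class ClassStyle:
    """Rendering and acoustic parameters of one facies class.

    color:     mean RGB of the class in the mosaic (0-255).
    noise_sd:  white per-pixel colour noise (DN).
    pattern:   structural texture kind ("none", "blotch", "speckle",
               "dropstones", "disc") with amplitude ``pattern_amp`` (DN) and
               correlation length ``grain_m`` (metres).
    bs_mean / bs_sd:  backscatter intensity statistics (dB-like units);
               hard substrates return brighter (less negative) than sediments.
    """

    color: tuple[float, float, float]
    noise_sd: float = 6.0
    pattern: str = "none"
    pattern_amp: float = 0.0
    grain_m: float = 0.05
    bs_mean: float = -25.0
    bs_sd: float = 3.0


def _default_styles() -> dict[str, ClassStyle]:
    return {
        "LCN": ClassStyle((235, 120, 130), 6, "blotch", 25, 0.04, -18.0, 4.0),
        "DC": ClassStyle((130, 120, 110), 6, "blotch", 22, 0.05, -16.0, 4.0),
        "SPG": ClassStyle((250, 245, 210), 5, "disc", 8, 0.04, -20.0, 3.0),
        "HEMS": ClassStyle((175, 165, 140), 6, "none", 0, 0.10, -32.0, 1.5),
        "HESDR": ClassStyle((170, 160, 135), 6, "dropstones", 60, 0.08, -26.0, 5.0),
        "CRUB": ClassStyle((200, 195, 185), 8, "speckle", 8, 0.01, -17.0, 3.0),
        "PEB": ClassStyle((95, 95, 100), 5, "blotch", 8, 0.03, -14.0, 3.0),
        "OTHER": ClassStyle((30, 30, 35), 4, "none", 0, 0.05, -30.0, 2.0),
    }


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic mound scene.

    Desk-scale defaults: a 12 m x 16 m scene, mosaic at 8 mm (1500 x 2000
    pixels) and bathymetry at 0.25 m, preserving the two-orders-of-magnitude
    resolution gap between optic and acoustic data without gigapixel rasters.
    """

    width_m: float = 12.0
    height_m: float = 16.0
    mosaic_cell: float = 0.008
    bathy_cell: float = 0.25
    base_depth: float = -976.0
    mound_height: float = 4.0
    mound_sigma_x: float = 2.5
    mound_sigma_y: float = 4.0  # ovoid: elongated along the N-S current axis
    regional_slope: float = 0.04  # m/m, deepening southward
    bathy_noise_sd: float = 0.02
    contrast: float = 1.0  # scales class colour separation about mid-grey

    # patch counts and radii (metres)
    n_lcn: int = 12
    lcn_radius: tuple[float, float] = (0.14, 0.24)
    n_spg: int = 14
    spg_radius: tuple[float, float] = (0.10, 0.20)
    n_dc: int = 10
    dc_radius: tuple[float, float] = (0.40, 0.90)
    n_peb: int = 40
    peb_radius: tuple[float, float] = (0.06, 0.12)
    n_hesdr: int = 8
    hesdr_radius: tuple[float, float] = (0.50, 1.20)
    n_other: int = 3
    min_patches: int = 1

    # zonation geometry
    north_sector_deg: float = 45.0  # half-width of the LCN aspect sector
    sector_margin_deg: float = 15.0  # placement keeps this margin inside it
    core_bell_frac: float = 0.35  # bell fraction defining the mound core
    seed: int = 0

    styles: dict = field(default_factory=_default_styles)

    def __post_init__(self):
        if self.mosaic_cell <= 0 or self.bathy_cell <= 0:
            raise ConfigurationError("cell sizes must be positive")
        if self.mosaic_cell > self.bathy_cell:
            raise ConfigurationError("mosaic_cell must be <= bathy_cell")
        if self.mound_height < 0:
            raise ConfigurationError("mound_height must be >= 0")
        if self.base_depth >= 0:
            raise ConfigurationError("base_depth must be negative (metres below sea level)")
        for cell in (self.mosaic_cell, self.bathy_cell):
            for ext in (self.width_m, self.height_m):
                if abs(ext / cell - round(ext / cell)) > 1e-9:
                    raise ConfigurationError(
                        f"extent {ext} m not divisible into whole {cell} m pixels"
                    )

    def grid_shape(self, cell: float) -> tuple[int, int]:
        return int(round(self.height_m / cell)), int(round(self.width_m / cell))


def _smooth_noise(rng, shape, sigma_px, sd):
    """Seeded zero-mean smooth noise field with the requested pointwise sd."""
    if sd == 0:
        return np.zeros(shape)
    white = rng.standard_normal(shape)
    if sigma_px > 0:
        f = ndimage.gaussian_filter(white, sigma_px, mode="reflect")
        s = f.std()
        if s > 0:
            f /= s
    else:
        f = white
    return f * sd


def _bell(spec: SceneSpec, x, y_from_top):
    """Unit bell (0..1) of the mound at local coordinates (metres)."""
    dx = x - spec.width_m / 2.0
    dy = y_from_top - spec.height_m / 2.0
    return np.exp(
        -(dx**2 / (2 * spec.mound_sigma_x**2) + dy**2 / (2 * spec.mound_sigma_y**2))
    )


def _local_coords(spec: SceneSpec, cell: float):
    rows, cols = spec.grid_shape(cell)
    x = (np.arange(cols) + 0.5) * cell
    y = (np.arange(rows) + 0.5) * cell  # from the top (northern) edge
    return np.meshgrid(x, y)


def generate_bathymetry(spec: SceneSpec) -> RasterGrid:
    """Depth plane: base + regional southward dip + ovoid bell + smooth noise."""
    x, y = _local_coords(spec, spec.bathy_cell)
    depth = (
        spec.base_depth
        - spec.regional_slope * (y - spec.height_m / 2.0)
        + spec.mound_height * _bell(spec, x, y)
    )
    rng = _rng(spec.seed, "bathy")
    depth = depth + _smooth_noise(rng, depth.shape, 1.5, spec.bathy_noise_sd)
    grid = RasterGrid(
        depth.astype(np.float64),
        origin_x=0.0,
        origin_y=spec.height_m,
        cell_size=spec.bathy_cell,
        band_names=("depth",),
    )
    if spec.mound_height > 0:
        r, c = np.unravel_index(np.argmax(grid.values), grid.values.shape)
        if _bell(spec, (c + 0.5) * spec.bathy_cell, (r + 0.5) * spec.bathy_cell) < 0.5:
            raise DataError("shallowest cell fell off the mound; lower bathy_noise_sd")
    return grid


# ---------------------------------------------------------------------------
# class map
# ---------------------------------------------------------------------------


def _upsample_to_mosaic(spec: SceneSpec, coarse: np.ndarray) -> np.ndarray:
    """Nearest-neighbour lookup of a bathy-grid field on the mosaic grid."""
    rows, cols = spec.grid_shape(spec.mosaic_cell)
    ratio = spec.mosaic_cell / spec.bathy_cell
    rb = np.minimum(((np.arange(rows) + 0.5) * ratio).astype(int), coarse.shape[0] - 1)
    cb = np.minimum(((np.arange(cols) + 0.5) * ratio).astype(int), coarse.shape[1] - 1)
    return coarse[np.ix_(rb, cb)]


def _in_sector(aspect, centre_deg, half_width_deg):
    d = np.abs((aspect - centre_deg + 180.0) % 360.0 - 180.0)
    return d <= half_width_deg


def _paint_patches(rng, labels, eligible, class_id, count, radius_rng, cell,
                   min_sep_m=0.0, wobble=0.35):
    """Paint `count` wobbly disks of a class at seed pixels drawn from `eligible`.

    Returns the list of seed centres (row, col).  Raises ConfigurationError if
    the eligible region cannot host the requested count.
    """
    if count == 0:
        return []
    idx = np.flatnonzero(eligible)
    if idx.size == 0:
        raise ConfigurationError(
            f"scene too small: no eligible pixels for class id {class_id}"
        )
    rows, cols = labels.shape
    centres: list[tuple[int, int]] = []
    tries = 0
    while len(centres) < count:
        tries += 1
        if tries > 200 * count:
            raise ConfigurationError(
                f"scene too small: cannot place {count} patches of class id {class_id}"
            )
        k = int(rng.integers(idx.size))
        r0, c0 = divmod(int(idx[k]), cols)
        if min_sep_m > 0 and any(
            (r0 - r) ** 2 + (c0 - c) ** 2 < (min_sep_m / cell) ** 2 for r, c in centres
        ):
            continue
        rad_m = float(rng.uniform(*radius_rng))
        rad = rad_m / cell
        kharm = int(rng.integers(2, 6))
        phase = float(rng.uniform(0, 2 * np.pi))
        half = int(np.ceil(rad * (1 + wobble))) + 1
        rlo, rhi = max(r0 - half, 0), min(r0 + half + 1, rows)
        clo, chi = max(c0 - half, 0), min(c0 + half + 1, cols)
        rr, cc = np.mgrid[rlo:rhi, clo:chi]
        dy, dx = rr - r0, cc - c0
        theta = np.arctan2(dy, dx)
        rb = rad * (1 + wobble * np.sin(kharm * theta + phase))
        inside = dy**2 + dx**2 <= rb**2
        labels[rlo:rhi, clo:chi][inside] = class_id
        centres.append((r0, c0))
    return centres


def generate_class_map(
    spec: SceneSpec, bathy: RasterGrid, scheme: ClassScheme = DEFAULT_SCHEME
) -> RasterGrid:
    """Ground-truth facies labels on the mosaic grid.

    Zonation: mound core = coral rubble background with dead-coral patches;
    live coral only where the flank faces the configured north sector;
    sponges near the summit and upper west flank; off-mound hemipelagic
    sediment with dropstone patches, pebbles preferentially south; sparse
    shadow streaks (OTHER) in the southern off-mound area.
    """
    rng = _rng(spec.seed, "class_map")
    rows, cols = spec.grid_shape(spec.mosaic_cell)
    cell = spec.mosaic_cell

    x, y = _local_coords(spec, cell)
    bell = _bell(spec, x, y)
    slope_b, aspect_b, _ = slope_aspect(bathy)
    aspect = _upsample_to_mosaic(spec, np.nan_to_num(aspect_b, nan=-1.0))

    core = bell > spec.core_bell_frac
    if spec.mound_height == 0:
        core = np.zeros_like(core)

    ids = {code: scheme.id_of(code) for code in scheme.all_codes}
    labels = np.full((rows, cols), ids["HEMS"], dtype=np.uint8)
    labels[core] = ids["CRUB"]

    # off-mound sediment patches with dropstones
    _paint_patches(rng, labels, ~core, ids["HESDR"], spec.n_hesdr, spec.hesdr_radius, cell)
    labels[core] = ids["CRUB"]  # clip any overhang back onto the mound core

    # pebbles off-mound, preferentially south: sample rows with a south bias
    off = ~core
    south_bias = off & (y > spec.height_m * (0.5 - 0.5 * rng.random()))
    peb_eligible = off & (rng.random((rows, cols)) < (y / spec.height_m) ** 2)
    if not peb_eligible.any():
        peb_eligible = south_bias if south_bias.any() else off
    _paint_patches(rng, labels, peb_eligible, ids["PEB"], spec.n_peb, spec.peb_radius, cell)

    # shadows / unclassified streaks, sparse, southern off-mound
    if spec.n_other > 0:
        streak_eligible = off & (y > 0.55 * spec.height_m)
        for _ in range(spec.n_other):
            idx = np.flatnonzero(streak_eligible)
            if idx.size == 0:
                raise ConfigurationError("scene too small for OTHER streaks")
            k = int(rng.integers(idx.size))
            r0, c0 = divmod(int(idx[k]), cols)
            length = rng.uniform(0.4, 1.2) / cell
            width = rng.uniform(0.02, 0.05) / cell
            ang = rng.uniform(0, np.pi)
            half = int(length / 2) + 2
            rlo, rhi = max(r0 - half, 0), min(r0 + half + 1, rows)
            clo, chi = max(c0 - half, 0), min(c0 + half + 1, cols)
            rr, cc = np.mgrid[rlo:rhi, clo:chi]
            u = (cc - c0) * np.cos(ang) + (rr - r0) * np.sin(ang)
            v = -(cc - c0) * np.sin(ang) + (rr - r0) * np.cos(ang)
            streak = (np.abs(u) <= length / 2) & (np.abs(v) <= width / 2)
            labels[rlo:rhi, clo:chi][streak] = ids["OTHER"]

    # dead coral framework patches on the mound core
    _paint_patches(rng, labels, core, ids["DC"], spec.n_dc, spec.dc_radius, cell)

    # sponges near summit and upper western flank
    west = _in_sector(aspect, 270.0, 30.0) & (bell > 0.30)
    spg_eligible = (bell > 0.55) | west
    if spec.mound_height == 0:
        spg_eligible = np.zeros_like(core)
    if spec.n_spg > 0:
        _paint_patches(
            rng, labels, spg_eligible, ids["SPG"], spec.n_spg, spec.spg_radius, cell,
            min_sep_m=0.5,
        )

    # live coral only on the north-facing flank, painted last so nothing
    # overwrites it (the north restriction is the scene's key pattern)
    inner = spec.north_sector_deg - spec.sector_margin_deg
    lcn_eligible = (
        _in_sector(aspect, 0.0, inner) & (bell > 0.10) & (bell < 0.85) & (aspect >= 0)
    )
    if spec.mound_height == 0:
        lcn_eligible = np.zeros_like(core)
    if spec.n_lcn > 0:
        _paint_patches(
            rng, labels, lcn_eligible, ids["LCN"], spec.n_lcn, spec.lcn_radius, cell,
            min_sep_m=0.7,
        )

    grid = RasterGrid(labels, 0.0, spec.height_m, cell, band_names=("class_id",))
    _check_patch_counts(spec, grid, scheme)
    return grid


def _check_patch_counts(spec: SceneSpec, labels: RasterGrid, scheme: ClassScheme):
    requested = {
        "LCN": spec.n_lcn, "SPG": spec.n_spg, "DC": spec.n_dc,
        "PEB": spec.n_peb, "HESDR": spec.n_hesdr,
    }
    for code, want in requested.items():
        if want == 0:
            continue
        mask = labels.values == scheme.id_of(code)
        n = int(measure.label(mask, connectivity=1).max())
        if n < min(spec.min_patches, want):
            raise ConfigurationError(
                f"class {code}: {n} discrete patches < required {spec.min_patches}"
            )


# ---------------------------------------------------------------------------
# mosaic and backscatter rendering
# ---------------------------------------------------------------------------


def render_mosaic(
    class_map: RasterGrid, spec: SceneSpec, scheme: ClassScheme = DEFAULT_SCHEME
) -> RasterGrid:
    """3-band 8-bit mosaic: per-class mean colour + class-specific texture.

    The structural pattern and white noise of each class are re-centred on
    the class mask so the class mean colour equals the configured colour;
    with all noise and pattern amplitudes at zero the image is piecewise
    constant at the class colours.
    """
    labels = class_map.values
    if labels.ndim != 2:
        raise DataError("class map must be single-band")
    present = np.unique(labels)
    known = {scheme.id_of(c) for c in scheme.all_codes}
    unknown = [int(v) for v in present if int(v) not in known]
    if unknown:
        raise DataError(f"unknown class ids in map: {unknown}")

    rng = _rng(spec.seed, "mosaic")
    rows, cols = labels.shape
    img = np.zeros((rows, cols, 3), dtype=np.float64)
    mid = 128.0
    for code in scheme.all_codes:
        cid = scheme.id_of(code)
        mask = labels == cid
        if not mask.any():
            continue
        style: ClassStyle = spec.styles[code]
        color = mid + (np.asarray(style.color, dtype=float) - mid) * spec.contrast
        # structural modulation shared by all bands
        grain_px = max(style.grain_m / spec.mosaic_cell, 0.0)
        if style.pattern in ("blotch", "dropstones") and style.pattern_amp > 0:
            f = _smooth_noise(rng, (rows, cols), grain_px, 1.0)
            if style.pattern == "blotch":
                pat = np.sign(f) * style.pattern_amp
            else:  # dropstones: dark rounded blobs on the sediment background
                pat = np.where(f > 1.1, -style.pattern_amp, 0.0)
        elif style.pattern == "speckle" and style.pattern_amp > 0:
            pat = rng.standard_normal((rows, cols)) * style.pattern_amp
        elif style.pattern == "disc" and style.pattern_amp > 0:
            # gentle radial brightening towards patch interiors
            dist = ndimage.distance_transform_edt(mask)
            m = dist.max()
            pat = (dist / m - 0.5) * 2 * style.pattern_amp if m > 0 else np.zeros_like(dist)
        else:
            pat = np.zeros((rows, cols))
        add = pat[mask]
        if add.size and add.std() + abs(add.mean()) > 0:
            add = add - add.mean()
        for b in range(3):
            noise = rng.standard_normal(int(mask.sum())) * style.noise_sd
            if noise.size:
                noise -= noise.mean()
            img[:, :, b][mask] = color[b] + add + noise
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return RasterGrid(
        img, class_map.origin_x, class_map.origin_y, class_map.cell_size,
        band_names=("red", "green", "blue"),
    )


def generate_backscatter(
    class_map: RasterGrid, spec: SceneSpec, scheme: ClassScheme = DEFAULT_SCHEME
) -> RasterGrid:
    """Backscatter intensity on the bathy grid: per-class mean + seeded noise."""
    labels = class_map.values
    present = np.unique(labels)
    known = {scheme.id_of(c) for c in scheme.all_codes}
    unknown = [int(v) for v in present if int(v) not in known]
    if unknown:
        raise DataError(f"unknown class ids in map: {unknown}")
    rng = _rng(spec.seed, "backscatter")
    rows, cols = spec.grid_shape(spec.bathy_cell)
    ratio = spec.bathy_cell / class_map.cell_size
    rm = np.minimum(((np.arange(rows) + 0.5) * ratio).astype(int), labels.shape[0] - 1)
    cm = np.minimum(((np.arange(cols) + 0.5) * ratio).astype(int), labels.shape[1] - 1)
    coarse_labels = labels[np.ix_(rm, cm)]
    mean = np.zeros(256)
    sd = np.zeros(256)
    for code in scheme.all_codes:
        style: ClassStyle = spec.styles[code]
        mean[scheme.id_of(code)] = style.bs_mean
        sd[scheme.id_of(code)] = style.bs_sd
    values = mean[coarse_labels] + rng.standard_normal((rows, cols)) * sd[coarse_labels]
    return RasterGrid(
        values.astype(np.float32), 0.0, spec.height_m, spec.bathy_cell,
        band_names=("backscatter",),
    )


# ---------------------------------------------------------------------------
# mound boundary from the topographic break
# ---------------------------------------------------------------------------


def mound_boundary(bathy: RasterGrid, slope_threshold_deg: float = 10.0) -> Polygon:
    """Largest closed polygon enclosing the summit, from the slope break.

    Cells steeper than the threshold form an annulus around the mound; the
    annulus is filled, the component containing the shallowest cell is kept
    and its outline traced in world coordinates.
    """
    if slope_threshold_deg <= 0:
        raise ConfigurationError("slope threshold must be positive")
    slope, _, _ = slope_aspect(bathy)
    mask = slope > slope_threshold_deg
    if not mask.any():
        raise EmptyBoundaryError(
            f"no cell exceeds slope threshold {slope_threshold_deg} deg"
        )
    filled = ndimage.binary_fill_holes(mask)
    comp = measure.label(filled, connectivity=1)
    rs, cs = np.unravel_index(np.argmax(bathy.values), bathy.values.shape)
    target = comp[rs, cs]
    if target == 0:
        # summit not inside any steep component: take the largest component
        counts = np.bincount(comp.ravel())
        counts[0] = 0
        target = int(np.argmax(counts))
    region = comp == target
    padded = np.pad(region.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        raise EmptyBoundaryError("slope break region too small to trace")
    polys = []
    for cont in contours:
        if len(cont) < 4:
            continue
        r = cont[:, 0] - 1.0
        c = cont[:, 1] - 1.0
        xs = bathy.origin_x + (c + 0.5) * bathy.cell_size
        ys = bathy.origin_y - (r + 0.5) * bathy.cell_size
        p = Polygon(zip(xs, ys))
        if p.is_valid and p.area > 0:
            polys.append(p)
    if not polys:
        raise EmptyBoundaryError("no valid boundary polygon traced")
    poly = max(polys, key=lambda p: p.area)
    poly = poly.simplify(bathy.cell_size / 4.0)
    sx, sy = bathy.pixel_to_world(rs, cs)
    if not poly.buffer(bathy.cell_size).contains(Point(sx, sy)):
        raise EmptyBoundaryError("traced boundary does not enclose the summit")
    return poly


# ---------------------------------------------------------------------------
# scene bundle
# ---------------------------------------------------------------------------


@dataclass
class Scene:
    spec: SceneSpec
    bathy: RasterGrid
    class_map: RasterGrid
    mosaic: RasterGrid
    backscatter: RasterGrid
    boundary: Polygon
    scheme: ClassScheme = DEFAULT_SCHEME

    @property
    def fractions(self) -> dict[str, float]:
        return class_fractions(self.class_map, self.scheme)


def class_fractions(class_map: RasterGrid, scheme: ClassScheme = DEFAULT_SCHEME):
    """Exact pixel fraction of each class present in the label raster."""
    counts = np.bincount(class_map.values.ravel(), minlength=len(scheme.all_codes) + 1)
    total = class_map.values.size
    return {
        code: counts[scheme.id_of(code)] / total
        for code in scheme.all_codes
        if counts[scheme.id_of(code)] > 0
    }


def generate_scene(
    spec: SceneSpec, scheme: ClassScheme = DEFAULT_SCHEME,
    boundary_slope_deg: float = 10.0,
) -> Scene:
    """Generate the full co-registered scene bundle for one spec."""
    bathy = generate_bathymetry(spec)
    class_map = generate_class_map(spec, bathy, scheme)
    mosaic = render_mosaic(class_map, spec, scheme)
    backscatter = generate_backscatter(class_map, spec, scheme)
    boundary = mound_boundary(bathy, boundary_slope_deg)
    return Scene(spec, bathy, class_map, mosaic, backscatter, boundary, scheme)
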