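"""Per-object feature extraction: spectral, texture, shape, bathymetric.

One row per segment.  The canonical 21-column feature scheme combines
RGB means and brightness from the mosaic, Haralick texture statistics
(homogeneity, entropy, mean) from a gray-level co-occurrence matrix over
the backscatter grid, ten geometry descriptors of the segment polygon, and
terrain statistics (depth, slope, aspect, curvature) aggregated from the
bathymetry.

Brightness is the *sum* of the three band means.  GLCM texture uses a
global scene-wide min-max quantisation to G=32 levels, distance 1, the four
symmetric offsets averaged, and natural-log entropy.  Aspect is the compass
direction of steepest descent, aggregated per segment with a circular mean;
flat cells are excluded and fully flat segments flagged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .grid import ConfigurationError, DataError, RasterGrid, curvature as _curvature
from .grid import slope_aspect
from .segmentation import SegmentMap

__all__ = [
    "FEATURE_COLUMNS",
    "spectral_features",
    "texture_features",
    "shape_features",
    "bathy_features",
    "build_feature_table",
    "segment_majority_class",
]

GLCM_LEVELS = 32

#: canonical feature scheme used by the classifiers
FEATURE_COLUMNS = [
    "mean_red", "mean_green", "mean_blue", "brightness",
    "glcm_homogeneity", "glcm_entropy", "glcm_mean",
    "area", "compactness", "density", "roundness", "main_direction",
    "rectangular_fit", "elliptic_fit", "asymmetry", "border_index", "shape_index",
    "mean_depth", "slope", "aspect", "curvature",
]


# ---------------------------------------------------------------------------
# spectral
# ---------------------------------------------------------------------------


def spectral_features(segmap: SegmentMap, mosaic: RasterGrid) -> pd.DataFrame:
    """Per-band segment means and total brightness (sum of the band means)."""
    labels = segmap.labels.values.ravel()
    k = segmap.n_segments
    if mosaic.n_bands == 3:
        names = ["mean_red", "mean_green", "mean_blue"]
    elif mosaic.band_names:
        names = [f"mean_{b}" for b in mosaic.band_names]
    else:
        raise ConfigurationError(
            f"expected 3 bands or explicit band names, got {mosaic.n_bands} bands"
        )
    counts = np.bincount(labels, minlength=k).astype(float)
    cols = {}
    for i, name in enumerate(names):
        band = np.asarray(mosaic.band(i), dtype=float).ravel()
        cols[name] = np.bincount(labels, weights=band, minlength=k) / counts
    df = pd.DataFrame(cols, index=pd.RangeIndex(k, name="segment_id"))
    df["brightness"] = df[names].sum(axis=1)
    return df


# ---------------------------------------------------------------------------
# texture (GLCM on the intensity grid, usually backscatter)
# ---------------------------------------------------------------------------


def _coarse_segment_grid(segmap: SegmentMap, grid: RasterGrid) -> np.ndarray:
    """Segment id of each cell of `grid`: the segment whose footprint holds
    the cell centre (nearest label pixel)."""
    lab = segmap.labels
    rows, cols = grid.values.shape[:2]
    # world coordinates of this grid's cell centres, mapped onto label pixels
    yc = grid.origin_y - (np.arange(rows) + 0.5) * grid.cell_size
    xc = grid.origin_x + (np.arange(cols) + 0.5) * grid.cell_size
    r_m = np.floor((lab.origin_y - yc) / lab.cell_size).astype(np.int64)
    c_m = np.floor((xc - lab.origin_x) / lab.cell_size).astype(np.int64)
    inside_r = (r_m >= 0) & (r_m < lab.rows)
    inside_c = (c_m >= 0) & (c_m < lab.cols)
    out = np.full((rows, cols), -1, dtype=np.int64)
    rm = np.clip(r_m, 0, lab.rows - 1)
    cm = np.clip(c_m, 0, lab.cols - 1)
    vals = lab.values[np.ix_(rm, cm)]
    out[np.ix_(inside_r, inside_c)] = vals[np.ix_(inside_r, inside_c)]
    return out


def quantize(values: np.ndarray, levels: int = GLCM_LEVELS) -> np.ndarray:
    """Global min-max quantisation to integer levels 0..levels-1."""
    v = np.asarray(values, dtype=float)
    lo, hi = np.nanmin(v), np.nanmax(v)
    if hi <= lo:
        return np.zeros(v.shape, dtype=np.int64)
    q = np.floor((v - lo) / (hi - lo) * levels).astype(np.int64)
    return np.clip(q, 0, levels - 1)


_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))


def texture_features(
    segmap: SegmentMap, intensity: RasterGrid, levels: int = GLCM_LEVELS
) -> pd.DataFrame:
    """Haralick homogeneity, entropy and GLCM mean per segment.

    The co-occurrence matrix is symmetric, distance 1, averaged over the
    horizontal, vertical and both diagonal offsets, restricted to cell pairs
    lying inside the same segment footprint.  Segments whose footprint
    yields no pair fall back to their single (or mean) level: homogeneity 1,
    entropy 0, flagged in ``glcm_single``.
    """
    k = segmap.n_segments
    if intensity.values.ndim != 2:
        raise DataError("intensity raster must be single-band")
    seg = _coarse_segment_grid(segmap, intensity)
    q = quantize(intensity.values, levels)

    keys = []
    for dr, dc in _OFFSETS:
        if dc >= 0:
            a_seg = seg[: seg.shape[0] - dr, : seg.shape[1] - dc]
            b_seg = seg[dr:, dc:]
            a_q = q[: q.shape[0] - dr, : q.shape[1] - dc]
            b_q = q[dr:, dc:]
        else:
            a_seg = seg[: seg.shape[0] - dr, -dc:]
            b_seg = seg[dr:, : seg.shape[1] + dc]
            a_q = q[: q.shape[0] - dr, -dc:]
            b_q = q[dr:, : q.shape[1] + dc]
        same = (a_seg == b_seg) & (a_seg >= 0)
        s = a_seg[same].ravel()
        la = a_q[same].ravel()
        lb = b_q[same].ravel()
        # symmetric matrix: count both orientations
        keys.append(s * levels * levels + la * levels + lb)
        keys.append(s * levels * levels + lb * levels + la)
    if keys:
        allk = np.concatenate(keys)
    else:
        allk = np.empty(0, dtype=np.int64)

    homog = np.full(k, np.nan)
    entropy = np.full(k, np.nan)
    gmean = np.full(k, np.nan)
    single = np.zeros(k, dtype=bool)

    if allk.size:
        uniq, counts = np.unique(allk, return_counts=True)
        s_of = uniq // (levels * levels)
        la_of = (uniq // levels) % levels
        lb_of = uniq % levels
        totals = np.bincount(s_of, weights=counts, minlength=k)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = counts / totals[s_of]
        np.add.at(homog_acc := np.zeros(k), s_of, p / (1.0 + (la_of - lb_of) ** 2))
        np.add.at(ent_acc := np.zeros(k), s_of, -p * np.log(p))
        np.add.at(mean_acc := np.zeros(k), s_of, la_of * p)
        has = totals > 0
        homog[has] = homog_acc[has]
        entropy[has] = ent_acc[has]
        gmean[has] = mean_acc[has]
    else:
        has = np.zeros(k, dtype=bool)

    # fallback: segments without any within-footprint pair
    missing = ~has
    if missing.any():
        flat_seg = seg.ravel()
        valid = flat_seg >= 0
        lev_sum = np.bincount(flat_seg[valid], weights=q.ravel()[valid], minlength=k)
        lev_n = np.bincount(flat_seg[valid], minlength=k)
        # segments with no footprint cell at all: nearest cell to the bbox centre
        for sid in np.flatnonzero(missing):
            if lev_n[sid] > 0:
                gmean[sid] = lev_sum[sid] / lev_n[sid]
            else:
                rmin, rmax, cmin, cmax = segmap.bbox[sid]
                rc = (rmin + rmax) / 2.0
                cc_ = (cmin + cmax) / 2.0
                x, y = segmap.labels.pixel_to_world(rc, cc_)
                r_i, c_i = intensity.world_to_pixel(x, y)
                r_i = int(np.clip(r_i, 0, intensity.rows - 1))
                c_i = int(np.clip(c_i, 0, intensity.cols - 1))
                gmean[sid] = q[r_i, c_i]
        homog[missing] = 1.0
        entropy[missing] = 0.0
        single[missing] = True

    return pd.DataFrame(
        {
            "glcm_homogeneity": homog,
            "glcm_entropy": entropy,
            "glcm_mean": gmean,
            "glcm_single": single,
        },
        index=pd.RangeIndex(k, name="segment_id"),
    )


# ---------------------------------------------------------------------------
# shape
# ---------------------------------------------------------------------------


def _ombr_dims(points: np.ndarray) -> tuple[float, float]:
    """Width and height of the oriented minimum-area bounding rectangle."""
    pts = np.unique(points, axis=0).astype(float)
    if pts.shape[0] == 1:
        return 0.0, 0.0
    try:
        hull = ConvexHull(pts)
        hp = pts[hull.vertices]
    except QhullError:  # collinear points
        d = pts - pts[0]
        length = np.hypot(d[:, 0], d[:, 1]).max()
        return float(length), 0.0
    best = None
    m = hp.shape[0]
    for i in range(m):
        ev = hp[(i + 1) % m] - hp[i]
        norm = np.hypot(*ev)
        if norm == 0:
            continue
        ux, uy = ev / norm
        proj1 = hp @ np.array([ux, uy])
        proj2 = hp @ np.array([-uy, ux])
        w = proj1.max() - proj1.min()
        h = proj2.max() - proj2.min()
        if best is None or w * h < best[0]:
            best = (w * h, w, h)
    return (best[1], best[2]) if best else (0.0, 0.0)


def shape_features(segmap: SegmentMap) -> pd.DataFrame:
    """Geometry descriptors per segment (pixel units; area/border in metres)."""
    labels = segmap.labels.values
    rows, cols = labels.shape
    cell = segmap.labels.cell_size
    k = segmap.n_segments
    n = segmap.n.astype(float)
    e = segmap.perimeter_edges.astype(float)

    flat = labels.ravel()
    rr, cc = np.divmod(np.arange(flat.size), cols)
    sr = np.bincount(flat, weights=rr, minlength=k)
    sc = np.bincount(flat, weights=cc, minlength=k)
    srr = np.bincount(flat, weights=rr * rr, minlength=k)
    scc = np.bincount(flat, weights=cc * cc, minlength=k)
    src = np.bincount(flat, weights=rr * cc, minlength=k)
    mr = sr / n
    mc = sc / n
    c_rr = srr / n - mr**2
    c_cc = scc / n - mc**2
    c_rc = src / n - mr * mc

    tr = c_rr + c_cc
    det = c_rr * c_cc - c_rc**2
    disc = np.sqrt(np.maximum((tr / 2) ** 2 - det, 0.0))
    lam1 = tr / 2 + disc
    lam2 = np.maximum(tr / 2 - disc, 0.0)

    # principal axis: eigenvector of lam1 in (row, col) space
    vrow = np.where(np.abs(c_rc) > 1e-12, lam1 - c_cc, np.where(c_rr >= c_cc, 1.0, 0.0))
    vcol = np.where(np.abs(c_rc) > 1e-12, c_rc, np.where(c_rr >= c_cc, 0.0, 1.0))
    norm = np.hypot(vrow, vcol)
    norm[norm == 0] = 1.0
    vrow, vcol = vrow / norm, vcol / norm
    # clockwise from grid north (north = -row direction), folded to [0, 180)
    main_dir = np.degrees(np.arctan2(vcol, -vrow)) % 180.0

    asym = np.where(lam1 > 0, 1.0 - lam2 / np.maximum(lam1, 1e-300), 0.0)
    density = np.sqrt(n) / (1.0 + np.sqrt(lam1 + lam2))
    shape_index = e / (4.0 * np.sqrt(n))
    compact = e**2 / (4.0 * np.pi * n)
    roundness = 4.0 * np.pi * n / e**2

    # fits and oriented bounding rectangles need per-segment pixel sets
    order = np.argsort(flat, kind="stable")
    bounds = np.searchsorted(flat[order], np.arange(k + 1))
    # boundary pixels (any exposed 4-edge) for the OMBR hulls
    bnd = np.zeros((rows, cols), dtype=bool)
    bnd[0, :] = bnd[-1, :] = bnd[:, 0] = bnd[:, -1] = True
    bnd[:, 1:] |= labels[:, 1:] != labels[:, :-1]
    bnd[:, :-1] |= labels[:, 1:] != labels[:, :-1]
    bnd[1:, :] |= labels[1:, :] != labels[:-1, :]
    bnd[:-1, :] |= labels[1:, :] != labels[:-1, :]
    bnd_flat = bnd.ravel()

    ell_fit = np.zeros(k)
    rect_fit = np.zeros(k)
    border_index = np.ones(k)
    for sid in range(k):
        pix = order[bounds[sid]: bounds[sid + 1]]
        pr = rr[pix].astype(float)
        pc = cc[pix].astype(float)
        npx = pix.size
        # oriented minimum bounding rectangle from boundary-pixel corners
        bsel = pix[bnd_flat[pix]]
        br = rr[bsel]
        bc = cc[bsel]
        corners = np.concatenate(
            [
                np.stack([br, bc], 1), np.stack([br, bc + 1], 1),
                np.stack([br + 1, bc], 1), np.stack([br + 1, bc + 1], 1),
            ]
        )
        w, h = _ombr_dims(corners)
        denom = 2.0 * (w + h)
        border_index[sid] = e[sid] / denom if denom > 0 else 1.0

        ux, uy = vrow[sid], vcol[sid]  # principal axis (row, col)
        dr_ = pr - mr[sid]
        dc_ = pc - mc[sid]
        p1 = dr_ * ux + dc_ * uy
        p2 = -dr_ * uy + dc_ * ux
        a = 2.0 * np.sqrt(lam1[sid])
        b = 2.0 * np.sqrt(lam2[sid])
        if a > 0 and b > 0:
            inside_e = (p1 / a) ** 2 + (p2 / b) ** 2 <= 1.0
            ell_fit[sid] = inside_e.sum() / max(npx, np.pi * a * b)
        else:
            ell_fit[sid] = 1.0 if npx == 1 else 0.0
        hw = np.sqrt(3.0 * lam1[sid])
        hh = np.sqrt(3.0 * lam2[sid])
        inside_r = (np.abs(p1) <= hw + 1e-9) & (np.abs(p2) <= hh + 1e-9)
        rect_area = (2 * hw) * (2 * hh)
        rect_fit[sid] = inside_r.sum() / max(npx, rect_area)

    return pd.DataFrame(
        {
            "area": n * cell**2,
            "border_length": e * cell,
            "compactness": compact,
            "density": density,
            "roundness": roundness,
            "main_direction": main_dir,
            "rectangular_fit": np.clip(rect_fit, 0, 1),
            "elliptic_fit": np.clip(ell_fit, 0, 1),
            "asymmetry": asym,
            "border_index": np.maximum(border_index, 1.0),
            "shape_index": shape_index,
        },
        index=pd.RangeIndex(k, name="segment_id"),
    )


# ---------------------------------------------------------------------------
# bathymetry
# ---------------------------------------------------------------------------


def bathy_features(segmap: SegmentMap, bathy: RasterGrid) -> pd.DataFrame:
    """Mean depth, Horn slope, circular-mean aspect and Laplacian curvature.

    Aggregated over the bathy cells whose centres fall inside each segment's
    footprint; segments covering no cell centre fall back to the cell nearest
    their bounding-box centre (flagged ``bathy_sliver``).  Fully flat
    segments get aspect 0 and the ``aspect_flat`` flag.
    """
    k = segmap.n_segments
    slope, aspect, flat_mask = slope_aspect(bathy)
    curv = _curvature(bathy)
    seg = _coarse_segment_grid(segmap, bathy)
    valid = seg >= 0
    s = seg[valid].ravel()
    depth_v = np.asarray(bathy.values, dtype=float)[valid].ravel()
    slope_v = slope[valid].ravel()
    curv_v = curv[valid].ravel()
    asp_v = aspect[valid].ravel()
    flat_v = flat_mask[valid].ravel()

    cnt = np.bincount(s, minlength=k).astype(float)
    mean_depth = np.full(k, np.nan)
    mean_slope = np.full(k, np.nan)
    mean_curv = np.full(k, np.nan)
    has = cnt > 0
    with np.errstate(invalid="ignore"):
        mean_depth[has] = np.bincount(s, weights=depth_v, minlength=k)[has] / cnt[has]
        mean_slope[has] = np.bincount(s, weights=slope_v, minlength=k)[has] / cnt[has]
        mean_curv[has] = np.bincount(s, weights=curv_v, minlength=k)[has] / cnt[has]

    nonflat = ~flat_v
    sn = s[nonflat]
    ang = np.radians(asp_v[nonflat])
    sin_s = np.bincount(sn, weights=np.sin(ang), minlength=k)
    cos_s = np.bincount(sn, weights=np.cos(ang), minlength=k)
    n_nonflat = np.bincount(sn, minlength=k)
    mean_aspect = np.where(
        n_nonflat > 0, np.degrees(np.arctan2(sin_s, cos_s)) % 360.0, np.nan
    )
    aspect_flat = has & (n_nonflat == 0)

    sliver = ~has
    if sliver.any():
        for sid in np.flatnonzero(sliver):
            rmin, rmax, cmin, cmax = segmap.bbox[sid]
            x, y = segmap.labels.pixel_to_world((rmin + rmax) / 2.0, (cmin + cmax) / 2.0)
            r_i, c_i = bathy.world_to_pixel(x, y)
            if not (0 <= r_i < bathy.rows and 0 <= c_i < bathy.cols):
                continue  # outside bathy extent: stays NaN / nodata-flagged
            mean_depth[sid] = bathy.values[r_i, c_i]
            mean_slope[sid] = slope[r_i, c_i]
            mean_curv[sid] = curv[r_i, c_i]
            if flat_mask[r_i, c_i]:
                aspect_flat[sid] = True
            else:
                mean_aspect[sid] = aspect[r_i, c_i]

    mean_aspect = np.where(np.isnan(mean_aspect), 0.0, mean_aspect)
    return pd.DataFrame(
        {
            "mean_depth": mean_depth,
            "slope": mean_slope,
            "aspect": mean_aspect,
            "curvature": mean_curv,
            "aspect_flat": aspect_flat,
            "bathy_sliver": sliver,
        },
        index=pd.RangeIndex(k, name="segment_id"),
    )


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------


def build_feature_table(
    segmap: SegmentMap,
    mosaic: RasterGrid,
    bathy: RasterGrid,
    backscatter: RasterGrid | None = None,
    labels: pd.Series | None = None,
) -> pd.DataFrame:
    """Assemble the full per-segment feature table.

    Texture comes from backscatter when available, otherwise from the mosaic
    luminance (mean of the RGB bands).
    """
    spec = spectral_features(segmap, mosaic)
    if backscatter is not None:
        intensity = backscatter
    else:
        lum = np.mean(
            [np.asarray(mosaic.band(i), dtype=float) for i in range(mosaic.n_bands)],
            axis=0,
        )
        intensity = mosaic.with_values(lum, ("luminance",))
    tex = texture_features(segmap, intensity)
    shp = shape_features(segmap)
    bat = bathy_features(segmap, bathy)
    table = pd.concat([spec, tex, shp, bat], axis=1)
    if labels is not None:
        table["label"] = labels
    ordered = FEATURE_COLUMNS + [c for c in table.columns if c not in FEATURE_COLUMNS]
    return table[ordered]


def segment_majority_class(segmap: SegmentMap, class_map: RasterGrid, scheme) -> pd.Series:
    """Ground-truth label of each segment by pixel-majority vote."""
    if class_map.values.shape != segmap.labels.values.shape:
        raise DataError("class map and segment map must share the mosaic grid")
    seg = segmap.labels.values.ravel()
    cls = class_map.values.ravel().astype(np.int64)
    k = segmap.n_segments
    n_cls = int(cls.max()) + 1
    counts = np.zeros((k, n_cls), dtype=np.int64)
    np.add.at(counts, (seg, cls), 1)
    maj = counts.argmax(axis=1)
    codes = [scheme.code_of(int(cid)) for cid in maj]
    return pd.Series(codes, index=pd.RangeIndex(k, name="segment_id"), name="label")
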