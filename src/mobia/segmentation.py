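"""Multiresolution region-merging segmentation with scale estimation.

Implements the Baatz–Schäpe heterogeneity-minimising region merge that
underlies commercial multiresolution segmentation.  Starting from single
pixels, neighbouring segments are fused whenever the increase in weighted
colour + shape heterogeneity

    f = w_color * dh_color + (1 - w_color) * dh_shape

stays below ``scale**2``, so the familiar "scale parameter" keeps its usual
units.  The colour term is the area-weighted increase in per-band standard
deviation; the shape term mixes compactness (perimeter / sqrt(area)) and
smoothness (perimeter / bounding-box perimeter).

Scheduling is deterministic local mutual best fitting: in each sweep a
segment merges with its minimum-cost neighbour only if the choice is
reciprocal (ties broken by lower cost, then lower neighbour id), and sweeps
repeat until no permitted merge remains.  All segment statistics are carried
incrementally as (n, sum, sum-of-squares, perimeter, bbox), which makes each
sweep a handful of vectorised array passes over the current edge list.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from shapely import affinity
from shapely.geometry import box
from shapely.ops import unary_union

from .grid import ConfigurationError, DataError, RasterGrid

__all__ = [
    "SegmentationParams",
    "SegmentMap",
    "ESPCurve",
    "segment",
    "esp_scale",
    "segments_to_polygons",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Scale and heterogeneity weights of the region merge."""

    scale: float = 400.0
    color_weight: float = 0.9  # 1 - shape weight; shape weight 0.1 by default
    compactness_weight: float = 0.5
    band_weights: tuple[float, ...] | None = None  # None = equal weights

    def __post_init__(self):
        if self.scale <= 0:
            raise ConfigurationError("scale must be positive")
        for name in ("color_weight", "compactness_weight"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if self.band_weights is not None:
            w = np.asarray(self.band_weights, dtype=float)
            if (w < 0).any() or w.sum() <= 0:
                raise ConfigurationError("band_weights must be nonnegative, sum > 0")

    def normalized_band_weights(self, n_bands: int) -> np.ndarray:
        if self.band_weights is None:
            return np.full(n_bands, 1.0 / n_bands)
        w = np.asarray(self.band_weights, dtype=float)
        if w.size != n_bands:
            raise ConfigurationError(
                f"{w.size} band weights for {n_bands} bands"
            )
        return w / w.sum()


@dataclass
class SegmentMap:
    """Label raster plus per-segment incremental statistics and adjacency.

    Segment ids are the contiguous range 0..n_segments-1.  ``perimeter_edges``
    counts exposed 4-neighbour pixel edges (image border included), so the
    world perimeter of segment s is ``perimeter_edges[s] * cell_size``.
    """

    labels: RasterGrid
    n: np.ndarray  # (K,) pixel counts
    band_sum: np.ndarray  # (K, B)
    band_sumsq: np.ndarray  # (K, B)
    perimeter_edges: np.ndarray  # (K,)
    bbox: np.ndarray  # (K, 4): rmin, rmax, cmin, cmax (inclusive)
    edges: np.ndarray  # (E, 2) adjacent segment id pairs (u < v)
    shared_edges: np.ndarray  # (E,) shared 4-neighbour pixel edge counts

    @property
    def n_segments(self) -> int:
        return int(self.n.size)

    @property
    def band_mean(self) -> np.ndarray:
        return self.band_sum / self.n[:, None]

    @property
    def band_std(self) -> np.ndarray:
        var = self.band_sumsq / self.n[:, None] - self.band_mean**2
        return np.sqrt(np.maximum(var, 0.0))

    @property
    def adjacency(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_segments))
        for (u, v), s in zip(self.edges, self.shared_edges):
            g.add_edge(int(u), int(v), shared_edges=int(s))
        return g


@dataclass
class ESPCurve:
    """Local-variance scale-selection curve."""

    scales: np.ndarray
    lv: np.ndarray
    roc_lv: np.ndarray  # per cent, NaN for the first scale
    candidates: list = field(default_factory=list)  # scales at local ROC-LV maxima


# ---------------------------------------------------------------------------
# merge cost
# ---------------------------------------------------------------------------


def _bbox_perim(bb: np.ndarray) -> np.ndarray:
    return 2.0 * ((bb[:, 1] - bb[:, 0] + 1) + (bb[:, 3] - bb[:, 2] + 1))


def segment(mosaic: RasterGrid, params: SegmentationParams | None = None) -> SegmentMap:
    """Segment a raster by mutual-best-fitting region merging.

    Deterministic for fixed input and parameters.  Works for any band count;
    non-finite pixel values are rejected.
    """
    params = params or SegmentationParams()
    vals = np.asarray(mosaic.values, dtype=np.float64)
    if vals.ndim == 2:
        vals = vals[:, :, None]
    rows, cols, nb_bands = vals.shape
    if vals.size == 0:
        raise DataError("empty raster")
    if not np.isfinite(vals).all():
        raise DataError("raster contains non-finite values")
    wb = params.normalized_band_weights(nb_bands)
    threshold = params.scale**2

    n0 = rows * cols
    flat = vals.reshape(n0, nb_bands)

    # per-segment stats, indexed by segment id (ids never exceed n0)
    n = np.ones(n0, dtype=np.int64)
    bsum = flat.copy()
    bsumsq = flat**2
    e = np.full(n0, 4, dtype=np.int64)
    rr, cc = np.divmod(np.arange(n0), cols)
    bb = np.stack([rr, rr, cc, cc], axis=1).astype(np.int64)

    # initial edges: 4-neighbour pixel adjacencies, each sharing one edge
    idx = np.arange(n0).reshape(rows, cols)
    hu = idx[:, :-1].ravel()
    hv = idx[:, 1:].ravel()
    vu = idx[:-1, :].ravel()
    vv = idx[1:, :].ravel()
    eu = np.concatenate([hu, vu])
    ev = np.concatenate([hv, vv])
    shared = np.ones(eu.size, dtype=np.int64)

    current = np.arange(n0, dtype=np.int64)  # pixel -> current segment id

    while eu.size:
        sigma = np.sqrt(np.maximum(bsumsq / n[:, None] - (bsum / n[:, None]) ** 2, 0.0))
        e_ab = e[eu] + e[ev] - 2 * shared
        nab = n[eu] + n[ev]
        bb_ab_h = np.maximum(bb[eu, 1], bb[ev, 1]) - np.minimum(bb[eu, 0], bb[ev, 0]) + 1
        bb_ab_w = np.maximum(bb[eu, 3], bb[ev, 3]) - np.minimum(bb[eu, 2], bb[ev, 2]) + 1
        d_cmpct = np.sqrt(nab) * e_ab - (np.sqrt(n[eu]) * e[eu] + np.sqrt(n[ev]) * e[ev])
        d_smooth = (
            nab * e_ab / (2.0 * (bb_ab_h + bb_ab_w))
            - n[eu] * e[eu] / _bbox_perim(bb[eu])
            - n[ev] * e[ev] / _bbox_perim(bb[ev])
        )
        s_ab = bsum[eu] + bsum[ev]
        q_ab = bsumsq[eu] + bsumsq[ev]
        var = q_ab / nab[:, None] - (s_ab / nab[:, None]) ** 2
        sig_ab = np.sqrt(np.maximum(var, 0.0))
        dh_color = (
            nab[:, None] * sig_ab - n[eu][:, None] * sigma[eu] - n[ev][:, None] * sigma[ev]
        ) @ wb
        cost = params.color_weight * dh_color + (1 - params.color_weight) * (
            params.compactness_weight * d_cmpct
            + (1 - params.compactness_weight) * d_smooth
        )

        # minimum-cost neighbour of every segment, ties to the lower neighbour id
        m = eu.size
        d_node = np.concatenate([eu, ev])
        d_nbr = np.concatenate([ev, eu])
        d_cost = np.concatenate([cost, cost])
        d_edge = np.concatenate([np.arange(m), np.arange(m)])
        order = np.lexsort((d_nbr, d_cost, d_node))
        sn = d_node[order]
        first = np.ones(sn.size, dtype=bool)
        first[1:] = sn[1:] != sn[:-1]
        best = np.full(n0, -1, dtype=np.int64)
        best[sn[first]] = d_edge[order[first]]

        eidx = np.arange(m)
        mutual = (best[eu] == eidx) & (best[ev] == eidx) & (cost < threshold)
        if not mutual.any():
            break

        mu, mv, ms = eu[mutual], ev[mutual], shared[mutual]
        tgt = np.minimum(mu, mv)
        src = np.maximum(mu, mv)
        n[tgt] += n[src]
        bsum[tgt] += bsum[src]
        bsumsq[tgt] += bsumsq[src]
        e[tgt] = e[tgt] + e[src] - 2 * ms
        bb[tgt, 0] = np.minimum(bb[tgt, 0], bb[src, 0])
        bb[tgt, 1] = np.maximum(bb[tgt, 1], bb[src, 1])
        bb[tgt, 2] = np.minimum(bb[tgt, 2], bb[src, 2])
        bb[tgt, 3] = np.maximum(bb[tgt, 3], bb[src, 3])

        remap = np.arange(n0, dtype=np.int64)
        remap[src] = tgt
        current = remap[current]
        u2 = remap[eu]
        v2 = remap[ev]
        keep = u2 != v2
        u2, v2, sh2 = u2[keep], v2[keep], shared[keep]
        lo = np.minimum(u2, v2)
        hi = np.maximum(u2, v2)
        key = lo * n0 + hi
        uniq, inv = np.unique(key, return_inverse=True)
        shared = np.bincount(inv, weights=sh2).astype(np.int64)
        eu = (uniq // n0).astype(np.int64)
        ev = (uniq % n0).astype(np.int64)

    # relabel to a contiguous range ordered by first-pixel occurrence
    uniq_ids, labels_flat = np.unique(current, return_inverse=True)
    k = uniq_ids.size
    lut = np.empty(n0, dtype=np.int64)
    lut[uniq_ids] = np.arange(k)
    label_raster = labels_flat.reshape(rows, cols).astype(np.int32)
    if eu.size:
        fe = np.stack([lut[eu], lut[ev]], axis=1)
        lo = fe.min(axis=1)
        hi = fe.max(axis=1)
        final_edges = np.stack([lo, hi], axis=1)
        final_shared = shared.copy()
    else:
        final_edges = np.empty((0, 2), dtype=np.int64)
        final_shared = np.empty(0, dtype=np.int64)

    return SegmentMap(
        labels=mosaic.with_values(label_raster, ("segment_id",)),
        n=n[uniq_ids].copy(),
        band_sum=bsum[uniq_ids].copy(),
        band_sumsq=bsumsq[uniq_ids].copy(),
        perimeter_edges=e[uniq_ids].copy(),
        bbox=bb[uniq_ids].copy(),
        edges=final_edges,
        shared_edges=final_shared,
    )


# ---------------------------------------------------------------------------
# ESP scale selection
# ---------------------------------------------------------------------------


def esp_scale(
    mosaic: RasterGrid,
    scales,
    params: SegmentationParams | None = None,
) -> ESPCurve:
    """Local variance (LV) and its rate of change across segmentation scales.

    LV at a scale is the mean over segments of the segment's mean per-band
    standard deviation; candidate scales are the local maxima of ROC-LV.
    """
    scales = np.asarray(list(scales), dtype=float)
    if scales.size < 2:
        raise ConfigurationError("need at least 2 scales for an ESP curve")
    if not (np.diff(scales) > 0).all() or (scales <= 0).any():
        raise ConfigurationError("scales must be strictly increasing and positive")
    base = params or SegmentationParams()
    lv = np.empty(scales.size)
    for i, s in enumerate(scales):
        p = SegmentationParams(
            scale=float(s),
            color_weight=base.color_weight,
            compactness_weight=base.compactness_weight,
            band_weights=base.band_weights,
        )
        sm = segment(mosaic, p)
        lv[i] = sm.band_std.mean(axis=1).mean()
    roc = np.full(scales.size, np.nan)
    prev = lv[:-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        r = 100.0 * (lv[1:] - prev) / prev
    r[prev == 0] = 0.0
    roc[1:] = r
    candidates = [
        float(scales[i])
        for i in range(1, scales.size)
        if (i == 1 or roc[i] > roc[i - 1]) and (i == scales.size - 1 or roc[i] > roc[i + 1])
        and np.isfinite(roc[i])
    ]
    return ESPCurve(scales=scales, lv=lv, roc_lv=roc, candidates=candidates)


# ---------------------------------------------------------------------------
# vector export
# ---------------------------------------------------------------------------


def segments_to_polygons(segmap: SegmentMap):
    """One polygon (with holes) per segment, traced along pixel boundaries.

    Geometry is built from horizontal pixel runs in integer pixel
    coordinates (exact) and then mapped to world coordinates, so polygon
    areas sum to the raster area.

    Returns a list of (segment_id, shapely geometry) in id order.
    """
    labels = segmap.labels.values
    rows, cols = labels.shape
    cell = segmap.labels.cell_size
    ox, oy = segmap.labels.origin_x, segmap.labels.origin_y

    boxes_by_seg: dict[int, list] = {}
    for r in range(rows):
        row = labels[r]
        breaks = np.flatnonzero(row[1:] != row[:-1])
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks + 1, [cols]])
        for s, t in zip(starts, ends):
            boxes_by_seg.setdefault(int(row[s]), []).append(box(s, r, t, r + 1))

    out = []
    for sid in range(segmap.n_segments):
        geom = unary_union(boxes_by_seg[sid])
        # pixel space -> world: x = ox + c*cell, y = oy - r*cell
        geom = affinity.affine_transform(geom, [cell, 0, 0, -cell, ox, oy])
        out.append((sid, geom))
    return out
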