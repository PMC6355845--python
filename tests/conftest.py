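import numpy as np
import pytest

from mobia.grid import RasterGrid
from mobia.segmentation import SegmentMap
from mobia.synthetic import SceneSpec, generate_scene


def segmap_from_labels(labels, values, origin_x=0.0, origin_y=None, cell_size=1.0):
    """Build a SegmentMap with exact statistics recomputed from a label array.

    Lets tests construct precise segment geometries (bars, squares, Ls)
    without going through the merge algorithm.
    """
    labels = np.asarray(labels, dtype=np.int32)
    rows, cols = labels.shape
    if origin_y is None:
        origin_y = rows * cell_size
    vals = np.asarray(values, dtype=float)
    if vals.ndim == 2:
        vals = vals[:, :, None]
    k = int(labels.max()) + 1
    flat = labels.ravel()
    n = np.bincount(flat, minlength=k)
    nb = vals.shape[2]
    bsum = np.zeros((k, nb))
    bsumsq = np.zeros((k, nb))
    for b in range(nb):
        v = vals[:, :, b].ravel()
        bsum[:, b] = np.bincount(flat, weights=v, minlength=k)
        bsumsq[:, b] = np.bincount(flat, weights=v * v, minlength=k)

    e = np.zeros(k, dtype=np.int64)
    edge_counts: dict[tuple[int, int], int] = {}
    for r in range(rows):
        for c in range(cols):
            s = labels[r, c]
            for dr, dc in ((0, 1), (0, -1), (1, 0), (-1, 0)):
                r2, c2 = r + dr, c + dc
                if not (0 <= r2 < rows and 0 <= c2 < cols):
                    e[s] += 1
                elif labels[r2, c2] != s:
                    e[s] += 1
                    if (dr, dc) in ((0, 1), (1, 0)):
                        t = labels[r2, c2]
                        key = (min(s, t), max(s, t))
                        edge_counts[key] = edge_counts.get(key, 0) + 1

    bb = np.zeros((k, 4), dtype=np.int64)
    for s in range(k):
        rr, cc = np.nonzero(labels == s)
        bb[s] = (rr.min(), rr.max(), cc.min(), cc.max())

    if edge_counts:
        pairs = sorted(edge_counts)
        edges = np.array(pairs, dtype=np.int64)
        shared = np.array([edge_counts[p] for p in pairs], dtype=np.int64)
    else:
        edges = np.empty((0, 2), dtype=np.int64)
        shared = np.empty(0, dtype=np.int64)

    grid = RasterGrid(labels, origin_x, origin_y, cell_size, band_names=("segment_id",))
    return SegmentMap(
        labels=grid, n=n, band_sum=bsum, band_sumsq=bsumsq,
        perimeter_edges=e, bbox=bb, edges=edges, shared_edges=shared,
    )


TINY_SCENE_KW = dict(width_m=6.0, height_m=8.0, mosaic_cell=0.02,
                     mound_sigma_x=1.4, mound_sigma_y=2.2,
                     n_lcn=6, n_spg=6, n_dc=5, n_peb=12, n_hesdr=4, n_other=2,
                     dc_radius=(0.25, 0.5), hesdr_radius=(0.3, 0.7))


@pytest.fixture(scope="session")
def tiny_spec():
    return SceneSpec(seed=7, **TINY_SCENE_KW)


@pytest.fixture(scope="session")
def tiny_scene(tiny_spec):
    return generate_scene(tiny_spec)
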