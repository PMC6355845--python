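import numpy as np
import pandas as pd
import pytest

from mobia.classes import DEFAULT_SCHEME
from mobia.features import (
    FEATURE_COLUMNS,
    GLCM_LEVELS,
    bathy_features,
    build_feature_table,
    quantize,
    segment_majority_class,
    shape_features,
    spectral_features,
    texture_features,
)
from mobia.grid import ConfigurationError, DataError, RasterGrid
from mobia.segmentation import SegmentationParams, segment

from .conftest import segmap_from_labels
from .oracles import oracle_glcm_stats


def _grid(arr, cell=1.0, names=()):
    arr = np.asarray(arr, dtype=float)
    return RasterGrid(arr, origin_y=arr.shape[0] * cell, cell_size=cell,
                      band_names=names)


# ---------------------------------------------------------------------------
# spectral
# ---------------------------------------------------------------------------


class TestSpectral:
    def test_brute_force_equality(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 255, (9, 9, 3))
        labels = rng.integers(0, 4, (9, 9))
        sm = segmap_from_labels(labels, img)
        df = spectral_features(sm, _grid(img))
        for sid in range(4):
            mask = labels == sid
            for b, col in enumerate(["mean_red", "mean_green", "mean_blue"]):
                assert df.loc[sid, col] == pytest.approx(img[:, :, b][mask].mean())
            assert df.loc[sid, "brightness"] == pytest.approx(
                sum(img[:, :, b][mask].mean() for b in range(3))
            )

    def test_brightness_worked_example(self):
        """Brightness is the SUM of the band means: 120 + 130.5 + 132 = 382.5."""
        img = np.empty((2, 2, 3))
        img[:, :, 0] = 120.0
        img[:, :, 1] = 130.5
        img[:, :, 2] = 132.0
        sm = segmap_from_labels(np.zeros((2, 2), int), img)
        df = spectral_features(sm, _grid(img))
        assert df.loc[0, "brightness"] == pytest.approx(382.5)

    def test_band_name_requirement(self):
        img = np.zeros((3, 3, 2))
        sm = segmap_from_labels(np.zeros((3, 3), int), img)
        with pytest.raises(ConfigurationError):
            spectral_features(sm, _grid(img))
        df = spectral_features(sm, _grid(img, names=("a", "b")))
        assert list(df.columns[:2]) == ["mean_a", "mean_b"]


# ---------------------------------------------------------------------------
# texture
# ---------------------------------------------------------------------------


class TestQuantize:
    def test_min_max_mapping(self):
        v = np.array([[0.0, 10.0], [5.0, 10.0]])
        q = quantize(v, 4)
        assert q.min() == 0 and q.max() == 3
        assert q[0, 0] == 0 and q[0, 1] == 3 and q[1, 0] == 2

    def test_constant_field(self):
        assert (quantize(np.full((3, 3), 7.0), 8) == 0).all()

    def test_levels_bound(self):
        rng = np.random.default_rng(1)
        q = quantize(rng.uniform(-40, -10, (20, 20)), GLCM_LEVELS)
        assert q.min() >= 0 and q.max() == GLCM_LEVELS - 1


class TestTexture:
    def test_single_segment_matches_oracle(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(-35, -10, (6, 6))
        labels = np.zeros((6, 6), int)
        sm = segmap_from_labels(labels, vals)
        df = texture_features(sm, _grid(vals))
        q = quantize(vals, GLCM_LEVELS)
        want = oracle_glcm_stats(q, np.ones((6, 6), bool), GLCM_LEVELS)
        assert df.loc[0, "glcm_homogeneity"] == pytest.approx(want[0], abs=1e-12)
        assert df.loc[0, "glcm_entropy"] == pytest.approx(want[1], abs=1e-12)
        assert df.loc[0, "glcm_mean"] == pytest.approx(want[2], abs=1e-12)
        assert not df.loc[0, "glcm_single"]

    def test_multi_segment_matches_oracle(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(0, 50, (8, 7))
        labels = rng.integers(0, 3, (8, 7))
        sm = segmap_from_labels(labels, vals)
        df = texture_features(sm, _grid(vals))
        q = quantize(vals, GLCM_LEVELS)
        for sid in range(3):
            want = oracle_glcm_stats(q, labels == sid, GLCM_LEVELS)
            if want is None:
                assert df.loc[sid, "glcm_single"]
            else:
                assert df.loc[sid, "glcm_homogeneity"] == pytest.approx(want[0], abs=1e-12)
                assert df.loc[sid, "glcm_entropy"] == pytest.approx(want[1], abs=1e-12)
                assert df.loc[sid, "glcm_mean"] == pytest.approx(want[2], abs=1e-12)

    def test_hand_enumerated_2x2(self):
        """One segment, levels [[0,1],[0,1]] with 2-level quantisation.

        Pairs (both orientations, 4 offsets): horizontal (0,1)x2, vertical
        (0,0) and (1,1), diagonal (0,1), anti-diagonal (1,0) -> symmetric
        counts: (0,1):3+(1,0):3, (0,0):2, (1,1):2, total 12 entries after
        symmetrisation (each pair counted once per direction).
        """
        vals = np.array([[0.0, 1.0], [0.0, 1.0]])
        labels = np.zeros((2, 2), int)
        sm = segmap_from_labels(labels, vals)
        df = texture_features(sm, _grid(vals), levels=2)
        # symmetric counts: 01:3, 10:3, 00:2, 11:2 -> p = [2,3,3,2]/10... wait
        # enumerate: offsets (0,1): (0,1),(0,1); (1,0): (0,0),(1,1);
        # (1,1): (0,1); (1,-1): (1,0). Each counted in both orders:
        # (0,1):2+1=3, (1,0):0+1=1 -> plus mirrored copies: (0,1)=3+1=4? No:
        # the matrix adds (a,b) and (b,a) for every pair, so
        # N(0,1)=N(1,0)=4, N(0,0)=N(1,1)=2, total 12.
        p_same = 4.0 / 12.0  # (0,0)+(1,1)
        p_diff = 8.0 / 12.0
        want_homog = p_same + p_diff / 2.0
        want_entropy = -(4 * (2 / 12) * np.log(2 / 12) + 2 * (2 / 12) * np.log(2 / 12))
        # cross-check via the oracle, then against the hand numbers
        oh, oe, om = oracle_glcm_stats(vals.astype(int), np.ones((2, 2), bool), 2)
        assert oh == pytest.approx(want_homog)
        assert om == pytest.approx(0.5)
        assert df.loc[0, "glcm_homogeneity"] == pytest.approx(want_homog)
        assert df.loc[0, "glcm_entropy"] == pytest.approx(oe, abs=1e-12)
        assert df.loc[0, "glcm_mean"] == pytest.approx(0.5)

    def test_constant_intensity_is_perfectly_homogeneous(self):
        vals = np.full((5, 5), -20.0)
        sm = segmap_from_labels(np.zeros((5, 5), int), vals)
        df = texture_features(sm, _grid(vals))
        assert df.loc[0, "glcm_homogeneity"] == pytest.approx(1.0)
        assert df.loc[0, "glcm_entropy"] == pytest.approx(0.0)

    def test_coarse_grid_fallback_flag(self):
        """A segment smaller than one intensity cell gets the fallback."""
        labels = np.zeros((8, 8), int)
        labels[3, 3] = 1  # single mosaic pixel
        mosaic_vals = np.random.default_rng(4).uniform(0, 255, (8, 8))
        sm = segmap_from_labels(labels, mosaic_vals, cell_size=0.25)
        # intensity raster at 4x coarser cells: 2x2
        intensity = RasterGrid(np.array([[1.0, 2.0], [3.0, 4.0]]),
                               origin_y=2.0, cell_size=1.0)
        df = texture_features(sm, intensity)
        assert df.loc[1, "glcm_single"]
        assert df.loc[1, "glcm_homogeneity"] == 1.0
        assert df.loc[1, "glcm_entropy"] == 0.0
        assert np.isfinite(df.loc[1, "glcm_mean"])

    def test_multiband_intensity_rejected(self):
        sm = segmap_from_labels(np.zeros((3, 3), int), np.zeros((3, 3)))
        with pytest.raises(DataError):
            texture_features(sm, RasterGrid(np.zeros((3, 3, 2)), origin_y=3.0))


# ---------------------------------------------------------------------------
# shape
# ---------------------------------------------------------------------------


class TestShape:
    def test_single_pixel(self):
        labels = np.zeros((1, 1), int)
        df = shape_features(segmap_from_labels(labels, np.zeros((1, 1))))
        row = df.loc[0]
        assert row["area"] == 1.0
        assert row["border_length"] == 4.0
        assert row["shape_index"] == pytest.approx(1.0)
        assert row["compactness"] == pytest.approx(4 / np.pi)
        assert row["roundness"] == pytest.approx(np.pi / 4)
        assert row["asymmetry"] == 0.0
        assert row["border_index"] == pytest.approx(1.0)
        assert row["elliptic_fit"] == 1.0
        assert row["rectangular_fit"] == 1.0
        assert row["density"] == pytest.approx(1.0)

    def test_square(self):
        labels = np.zeros((10, 10), int)
        df = shape_features(segmap_from_labels(labels, np.zeros((10, 10))))
        row = df.loc[0]
        assert row["area"] == 100.0
        assert row["border_length"] == 40.0
        assert row["shape_index"] == pytest.approx(1.0)
        assert row["compactness"] == pytest.approx(4 / np.pi)
        assert row["asymmetry"] == pytest.approx(0.0, abs=1e-12)
        assert row["border_index"] == pytest.approx(1.0)
        assert row["main_direction"] == pytest.approx(0.0)
        # rectangular fit of a square is high; elliptic lower
        assert row["rectangular_fit"] > 0.95
        assert 0.5 < row["elliptic_fit"] <= 1.0

    def test_horizontal_bar(self):
        labels = np.ones((5, 20), int)
        labels[1, :] = 0  # 1x20 bar is segment 0, rest segment 1
        df = shape_features(segmap_from_labels(labels, np.zeros((5, 20))))
        row = df.loc[0]
        n, e = 20.0, 42.0
        lam1 = (20**2 - 1) / 12.0
        assert row["area"] == n
        assert row["border_length"] == e
        assert row["shape_index"] == pytest.approx(e / (4 * np.sqrt(n)))
        assert row["main_direction"] == pytest.approx(90.0)
        assert row["asymmetry"] == pytest.approx(1.0)
        assert row["border_index"] == pytest.approx(1.0)  # 42 / (2*(20+1))
        assert row["rectangular_fit"] == pytest.approx(1.0)
        assert row["density"] == pytest.approx(np.sqrt(n) / (1 + np.sqrt(lam1)))

    def test_vertical_bar_direction(self):
        labels = np.ones((20, 5), int)
        labels[:, 2] = 0
        df = shape_features(segmap_from_labels(labels, np.zeros((20, 5))))
        assert df.loc[0, "main_direction"] == pytest.approx(0.0)

    def test_diagonal_direction(self):
        labels = np.ones((12, 12), int)
        for i in range(12):
            labels[i, i] = 0  # NW-SE diagonal
        df = shape_features(segmap_from_labels(labels, np.zeros((12, 12))))
        # NW-SE runs at 135 deg clockwise from north (equivalently -45)
        assert df.loc[0, "main_direction"] == pytest.approx(135.0)

    def test_units_scale_with_cell_size(self):
        labels = np.zeros((4, 6), int)
        a = shape_features(segmap_from_labels(labels, np.zeros((4, 6)), cell_size=1.0))
        b = shape_features(segmap_from_labels(labels, np.zeros((4, 6)), cell_size=0.5))
        assert b.loc[0, "area"] == pytest.approx(a.loc[0, "area"] / 4)
        assert b.loc[0, "border_length"] == pytest.approx(a.loc[0, "border_length"] / 2)
        # dimensionless descriptors are invariant
        for col in ("shape_index", "compactness", "roundness", "asymmetry",
                    "border_index", "main_direction"):
            assert b.loc[0, col] == pytest.approx(a.loc[0, col])

    def test_roundness_orders_shapes(self):
        """A blocky blob is rounder than a long thin bar."""
        square = np.ones((12, 12), int)
        square[2:8, 2:8] = 0
        bar = np.ones((12, 12), int)
        bar[5, 1:11] = 0
        r_sq = shape_features(
            segmap_from_labels(square, np.zeros((12, 12)))).loc[0, "roundness"]
        r_bar = shape_features(
            segmap_from_labels(bar, np.zeros((12, 12)))).loc[0, "roundness"]
        assert r_sq > r_bar

    def test_concave_border_index(self):
        """A U-shaped segment: perimeter 36, bounding rectangle 8x6 -> 36/28."""
        labels = np.ones((10, 12), int)
        labels[2:8, 2:4] = 0   # left wall
        labels[2:8, 8:10] = 0  # right wall
        labels[6:8, 2:10] = 0  # base
        df = shape_features(segmap_from_labels(labels, np.zeros((10, 12))))
        assert df.loc[0, "border_index"] == pytest.approx(36.0 / 28.0, abs=0.02)


# ---------------------------------------------------------------------------
# bathymetric
# ---------------------------------------------------------------------------


class TestBathyFeatures:
    def _plane(self, rows=16, cols=16, cell=1.0, a_east=0.1):
        c = np.arange(cols)
        x = (c[None, :] + 0.5) * cell
        z = -976.0 + a_east * x * np.ones((rows, 1))
        return RasterGrid(z, origin_y=rows * cell, cell_size=cell)

    def test_plane_slope_aspect_depth(self):
        # interior segment only: Horn gradients are exact away from the border
        bathy = self._plane()
        labels = np.ones((16, 16), int)
        labels[4:12, 4:12] = 0
        sm = segmap_from_labels(labels, np.zeros((16, 16)), cell_size=1.0)
        df = bathy_features(sm, bathy)
        want_depth = np.mean([-976.0 + 0.1 * (c + 0.5) for c in range(4, 12)])
        assert df.loc[0, "mean_depth"] == pytest.approx(want_depth)
        assert df.loc[0, "slope"] == pytest.approx(
            np.degrees(np.arctan(0.1)), abs=1e-9
        )
        assert df.loc[0, "aspect"] == pytest.approx(270.0)
        assert not df.loc[0, "aspect_flat"]
        assert not df.loc[0, "bathy_sliver"]
        assert df.loc[0, "curvature"] == pytest.approx(0.0, abs=1e-9)

    def test_circular_aspect_mean(self):
        """Aspects oscillating about north average to ~0, not ~180.

        The surface dips north with a small east-west ripple, so per-cell
        aspects lie just either side of 0/360 deg.  An arithmetic mean would
        land near 180; the circular mean must stay near 0.
        """
        rows, cols, cell = 24, 24, 1.0
        rr = np.arange(rows)[:, None] + 0.5
        cc = np.arange(cols)[None, :] + 0.5
        y = rows - rr
        x = cc
        z = -976.0 - 0.1 * y + 0.02 * np.sin(2 * np.pi * x / 8.0)
        bathy = RasterGrid(np.broadcast_to(z, (rows, cols)).copy(),
                           origin_y=rows, cell_size=cell)
        sm = segmap_from_labels(np.zeros((rows, cols), int), np.zeros((rows, cols)))
        df = bathy_features(sm, bathy)
        a = df.loc[0, "aspect"]
        dist_from_north = min(a, 360.0 - a)
        assert dist_from_north < 2.0

    def test_flat_bathy_flagged(self):
        bathy = RasterGrid(np.full((8, 8), -976.0), origin_y=8.0)
        sm = segmap_from_labels(np.zeros((8, 8), int), np.zeros((8, 8)))
        df = bathy_features(sm, bathy)
        assert df.loc[0, "aspect_flat"]
        assert df.loc[0, "aspect"] == 0.0
        assert df.loc[0, "slope"] == pytest.approx(0.0)

    def test_sliver_fallback(self):
        """Segments too small to cover a bathy cell centre use the nearest cell."""
        labels = np.ones((8, 8), int)
        labels[0, 0] = 0  # tiny corner segment at 0.25 m pixels
        sm = segmap_from_labels(labels, np.zeros((8, 8)), cell_size=0.25)
        bathy = self._plane(rows=2, cols=2, cell=1.0)
        df = bathy_features(sm, bathy)
        assert df.loc[0, "bathy_sliver"]
        assert df.loc[0, "mean_depth"] == pytest.approx(bathy.values[0, 0])
        assert not df.loc[1, "bathy_sliver"]


# ---------------------------------------------------------------------------
# assembly and labels
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def scene_pieces(tiny_scene):
    sm = segment(tiny_scene.mosaic, SegmentationParams(scale=100.0))
    return tiny_scene, sm


class TestBuildFeatureTable:

    def test_canonical_columns_and_finiteness(self, scene_pieces):
        scene, sm = scene_pieces
        table = build_feature_table(sm, scene.mosaic, scene.bathy, scene.backscatter)
        assert list(table.columns[: len(FEATURE_COLUMNS)]) == FEATURE_COLUMNS
        assert len(table) == sm.n_segments
        assert np.isfinite(table[FEATURE_COLUMNS].to_numpy()).all()

    def test_label_column(self, scene_pieces):
        scene, sm = scene_pieces
        labels = segment_majority_class(sm, scene.class_map, DEFAULT_SCHEME)
        table = build_feature_table(
            sm, scene.mosaic, scene.bathy, scene.backscatter, labels
        )
        assert "label" in table.columns
        assert set(table["label"]) <= set(DEFAULT_SCHEME.all_codes)

    def test_luminance_fallback(self, scene_pieces):
        scene, sm = scene_pieces
        lum = np.mean(
            [scene.mosaic.band(i).astype(float) for i in range(3)], axis=0
        )
        via_fallback = build_feature_table(sm, scene.mosaic, scene.bathy, None)
        explicit = texture_features(sm, scene.mosaic.with_values(lum, ("luminance",)))
        pd.testing.assert_series_equal(
            via_fallback["glcm_mean"], explicit["glcm_mean"], check_names=False
        )


class TestMajorityClass:
    def test_hand_example(self):
        seg = np.array([[0, 0, 1, 1], [0, 0, 1, 1], [2, 2, 2, 2], [2, 2, 2, 2]])
        cls = np.array([[1, 1, 3, 3], [1, 2, 3, 8], [4, 4, 4, 5], [4, 4, 5, 5]])
        sm = segmap_from_labels(seg, np.zeros((4, 4)))
        cmap = RasterGrid(cls.astype(np.uint8), origin_y=4.0)
        got = segment_majority_class(sm, cmap, DEFAULT_SCHEME)
        assert list(got) == ["LCN", "SPG", "HEMS"]

    def test_shape_mismatch(self):
        sm = segmap_from_labels(np.zeros((3, 3), int), np.zeros((3, 3)))
        cmap = RasterGrid(np.ones((4, 4), dtype=np.uint8), origin_y=4.0)
        with pytest.raises(DataError):
            segment_majority_class(sm, cmap, DEFAULT_SCHEME)

    def test_tie_goes_to_lower_id(self):
        seg = np.zeros((2, 2), int)
        cls = np.array([[1, 1], [3, 3]], dtype=np.uint8)  # 2 LCN vs 2 SPG
        sm = segmap_from_labels(seg, np.zeros((2, 2)))
        got = segment_majority_class(sm, RasterGrid(cls, origin_y=2.0), DEFAULT_SCHEME)
        assert got.iloc[0] == "LCN"
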