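import numpy as np
import pytest

from spsi.bands import BandSet, CAMERA_BANDS
from spsi.masking import GreenMask, build_green_mask
from spsi.raster import GeoTransform, PlotROI, ReflectanceImage
from spsi.texture import (FEATURES, GlcmConfig, glcm_features, glcm_window,
                          quantize, sliding_features, texture_image,
                          zonal_texture)
from shapely.geometry import box

from oracles import brute_sliding_features, brute_window_features


class TestQuantize:
    def test_hand_example(self):
        img = np.array([[0.0, 0.5, 1.0]])
        q = quantize(img, np.ones_like(img, bool), 4)
        assert q.tolist() == [[0, 2, 3]]

    def test_constant_image(self):
        q = quantize(np.full((3, 3), 0.4), np.ones((3, 3), bool), 64)
        assert (q == 0).all()

    def test_monotone(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(size=(6, 6))
        q = quantize(x, np.ones_like(x, bool), 16)
        order = np.argsort(x.ravel())
        assert (np.diff(q.ravel()[order]) >= 0).all()

    def test_invalid_pixels_get_sentinel(self):
        x = np.array([[0.1, 0.9], [0.5, 0.2]])
        valid = np.array([[True, False], [True, True]])
        q = quantize(x, valid, 8)
        assert q[0, 1] == -1 and (q[valid] >= 0).all()

    def test_no_valid_pixels_raises(self):
        with pytest.raises(ValueError):
            quantize(np.ones((2, 2)), np.zeros((2, 2), bool), 8)


class TestGlcmWindow:
    cfg = GlcmConfig(levels=4)

    def test_uniform_window_single_cell(self):
        P = glcm_window(np.ones((3, 3), int), np.ones((3, 3), bool), self.cfg)
        assert P[1, 1] == 1.0 and P.sum() == 1.0

    def test_checkerboard_horizontal(self):
        cfg = GlcmConfig(angle=0, levels=2)
        q = np.indices((3, 3)).sum(axis=0) % 2
        P = glcm_window(q, np.ones((3, 3), bool), cfg)
        assert P[0, 1] == pytest.approx(0.5) and P[1, 0] == pytest.approx(0.5)
        assert P[0, 0] == 0 and P[1, 1] == 0

    def test_masked_rows_match_brute_force(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            q = rng.integers(0, 4, size=(3, 3))
            valid = rng.random((3, 3)) > 0.3
            valid[1, :] = False      # centre row invalid
            P = glcm_window(q, valid, self.cfg)
            ref = brute_window_features(q, valid, 3, 1, 45, True)
            if P is None:
                assert ref is None
                continue
            ours = glcm_features(P)
            for name in FEATURES:
                if np.isnan(ref[name]):
                    assert np.isnan(ours[name])
                else:
                    assert ours[name] == pytest.approx(ref[name], abs=1e-12)

    def test_all_invalid_returns_none(self):
        assert glcm_window(np.ones((3, 3), int),
                           np.zeros((3, 3), bool), self.cfg) is None


class TestGlcmFeatures:
    def test_degenerate_single_entry(self):
        P = np.zeros((8, 8))
        P[5, 5] = 1.0
        f = glcm_features(P)
        assert f["MEA"] == 5 and f["VAR"] == 0 and f["HOM"] == 1
        assert f["CON"] == 0 and f["DIS"] == 0 and f["ENT"] == 0
        assert f["SEM"] == 1 and np.isnan(f["COR"])

    def test_two_cell_hand_evaluation(self):
        P = np.zeros((4, 4))
        P[0, 1] = P[1, 0] = 0.5
        f = glcm_features(P)
        assert f["MEA"] == pytest.approx(0.5)
        assert f["VAR"] == pytest.approx(0.25)
        assert f["CON"] == pytest.approx(1.0)
        assert f["DIS"] == pytest.approx(1.0)
        assert f["HOM"] == pytest.approx(0.5)
        assert f["ENT"] == pytest.approx(np.log(2))
        assert f["SEM"] == pytest.approx(0.5)
        assert f["COR"] == pytest.approx(-1.0)

    def test_random_matrices_match_literal_formulas(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            P = rng.random((4, 4))
            P /= P.sum()
            f = glcm_features(P)
            i = np.arange(4)[:, None] * np.ones((1, 4))
            j = i.T
            assert f["MEA"] == pytest.approx((i * P).sum(), abs=1e-12)
            assert f["CON"] == pytest.approx(((i - j) ** 2 * P).sum(), abs=1e-12)
            assert f["ENT"] == pytest.approx(-(P * np.log(P)).sum(), abs=1e-12)
            assert f["SEM"] == pytest.approx((P ** 2).sum(), abs=1e-12)

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError):
            glcm_features(np.ones((3, 3)))


@pytest.mark.parametrize("angle", [0, 45, 90, 135])
@pytest.mark.parametrize("symmetric", [True, False])
def test_sliding_engine_matches_brute_force(angle, symmetric):
    """Windowed features equal explicit per-window pair enumeration."""
    rng = np.random.default_rng(angle + symmetric)
    cfg = GlcmConfig(angle=angle, symmetric=symmetric, levels=8)
    for _ in range(25):
        q = rng.integers(0, 8, size=(8, 8))
        eligible = rng.random((8, 8)) > 0.25
        q[~eligible] = -1
        ours = sliding_features(q, eligible, cfg)
        ref = brute_sliding_features(q, eligible, 3, 1, angle, symmetric)
        np.testing.assert_allclose(ours, ref, atol=1e-10, equal_nan=True)


def test_symmetric_cor_is_pearson_of_paired_levels():
    """With symmetric accumulation, COR equals the Pearson correlation of
    the pooled (i, j) level pairs."""
    rng = np.random.default_rng(9)
    cfg = GlcmConfig(levels=8)
    for _ in range(50):
        q = rng.integers(0, 8, size=(3, 3))
        P = glcm_window(q, np.ones((3, 3), bool), cfg)
        cor = glcm_features(P)["COR"]
        pairs = [(q[r, c], q[r - 1, c + 1])
                 for r in range(1, 3) for c in range(0, 2)]
        xs = [i for i, j in pairs] + [j for i, j in pairs]
        ys = [j for i, j in pairs] + [i for i, j in pairs]
        if np.std(xs) == 0 or np.std(ys) == 0:
            assert np.isnan(cor)
        else:
            assert cor == pytest.approx(np.corrcoef(xs, ys)[0, 1], abs=1e-10)


def test_against_skimage_on_full_windows():
    """Cross-check the unmasked window path against scikit-image.

    skimage measures angles with row offsets downward, so its 3*pi/4
    offset (+1, -1) is the symmetric equivalent of the up-right pairing.
    """
    graycomatrix = pytest.importorskip("skimage.feature").graycomatrix
    rng = np.random.default_rng(4)
    cfg = GlcmConfig(levels=6)
    for _ in range(20):
        q = rng.integers(0, 6, size=(3, 3))
        ours = glcm_window(q, np.ones((3, 3), bool), cfg)
        ref = graycomatrix(q.astype(np.uint8), [1], [3 * np.pi / 4], levels=6,
                           symmetric=True, normed=True)[:, :, 0, 0]
        np.testing.assert_allclose(ours, ref, atol=1e-12)


class TestTextureImage:
    def _image(self, pixels):
        bands = BandSet(tuple(450.0 + 50 * i for i in range(pixels.shape[0])))
        return ReflectanceImage(pixels, bands,
                                transform=GeoTransform(0, pixels.shape[1], 1, 1))

    def test_constant_image_identities(self):
        img = self._image(np.full((2, 6, 6), 0.3))
        cube = texture_image(img, None, GlcmConfig())
        interior = (slice(1, 5), slice(1, 5))
        for b in range(2):
            assert (cube.plane(450 + 50 * b, "CON")[interior] == 0).all()
            assert (cube.plane(450 + 50 * b, "VAR")[interior] == 0).all()
            assert (cube.plane(450 + 50 * b, "ENT")[interior] == 0).all()
            assert (cube.plane(450 + 50 * b, "HOM")[interior] == 1).all()
            assert (cube.plane(450 + 50 * b, "SEM")[interior] == 1).all()

    def test_border_is_invalid(self):
        img = self._image(np.random.default_rng(0).uniform(size=(2, 5, 5)))
        cube = texture_image(img, None, GlcmConfig())
        assert np.isnan(cube.values[:, :, 0, :]).all()
        assert np.isnan(cube.values[:, :, :, -1]).all()

    def test_band_permutation_no_leakage(self):
        rng = np.random.default_rng(6)
        pixels = rng.uniform(size=(3, 7, 7))
        a = texture_image(self._image(pixels), None, GlcmConfig())
        flipped = pixels[::-1].copy()
        b = texture_image(self._image(flipped), None, GlcmConfig())
        np.testing.assert_allclose(a.values, b.values[::-1], equal_nan=True)

    def test_masked_vs_all_differ_on_striped_scene(self, small_scene):
        mask = build_green_mask(small_scene.image)
        all_cube = texture_image(small_scene.image, None, GlcmConfig())
        green_cube = texture_image(small_scene.image, mask,
                                   GlcmConfig(masked=True))
        a = all_cube.plane(850.0, "COR")
        g = green_cube.plane(850.0, "COR")
        both = np.isfinite(a) & np.isfinite(g)
        assert both.any()
        assert np.nanmax(np.abs(a[both] - g[both])) > 0.0

    def test_two_modes_times_eight_features_shapes(self, small_scene):
        mask = build_green_mask(small_scene.image)
        cubes = [texture_image(small_scene.image, None, GlcmConfig()),
                 texture_image(small_scene.image, mask, GlcmConfig(masked=True))]
        n_sets = 0
        for cube in cubes:
            assert cube.values.shape == (6, 8) + small_scene.image.shape
            n_sets += len(cube.features)
        assert n_sets == 16
        assert {c.pixel_mode for c in cubes} == {"all", "green"}

    def test_masked_mode_requires_mask(self, small_scene):
        with pytest.raises(ValueError):
            texture_image(small_scene.image, None, GlcmConfig(masked=True))


class TestZonalTexture:
    def test_constant_cube(self):
        values = np.full((2, 8, 5, 5), 0.4)
        cube_bands = BandSet((450.0, 850.0))
        from spsi.texture import TextureCube
        cube = TextureCube(values, FEATURES, cube_bands,
                           GeoTransform(0, 5, 1, 1))
        stats = zonal_texture(cube, PlotROI("p", box(0, 0, 5, 5)))
        assert all(v == pytest.approx(0.4) for v in stats.values.values())

    def test_additivity_over_disjoint_rois(self, small_scene):
        mask = build_green_mask(small_scene.image)
        cube = texture_image(small_scene.image, mask, GlcmConfig(masked=True))
        H = small_scene.image.shape[0]
        left = PlotROI("l", box(10, 10, 30, H - 10))
        right = PlotROI("r", box(30, 10, 50, H - 10))
        union = PlotROI("u", box(10, 10, 50, H - 10))
        plane = cube.plane(850.0, "MEA")
        from spsi.raster import roi_pixel_mask
        def stat(roi):
            sel = roi_pixel_mask(roi, cube.transform, plane.shape)
            ok = sel & np.isfinite(plane)
            return plane[ok].sum(), ok.sum()
        sl, nl = stat(left)
        sr, nr = stat(right)
        su, nu = stat(union)
        assert nu == nl + nr
        assert su == pytest.approx(sl + sr, rel=1e-9)
        stats = zonal_texture(cube, union)
        assert stats.get(850.0, "MEA") == pytest.approx(su / nu, rel=1e-9)

    def test_cor_bounds(self, small_scene):
        mask = build_green_mask(small_scene.image)
        cube = texture_image(small_scene.image, mask, GlcmConfig(masked=True))
        for roi in small_scene.rois:
            c = zonal_texture(cube, roi).get(850.0, "COR")
            assert -1.0 <= c <= 1.0


def test_glcm_config_validation():
    with pytest.raises(ValueError):
        GlcmConfig(window=4)
    with pytest.raises(ValueError):
        GlcmConfig(window=1)
    with pytest.raises(ValueError):
        GlcmConfig(angle=30)
    with pytest.raises(ValueError):
        GlcmConfig(levels=1)
    with pytest.raises(ValueError):
        GlcmConfig(distance=0)
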