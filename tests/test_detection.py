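import numpy as np
import pytest
from scipy import ndimage as ndi

from quadmosaic.detection import (
    DetectionParams,
    LabelMask,
    TroughNotFoundWarning,
    binarize,
    detect_cells,
    find_cell_centroids,
    gaussian_blur,
    params_for_cell_radius,
    trough_threshold,
    watershed_split,
)
from quadmosaic.image_io import RasterImage


def disk_mask(shape, centre, radius):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (xx - centre[0]) ** 2 + (yy - centre[1]) ** 2 <= radius**2


class TestGaussianBlur:
    def test_radius_zero_identity(self, random_image):
        out = gaussian_blur(random_image, 0)
        np.testing.assert_array_equal(out.pixels, random_image.pixels)

    def test_constant_unchanged(self):
        img = RasterImage(np.full((16, 16), 9.0))
        np.testing.assert_allclose(gaussian_blur(img, 3.0).pixels, 9.0)

    def test_mean_preserved(self, random_image):
        out = gaussian_blur(random_image, 2.0)
        assert out.pixels.mean() == pytest.approx(random_image.pixels.mean(), rel=5e-3)

    def test_impulse_response_matches_gaussian(self):
        img = np.zeros((41, 41))
        img[20, 20] = 1.0
        out = gaussian_blur(RasterImage(img), 2.0).pixels
        assert out.sum() == pytest.approx(1.0, rel=1e-6)
        np.testing.assert_allclose(out, out[::-1, :], atol=1e-12)  # symmetric
        np.testing.assert_allclose(out, out.T, atol=1e-12)
        # central row follows a sampled Gaussian with sigma = 2
        xs = np.arange(41) - 20
        profile = out[20] / out[20].sum()
        ref = np.exp(-(xs**2) / (2 * 2.0**2))
        ref /= ref.sum()
        np.testing.assert_allclose(profile, ref, atol=5e-4)

    def test_negative_radius_rejected(self, random_image):
        with pytest.raises(ValueError):
            gaussian_blur(random_image, -1)


class TestTroughThreshold:
    def test_two_gaussian_mixture(self):
        rng = np.random.default_rng(7)
        v = np.concatenate(
            [rng.normal(60, 10, 128 * 64), rng.normal(180, 10, 128 * 64)]
        ).reshape(128, 128)
        cutoff = trough_threshold(RasterImage(np.clip(v, 0, 255)))
        assert 90 < cutoff < 150

    def test_binary_values_cutoff_strictly_between(self):
        rng = np.random.default_rng(3)
        v = np.zeros(64 * 64)
        v[::2] = 255.0
        rng.shuffle(v)
        cutoff = trough_threshold(RasterImage(v.reshape(64, 64)))
        assert 0 < cutoff < 255

    def test_unimodal_falls_back_to_otsu(self):
        from skimage.filters import threshold_otsu

        rng = np.random.default_rng(42)
        v = np.clip(rng.normal(128, 20, 128 * 128), 0, 255).reshape(128, 128)
        with pytest.warns(TroughNotFoundWarning):
            cutoff = trough_threshold(RasterImage(v))
        assert cutoff == pytest.approx(threshold_otsu(v))

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            trough_threshold(RasterImage(np.full((8, 8), 5.0)))


class TestBinarize:
    def test_basic(self):
        img = RasterImage(np.array([[1.0, 2.0, 3.0]]))
        np.testing.assert_array_equal(binarize(img, 2.0), [[False, False, True]])

    def test_invert_complementarity(self, random_image):
        cutoff = 128.0
        fwd = binarize(random_image, cutoff)
        inv = binarize(random_image, cutoff, invert=True)
        equal = random_image.pixels == cutoff
        np.testing.assert_array_equal(fwd | inv | equal, np.ones_like(fwd))
        assert not np.any(fwd & inv)

    def test_all_below_cutoff_empty(self):
        img = RasterImage(np.full((4, 4), 1.0))
        assert not binarize(img, 5.0).any()


class TestWatershedSplit:
    def test_single_disk_one_label(self):
        mask = disk_mask((32, 32), (16, 16), 8)
        assert watershed_split(mask).n_labels == 1

    def test_two_overlapping_disks_split(self):
        mask = disk_mask((40, 60), (22, 20), 8) | disk_mask((40, 60), (36, 20), 8)
        assert ndi.label(mask)[1] == 1  # genuinely merged input
        lm = watershed_split(mask)
        assert lm.n_labels == 2

    def test_empty_mask(self):
        lm = watershed_split(np.zeros((16, 16), dtype=bool))
        assert lm.n_labels == 0

    def test_min_area_filter(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[2:4, 2:4] = True  # 4 px
        mask[10:16, 10:16] = True  # 36 px
        assert watershed_split(mask, min_area=5).n_labels == 1
        assert watershed_split(mask, min_area=4).n_labels == 2

    def test_max_area_removes_plateau_before_watershed(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[:, :20] = True  # 800-px plateau
        mask[5:15, 25:35] = True  # 100-px cell
        lm = watershed_split(mask, min_area=4, max_area=400)
        assert lm.n_labels >= 1
        # the plateau must not contribute any region
        assert not np.any(lm.labels[:, :20])

    def test_never_merges(self, rng):
        mask = rng.random((48, 48)) > 0.6
        lm = watershed_split(mask, min_area=1)
        assert lm.n_labels >= ndi.label(mask)[1]


class TestFindCellCentroids:
    def test_square_label_centroid(self):
        labels = np.zeros((32, 32), dtype=np.int32)
        labels[10:20, 10:20] = 1
        cs = find_cell_centroids(LabelMask(labels))
        assert cs.points[0] == pytest.approx([14.5, 14.5])

    def test_one_centroid_per_label(self, rng):
        mask = disk_mask((64, 64), (16, 16), 6) | disk_mask((64, 64), (44, 40), 7)
        lm = watershed_split(mask)
        cs = find_cell_centroids(lm)
        assert len(cs) == lm.n_labels == 2

    def test_centroid_inside_bounding_box(self, rng):
        labels, n = ndi.label(rng.random((32, 32)) > 0.7)
        cs = find_cell_centroids(LabelMask(labels.astype(np.int32)))
        for k, (x, y) in enumerate(cs.points, start=1):
            ys, xs = np.nonzero(labels == k)
            assert xs.min() <= x <= xs.max()
            assert ys.min() <= y <= ys.max()

    def test_regional_maxima_mode(self):
        labels = np.zeros((16, 16), dtype=np.int32)
        labels[4:12, 4:12] = 1
        intensity = np.zeros((16, 16))
        intensity[9, 6] = 10.0
        cs = find_cell_centroids(LabelMask(labels), RasterImage(intensity), mode="regional-maxima")
        assert cs.points[0] == pytest.approx([6.0, 9.0])

    def test_regional_maxima_requires_intensity(self):
        labels = np.zeros((4, 4), dtype=np.int32)
        labels[1, 1] = 1
        with pytest.raises(ValueError, match="intensity"):
            find_cell_centroids(LabelMask(labels), mode="regional-maxima")


class TestDetectCells:
    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            detect_cells(RasterImage(np.full((32, 32), 7.0)))

    def test_single_bright_disk(self):
        rng = np.random.default_rng(11)
        img = np.full((64, 64), 50.0)
        img[disk_mask((64, 64), (30, 34), 6)] = 200.0
        img += rng.normal(0, 5, img.shape)
        cs = detect_cells(RasterImage(np.clip(img, 0, 255)))
        assert len(cs) == 1
        assert np.hypot(cs.points[0, 0] - 30, cs.points[0, 1] - 34) < 1.0

    def test_translation_equivariance(self):
        rng = np.random.default_rng(5)
        img = np.full((96, 96), 40.0)
        for cx, cy in [(30, 30), (60, 44), (40, 70)]:
            img[disk_mask((96, 96), (cx, cy), 6)] = 220.0
        img += rng.normal(0, 2, img.shape)
        shifted = np.roll(img, (7, 11), axis=(0, 1))  # dy=7, dx=11
        c0 = detect_cells(RasterImage(np.clip(img, 0, 255))).points
        c1 = detect_cells(RasterImage(np.clip(shifted, 0, 255))).points
        c0 = c0[np.lexsort(c0.T)]
        c1 = c1[np.lexsort(c1.T)] - np.array([11, 7])
        np.testing.assert_allclose(c0, c1, atol=0.3)

    def test_constant_offset_invariance(self):
        rng = np.random.default_rng(9)
        img = np.full((64, 64), 60.0)
        img[disk_mask((64, 64), (32, 32), 7)] = 180.0
        img += rng.normal(0, 2, img.shape)
        c0 = detect_cells(RasterImage(img)).points
        c1 = detect_cells(RasterImage(img + 20.0)).points
        np.testing.assert_allclose(c0, c1, atol=1e-9)

    def test_edge_margin_drops_border_regions(self):
        img = np.full((64, 64), 50.0)
        img[disk_mask((64, 64), (4, 30), 5)] = 200.0  # touches border
        img[disk_mask((64, 64), (40, 30), 5)] = 200.0
        all_cells = detect_cells(RasterImage(img), DetectionParams())
        interior = detect_cells(RasterImage(img), DetectionParams(edge_margin=8))
        assert len(all_cells) == 2
        assert len(interior) == 1
        assert interior.points[0, 0] == pytest.approx(40, abs=1)

    def test_mosaic_recovery(self, default_mosaic):
        from quadmosaic.enhancement import enhance
        from quadmosaic.evaluation import match_centroids
        from quadmosaic.quadrant_math import directional_splits, normalize_quadrant_means

        qset, truth, _, _ = default_mosaic
        enhanced = enhance(directional_splits(normalize_quadrant_means(qset)))
        auto = detect_cells(enhanced, params_for_cell_radius(10.0))
        assert abs(len(auto) - len(truth)) <= 5
        m = match_centroids(auto, truth, radius=3.0)
        assert m.true_positives / m.n_manual >= 0.95


def test_params_for_cell_radius_scaling():
    p = params_for_cell_radius(10.0)
    assert p.min_area == 31
    assert p.max_area == 628
    assert p.edge_margin == 8
    with pytest.raises(ValueError):
        params_for_cell_radius(0)
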