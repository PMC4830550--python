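import numpy as np
import pytest

from cropsense.core_io import ValidationError
from cropsense.image_height import (binarize, circle_roi, clean_mask,
                                    crop_height_from_extents,
                                    estimate_from_image, estimate_from_masks,
                                    pixel_features, segment,
                                    train_pixel_classifier, vertical_extent)
from cropsense.synthetic_data import render_marker_image


class TestPixelFeatures:
    def test_constant_image_has_zero_gradient_and_variance(self):
        img = np.full((40, 40, 3), 120.0)
        feats = pixel_features(img, scales=(1.0, 2.0))
        # per scale: 3 color, then edge, texture, coherence
        for s in range(2):
            base = s * 6
            assert np.allclose(feats[..., base + 3], 0.0, atol=1e-9)
            assert np.allclose(feats[..., base + 4], 0.0, atol=1e-6)

    def test_step_edge_gradient_peaks_at_edge(self):
        img = np.zeros((40, 40, 3))
        img[:, 20:] = 200.0
        feats = pixel_features(img, scales=(1.0,))
        grad = feats[..., 3]
        peak_cols = np.argmax(grad, axis=1)
        assert np.all((peak_cols >= 19) & (peak_cols <= 20))

    def test_feature_count_bookkeeping(self):
        img = np.zeros((32, 32, 3))
        assert pixel_features(img, scales=(1, 2, 4)).shape == (32, 32, 18)


class TestClassifier:
    def test_separable_colors_learned_exactly(self):
        rng = np.random.default_rng(0)
        img = np.zeros((40, 40, 3))
        labels = np.full((40, 40), -1, dtype=int)
        colors = [(200, 0, 0), (0, 200, 0), (0, 0, 200), (200, 200, 0)]
        for cls, color in enumerate(colors):
            r0 = 10 * cls
            img[r0:r0 + 10] = color
            pick = rng.integers(0, 40, 30)
            labels[r0 + 5, pick] = cls
        clf = train_pixel_classifier([(img, labels)], n_trees=20, seed=1)
        maps = segment(clf, img)
        pred = maps.argmax(axis=2)
        sel = labels != -1
        assert np.mean(pred[sel] == labels[sel]) == 1.0

    def test_missing_class_named_in_error(self):
        img = np.zeros((35, 35, 3))
        labels = np.full((35, 35), -1, dtype=int)
        labels[0, :5] = 0
        labels[1, :5] = 1
        labels[2, :5] = 2  # class 3 (circle) never labeled
        with pytest.raises(ValidationError, match="circle"):
            train_pixel_classifier([(img, labels)], n_trees=5, seed=0)

    def test_probabilities_sum_to_one_and_deterministic(self, trained_classifier):
        img, _ = render_marker_image(100, seed=9)
        maps = segment(trained_classifier, img)
        np.testing.assert_allclose(maps.sum(axis=2), 1.0, atol=1e-6)
        maps2 = segment(trained_classifier, img)
        np.testing.assert_array_equal(maps, maps2)


class TestBinarizeAndClean:
    def test_tie_at_half_included(self):
        maps = np.zeros((2, 2, 4))
        maps[..., 1] = 0.5
        assert binarize(maps, 1, 0.5).all()

    def test_opening_removes_speck(self):
        mask = np.zeros((30, 30), bool)
        mask[5, 5] = True
        mask[15:25, 10:20] = True
        out = clean_mask(mask, open_radius_px=2, dilate_radius_px=0)
        assert not out[5, 5]
        assert out[20, 15]

    def test_dilation_merges_nearby_blobs(self):
        mask = np.zeros((40, 40), bool)
        mask[10:16, 5:11] = True
        mask[10:16, 15:21] = True  # 4 px gap
        merged = clean_mask(mask, open_radius_px=0, dilate_radius_px=5,
                            erode_back=False)
        from skimage import measure
        assert measure.label(merged, connectivity=2).max() == 1

    def test_largest_component_kept(self):
        mask = np.zeros((60, 60), bool)
        mask[5:15, 5:15] = True     # 100 px
        mask[30:55, 30:55] = True   # 625 px
        out = clean_mask(mask, open_radius_px=0, dilate_radius_px=0)
        assert out[40, 40] and not out[10, 10]


class TestGeometry:
    def test_circle_roi_of_rendered_stroke(self):
        mask = np.zeros((200, 200), bool)
        yy, xx = np.mgrid[0:200, 0:200]
        q = (xx - 100.0) ** 2 + (yy - 100.0) ** 2
        mask[(q >= 48 ** 2) & (q <= 52 ** 2)] = True
        r0, r1, c0, c1 = circle_roi(mask)
        assert abs(r0 - 48) <= 4 and abs(r1 - 152) <= 4
        assert abs(c0 - 48) <= 4 and abs(c1 - 152) <= 4

    def test_single_pixel_and_empty_roi(self):
        mask = np.zeros((10, 10), bool)
        assert circle_roi(mask) is None
        mask[3, 7] = True
        assert circle_roi(mask) == (3, 3, 7, 7)

    def test_vertical_extent_column_counts(self):
        mask = np.zeros((5, 5), bool)
        mask[:, 1] = [1, 1, 1, 0, 0]
        mask[:, 2] = [1, 1, 0, 0, 0]
        mask[:, 3] = [1, 1, 1, 1, 1]
        mask[:, 4] = [0, 1, 0, 0, 0]
        assert vertical_extent(mask) == 5
        assert vertical_extent(np.zeros((4, 4), bool)) == 0
        full = np.zeros((5, 5), bool)
        full[:, 2] = True
        assert vertical_extent(full) == 5


class TestCropHeightFromExtents:
    def test_examples(self):
        full = crop_height_from_extents(int(10 * 200 / 15 * 1), 10)
        # fully visible bar (marker/reference ratio = 200/15) -> crop 0
        assert full.crop_height_cm == pytest.approx(0.0, abs=1.0)
        est = crop_height_from_extents(40, 10)
        assert est.visible_marker_cm == pytest.approx(60.0)
        assert est.crop_height_cm == pytest.approx(140.0)

    def test_failure_statuses(self):
        assert crop_height_from_extents(0, 10).status == "failed_no_marker"
        assert crop_height_from_extents(10, 0).status == "failed_no_reference"
        assert crop_height_from_extents(10, 0).crop_height_cm is None

    def test_decreasing_in_marker_and_scale_invariant(self):
        heights = [crop_height_from_extents(m, 30).crop_height_cm
                   for m in range(10, 400, 30)]
        assert all(a > b for a, b in zip(heights, heights[1:]))
        a = crop_height_from_extents(120, 30)
        b = crop_height_from_extents(480, 120)
        assert a.crop_height_cm == pytest.approx(b.crop_height_cm)


class TestEstimateFromImage:
    def test_truth_mask_inversion_within_pixel_quantum(self):
        quantum = 15.0 / 30.0  # cm per pixel at 2 px/cm
        for h in range(0, 181, 20):
            _, truth = render_marker_image(h, ref_px_per_cm=2.0, seed=h)
            est = estimate_from_masks(truth == 1, truth == 2, truth == 3)
            assert est.status == "ok"
            assert est.crop_height_cm == pytest.approx(h, abs=quantum + 1e-9)

    def test_batch_truth_masks_mae_below_2cm(self):
        rng = np.random.default_rng(10)
        errs = []
        for k in range(20):
            h = float(rng.uniform(40, 180))
            _, truth = render_marker_image(h, seed=500 + k)
            est = estimate_from_masks(truth == 1, truth == 2, truth == 3)
            errs.append(abs(est.crop_height_cm - h))
        assert np.mean(errs) < 2.0

    def test_all_black_image_fails_dark(self, trained_classifier):
        img = np.zeros((480, 160, 3), dtype=np.uint8)
        assert estimate_from_image(trained_classifier, img).status == "failed_dark"

    def test_classifier_loop_recovers_height(self, trained_classifier):
        img, _ = render_marker_image(140, seed=77)
        est = estimate_from_image(trained_classifier, img)
        assert est.status == "ok"
        assert est.crop_height_cm == pytest.approx(140.0, abs=8.0)
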