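"""ROI extraction, ground-truth hygiene, confusion metrics, error maps."""

import numpy as np
import pytest

from lifhsi.cube_io import CLEAN, CONTAMINATED, UNLABELED, HSCube, LabelMask, WavelengthGrid
from lifhsi.evaluate import (
    ConfusionCounts,
    ERROR_MAP_PALETTE,
    ROISpec,
    balanced_sample,
    class_fraction,
    confusion,
    counts_from_precision_recall,
    erode_mask,
    error_map,
    extract_roi,
    metrics,
)


def _cube(rows, cols, bands=4):
    data = np.arange(rows * cols * bands, dtype=float).reshape(rows, cols, bands)
    return HSCube(data, WavelengthGrid(np.linspace(500, 800, bands)))


class TestExtractRoi:
    def test_30x30_roi_yields_900_labeled_rows(self):
        cube = _cube(400, 400)
        roi = ROISpec(origin=(339, 300), label=CLEAN)
        m = extract_roi(cube, roi)
        assert m.n == 900
        assert np.all(m.labels == CLEAN)

    def test_1x1_roi_is_that_pixels_spectrum(self):
        cube = _cube(10, 10)
        m = extract_roi(cube, ROISpec(origin=(3, 7), width=1, height=1, label=CONTAMINATED))
        # origin is (x=col, y=row) -> pixel (row 7, col 3)
        np.testing.assert_array_equal(m.values[0], cube.data[7, 3])

    def test_out_of_bounds_rejected(self):
        cube = _cube(400, 300)  # only 300 columns
        with pytest.raises(IndexError):
            extract_roi(cube, ROISpec(origin=(339, 300)))

    def test_row_col_origin_convention(self):
        cube = _cube(10, 10)
        xy = extract_roi(cube, ROISpec(origin=(3, 7), width=2, height=2))
        rc = extract_roi(cube, ROISpec(origin=(7, 3), width=2, height=2, origin_is_xy=False))
        np.testing.assert_array_equal(xy.values, rc.values)


class TestErodeMask:
    def test_5x4_rectangle_erodes_to_3x2_core(self):
        labels = np.zeros((9, 10), dtype=np.uint8)
        labels[2:6, 3:8] = CONTAMINATED  # 4 rows x 5 cols solid block
        out = erode_mask(LabelMask(labels), radius=1)
        core = out.labels == CONTAMINATED
        assert core.sum() == 6  # 2 x 3 core
        assert core[3:5, 4:7].all()
        # stripped boundary pixels become unlabeled, not clean
        assert np.sum(out.labels == UNLABELED) == 20 - 6

    def test_empty_contaminated_region_unchanged(self):
        mask = LabelMask(np.zeros((5, 5), dtype=np.uint8))
        np.testing.assert_array_equal(erode_mask(mask).labels, mask.labels)

    def test_border_treated_as_background(self):
        labels = np.full((4, 4), CONTAMINATED, dtype=np.uint8)
        out = erode_mask(LabelMask(labels), radius=1)
        # only the interior 2x2 survives
        assert (out.labels == CONTAMINATED).sum() == 4
        assert np.all(out.labels[0, :] == UNLABELED)

    def test_radius_zero_is_identity(self, rng):
        labels = (rng.random((6, 6)) > 0.5).astype(np.uint8)
        mask = LabelMask(labels)
        np.testing.assert_array_equal(erode_mask(mask, radius=0).labels, labels)

    def test_eroded_set_is_subset_of_input(self, rng):
        labels = (rng.random((20, 20)) > 0.4).astype(np.uint8)
        out = erode_mask(LabelMask(labels), radius=1)
        assert np.all((out.labels == CONTAMINATED) <= (labels == CONTAMINATED))


class TestBalancedSample:
    def _mask(self):
        labels = np.zeros((100, 100), dtype=np.uint8)
        labels[:, :60] = CONTAMINATED
        labels[0, :] = UNLABELED
        return LabelMask(labels)

    def test_draws_exactly_n_per_class(self):
        sample = balanced_sample(self._mask(), 2000, seed=0)
        labels = np.array([s[2] for s in sample])
        assert len(sample) == 4000
        assert np.sum(labels == CLEAN) == 2000
        assert np.sum(labels == CONTAMINATED) == 2000

    def test_sampled_coordinates_carry_their_mask_label(self):
        mask = self._mask()
        for r, c, label in balanced_sample(mask, 500, seed=1):
            assert mask.labels[r, c] == label

    def test_reproducible_under_seed_and_without_replacement(self):
        a = balanced_sample(self._mask(), 1000, seed=7)
        b = balanced_sample(self._mask(), 1000, seed=7)
        assert a == b
        assert len(set((r, c) for r, c, _ in a)) == len(a)

    def test_insufficient_pixels_names_the_class(self):
        labels = np.zeros((10, 10), dtype=np.uint8)
        labels[0, 0] = CONTAMINATED
        with pytest.raises(ValueError, match="contaminated"):
            balanced_sample(LabelMask(labels), 5, seed=0)


class TestConfusion:
    def test_perfect_prediction(self, rng):
        truth = LabelMask((rng.random((8, 8)) > 0.5).astype(np.uint8))
        c = confusion(truth, truth)
        assert c.fp == 0 and c.fn == 0
        assert c.total == 64

    def test_inverted_prediction(self, rng):
        labels = (rng.random((8, 8)) > 0.5).astype(np.uint8)
        c = confusion(LabelMask(1 - labels), LabelMask(labels))
        assert c.tp == 0 and c.tn == 0

    def test_hand_counted_2x2_toy(self):
        truth = LabelMask(np.array([[1, 0], [1, 0]], dtype=np.uint8))
        pred = LabelMask(np.array([[1, 1], [0, 0]], dtype=np.uint8))
        c = confusion(pred, truth)
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 1, 1, 1)

    def test_unlabeled_pixels_excluded_and_counts_conserved(self, rng):
        truth_labels = rng.choice(
            [CLEAN, CONTAMINATED, UNLABELED], size=(12, 12), p=[0.4, 0.4, 0.2]
        ).astype(np.uint8)
        pred = LabelMask((rng.random((12, 12)) > 0.5).astype(np.uint8))
        c = confusion(pred, LabelMask(truth_labels))
        assert c.total == int(np.sum(truth_labels != UNLABELED))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            confusion(
                LabelMask(np.zeros((2, 2), dtype=np.uint8)),
                LabelMask(np.zeros((3, 3), dtype=np.uint8)),
            )


class TestMetrics:
    def test_full_image_counts_reproduce_reported_metrics(self):
        """The printed whole-image confusion counts give 96.09% accuracy,
        precision 0.9899, recall 0.9451, F1 0.9670."""
        c = ConfusionCounts(tp=207068, tn=140714, fp=2120, fn=12018)
        assert c.total == 361920
        report = metrics(c).as_percent()
        assert report["accuracy_pct"] == 96.09
        assert report["precision"] == 0.9899
        assert report["recall"] == 0.9451
        assert report["f1"] == 0.9670

    def test_perfect_classifier(self):
        report = metrics(ConfusionCounts(tp=50, tn=50, fp=0, fn=0))
        assert (report.accuracy, report.precision, report.recall, report.f1) == (
            1.0, 1.0, 1.0, 1.0,
        )

    def test_uniform_counts_give_half_everywhere(self):
        report = metrics(ConfusionCounts(tp=25, tn=25, fp=25, fn=25))
        assert (report.accuracy, report.precision, report.recall, report.f1) == (
            0.5, 0.5, 0.5, 0.5,
        )

    def test_undefined_metrics_flagged_not_coerced(self):
        # no predicted positives -> precision undefined
        report = metrics(ConfusionCounts(tp=0, tn=10, fp=0, fn=5))
        assert report.precision is None
        assert "precision" in report.undefined
        assert report.accuracy == pytest.approx(10 / 15)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            metrics(ConfusionCounts(tp=0, tn=0, fp=0, fn=0))

    def test_balanced_accuracy_identity_for_balanced_truth(self, rng):
        """With n positives = n negatives, accuracy equals
        (recall + specificity) / 2."""
        pred = LabelMask((rng.random((20, 20)) > 0.5).astype(np.uint8))
        truth_labels = np.zeros(400, dtype=np.uint8)
        truth_labels[:200] = CONTAMINATED
        truth = LabelMask(rng.permutation(truth_labels).reshape(20, 20))
        c = confusion(pred, truth)
        report = metrics(c)
        specificity = c.tn / (c.tn + c.fp)
        assert report.accuracy == pytest.approx((report.recall + specificity) / 2)


class TestCountsFromPrecisionRecall:
    def test_balanced_gt_subset_reconstruction(self):
        """Printed precision/recall on the balanced 2000+2000 set imply
        accuracy 96.65% and F1 0.9658."""
        c = counts_from_precision_recall(0.9854, 0.9470, n_pos=2000, n_neg=2000)
        assert c.total == 4000
        report = metrics(c).as_percent()
        assert report["accuracy_pct"] == 96.65
        assert report["f1"] == 0.9658

    def test_perfect_scores_round_trip(self):
        c = counts_from_precision_recall(1.0, 1.0, n_pos=100, n_neg=100)
        assert (c.tp, c.tn, c.fp, c.fn) == (100, 100, 0, 0)


class TestClassFraction:
    def test_reported_contaminated_fraction(self):
        """209,188 predicted positives of 361,920 pixels -> 57.8%."""
        labels = np.zeros(361920, dtype=np.uint8)
        labels[:209188] = CONTAMINATED
        fractions = class_fraction(LabelMask(labels.reshape(520, 696)))
        assert round(fractions["contaminated"] * 100, 1) == 57.8
        assert round(fractions["clean"] * 100, 1) == 42.2

    def test_all_clean_map(self):
        fractions = class_fraction(LabelMask(np.zeros((5, 5), dtype=np.uint8)))
        assert fractions["contaminated"] == 0.0

    def test_checkerboard_is_half(self):
        labels = (np.indices((6, 6)).sum(axis=0) % 2).astype(np.uint8)
        assert class_fraction(LabelMask(labels))["contaminated"] == 0.5

    def test_unlabeled_denominator_mode(self):
        labels = np.zeros((4, 4), dtype=np.uint8)
        labels[0] = CONTAMINATED
        labels[1] = UNLABELED
        over_labeled = class_fraction(LabelMask(labels))
        over_all = class_fraction(LabelMask(labels), include_unlabeled=True)
        assert over_labeled["contaminated"] == pytest.approx(4 / 12)
        assert over_all["contaminated"] == pytest.approx(4 / 16)

    def test_all_unlabeled_rejected(self):
        with pytest.raises(ValueError):
            class_fraction(LabelMask(np.full((3, 3), UNLABELED, dtype=np.uint8)))


class TestErrorMap:
    def test_perfect_prediction_is_blue_and_green_only(self, rng):
        truth = LabelMask((rng.random((8, 8)) > 0.5).astype(np.uint8))
        img = error_map(truth, truth)
        colors = {tuple(c) for c in img.reshape(-1, 3)}
        assert colors <= {ERROR_MAP_PALETTE["TP"], ERROR_MAP_PALETTE["TN"]}

    def test_toy_map_has_one_pixel_of_each_category(self):
        truth = LabelMask(np.array([[1, 0], [1, 0]], dtype=np.uint8))
        pred = LabelMask(np.array([[1, 1], [0, 0]], dtype=np.uint8))
        img = error_map(pred, truth)
        colors = [tuple(c) for c in img.reshape(-1, 3)]
        for cat in ("TP", "TN", "FP", "FN"):
            assert colors.count(ERROR_MAP_PALETTE[cat]) == 1

    def test_color_histogram_matches_confusion_counts(self, rng):
        truth = LabelMask(
            rng.choice([CLEAN, CONTAMINATED, UNLABELED], size=(15, 15),
                       p=[0.4, 0.4, 0.2]).astype(np.uint8)
        )
        pred = LabelMask((rng.random((15, 15)) > 0.5).astype(np.uint8))
        img = error_map(pred, truth)
        c = confusion(pred, truth)
        flat = img.reshape(-1, 3)
        for cat, count in (("TP", c.tp), ("TN", c.tn), ("FP", c.fp), ("FN", c.fn)):
            assert int(np.sum(np.all(flat == ERROR_MAP_PALETTE[cat], axis=1))) == count
        n_black = int(np.sum(np.all(flat == (0, 0, 0), axis=1)))
        assert n_black == 225 - c.total
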