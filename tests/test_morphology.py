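"""Nucleus segmentation and shape measurement on analytic ground truth."""

import math

import numpy as np
import pytest
from skimage.measure import label as sk_label
from skimage.measure import regionprops

from nucleoform.morphology import (
    compare_morphology,
    max_project,
    measure_all,
    measure_nucleus,
    read_image_stack,
    segment_nuclei,
)
from nucleoform.simulate import NucleusSimParams, ellipse_truth, simulate_nucleus_image


def disk_mask(shape, cr, cc, r):
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (rows - cr) ** 2 + (cols - cc) ** 2 <= r**2


class TestMaxProject:
    def test_single_slice_identity(self, rng):
        img = rng.random((8, 9))
        assert np.array_equal(max_project(img[None]), img)

    def test_elementwise_maximum(self):
        stack = np.array([[[1, 5], [3, 2]], [[2, 4], [1, 6]]])
        assert np.array_equal(max_project(stack), [[2, 5], [3, 6]])

    def test_commutes_with_slice_order(self, rng):
        stack = rng.random((5, 10, 10))
        assert np.array_equal(max_project(stack), max_project(stack[::-1]))

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            max_project(np.empty((0, 4, 4)))


class TestSegmentation:
    def test_two_disjoint_circles_two_labels(self):
        img = np.zeros((120, 120))
        img[disk_mask(img.shape, 30, 30, 12)] = 200
        img[disk_mask(img.shape, 85, 85, 15)] = 200
        labels = segment_nuclei(img, min_area=50)
        assert labels.max() == 2

    def test_min_area_drops_small_objects(self):
        img = np.zeros((60, 60))
        img[disk_mask(img.shape, 30, 30, 4)] = 200  # ~50 px
        assert segment_nuclei(img, min_area=100).max() == 0

    def test_blank_image_zero_objects(self):
        assert segment_nuclei(np.zeros((30, 30)), min_area=10).max() == 0

    def test_border_touching_object_discarded(self):
        img = np.zeros((60, 60))
        img[disk_mask(img.shape, 0, 30, 10)] = 200
        assert segment_nuclei(img, min_area=10).max() == 0

    def test_holes_filled_before_measurement(self):
        img = np.zeros((80, 80))
        img[disk_mask(img.shape, 40, 40, 20)] = 200
        img[disk_mask(img.shape, 40, 40, 5)] = 0  # nucleolar void
        labels = segment_nuclei(img, min_area=50)
        rec = measure_all(labels)[0]
        assert rec.area == pytest.approx(np.sum(disk_mask(img.shape, 40, 40, 20)), rel=0.01)


class TestMeasurement:
    def test_disk_area_and_circularity(self):
        mask = disk_mask((120, 120), 60, 60, 50)
        rec = measure_nucleus(mask)
        assert rec.area == pytest.approx(2500 * math.pi, rel=0.01)
        assert 0.95 <= rec.circularity <= 1.05

    def test_pixel_size_scales_area_not_circularity(self):
        mask = disk_mask((120, 120), 60, 60, 50)
        r1 = measure_nucleus(mask, pixel_size=1.0)
        r2 = measure_nucleus(mask, pixel_size=0.1)
        assert r2.area == pytest.approx(r1.area * 0.01)
        assert r2.perimeter == pytest.approx(r1.perimeter * 0.1)
        assert r2.circularity == pytest.approx(r1.circularity, abs=1e-12)

    def test_elongation_lowers_circularity(self):
        disk = measure_nucleus(disk_mask((120, 120), 60, 60, 40))
        p = NucleusSimParams((120, 200), ((60, 100, 40, 20, 0.0),),
                             foreground=255, background=0)
        img, truth = simulate_nucleus_image(p)
        ell = measure_all(segment_nuclei(img, min_area=50))[0]
        assert ell.circularity < disk.circularity
        assert ell.circularity == pytest.approx(truth[0].circularity, abs=0.05)

    def test_circularity_invariant_to_translation_and_rotation(self):
        mask = np.zeros((150, 150), dtype=bool)
        mask[40:80, 30:100] = True  # 40x70 rectangle
        base = measure_nucleus(mask)
        shifted = np.roll(mask, (20, 15), axis=(0, 1))
        rotated = np.rot90(mask)
        assert measure_nucleus(shifted).circularity == pytest.approx(base.circularity)
        assert measure_nucleus(rotated).circularity == pytest.approx(base.circularity)

    def test_monotone_in_aspect_ratio_at_fixed_area(self):
        area = math.pi * 40 * 40
        prev = None
        for ratio in (1.0, 0.75, 0.5, 0.25):
            a = math.sqrt(area / (math.pi * ratio))
            b = a * ratio
            p = NucleusSimParams((300, 300), ((150, 150, a, b, 0.0),),
                                 foreground=255, background=0)
            img, _ = simulate_nucleus_image(p)
            rec = measure_all(segment_nuclei(img, min_area=50))[0]
            if prev is not None:
                assert rec.circularity < prev
            prev = rec.circularity

    def test_naive_boundary_count_would_bias_circularity(self):
        """The Crofton estimator is required: counting boundary steps
        (the classic 'perimeter' chain estimator) inflates a disk's
        perimeter enough to push C far from 1."""
        mask = disk_mask((120, 120), 60, 60, 50)
        (region,) = regionprops(sk_label(mask))
        naive_c = 4 * math.pi * region.area / region.perimeter**2
        crofton_c = measure_nucleus(mask).circularity
        assert abs(crofton_c - 1.0) < 0.02
        assert naive_c < 0.92  # visibly biased

    def test_multi_object_mask_rejected(self):
        mask = np.zeros((60, 60), dtype=bool)
        mask[5:10, 5:10] = True
        mask[40:45, 40:45] = True
        with pytest.raises(ValueError, match="2 objects"):
            measure_nucleus(mask)
        with pytest.raises(ValueError, match="empty"):
            measure_nucleus(np.zeros((10, 10), dtype=bool))


class TestEndToEnd:
    def test_planted_ellipses_recovered_within_tolerance(self):
        ellipses = (
            (60, 70, 30, 30, 0.0),
            (60, 200, 40, 20, 0.5),
            (180, 70, 25, 15, 1.2),
            (180, 200, 35, 28, -0.7),
        )
        p = NucleusSimParams((260, 280), ellipses, foreground=20000,
                             background=1000, noise_sd=0.0)
        img, truth = simulate_nucleus_image(p)
        records = measure_all(segment_nuclei(img, min_area=100))
        assert len(records) == len(truth)  # recall = 1
        # match by centroid
        for t in truth:
            rec = min(records, key=lambda r: (r.centroid[0] - t.centroid[0]) ** 2
                      + (r.centroid[1] - t.centroid[1]) ** 2)
            assert rec.area == pytest.approx(t.area, rel=0.02)
            assert rec.circularity == pytest.approx(t.circularity, abs=0.05)

    def test_stack_reading_and_projection(self, tmp_path):
        import tifffile

        stack = np.zeros((3, 60, 60), dtype=np.uint16)
        stack[1][disk_mask((60, 60), 30, 30, 10)] = 30000
        path = tmp_path / "stack.tiff"
        tifffile.imwrite(path, stack, photometric="minisblack")
        back = read_image_stack(path)
        assert back.shape == (3, 60, 60)
        proj = max_project(back)
        assert measure_all(segment_nuclei(proj, min_area=50))[0].area == pytest.approx(
            np.sum(disk_mask((60, 60), 30, 30, 10)), rel=0.01
        )


class TestCompare:
    def make_records(self, areas):
        return [
            measure_nucleus(disk_mask((2 * int(a) + 20,) * 2, int(a) + 10, int(a) + 10, a))
            for a in areas
        ]

    def test_identical_groups_p_near_one(self):
        group = self.make_records([20, 25, 30, 35])
        res = compare_morphology(group, group, metric="area")
        assert res["median_diff"] == 0.0
        assert res["p"] > 0.9

    def test_shrunken_areas_detected(self, rng):
        radii = rng.uniform(20, 40, size=45)
        a = self.make_records(radii)
        b = self.make_records(radii * math.sqrt(0.7))  # areas scaled by 0.7
        res = compare_morphology(a, b, metric="area")
        assert res["p"] < 0.001
        assert res["median_diff"] < 0

    def test_unknown_metric_and_small_group_rejected(self):
        group = self.make_records([20, 25, 30])
        with pytest.raises(ValueError, match="metric"):
            compare_morphology(group, group, metric="perimeterness")
        with pytest.raises(ValueError, match="at least 3"):
            compare_morphology(group[:2], group, metric="area")
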