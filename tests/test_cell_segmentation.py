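"""Li thresholding, diameter gating and the brightness (viability) rule."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ire1quant import SegmentationParams, li_threshold, segment_cells
from ire1quant.cell_segmentation import CellRecord, exclude_bright_cells
from ire1quant.errors import DegenerateImageError
from ire1quant.io_projection import Image2D

from conftest import disk_mask


def naive_li_objective(values, t):
    """Independent Li-Lee cross-entropy: partition pixels, -S log(mu) per class."""
    below = values[values <= t]
    above = values[values > t]
    obj = 0.0
    for cls in (below, above):
        s = cls.sum()
        if s > 0:
            obj -= s * np.log(s / len(cls))
    return obj


def naive_li_threshold(values):
    """Exhaustive search over all distinct levels except the maximum."""
    levels = np.unique(values)
    candidates = levels[:-1]
    objs = [naive_li_objective(values, t) for t in candidates]
    return candidates[int(np.argmin(objs))]


class TestLiThreshold:
    def test_two_class_image_separates_exactly(self):
        arr = np.concatenate([np.full(100, 10.0), np.full(100, 200.0)])
        img = Image2D(arr.reshape(10, 20), 0.13)
        t = li_threshold(img)
        assert 10 <= t < 200
        assert np.array_equal(img.data > t, img.data == 200)

    def test_constant_image_raises(self):
        with pytest.raises(DegenerateImageError):
            li_threshold(Image2D(np.full((8, 8), 42.0), 0.13))

    def test_matches_exhaustive_search_on_random_8bit(self, rng):
        for _ in range(20):
            arr = rng.integers(0, 256, size=(32, 32)).astype(float)
            assert li_threshold(arr) == naive_li_threshold(arr.ravel())

    def test_matches_exhaustive_on_bimodal(self, rng):
        arr = np.concatenate([rng.normal(40, 8, 400), rng.normal(180, 15, 200)])
        arr = np.clip(np.rint(arr), 0, 255)
        assert li_threshold(arr.reshape(20, 30)) == naive_li_threshold(arr)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.integers(0, 255), min_size=4, max_size=64))
    def test_property_minimiser_over_all_levels(self, pixels):
        arr = np.array(pixels, dtype=float)
        if np.unique(arr).size < 2:
            return
        t = li_threshold(arr.reshape(1, -1))
        best = min(naive_li_objective(arr, c) for c in np.unique(arr)[:-1])
        assert naive_li_objective(arr, t) == pytest.approx(best, rel=1e-12)


class TestBrightnessExclusion:
    @staticmethod
    def records(intensities):
        return [
            CellRecord(i + 1, 100, 1.0, 1.1, float(v), float(v), (0.0, 0.0), "kept")
            for i, v in enumerate(intensities)
        ]

    @pytest.mark.parametrize(
        "intensities, exclusion, expected_kept",
        [
            # 30% rule: M = 136.67, cutoff 177.67 -> 200 excluded
            ([100, 110, 200], 0.30, [True, True, False]),
            # equal intensities: nothing excluded at any positive margin
            ([150, 150, 150], 0.30, [True, True, True]),
            # 10% rule arithmetic: M = 104.5, cutoff 114.95 -> both kept
            ([100, 109], 0.10, [True, True]),
            # M = 110, cutoff 121 -> both kept
            ([100, 120], 0.10, [True, True]),
            # M = 112.5, cutoff 123.75 -> 125 excluded
            ([100, 125], 0.10, [True, False]),
        ],
    )
    def test_rule_arithmetic(self, intensities, exclusion, expected_kept):
        out = exclude_bright_cells(self.records(intensities), exclusion)
        assert [r.kept for r in out] == expected_kept

    def test_empty_input(self):
        assert exclude_bright_cells([], 0.3) == []

    def test_mean_single_pass_not_recomputed(self):
        # after excluding 400, the residual mean would drop and 140 would fail
        # a recomputed 30% cutoff; the single-pass rule keeps it
        out = exclude_bright_cells(self.records([100, 100, 140, 400]), 0.30)
        assert [r.kept for r in out] == [True, True, True, False]

    def test_monotone_in_exclusion_margin(self, rng):
        intensities = rng.uniform(50, 400, size=30)
        kept_counts = [
            sum(r.kept for r in exclude_bright_cells(self.records(intensities), e))
            for e in (0.05, 0.10, 0.30, 0.50)
        ]
        assert kept_counts == sorted(kept_counts)


class TestSegmentCells:
    PX = 0.13

    def field_with_disk(self, radius_px, value=500.0, shape=(120, 120)):
        arr = np.full(shape, 10.0)
        arr[disk_mask(shape, (60, 60), radius_px)] = value
        return Image2D(arr, self.PX)

    def test_single_cell_diameter_recovered(self):
        # 4.0 um cell -> radius ~15.4 px
        img = self.field_with_disk(radius_px=15.4)
        label_map, records = segment_cells(img, SegmentationParams())
        kept = [r for r in records if r.kept]
        assert len(kept) == 1
        assert kept[0].equiv_diameter_um == pytest.approx(4.0, rel=0.15)
        assert set(np.unique(label_map.labels)) == {0, kept[0].cell_id}

    @pytest.mark.parametrize(
        "diameter_um, expected_status",
        [(1.0, "too_small"), (8.0, "too_large"), (4.0, "kept")],
    )
    def test_diameter_gate(self, diameter_um, expected_status):
        radius_px = diameter_um / 2 / self.PX
        img = self.field_with_disk(radius_px, shape=(160, 160))
        label_map, records = segment_cells(img, SegmentationParams())
        assert len(records) == 1
        assert records[0].status == expected_status
        assert (records[0].cell_id in label_map.labels) == (expected_status == "kept")

    def test_kept_cells_always_inside_gate(self, rng):
        """Gate soundness on a crowd of random-size objects."""
        shape = (400, 400)
        arr = np.full(shape, 10.0)
        centers = [(50 + 90 * i, 50 + 90 * j) for i in range(4) for j in range(4)]
        for (r, c) in centers:
            radius = rng.uniform(3, 40)
            arr[disk_mask(shape, (r, c), radius)] = 500.0
        _, records = segment_cells(Image2D(arr, self.PX), SegmentationParams())
        for rec in records:
            if rec.kept:
                assert 1.9 <= rec.equiv_diameter_um <= 6.3
            assert rec.equiv_diameter_um == pytest.approx(2 * np.sqrt(rec.area_um2 / np.pi))

    def test_features_measured_on_unsmoothed_image(self):
        # a hot pixel inside the cell survives in max_intensity even though
        # smoothing removes it for thresholding
        img = self.field_with_disk(15.4)
        img.data[60, 60] = 5000.0
        _, records = segment_cells(img, SegmentationParams())
        kept = [r for r in records if r.kept]
        assert kept and kept[0].max_intensity == 5000.0

    def test_hole_filling(self):
        img = self.field_with_disk(15.4)
        img.data[disk_mask(img.data.shape, (60, 60), 3)] = 10.0  # punch a hole
        _, records = segment_cells(img, SegmentationParams())
        kept = [r for r in records if r.kept]
        assert len(kept) == 1
        # area includes the filled hole
        assert kept[0].area_px >= np.pi * 15.4**2 * 0.95
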