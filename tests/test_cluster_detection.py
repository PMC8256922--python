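"""Standard and stringent cluster calling on exactly constructed cells."""

import numpy as np
import pytest

from ire1quant import ClusterParams, call_fraction, detect_clusters_standard, detect_clusters_stringent
from ire1quant.cluster_detection import CellClusterCall
from ire1quant.errors import CalibrationMismatchError, EmptyFieldError

from conftest import PIXEL_UM, make_cell_field


def spot_radius_px(diameter_um):
    return diameter_um / 2 / PIXEL_UM


def big_cell(center=(100, 100), radius_px=40, value=100.0, spots=()):
    return {"center": center, "radius_px": radius_px, "value": value, "spots": list(spots)}


class TestStandardMode:
    def test_bright_small_spot_counted(self):
        # 0.5-um spot at 300 in a cell of 100: pooled mean ~100, threshold 150
        img, labels, recs = make_cell_field(
            [big_cell(spots=[((100, 100), spot_radius_px(0.5), 300.0)])]
        )
        clusters, calls = detect_clusters_standard(img, labels, recs)
        counted = [c for c in clusters if c.counted]
        assert len(counted) == 1
        assert calls[0].cluster_positive
        assert 0.3 <= counted[0].equiv_diameter_um <= 0.9

    def test_large_spot_discarded(self):
        # 1.0-um spot, bright: outside the 0.3-0.9 um standard gate
        img, labels, recs = make_cell_field(
            [big_cell(spots=[((100, 100), spot_radius_px(1.0), 300.0)])]
        )
        clusters, calls = detect_clusters_standard(img, labels, recs)
        assert not any(c.counted for c in clusters)
        assert not calls[0].cluster_positive

    def test_uniform_cells_negative(self):
        img, labels, recs = make_cell_field([big_cell(), big_cell(center=(100, 280), value=120.0)], shape=(200, 400))
        clusters, calls = detect_clusters_standard(img, labels, recs)
        assert clusters == []
        assert all(not c.cluster_positive for c in calls)
        assert len(calls) == 2

    def test_dim_spot_below_global_threshold_not_detected(self):
        # spot at 140 < 1.5 x pooled mean (~100) -> never a candidate
        img, labels, recs = make_cell_field(
            [big_cell(spots=[((100, 100), spot_radius_px(0.5), 140.0)])]
        )
        clusters, calls = detect_clusters_standard(img, labels, recs)
        assert clusters == []
        assert not calls[0].cluster_positive

    def test_threshold_monotonicity(self):
        """Raising rel_threshold never gains counted clusters on sparse spots."""
        img, labels, recs = make_cell_field(
            [
                big_cell(
                    spots=[
                        ((85, 85), spot_radius_px(0.5), 200.0),
                        ((115, 115), spot_radius_px(0.5), 400.0),
                    ]
                )
            ]
        )
        counts = []
        for rel in (1.2, 1.5, 2.0, 3.0):
            clusters, _ = detect_clusters_standard(
                img, labels, recs, ClusterParams(rel_threshold=rel)
            )
            counts.append(sum(c.counted for c in clusters))
        assert counts == sorted(counts, reverse=True)

    def test_counted_clusters_respect_gate(self):
        img, labels, recs = make_cell_field(
            [
                big_cell(
                    spots=[
                        ((80, 80), spot_radius_px(0.2), 500.0),   # too small
                        ((100, 120), spot_radius_px(0.5), 500.0),  # in gate
                        ((125, 90), spot_radius_px(1.1), 500.0),   # too large
                    ]
                )
            ]
        )
        clusters, _ = detect_clusters_standard(img, labels, recs)
        for c in clusters:
            assert c.counted == (0.3 <= c.equiv_diameter_um <= 0.9)
        assert sum(c.counted for c in clusters) == 1

    def test_calibration_mismatch_raises(self):
        img, labels, recs = make_cell_field([big_cell()])
        labels.pixel_size_um = 0.5
        with pytest.raises(CalibrationMismatchError):
            detect_clusters_standard(img, labels, recs)


class TestStringentMode:
    def test_bright_candidate_counted(self):
        # cell mean ~100, candidate max 300 >= 2.5 x mean, coverage ~1%
        img, labels, recs = make_cell_field(
            [big_cell(radius_px=45, spots=[((100, 100), spot_radius_px(0.5), 300.0)])]
        )
        clusters, calls = detect_clusters_stringent(img, labels, recs)
        assert calls[0].status == "fit"
        assert calls[0].cluster_positive
        assert sum(c.counted for c in clusters) == 1

    def test_weak_candidate_not_counted(self):
        # candidate max 240 < 2.5 x cell mean (~100): detected but not counted
        img, labels, recs = make_cell_field(
            [big_cell(radius_px=45, spots=[((100, 100), spot_radius_px(0.5), 240.0)])]
        )
        params = ClusterParams.for_mode("stringent", rel_threshold=1.3)
        clusters, calls = detect_clusters_stringent(img, labels, recs, params)
        assert any(not c.counted for c in clusters)
        assert not calls[0].cluster_positive

    def test_high_coverage_cell_unfit_but_in_denominator(self):
        # many bright candidates covering ~4% of the cell
        spots = [((80 + 15 * i, 80 + 13 * j), spot_radius_px(1.1), 400.0) for i in range(3) for j in range(3)]
        img, labels, recs = make_cell_field([big_cell(radius_px=45, spots=spots)])
        clusters, calls = detect_clusters_stringent(img, labels, recs)
        call = calls[0]
        assert call.coverage > 0.035
        assert call.status == "unfit"
        assert call.n_clusters_counted == 0
        assert not call.cluster_positive
        assert not any(c.counted for c in clusters)
        # the unfit cell still appears in the denominator
        assert call_fraction(calls) == 0.0

    def test_wider_diameter_gate_than_standard(self):
        # a 1.05-um spot: discarded by standard, allowed (and bright) in stringent
        img, labels, recs = make_cell_field(
            [big_cell(radius_px=45, spots=[((100, 100), spot_radius_px(1.05), 400.0)])]
        )
        std_clusters, _ = detect_clusters_standard(img, labels, recs)
        str_clusters, str_calls = detect_clusters_stringent(img, labels, recs)
        assert not any(c.counted for c in std_clusters)
        assert any(c.counted for c in str_clusters)
        assert str_calls[0].cluster_positive

    def test_peak_rule_monotonicity(self):
        img, labels, recs = make_cell_field(
            [big_cell(radius_px=45, spots=[((100, 100), spot_radius_px(0.5), 290.0)])]
        )
        counts = []
        for rel in (2.0, 2.5, 3.5):
            _, calls = detect_clusters_stringent(
                img, labels, recs, ClusterParams.for_mode("stringent", rel_max_intensity=rel)
            )
            counts.append(calls[0].n_clusters_counted)
        assert counts == sorted(counts, reverse=True)


class TestCallFraction:
    @staticmethod
    def call(positive, status="fit"):
        return CellClusterCall(1, int(positive), 0.0, status, positive)

    def test_simple_ratio(self):
        calls = [self.call(True)] * 3 + [self.call(False)] * 7
        assert call_fraction(calls) == pytest.approx(0.3)

    def test_all_unfit_zero(self):
        calls = [self.call(False, "unfit")] * 5
        assert call_fraction(calls) == 0.0

    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(10):
            flags = rng.random(rng.integers(1, 40)) < 0.5
            calls = [self.call(bool(f)) for f in flags]
            assert call_fraction(calls) == sum(flags) / len(flags)

    def test_empty_raises(self):
        with pytest.raises(EmptyFieldError):
            call_fraction([])
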