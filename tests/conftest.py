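"""Shared fixtures: constructed fields with exactly known geometry."""

from __future__ import annotations

import numpy as np
import pytest

from ire1quant.cell_segmentation import CellLabelMap, CellRecord
from ire1quant.io_projection import Image2D

PIXEL_UM = 0.13


def disk_mask(shape, center, radius):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def make_cell_field(cells, shape=(200, 200), background=0.0, pixel_um=PIXEL_UM):
    """Build (Image2D, CellLabelMap, [CellRecord]) from disk-cell specs.

    Each spec: dict(center, radius_px, value, spots=[(center, radius_px, value)]).
    Spot values replace cell pixels, so intensities are exactly known.
    """
    img = np.full(shape, float(background))
    labels = np.zeros(shape, dtype=np.int32)
    records = []
    for i, spec in enumerate(cells, start=1):
        m = disk_mask(shape, spec["center"], spec["radius_px"])
        img[m] = spec["value"]
        labels[m] = i
        for s_center, s_radius, s_value in spec.get("spots", []):
            sm = disk_mask(shape, s_center, s_radius) & m
            img[sm] = s_value
        area = int(m.sum())
        area_um2 = area * pixel_um**2
        records.append(
            CellRecord(
                cell_id=i,
                area_px=area,
                area_um2=area_um2,
                equiv_diameter_um=2 * np.sqrt(area_um2 / np.pi),
                mean_intensity=float(img[m].mean()),
                max_intensity=float(img[m].max()),
                centroid_px=(float(spec["center"][0]), float(spec["center"][1])),
                status="kept",
            )
        )
    return Image2D(img, pixel_size_um=pixel_um, projection_kind="max"), CellLabelMap(labels, pixel_um), records


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
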