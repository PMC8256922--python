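"""Cell identification on the smoothed sum projection.

The detection image is median-smoothed and thresholded globally by
minimum cross-entropy (Li); connected components become candidate cells.
Candidates are then gated by equivalent circular diameter (1.9-6.3 um by
default) and by the viability rule: a cell whose mean intensity exceeds
the mean of all diameter-passing candidates by more than the configured
fraction (30% standard, 10% stringent) is flagged as dead ("too bright")
and excluded.  Object features are always measured on the *unsmoothed*
detection image; smoothing exists only to stabilise the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage.measure import regionprops

from .errors import DegenerateImageError
from .io_projection import Image2D, median_smooth

__all__ = [
    "SegmentationParams",
    "CellRecord",
    "CellLabelMap",
    "li_threshold",
    "li_cross_entropy",
    "exclude_bright_cells",
    "segment_cells",
]

#: Brightness-exclusion fractions for the two analysis modes.
BRIGHTNESS_EXCLUSION_STANDARD = 0.30
BRIGHTNESS_EXCLUSION_STRINGENT = 0.10


@dataclass(frozen=True)
class SegmentationParams:
    """Parameters of the cell-identification stage.

    ``brightness_exclusion`` is the fractional margin of the dead-cell
    rule: 0.30 excludes cells brighter than 1.3x the candidate mean
    (standard mode); stringent re-analysis uses 0.10.
    """

    smooth_radius_px: int = 2
    cell_diameter_min_um: float = 1.9
    cell_diameter_max_um: float = 6.3
    brightness_exclusion: float = BRIGHTNESS_EXCLUSION_STANDARD

    def __post_init__(self) -> None:
        if not (0 < self.cell_diameter_min_um < self.cell_diameter_max_um):
            raise ValueError("require 0 < cell_diameter_min_um < cell_diameter_max_um")
        if self.brightness_exclusion <= 0:
            raise ValueError("brightness_exclusion must be positive")
        if self.smooth_radius_px < 1:
            raise ValueError("smooth_radius_px must be >= 1")

    @classmethod
    def for_mode(cls, mode: str, **kwargs) -> "SegmentationParams":
        """Standard (30% exclusion) or stringent (10% exclusion) parameters."""
        if mode == "standard":
            return cls(brightness_exclusion=BRIGHTNESS_EXCLUSION_STANDARD, **kwargs)
        if mode == "stringent":
            return cls(brightness_exclusion=BRIGHTNESS_EXCLUSION_STRINGENT, **kwargs)
        raise ValueError(f"unknown mode {mode!r}; expected 'standard' or 'stringent'")


@dataclass
class CellRecord:
    """One candidate cell with its measured features and gate verdict."""

    cell_id: int
    area_px: int
    area_um2: float
    equiv_diameter_um: float
    mean_intensity: float
    max_intensity: float
    centroid_px: tuple[float, float]
    status: str = "kept"  # {kept, too_small, too_large, too_bright}

    @property
    def kept(self) -> bool:
        return self.status == "kept"


@dataclass
class CellLabelMap:
    """Integer label image of the kept cells (0 = background)."""

    labels: np.ndarray
    pixel_size_um: float

    def mask(self, cell_id: int) -> np.ndarray:
        return self.labels == cell_id


def li_cross_entropy(values: np.ndarray, threshold: float) -> float:
    """Li-Lee cross-entropy objective for one candidate threshold.

    For foreground pixels g > t with mean mu_f and background pixels
    g <= t with mean mu_b the (constant-shifted) objective is
    ``-(sum_b g) log mu_b - (sum_f g) log mu_f``; the minimising t is the
    minimum cross-entropy threshold.  Classes with zero total intensity
    contribute nothing.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    below = values[values <= threshold]
    above = values[values > threshold]
    obj = 0.0
    for cls in (below, above):
        s = cls.sum()
        if s > 0:
            obj -= s * np.log(s / cls.size)
    return obj


def li_threshold(image: Image2D | np.ndarray) -> float:
    """Minimum cross-entropy (Li) threshold of an image.

    Returns the grey level t (one of the distinct values present) that
    minimises the Li-Lee cross-entropy between the image and its
    two-class mean reconstruction, with foreground defined as pixels
    strictly above t.  The minimisation is exact over all candidate
    levels, evaluated with cumulative sums.

    Raises
    ------
    DegenerateImageError
        If the image holds fewer than two distinct values.
    """
    data = image.data if isinstance(image, Image2D) else np.asarray(image)
    values = np.asarray(data, dtype=np.float64).ravel()
    levels, counts = np.unique(values, return_counts=True)
    if levels.size < 2:
        raise DegenerateImageError("cannot threshold an image with fewer than two distinct values")

    mass = levels * counts
    csum = np.cumsum(mass)          # total intensity at or below each level
    ccount = np.cumsum(counts)
    total_sum, total_count = csum[-1], ccount[-1]

    # candidate thresholds: every level except the maximum (which would
    # leave an empty foreground class)
    s_below = csum[:-1]
    n_below = ccount[:-1]
    s_above = total_sum - s_below
    n_above = total_count - n_below

    with np.errstate(divide="ignore", invalid="ignore"):
        term_b = np.where(s_below > 0, s_below * np.log(s_below / n_below), 0.0)
        term_a = np.where(s_above > 0, s_above * np.log(s_above / n_above), 0.0)
    objective = -(term_b + term_a)
    return float(levels[int(np.argmin(objective))])


def exclude_bright_cells(candidates: list[CellRecord], brightness_exclusion: float) -> list[CellRecord]:
    """Apply the dead-cell brightness rule to one field's candidates.

    The reference M is the mean of the candidates' per-cell mean
    intensities, computed once over *all* diameter-passing candidates
    (bright cells included); any cell with mean intensity strictly above
    ``(1 + brightness_exclusion) * M`` is marked ``too_bright``.  The
    mean is not recomputed after exclusions.
    """
    gated = [c for c in candidates if c.status in ("kept", "too_bright")]
    if not gated:
        return list(candidates)
    reference = float(np.mean([c.mean_intensity for c in gated]))
    cutoff = (1.0 + brightness_exclusion) * reference
    out = []
    for c in candidates:
        if c.status in ("kept", "too_bright"):
            status = "too_bright" if c.mean_intensity > cutoff else "kept"
            out.append(replace(c, status=status))
        else:
            out.append(c)
    return out


def segment_cells(
    detection_image: Image2D,
    params: SegmentationParams | None = None,
) -> tuple[CellLabelMap, list[CellRecord]]:
    """Identify cells on a calibrated detection image.

    Pipeline: median-smooth -> Li threshold -> 8-connected components ->
    fill holes -> per-object features on the unsmoothed image ->
    equivalent-diameter gate -> brightness (viability) exclusion.

    Returns the label map of kept cells and the full candidate list with
    per-cell status.  An image in which no object survives yields an
    empty result, not an error; a constant image raises
    :class:`DegenerateImageError`.
    """
    if params is None:
        params = SegmentationParams()
    px = detection_image.pixel_size_um
    px_area_um2 = px * px

    smoothed = median_smooth(detection_image, params.smooth_radius_px)
    t = li_threshold(smoothed)
    fg = smoothed.data > t
    fg = ndimage.binary_fill_holes(fg)
    structure = np.ones((3, 3), dtype=bool)  # 8-connectivity
    labels, n_objects = ndimage.label(fg, structure=structure)

    raw = np.asarray(detection_image.data, dtype=np.float64)
    records: list[CellRecord] = []
    for prop in regionprops(labels, intensity_image=raw):
        area_px = int(prop.area)
        area_um2 = area_px * px_area_um2
        equiv_d = 2.0 * np.sqrt(area_um2 / np.pi)
        if equiv_d < params.cell_diameter_min_um:
            status = "too_small"
        elif equiv_d > params.cell_diameter_max_um:
            status = "too_large"
        else:
            status = "kept"
        records.append(
            CellRecord(
                cell_id=int(prop.label),
                area_px=area_px,
                area_um2=area_um2,
                equiv_diameter_um=equiv_d,
                mean_intensity=float(prop.intensity_mean),
                max_intensity=float(prop.intensity_max),
                centroid_px=(float(prop.centroid[0]), float(prop.centroid[1])),
                status=status,
            )
        )

    records = exclude_bright_cells(records, params.brightness_exclusion)

    kept_ids = {r.cell_id for r in records if r.kept}
    kept_labels = np.where(np.isin(labels, list(kept_ids)), labels, 0) if kept_ids else np.zeros_like(labels)
    return CellLabelMap(kept_labels, pixel_size_um=px), records
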