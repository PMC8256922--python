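"""Calibrated z-stack I/O, projections, smoothing and optional drift correction.

Cell detection runs on the median-smoothed sum projection of the stack;
cluster detection runs on the raw maximum projection.  Both projections
carry the pixel calibration of the source stack so that every downstream
gate can be expressed in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile
from scipy import ndimage
from skimage.morphology import disk
from skimage.registration import phase_cross_correlation

from .errors import FormatError, MetadataError

__all__ = [
    "ImageStack",
    "Image2D",
    "read_stack",
    "write_stack",
    "sum_projection",
    "max_projection",
    "median_smooth",
    "register_xy",
]


@dataclass
class ImageStack:
    """A 3-D fluorescence stack (planes x rows x cols) with physical calibration.

    Parameters
    ----------
    data : ndarray
        Intensities, shape ``(n_planes, rows, cols)``, arbitrary units, >= 0.
    pixel_size_um : float
        Lateral pixel size in micrometres per pixel.
    z_step_um : float
        Axial step between consecutive planes in micrometres.
    channel : str
        Free-form channel label (e.g. ``"GFP"``).
    """

    data: np.ndarray
    pixel_size_um: float
    z_step_um: float
    channel: str = "GFP"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise FormatError(f"stack must be 3-D (planes, rows, cols), got shape {self.data.shape}")
        if self.data.shape[0] < 1:
            raise FormatError("stack must contain at least one plane")
        if self.pixel_size_um <= 0:
            raise MetadataError("pixel_size_um must be positive")
        if np.issubdtype(self.data.dtype, np.number) and self.data.size and self.data.min() < 0:
            raise FormatError("stack intensities must be non-negative")

    @property
    def n_planes(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class Image2D:
    """A single calibrated 2-D image, optionally the projection of a stack."""

    data: np.ndarray
    pixel_size_um: float
    projection_kind: str = "none"  # {"sum", "max", "none"}

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise FormatError(f"image must be 2-D, got shape {self.data.shape}")
        if self.pixel_size_um <= 0:
            raise MetadataError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


def read_stack(
    path,
    pixel_size_um: float | None = None,
    z_step_um: float | None = None,
    channel: str = "GFP",
) -> ImageStack:
    """Read a single- or multi-page grayscale TIFF as a calibrated stack.

    Integer pixel data are preserved losslessly; plane order is the storage
    order.  Calibration must be supplied (this reader does not parse
    OME-XML metadata).
    """
    try:
        arr = tifffile.imread(path)
    except Exception as exc:  # noqa: BLE001 - re-raise as domain error
        raise FormatError(f"could not read TIFF {path!r}: {exc}") from exc
    if arr.ndim == 2:
        arr = arr[np.newaxis, ...]
    if arr.ndim != 3:
        raise FormatError(f"expected grayscale pages, got array of shape {arr.shape}")
    if arr.shape[-1] in (3, 4) and arr.ndim == 3 and arr.shape[0] > 8 and arr.shape[-1] < 5:
        # heuristic: trailing small axis on a 3-D array is an RGB(A) channel axis
        raise FormatError("RGB images are not supported; provide grayscale TIFF")
    if pixel_size_um is None:
        raise MetadataError("pixel_size_um not supplied and not stored in the file")
    if z_step_um is None:
        z_step_um = 0.0 if arr.shape[0] == 1 else None
    if z_step_um is None:
        raise MetadataError("z_step_um not supplied and not stored in the file")
    return ImageStack(arr, pixel_size_um=pixel_size_um, z_step_um=z_step_um, channel=channel)


def write_stack(path, stack: ImageStack) -> None:
    """Write a stack as a multi-page grayscale TIFF, one page per plane."""
    tifffile.imwrite(path, np.asarray(stack.data))


def sum_projection(stack: ImageStack) -> Image2D:
    """Pixelwise sum over planes, accumulated in float64 (no integer overflow)."""
    proj = np.sum(stack.data, axis=0, dtype=np.float64)
    return Image2D(proj, pixel_size_um=stack.pixel_size_um, projection_kind="sum")


def max_projection(stack: ImageStack) -> Image2D:
    """Pixelwise maximum over planes."""
    proj = np.max(stack.data, axis=0).astype(np.float64)
    return Image2D(proj, pixel_size_um=stack.pixel_size_um, projection_kind="max")


def median_smooth(image: Image2D, radius_px: int = 2) -> Image2D:
    """Median filter with a disk footprint of the given radius.

    Borders are handled by edge replication (``mode='nearest'``), so flat
    regions stay flat up to the image edge.
    """
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    footprint = disk(radius_px)
    smoothed = ndimage.median_filter(np.asarray(image.data, dtype=np.float64), footprint=footprint, mode="nearest")
    return Image2D(smoothed, pixel_size_um=image.pixel_size_um, projection_kind=image.projection_kind)


def register_xy(stack: ImageStack) -> tuple[ImageStack, list[tuple[int, int]]]:
    """Correct x-y drift by integer translation against the middle plane.

    Each plane is shifted by the integer offset maximising its
    cross-correlation with the reference (middle) plane.  Featureless
    planes produce zero shift.  Returns the registered stack and the list
    of applied (row, col) shifts, one per plane.
    """
    if stack.n_planes < 2:
        return stack, [(0, 0)] * stack.n_planes
    ref_idx = stack.n_planes // 2
    ref = np.asarray(stack.data[ref_idx], dtype=np.float64)
    out = np.empty_like(np.asarray(stack.data, dtype=np.float64))
    shifts: list[tuple[int, int]] = []
    for i in range(stack.n_planes):
        plane = np.asarray(stack.data[i], dtype=np.float64)
        if i == ref_idx or plane.std() == 0 or ref.std() == 0:
            shift = (0, 0)
        else:
            est, _, _ = phase_cross_correlation(ref, plane, upsample_factor=1)
            shift = (int(round(est[0])), int(round(est[1])))
        out[i] = np.roll(plane, shift, axis=(0, 1))
        shifts.append(shift)
    registered = ImageStack(out, pixel_size_um=stack.pixel_size_um, z_step_um=stack.z_step_um, channel=stack.channel)
    return registered, shifts
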