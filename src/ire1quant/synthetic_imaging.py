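"""Seeded generator of confocal-like z-stacks of yeast cells with ground truth.

The generator emulates the acquisition geometry the pipeline targets:
fields of budding-yeast cells (near-circular cross-sections, 1.9-6.3 um)
carrying diffuse cytosolic autofluorescence, a minority of over-bright
dead cells, and diffraction-limited GFP clusters in a configurable
fraction of the live cells.  Every stochastic choice flows from one
integer seed, so a (config, seed) pair maps to bit-identical output.

The noiseless intermediate stack is exposed alongside the noisy one so
tests can assert on expected intensities before shot/read noise.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigError, PlacementError
from .io_projection import ImageStack, write_stack

__all__ = [
    "SimulationConfig",
    "CellTruth",
    "ClusterTruth",
    "GroundTruth",
    "generate_field",
    "generate_dataset",
    "write_field",
]

_MAX_PLACEMENT_ATTEMPTS = 1000


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of a simulated field of view.

    Lengths are in micrometres, intensities in arbitrary camera units.
    Defaults describe a 63x/1.4 NA confocal acquisition (0.13 um pixels,
    nine planes at the 450-nm step used for GFP stacks) of a field of
    ~30 cells, 10% of which are dead (2x brighter), with 60% of live
    cells carrying one or two clusters at 4x the cell's mean
    autofluorescence.
    """

    field_shape_px: tuple[int, int] = (400, 400)
    pixel_size_um: float = 0.13
    n_planes: int = 9
    z_step_um: float = 0.45
    n_cells: int = 30
    cell_diameter_range_um: tuple[float, float] = (2.5, 5.5)
    cell_autofluor_mean: float = 100.0
    cell_autofluor_sd: float = 5.0
    background_level: float = 20.0
    dead_cell_fraction: float = 0.1
    dead_brightness_factor: float = 2.0
    cluster_positive_fraction: float = 0.6
    clusters_per_positive_cell: float = 1.5
    cluster_diameter_range_um: tuple[float, float] = (0.5, 0.5)
    cluster_amplitude_factor: float = 4.0
    psf_sigma_um: float = 0.12
    poisson_scale: float = 1.0
    read_sd: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("dead_cell_fraction", "cluster_positive_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        for name in ("cell_diameter_range_um", "cluster_diameter_range_um"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ConfigError(f"{name} must satisfy 0 < min <= max, got ({lo}, {hi})")
        if self.dead_brightness_factor <= 1:
            raise ConfigError("dead_brightness_factor must exceed 1")
        if self.cluster_amplitude_factor <= 0:
            raise ConfigError("cluster_amplitude_factor must be positive")
        if self.n_planes < 1 or self.n_cells < 0:
            raise ConfigError("n_planes must be >= 1 and n_cells >= 0")
        if self.pixel_size_um <= 0 or self.psf_sigma_um <= 0:
            raise ConfigError("pixel_size_um and psf_sigma_um must be positive")
        # coarse capacity check: total cell bounding boxes must fit the field
        rows, cols = self.field_shape_px
        max_d_px = self.cell_diameter_range_um[1] / self.pixel_size_um
        if self.n_cells * (max_d_px + 2) ** 2 > 0.7 * rows * cols:
            raise ConfigError(
                f"field {rows}x{cols} px is too small to hold {self.n_cells} "
                f"non-overlapping cells of up to {max_d_px:.0f} px diameter"
            )


@dataclass
class CellTruth:
    cell_id: int
    centroid_px: tuple[float, float]
    diameter_um: float
    dead: bool
    cluster_positive: bool
    autofluor: float = 0.0


@dataclass
class ClusterTruth:
    cell_id: int
    centroid_px: tuple[float, float]
    diameter_um: float
    amplitude: float


@dataclass
class GroundTruth:
    """Per-cell and per-cluster truth emitted by the simulator."""

    cells: list[CellTruth] = field(default_factory=list)
    clusters: list[ClusterTruth] = field(default_factory=list)

    @property
    def live_positive_fraction(self) -> float:
        """True cluster-positive fraction among live cells."""
        live = [c for c in self.cells if not c.dead]
        if not live:
            return float("nan")
        return sum(c.cluster_positive for c in live) / len(live)


def _place_cells(config: SimulationConfig, rng: np.random.Generator) -> list[dict]:
    """Rejection-sample non-overlapping ellipse centres and geometries."""
    rows, cols = config.field_shape_px
    placed: list[dict] = []
    lo, hi = config.cell_diameter_range_um
    for i in range(config.n_cells):
        d_um = float(rng.uniform(lo, hi))
        axis_ratio = float(rng.uniform(0.8, 1.0))
        # semi-axes preserving the requested equivalent diameter
        r_eq_px = d_um / 2.0 / config.pixel_size_um
        a = r_eq_px / np.sqrt(axis_ratio)
        b = r_eq_px * np.sqrt(axis_ratio)
        theta = float(rng.uniform(0, np.pi))
        r_max = max(a, b)
        for _ in range(_MAX_PLACEMENT_ATTEMPTS):
            cy = float(rng.uniform(r_max + 2, rows - r_max - 2))
            cx = float(rng.uniform(r_max + 2, cols - r_max - 2))
            ok = all(
                np.hypot(cy - p["cy"], cx - p["cx"]) > r_max + p["r_max"] + 2
                for p in placed
            )
            if ok:
                placed.append(
                    {"cy": cy, "cx": cx, "a": a, "b": b, "theta": theta, "r_max": r_max, "d_um": d_um}
                )
                break
        else:
            raise PlacementError(
                f"could not place cell {i + 1}/{config.n_cells} without overlap "
                f"after {_MAX_PLACEMENT_ATTEMPTS} attempts"
            )
    return placed


def _ellipse_mask(shape: tuple[int, int], cy, cx, a, b, theta) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dy, dx = rr - cy, cc - cx
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def generate_field(config: SimulationConfig, seed: int | None = None) -> tuple[ImageStack, GroundTruth, ImageStack]:
    """Render one field of view.

    Returns ``(stack, truth, noiseless)`` where ``stack`` carries Poisson
    shot noise and Gaussian read noise and ``noiseless`` is the expected
    image before noise (useful for intensity assertions).
    """
    config.validate()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    rows, cols = config.field_shape_px
    clean = np.full((config.n_planes, rows, cols), float(config.background_level))

    placed = _place_cells(config, rng)
    truth = GroundTruth()
    psf_px = config.psf_sigma_um / config.pixel_size_um

    for i, geo in enumerate(placed):
        dead = bool(rng.random() < config.dead_cell_fraction)
        fluor = float(rng.normal(config.cell_autofluor_mean, config.cell_autofluor_sd))
        fluor = max(fluor, 0.2 * config.cell_autofluor_mean)
        if dead:
            fluor *= config.dead_brightness_factor
        positive = (not dead) and bool(rng.random() < config.cluster_positive_fraction)
        mask = _ellipse_mask((rows, cols), geo["cy"], geo["cx"], geo["a"], geo["b"], geo["theta"])
        clean[:, mask] += fluor
        cell = CellTruth(
            cell_id=i + 1,
            centroid_px=(geo["cy"], geo["cx"]),
            diameter_um=geo["d_um"],
            dead=dead,
            cluster_positive=positive,
            autofluor=fluor,
        )
        truth.cells.append(cell)
        if not positive:
            continue
        n_clusters = max(1, int(rng.poisson(config.clusters_per_positive_cell)))
        for _ in range(n_clusters):
            # cluster centre well inside the cell so its footprint stays in the mask
            rad = float(rng.uniform(0, 0.5)) * min(geo["a"], geo["b"])
            ang = float(rng.uniform(0, 2 * np.pi))
            ccy = geo["cy"] + rad * np.sin(ang)
            ccx = geo["cx"] + rad * np.cos(ang)
            d_um = float(rng.uniform(*config.cluster_diameter_range_um))
            amplitude = config.cluster_amplitude_factor * fluor
            focus_plane = int(rng.integers(1, max(2, config.n_planes - 1)))
            _render_cluster(clean, ccy, ccx, d_um, amplitude, focus_plane, psf_px, config)
            truth.clusters.append(
                ClusterTruth(cell_id=cell.cell_id, centroid_px=(ccy, ccx), diameter_um=d_um, amplitude=amplitude)
            )

    noisy = rng.poisson(np.clip(clean * config.poisson_scale, 0, None)) / config.poisson_scale
    noisy = noisy + rng.normal(0.0, config.read_sd, size=noisy.shape)
    noisy = np.clip(np.rint(noisy), 0, 65535).astype(np.uint16)

    stack = ImageStack(noisy, pixel_size_um=config.pixel_size_um, z_step_um=config.z_step_um)
    clean_stack = ImageStack(clean, pixel_size_um=config.pixel_size_um, z_step_um=config.z_step_um)
    return stack, truth, clean_stack


def _render_cluster(clean, cy, cx, d_um, amplitude, focus_plane, psf_px, config) -> None:
    """Add a Gaussian spot with a Gaussian in-focus z-envelope (peak weight 1)."""
    # lateral width: diffraction-limited object of size d blurred by the PSF
    sigma_px = float(np.hypot(d_um / 4.0 / config.pixel_size_um, psf_px))
    rows, cols = clean.shape[1:]
    half = int(np.ceil(4 * sigma_px))
    r0, r1 = max(0, int(cy) - half), min(rows, int(cy) + half + 1)
    c0, c1 = max(0, int(cx) - half), min(cols, int(cx) + half + 1)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    lateral = np.exp(-((rr - cy) ** 2 + (cc - cx) ** 2) / (2 * sigma_px**2))
    z = np.arange(config.n_planes)
    z_sigma = max(1.0, 0.3 / config.z_step_um)  # ~300 nm axial extent
    axial = np.exp(-((z - focus_plane) ** 2) / (2 * z_sigma**2))
    clean[:, r0:r1, c0:c1] += amplitude * axial[:, None, None] * lateral[None, :, :]


def generate_dataset(
    config: SimulationConfig, n_fields: int, base_seed: int | None = None
) -> list[tuple[ImageStack, GroundTruth, ImageStack]]:
    """Generate ``n_fields`` fields with per-field seeds ``base_seed + index``."""
    if n_fields < 1:
        raise ConfigError("n_fields must be >= 1")
    if base_seed is None:
        base_seed = config.seed
    return [generate_field(config, seed=base_seed + i) for i in range(n_fields)]


def write_field(out_dir, stack: ImageStack, truth: GroundTruth, config: SimulationConfig, seed: int) -> None:
    """Write one field as TIFF + truth CSVs + a plain-text metadata sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_stack(out_dir / "stack.tif", stack)
    with open(out_dir / "cells.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["cell_id", "centroid_row_px", "centroid_col_px", "diameter_um", "dead", "cluster_positive"])
        for c in truth.cells:
            w.writerow(
                [c.cell_id, f"{c.centroid_px[0]:.3f}", f"{c.centroid_px[1]:.3f}", f"{c.diameter_um:.4f}", int(c.dead), int(c.cluster_positive)]
            )
    with open(out_dir / "clusters.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["cell_id", "centroid_row_px", "centroid_col_px", "diameter_um", "amplitude"])
        for cl in truth.clusters:
            w.writerow(
                [cl.cell_id, f"{cl.centroid_px[0]:.3f}", f"{cl.centroid_px[1]:.3f}", f"{cl.diameter_um:.4f}", f"{cl.amplitude:.4f}"]
            )
    with open(out_dir / "metadata.txt", "w") as fh:
        fh.write(f"pixel_size_um\t{config.pixel_size_um}\n")
        fh.write(f"z_step_um\t{config.z_step_um}\n")
        fh.write(f"n_planes\t{config.n_planes}\n")
        fh.write(f"seed\t{seed}\n")
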