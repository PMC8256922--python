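"""Bilayer thickness maps from leaflet phosphate coordinates.

The thickness statistic is computed per trajectory frame and per x-y
bin: thickness(bin, frame) = mean z of upper-leaflet phosphates in the
bin minus mean z of lower-leaflet phosphates in the same bin.  Bins in
which either leaflet is empty for a frame contribute nothing for that
frame.  The map reports the mean over contributing frames and its SEM
(sd over frames / sqrt(n)); bins never populated by both leaflets are
flagged missing (NaN), never silently zero.

Coordinates arrive as a plain CSV (columns frame, leaflet, x, y, z plus
box dimensions), decoupling the statistic from any MD trajectory
format.  ``generate_synthetic_bilayer`` produces flat or locally
thinned ("dimpled") bilayers with known ground truth for testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, EmptyGridError, LeafletError, SchemaError

__all__ = [
    "PhosphateFrame",
    "ThicknessGrid",
    "load_frames",
    "save_frames",
    "thickness_map",
    "generate_synthetic_bilayer",
]

_REQUIRED_COLUMNS = ("frame", "leaflet", "x", "y", "z")


@dataclass
class PhosphateFrame:
    """Phosphate coordinates of one trajectory frame (lengths in nm)."""

    frame_id: int
    upper: np.ndarray  # (n, 3) x, y, z of upper-leaflet phosphates
    lower: np.ndarray
    box: tuple[float, float]  # (Lx, Ly)

    def __post_init__(self) -> None:
        self.upper = np.atleast_2d(np.asarray(self.upper, dtype=np.float64))
        self.lower = np.atleast_2d(np.asarray(self.lower, dtype=np.float64))
        if self.upper.size == 0 or self.lower.size == 0:
            raise LeafletError(f"frame {self.frame_id}: both leaflets must be nonempty")


@dataclass
class ThicknessGrid:
    """x-y binned thickness map with per-bin SEM over frames."""

    nx: int
    ny: int
    x_centers: np.ndarray
    y_centers: np.ndarray
    mean_thickness: np.ndarray  # (nx, ny), NaN where never populated
    sem_thickness: np.ndarray
    n_frames_per_bin: np.ndarray

    @property
    def occupied(self) -> np.ndarray:
        return self.n_frames_per_bin > 0

    def to_frame(self) -> pd.DataFrame:
        ix, iy = np.meshgrid(np.arange(self.nx), np.arange(self.ny), indexing="ij")
        return pd.DataFrame(
            {
                "bin_x": ix.ravel(),
                "bin_y": iy.ravel(),
                "x_nm": np.repeat(self.x_centers, self.ny),
                "y_nm": np.tile(self.y_centers, self.nx),
                "mean_nm": self.mean_thickness.ravel(),
                "sem_nm": self.sem_thickness.ravel(),
                "n": self.n_frames_per_bin.ravel(),
            }
        )


def load_frames(path) -> list[PhosphateFrame]:
    """Read a coordinate CSV into validated per-frame leaflet arrays.

    The CSV needs columns frame, leaflet ('upper'/'lower'), x, y, z and
    either box_x/box_y columns or a ``# box: Lx Ly`` comment line.
    """
    with open(path) as fh:
        first = fh.readline()
    box_from_comment = None
    if first.startswith("#"):
        parts = first.replace("#", "").replace("box:", "").split()
        if len(parts) >= 2:
            box_from_comment = (float(parts[0]), float(parts[1]))
    df = pd.read_csv(path, comment="#")
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"coordinate table missing columns: {missing}")
    if {"box_x", "box_y"}.issubset(df.columns):
        box = (float(df["box_x"].iloc[0]), float(df["box_y"].iloc[0]))
    elif box_from_comment is not None:
        box = box_from_comment
    else:
        raise SchemaError("box dimensions absent: provide box_x/box_y columns or a '# box: Lx Ly' line")

    frames: list[PhosphateFrame] = []
    for frame_id, grp in df.groupby("frame", sort=True):
        upper = grp.loc[grp["leaflet"] == "upper", ["x", "y", "z"]].to_numpy(dtype=np.float64)
        lower = grp.loc[grp["leaflet"] == "lower", ["x", "y", "z"]].to_numpy(dtype=np.float64)
        if upper.size == 0 or lower.size == 0:
            raise LeafletError(f"frame {frame_id} lacks a leaflet")
        frames.append(PhosphateFrame(frame_id=int(frame_id), upper=upper, lower=lower, box=box))
    return frames


def save_frames(path, frames: list[PhosphateFrame]) -> None:
    """Write frames to the coordinate-CSV schema read by :func:`load_frames`."""
    rows = []
    for fr in frames:
        for leaflet, arr in (("upper", fr.upper), ("lower", fr.lower)):
            for x, y, z in arr:
                rows.append((fr.frame_id, leaflet, x, y, z, fr.box[0], fr.box[1]))
    df = pd.DataFrame(rows, columns=["frame", "leaflet", "x", "y", "z", "box_x", "box_y"])
    df.to_csv(path, index=False, float_format="%.6f")


def thickness_map(frames: list[PhosphateFrame], nx: int, ny: int) -> ThicknessGrid:
    """Per-bin mean +/- SEM bilayer thickness over frames.

    Bin edges come from the box (periodic x-y wrapping is applied before
    binning), not from the data extent.  A single contributing frame
    gives SEM 0 with n = 1.
    """
    if not frames:
        raise ConfigError("need at least one frame")
    if nx < 1 or ny < 1:
        raise ConfigError("nx and ny must be >= 1")
    box = frames[0].box
    sums = np.zeros((nx, ny))
    sq_sums = np.zeros((nx, ny))
    counts = np.zeros((nx, ny), dtype=np.int64)

    for fr in frames:
        per_frame = _frame_thickness(fr, nx, ny, box)
        have = ~np.isnan(per_frame)
        sums[have] += per_frame[have]
        sq_sums[have] += per_frame[have] ** 2
        counts[have] += 1

    if not counts.any():
        raise EmptyGridError("no bin ever received phosphates from both leaflets")

    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        var = np.where(
            counts > 1,
            (sq_sums - counts * mean**2) / np.maximum(counts - 1, 1),
            0.0,
        )
        var = np.clip(var, 0.0, None)  # guard tiny negative rounding
        sem = np.where(counts > 0, np.sqrt(var) / np.sqrt(np.maximum(counts, 1)), np.nan)

    x_centers = (np.arange(nx) + 0.5) * box[0] / nx
    y_centers = (np.arange(ny) + 0.5) * box[1] / ny
    return ThicknessGrid(
        nx=nx, ny=ny, x_centers=x_centers, y_centers=y_centers,
        mean_thickness=mean, sem_thickness=sem, n_frames_per_bin=counts,
    )


def _frame_thickness(fr: PhosphateFrame, nx: int, ny: int, box) -> np.ndarray:
    """One frame's per-bin thickness; NaN where either leaflet is absent."""
    out = np.full((nx, ny), np.nan)
    leaflet_means = []
    for arr in (fr.upper, fr.lower):
        x = np.mod(arr[:, 0], box[0])
        y = np.mod(arr[:, 1], box[1])
        ix = np.minimum((x / box[0] * nx).astype(int), nx - 1)
        iy = np.minimum((y / box[1] * ny).astype(int), ny - 1)
        zsum = np.zeros((nx, ny))
        n = np.zeros((nx, ny))
        np.add.at(zsum, (ix, iy), arr[:, 2])
        np.add.at(n, (ix, iy), 1.0)
        with np.errstate(invalid="ignore"):
            leaflet_means.append(np.where(n > 0, zsum / np.maximum(n, 1), np.nan))
    both = ~np.isnan(leaflet_means[0]) & ~np.isnan(leaflet_means[1])
    out[both] = leaflet_means[0][both] - leaflet_means[1][both]
    return out


def generate_synthetic_bilayer(
    nx_particles: int = 30,
    n_frames: int = 10,
    box: tuple[float, float] = (12.0, 12.0),
    z0: float = 2.0,
    dimple: dict | None = None,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> list[PhosphateFrame]:
    """Flat or dimpled synthetic bilayer frames on a jittered lattice.

    The upper leaflet sits at ``+z0 - depth/2 * exp(-r^2 / 2 width^2)``
    and the lower leaflet mirrors it, so the true thickness field is
    ``2 z0 - depth * exp(-r^2 / 2 width^2)`` with minimum ``2 z0 - depth``
    at the dimple centre.  i.i.d. Gaussian z-noise of sd ``noise_sd`` is
    added to every phosphate in every frame.
    """
    if nx_particles < 2 or n_frames < 1 or z0 <= 0 or noise_sd < 0:
        raise ConfigError("invalid bilayer parameters")
    dimple = dimple or {"depth": 0.0, "width": 1.0, "center": (box[0] / 2, box[1] / 2)}
    if dimple["width"] <= 0 or dimple["depth"] < 0:
        raise ConfigError("dimple width must be positive and depth non-negative")
    rng = np.random.default_rng(seed)
    spacing = (box[0] / nx_particles, box[1] / nx_particles)
    gx, gy = np.meshgrid(
        (np.arange(nx_particles) + 0.5) * spacing[0],
        (np.arange(nx_particles) + 0.5) * spacing[1],
        indexing="ij",
    )
    base_xy = np.column_stack([gx.ravel(), gy.ravel()])
    cx, cy = dimple["center"]

    frames: list[PhosphateFrame] = []
    for f in range(n_frames):
        leaflets = {}
        for sign, name in ((1.0, "upper"), (-1.0, "lower")):
            xy = np.mod(base_xy + rng.normal(0, 0.1 * spacing[0], size=base_xy.shape), box)
            r2 = (xy[:, 0] - cx) ** 2 + (xy[:, 1] - cy) ** 2
            depression = 0.5 * dimple["depth"] * np.exp(-r2 / (2 * dimple["width"] ** 2))
            z = sign * (z0 - depression) + rng.normal(0, noise_sd, size=xy.shape[0])
            leaflets[name] = np.column_stack([xy, z])
        frames.append(PhosphateFrame(frame_id=f, upper=leaflets["upper"], lower=leaflets["lower"], box=box))
    return frames
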