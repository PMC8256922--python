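"""Two-tier detection of Ire1-GFP clusters within segmented cells.

Standard mode: a single global threshold at 1.5x the pixel-pooled mean
intensity of all kept-cell pixels on the maximum projection; candidate
components are gated to 0.3-0.9 um equivalent diameter and assigned to
the cell containing their centroid.

Stringent mode (used when elevated autofluorescence threatens false
positives): candidates in 0.3-1.2 um are allowed, a cell whose
candidates cover more than 3.5% of its area is declared unfit and
counted as cluster-free (but stays in the denominator), and a surviving
candidate is only counted if its maximum intensity reaches 2.5x the mean
intensity of its own cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .cell_segmentation import CellLabelMap, CellRecord
from .errors import CalibrationMismatchError, EmptyFieldError
from .io_projection import Image2D

__all__ = [
    "ClusterParams",
    "ClusterRecord",
    "CellClusterCall",
    "detect_clusters_standard",
    "detect_clusters_stringent",
    "detect_clusters",
    "call_fraction",
]


@dataclass(frozen=True)
class ClusterParams:
    """Gate parameters of the two cluster-calling modes.

    rel_threshold
        Standard mode: global threshold multiplier on the pooled
        kept-cell mean intensity (1.5).
    rel_max_intensity
        Stringent mode: per-cluster peak must reach this multiple of the
        parent cell's mean intensity (2.5).
    coverage_cutoff
        Stringent mode: a cell is unfit when diameter-passing candidates
        cover more than this fraction of its area (0.035).
    per_cell_threshold
        Optional variant of standard mode in which the 1.5x threshold is
        taken per cell instead of globally.
    """

    mode: str = "standard"
    rel_threshold: float = 1.5
    rel_max_intensity: float = 2.5
    cluster_diameter_min_um: float = 0.3
    cluster_diameter_max_um: float = 0.9
    coverage_cutoff: float = 0.035
    per_cell_threshold: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("standard", "stringent"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.rel_threshold <= 1 or self.rel_max_intensity <= 1:
            raise ValueError("intensity multipliers must exceed 1")
        if not (0 < self.cluster_diameter_min_um < self.cluster_diameter_max_um):
            raise ValueError("require 0 < cluster_diameter_min_um < cluster_diameter_max_um")
        if not (0 < self.coverage_cutoff < 1):
            raise ValueError("coverage_cutoff must be in (0, 1)")

    @classmethod
    def for_mode(cls, mode: str, **kwargs) -> "ClusterParams":
        if mode == "standard":
            kwargs.setdefault("cluster_diameter_max_um", 0.9)
        elif mode == "stringent":
            kwargs.setdefault("cluster_diameter_max_um", 1.2)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        return cls(mode=mode, **kwargs)


@dataclass
class ClusterRecord:
    """One detected cluster, measured on the maximum projection."""

    cluster_id: int
    cell_id: int
    area_px: int
    equiv_diameter_um: float
    max_intensity: float
    integrated_intensity: float
    centroid_px: tuple[float, float]
    counted: bool


@dataclass
class CellClusterCall:
    """Per-cell verdict: number of counted clusters and fitness status."""

    cell_id: int
    n_clusters_counted: int
    coverage: float
    status: str  # {fit, unfit}
    cluster_positive: bool


def _candidate_components(
    max_proj: Image2D,
    cells: CellLabelMap,
    records: list[CellRecord],
    threshold_map: np.ndarray,
) -> list[dict]:
    """Connected components above threshold, clipped to cells and measured.

    Components are 8-connected; each is assigned to the cell containing
    its centroid and clipped to that cell's mask before measurement.
    Components whose centroid falls outside every kept cell are dropped.
    """
    data = np.asarray(max_proj.data, dtype=np.float64)
    above = data > threshold_map
    structure = np.ones((3, 3), dtype=bool)
    comp_labels, n_comp = ndimage.label(above, structure=structure)
    px = max_proj.pixel_size_um
    out: list[dict] = []
    next_id = 1
    for comp_id in range(1, n_comp + 1):
        comp_mask = comp_labels == comp_id
        rows, cols = np.nonzero(comp_mask)
        centroid = (rows.mean(), cols.mean())
        cell_id = int(cells.labels[int(round(centroid[0])), int(round(centroid[1]))])
        if cell_id == 0:
            continue
        clipped = comp_mask & (cells.labels == cell_id)
        if not clipped.any():
            continue
        rows, cols = np.nonzero(clipped)
        area_px = int(clipped.sum())
        area_um2 = area_px * px * px
        out.append(
            {
                "cluster_id": next_id,
                "cell_id": cell_id,
                "mask_area_px": area_px,
                "equiv_diameter_um": 2.0 * np.sqrt(area_um2 / np.pi),
                "max_intensity": float(data[clipped].max()),
                "integrated_intensity": float(data[clipped].sum()),
                "centroid_px": (float(rows.mean()), float(cols.mean())),
            }
        )
        next_id += 1
    return out


def _check_calibration(max_proj: Image2D, cells: CellLabelMap) -> None:
    if not np.isclose(max_proj.pixel_size_um, cells.pixel_size_um):
        raise CalibrationMismatchError(
            f"projection pixel size {max_proj.pixel_size_um} um differs from "
            f"label map pixel size {cells.pixel_size_um} um"
        )
    if max_proj.shape != cells.labels.shape:
        raise CalibrationMismatchError("projection and label map shapes differ")


def detect_clusters_standard(
    max_proj: Image2D,
    cells: CellLabelMap,
    records: list[CellRecord],
    params: ClusterParams | None = None,
) -> tuple[list[ClusterRecord], list[CellClusterCall]]:
    """Standard-mode cluster detection (1.5x global threshold, 0.3-0.9 um gate)."""
    if params is None:
        params = ClusterParams.for_mode("standard")
    _check_calibration(max_proj, cells)
    kept = [r for r in records if r.kept]
    if not kept:
        return [], []

    data = np.asarray(max_proj.data, dtype=np.float64)
    cell_union = cells.labels > 0
    if params.per_cell_threshold:
        threshold_map = np.full(data.shape, np.inf)
        means = {r.cell_id: float(data[cells.labels == r.cell_id].mean()) for r in kept}
        for r in kept:
            threshold_map[cells.labels == r.cell_id] = params.rel_threshold * means[r.cell_id]
    else:
        pooled_mean = float(data[cell_union].mean())
        threshold_map = np.full(data.shape, params.rel_threshold * pooled_mean)
        # pixels outside cells can never seed a candidate
        threshold_map[~cell_union] = np.inf

    candidates = _candidate_components(max_proj, cells, records, threshold_map)
    clusters: list[ClusterRecord] = []
    per_cell: dict[int, int] = {r.cell_id: 0 for r in kept}
    for cand in candidates:
        in_gate = params.cluster_diameter_min_um <= cand["equiv_diameter_um"] <= params.cluster_diameter_max_um
        clusters.append(
            ClusterRecord(
                cluster_id=cand["cluster_id"],
                cell_id=cand["cell_id"],
                area_px=cand["mask_area_px"],
                equiv_diameter_um=cand["equiv_diameter_um"],
                max_intensity=cand["max_intensity"],
                integrated_intensity=cand["integrated_intensity"],
                centroid_px=cand["centroid_px"],
                counted=in_gate,
            )
        )
        if in_gate:
            per_cell[cand["cell_id"]] = per_cell.get(cand["cell_id"], 0) + 1

    calls = [
        CellClusterCall(
            cell_id=r.cell_id,
            n_clusters_counted=per_cell.get(r.cell_id, 0),
            coverage=0.0,
            status="fit",
            cluster_positive=per_cell.get(r.cell_id, 0) >= 1,
        )
        for r in kept
    ]
    return clusters, calls


def detect_clusters_stringent(
    max_proj: Image2D,
    cells: CellLabelMap,
    records: list[CellRecord],
    params: ClusterParams | None = None,
) -> tuple[list[ClusterRecord], list[CellClusterCall]]:
    """Stringent-mode detection (0.3-1.2 um gate, 2.5x peak rule, 3.5% unfit rule).

    Coverage is computed over diameter-passing candidates *before* the
    intensity gate; unfit cells are called cluster-free but remain in
    the denominator of any downstream fraction.
    """
    if params is None:
        params = ClusterParams.for_mode("stringent")
    _check_calibration(max_proj, cells)
    kept = [r for r in records if r.kept]
    if not kept:
        return [], []

    data = np.asarray(max_proj.data, dtype=np.float64)
    cell_union = cells.labels > 0
    pooled_mean = float(data[cell_union].mean())
    threshold_map = np.full(data.shape, params.rel_threshold * pooled_mean)
    threshold_map[~cell_union] = np.inf

    candidates = _candidate_components(max_proj, cells, records, threshold_map)
    by_cell: dict[int, list[dict]] = {}
    for cand in candidates:
        in_gate = params.cluster_diameter_min_um <= cand["equiv_diameter_um"] <= params.cluster_diameter_max_um
        cand["in_gate"] = in_gate
        by_cell.setdefault(cand["cell_id"], []).append(cand)

    # the 2.5x peak rule compares intensities on the max projection, so the
    # reference cell mean is measured there too (all cell pixels, spots included)
    cell_mean = {r.cell_id: float(data[cells.labels == r.cell_id].mean()) for r in kept}
    cell_area = {r.cell_id: int((cells.labels == r.cell_id).sum()) for r in kept}

    clusters: list[ClusterRecord] = []
    calls: list[CellClusterCall] = []
    for r in kept:
        cands = by_cell.get(r.cell_id, [])
        gated = [c for c in cands if c["in_gate"]]
        coverage = sum(c["mask_area_px"] for c in gated) / cell_area[r.cell_id]
        unfit = coverage > params.coverage_cutoff
        n_counted = 0
        for cand in cands:
            counted = (
                not unfit
                and cand["in_gate"]
                and cand["max_intensity"] >= params.rel_max_intensity * cell_mean[r.cell_id]
            )
            clusters.append(
                ClusterRecord(
                    cluster_id=cand["cluster_id"],
                    cell_id=cand["cell_id"],
                    area_px=cand["mask_area_px"],
                    equiv_diameter_um=cand["equiv_diameter_um"],
                    max_intensity=cand["max_intensity"],
                    integrated_intensity=cand["integrated_intensity"],
                    centroid_px=cand["centroid_px"],
                    counted=counted,
                )
            )
            if counted:
                n_counted += 1
        calls.append(
            CellClusterCall(
                cell_id=r.cell_id,
                n_clusters_counted=0 if unfit else n_counted,
                coverage=coverage,
                status="unfit" if unfit else "fit",
                cluster_positive=(not unfit) and n_counted >= 1,
            )
        )
    return clusters, calls


def detect_clusters(max_proj, cells, records, mode: str = "standard", params: ClusterParams | None = None):
    """Dispatch to the standard or stringent detector."""
    if mode == "standard":
        return detect_clusters_standard(max_proj, cells, records, params)
    if mode == "stringent":
        return detect_clusters_stringent(max_proj, cells, records, params)
    raise ValueError(f"unknown mode {mode!r}")


def call_fraction(calls: list[CellClusterCall]) -> float:
    """Fraction of cluster-positive cells; unfit cells stay in the denominator."""
    if not calls:
        raise EmptyFieldError("cannot compute a positive fraction over zero cells")
    return sum(c.cluster_positive for c in calls) / len(calls)
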