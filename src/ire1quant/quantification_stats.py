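"""Per-field aggregation, significance tests and sequence-annotation helpers.

The unit of replication is the field of view: each field contributes one
cluster-positive fraction, and dataset summaries report the mean and SEM
over fields, matching how imaging replicates are reported.  Cluster
morphometrics (areas, integrated intensities) are pooled across fields
and compared between conditions with a two-sample Kolmogorov-Smirnov
test; per-field fractions are compared with an unpaired two-tailed
Student's t test (pooled variance).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cluster_detection import CellClusterCall, ClusterRecord, call_fraction
from .errors import EmptyInputError, InsufficientDataError

__all__ = [
    "FieldResult",
    "DatasetSummary",
    "field_result",
    "summarize",
    "ttest_unpaired",
    "ks_test",
    "helical_wheel",
]


@dataclass
class FieldResult:
    """Cluster-calling outcome of one field of view."""

    field_id: str
    n_cells: int
    n_positive: int
    fraction: float
    cluster_areas_px: list[float] = field(default_factory=list)
    cluster_integrated: list[float] = field(default_factory=list)


@dataclass
class DatasetSummary:
    """Mean +/- SEM of per-field fractions plus pooled morphometrics."""

    condition: str
    mean_fraction: float
    sem_fraction: float
    n_fields: int
    cluster_areas_px: list[float]
    cluster_integrated: list[float]


def field_result(field_id: str, calls: list[CellClusterCall], clusters: list[ClusterRecord]) -> FieldResult:
    """Assemble one field's result from its calls and counted clusters."""
    counted = [c for c in clusters if c.counted]
    return FieldResult(
        field_id=field_id,
        n_cells=len(calls),
        n_positive=sum(c.cluster_positive for c in calls),
        fraction=call_fraction(calls) if calls else float("nan"),
        cluster_areas_px=[float(c.area_px) for c in counted],
        cluster_integrated=[c.integrated_intensity for c in counted],
    )


def summarize(fields: list[FieldResult], condition: str = "") -> DatasetSummary:
    """Mean and SEM of per-field positive fractions; pooled morphometrics.

    SEM is sd/sqrt(n) with the sample (ddof=1) standard deviation; a
    single field reports SEM 0 by convention.
    """
    if not fields:
        raise EmptyInputError("summarize requires at least one field")
    fractions = np.array([f.fraction for f in fields], dtype=np.float64)
    mean = float(fractions.mean())
    sem = 0.0 if len(fields) == 1 else float(fractions.std(ddof=1) / np.sqrt(len(fields)))
    areas: list[float] = []
    integ: list[float] = []
    for f in fields:
        areas.extend(f.cluster_areas_px)
        integ.extend(f.cluster_integrated)
    return DatasetSummary(
        condition=condition,
        mean_fraction=mean,
        sem_fraction=sem,
        n_fields=len(fields),
        cluster_areas_px=areas,
        cluster_integrated=integ,
    )


def ttest_unpaired(a, b) -> tuple[float, float]:
    """Classical unpaired two-tailed Student's t test (pooled variance)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each sample needs at least two values")
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def ks_test(a, b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test (sup CDF distance, asymptotic p)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 1 or b.size < 1:
        raise InsufficientDataError("each sample needs at least one value")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def helical_wheel(sequence: str, start_index: int = 1) -> list[tuple[str, int, float]]:
    """Place residues on an alpha-helical wheel (100 degrees per residue).

    Residue at 0-based offset k sits at angle ``(k * 100) % 360`` degrees;
    the radius is constant, so only (residue, index, angle) is returned.
    ``start_index`` labels the first residue (e.g. 540 for the Ire1
    transmembrane-helix stretch 540-552).
    """
    if not sequence:
        raise ValueError("sequence must be nonempty")
    return [(res, start_index + k, float((k * 100) % 360)) for k, res in enumerate(sequence)]
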