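"""End-to-end per-field analysis: stack in, cluster calls out."""

from __future__ import annotations

from .cell_segmentation import SegmentationParams, segment_cells
from .cluster_detection import ClusterParams, detect_clusters
from .io_projection import ImageStack, max_projection, median_smooth, register_xy, sum_projection
from .quantification_stats import FieldResult, field_result

__all__ = ["analyze_field"]


def analyze_field(
    stack: ImageStack,
    field_id: str = "field",
    mode: str = "standard",
    seg_params: SegmentationParams | None = None,
    cluster_params: ClusterParams | None = None,
    register: bool = False,
) -> FieldResult:
    """Run the full quantification on one z-stack.

    Cells are segmented on the median-smoothed sum projection; clusters
    are detected on the raw maximum projection in the requested mode
    (``standard`` or ``stringent``, which also selects the matching
    brightness-exclusion fraction).  Drift correction is opt-in since
    simulated stacks carry none.
    """
    if register:
        stack, _ = register_xy(stack)
    if seg_params is None:
        seg_params = SegmentationParams.for_mode(mode)
    if cluster_params is None:
        cluster_params = ClusterParams.for_mode(mode)
    detection = sum_projection(stack)
    label_map, records = segment_cells(detection, seg_params)
    clusters, calls = detect_clusters(max_projection(stack), label_map, records, mode=mode, params=cluster_params)
    return field_result(field_id, calls, clusters)
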