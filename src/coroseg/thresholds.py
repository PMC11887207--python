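"""Two-pass per-patch threshold selection.

For every patch the pipeline runs: Ward clustering -> cluster graph -> MST ->
vessel path -> background removal, then re-clusters the cleaned patch with the
same cluster count and traces the path again.  The second path is a sequence
of brightness levels from the lumen interior outward; the segmentation
threshold is read off it by a fixed rule:

* keep only path clusters whose mean HU lies in the [100, 600] band;
* more than three remain  -> take the third (two interior levels are skipped,
  landing near the lumen edge);
* one to three remain     -> take the last;
* none remain             -> emit the 150 HU fallback and flag it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .clustering import cluster_stats, ward_cluster
from .config import PipelineConfig
from .graph import (VesselPath, boruvka_mst, build_graph, find_vessel_path,
                    remove_background)
from .patches import Patch, clip_intensities

__all__ = ["ThresholdRecord", "select_threshold_from_path", "threshold_for_patch"]


@dataclass
class ThresholdRecord:
    """One segmentation threshold, traced back to its centerline point."""

    source_point: tuple[int, int]
    view_tag: str
    threshold_hu: float
    used_fallback: bool
    path_len: int
    details: dict = field(default_factory=dict, repr=False)


def select_threshold_from_path(path_mean_hus, hu_low: float = 100.0,
                               hu_high: float = 600.0,
                               fallback_hu: float = 150.0
                               ) -> tuple[float, bool]:
    """Apply the third-cluster rule to a brightest-first path of mean HUs.

    The lower bound is exclusive: cluster means sitting exactly at ``hu_low``
    can only arise from intensities saturated at the clip floor, i.e. pure
    background, and counting them in range would make the fallback
    unreachable.
    """
    in_range = [hu for hu in path_mean_hus if hu_low < hu <= hu_high]
    if not in_range:
        return float(fallback_hu), True
    if len(in_range) > 3:
        return float(in_range[2]), False
    return float(in_range[-1]), False


def threshold_for_patch(patch: Patch, config: PipelineConfig | None = None,
                        capture_details: bool = False) -> ThresholdRecord:
    """Run the full two-pass procedure on one patch and emit its threshold.

    The patch is clipped here if the caller has not clipped it already.  With
    ``capture_details`` the record carries the intermediate labelings, paths
    and the cleaned patch for inspection and testing.
    """
    config = config or PipelineConfig()
    if patch.clip_bounds is None:
        patch = clip_intensities(patch, config.hu_low, config.hu_high)

    def one_pass(p: Patch) -> tuple[VesselPath, "np.ndarray", object]:
        labeling = cluster_stats(p, ward_cluster(p, config.n_clusters))
        graph = boruvka_mst(build_graph(labeling, patch.center_px))
        return find_vessel_path(graph, config.stop_hu), labeling, graph

    path1, labeling1, graph1 = one_pass(patch)
    cleaned, removed = remove_background(patch, labeling1, path1)
    path2, labeling2, graph2 = one_pass(cleaned)
    threshold, fallback = select_threshold_from_path(
        path2.mean_hus, config.hu_low, config.hu_high, config.fallback_hu)

    details = {}
    if capture_details:
        details = dict(path1=path1, labeling1=labeling1, graph1=graph1,
                       cleaned=cleaned, background_removed=removed,
                       path2=path2, labeling2=labeling2, graph2=graph2)
    return ThresholdRecord(patch.source_point, patch.view_tag, threshold,
                           fallback, len(path2), details)
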