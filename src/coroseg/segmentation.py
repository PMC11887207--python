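"""3D mask reconstruction from per-point thresholds.

Two reconstruction variants:

* ``perp`` -- at every centerline point, all voxels within a 2 mm sphere are
  *assigned* (1 where HU >= threshold, 0 otherwise).  Points are processed in
  ascending threshold order so spheres with higher thresholds -- narrower
  lumens -- overwrite earlier, more permissive ones.  Just after a
  bifurcation the sphere is clipped to the forward half-space of the child
  branch so it cannot repaint the parent vessel.
* ``3axis`` -- per anatomical plane, a flat 4 mm brush assigns the single
  grid slice through the point with that plane's threshold (same ascending
  overwrite order per plane); the three per-plane masks are then combined by
  voxelwise union.

Both variants end with a 1 mm binary median (majority) smoothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter

from .centerline import Centerline, resample_centerline
from .config import PipelineConfig
from .errors import GeometryError, MarginError
from .patches import (compute_perpendicular_frame, extract_perpendicular_patch,
                      extract_triaxial_patches, clip_intensities)
from .thresholds import ThresholdRecord, threshold_for_patch
from .volume import CTVolume, resample_isotropic

logger = logging.getLogger(__name__)

__all__ = [
    "SegmentationMask",
    "paint_spheres",
    "paint_triaxial",
    "combine_planes",
    "median_smooth",
    "segment_vessel_tree",
]

_PLANE_AXIS = {"axial": 2, "sagittal": 0, "coronal": 1}


@dataclass
class SegmentationMask:
    """Binary 3D grid aligned to a reference CTVolume."""

    grid: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid).astype(bool)
        if self.grid.ndim != 3:
            raise GeometryError("mask must be 3D")

    @property
    def shape(self):
        return self.grid.shape

    def voxel_count(self) -> int:
        return int(self.grid.sum())


def _point_lookup(cl: Centerline, forward_only_mm: float):
    """Map (branch_id, point_index) -> (point, tangent, forward_clip)."""
    lookup = {}
    for b in cl.branches:
        arcs = b.arclengths()
        for i, (p, t) in enumerate(zip(b.points, b.tangents)):
            fwd = b.parent_id is not None and arcs[i] <= forward_only_mm
            lookup[(b.branch_id, i)] = (p, t, fwd)
    return lookup


def _sorted_records(records):
    return sorted(records, key=lambda r: (r.threshold_hu, r.source_point))


def paint_spheres(vol: CTVolume, records, cl: Centerline,
                  radius_mm: float = 2.0,
                  forward_only_mm: float = 2.0) -> SegmentationMask:
    """Perpendicular-variant painting: threshold inside spheres, ascending
    threshold order, forward-half-space clipping after bifurcations."""
    grid = np.zeros(vol.shape, dtype=bool)
    if not records:
        logger.warning("paint_spheres called with no threshold records")
        return SegmentationMask(grid, {"method": "perp", "radius_mm": radius_mm})
    lookup = _point_lookup(cl, forward_only_mm)
    shape = np.array(vol.shape)
    for rec in _sorted_records(records):
        point, tangent, fwd = lookup[rec.source_point]
        lo = np.maximum(np.ceil((point - radius_mm - vol.origin) / vol.spacing), 0)
        hi = np.minimum(np.floor((point + radius_mm - vol.origin) / vol.spacing),
                        shape - 1)
        lo, hi = lo.astype(int), hi.astype(int)
        if np.any(hi < lo):
            continue
        ax = [vol.origin[d] + np.arange(lo[d], hi[d] + 1) * vol.spacing[d] - point[d]
              for d in range(3)]
        dx, dy, dz = np.meshgrid(*ax, indexing="ij")
        inside = dx * dx + dy * dy + dz * dz <= radius_mm ** 2
        if fwd:
            inside &= dx * tangent[0] + dy * tangent[1] + dz * tangent[2] >= 0
        box = (slice(lo[0], hi[0] + 1), slice(lo[1], hi[1] + 1),
               slice(lo[2], hi[2] + 1))
        sub = grid[box]
        sub[inside] = vol.voxels[box][inside] >= rec.threshold_hu
        grid[box] = sub
    return SegmentationMask(grid, {"method": "perp", "radius_mm": radius_mm,
                                   "n_records": len(records)})


def paint_triaxial(vol: CTVolume, records, cl: Centerline,
                   radius_mm: float = 4.0) -> dict[str, SegmentationMask]:
    """3-axis variant painting: per plane, a flat disc brush on the one grid
    slice through each point.  Returns one mask per plane tag."""
    lookup = _point_lookup(cl, 0.0)
    masks = {}
    shape = np.array(vol.shape)
    for tag, axis in _PLANE_AXIS.items():
        grid = np.zeros(vol.shape, dtype=bool)
        plane_recs = [r for r in records if r.view_tag == tag]
        if not plane_recs:
            logger.warning("no records for %s plane", tag)
        in_plane = [d for d in range(3) if d != axis]
        for rec in _sorted_records(plane_recs):
            point, _, _ = lookup[rec.source_point]
            k = int(round((point[axis] - vol.origin[axis]) / vol.spacing[axis]))
            if not 0 <= k < shape[axis]:
                continue
            lo = np.maximum(np.ceil(
                (point - radius_mm - vol.origin) / vol.spacing), 0).astype(int)
            hi = np.minimum(np.floor(
                (point + radius_mm - vol.origin) / vol.spacing),
                shape - 1).astype(int)
            ax = [vol.origin[d] + np.arange(lo[d], hi[d] + 1) * vol.spacing[d]
                  - point[d] for d in in_plane]
            du, dv = np.meshgrid(*ax, indexing="ij")
            disc = du * du + dv * dv <= radius_mm ** 2
            idx = [None, None, None]
            idx[axis] = k
            idx[in_plane[0]] = slice(lo[in_plane[0]], hi[in_plane[0]] + 1)
            idx[in_plane[1]] = slice(lo[in_plane[1]], hi[in_plane[1]] + 1)
            box = tuple(idx)
            sub = grid[box]
            sub[disc] = vol.voxels[box][disc] >= rec.threshold_hu
            grid[box] = sub
        masks[tag] = SegmentationMask(grid, {"method": "3axis", "plane": tag,
                                             "radius_mm": radius_mm})
    return masks


def combine_planes(masks) -> SegmentationMask:
    """Voxelwise union of the per-plane masks."""
    mask_list = list(masks.values()) if isinstance(masks, dict) else list(masks)
    shapes = {m.shape for m in mask_list}
    if len(shapes) != 1:
        raise GeometryError(f"plane masks have mismatched shapes: {shapes}")
    grid = np.zeros(mask_list[0].shape, dtype=bool)
    for m in mask_list:
        grid |= m.grid
    return SegmentationMask(grid, {"method": "3axis", "combined": True})


def median_smooth(mask: SegmentationMask, kernel_mm: float = 1.0,
                  spacing_mm: float = 0.25) -> SegmentationMask:
    """Binary median (majority) filter with a cubic kernel of ``kernel_mm``
    edge, rounded to an odd voxel count of at least 3."""
    edge = max(3, 2 * int(np.floor(kernel_mm / spacing_mm / 2)) + 1)
    smoothed = median_filter(mask.grid.astype(np.uint8), size=edge) > 0
    prov = dict(mask.provenance, smooth_mm=kernel_mm, kernel_vox=edge)
    return SegmentationMask(smoothed, prov)


def segment_vessel_tree(vol: CTVolume, cl: Centerline, method: str = "perp",
                        config: PipelineConfig | None = None,
                        details_out: list | None = None
                        ) -> tuple[SegmentationMask, list[ThresholdRecord]]:
    """Run the complete pipeline: resample, extract patches, select per-point
    thresholds, paint, combine (3axis) and median-smooth.

    Points whose 8 mm patch field of view leaves the volume are skipped with
    a warning.  ``details_out``, when given a list, receives
    ``(patch, record)`` pairs with full intermediate diagnostics.
    """
    config = config or PipelineConfig()
    if method not in ("perp", "3axis"):
        raise GeometryError(f"unknown method {method!r}")
    vol = resample_isotropic(vol, config.resample_mm)
    cl = resample_centerline(cl, config.centerline_step_mm)

    capture = details_out is not None
    records: list[ThresholdRecord] = []
    n_skipped = 0
    for branch in cl.branches:
        frames = compute_perpendicular_frame(branch) if method == "perp" else None
        for i, point in enumerate(branch.points):
            src = (branch.branch_id, i)
            try:
                if method == "perp":
                    patches = [extract_perpendicular_patch(vol, point, frames[i],
                                                           src)]
                else:
                    patches = list(extract_triaxial_patches(vol, point, src)
                                   .values())
            except MarginError:
                n_skipped += 1
                logger.warning("skipping point %s: patch leaves the volume", src)
                continue
            for patch in patches:
                patch = clip_intensities(patch, config.hu_low, config.hu_high)
                rec = threshold_for_patch(patch, config, capture_details=capture)
                records.append(rec)
                if capture:
                    details_out.append((patch, rec))

    if method == "perp":
        mask = paint_spheres(vol, records, cl, config.sphere_radius_mm,
                             config.forward_only_mm)
    else:
        mask = combine_planes(paint_triaxial(vol, records, cl,
                                             config.brush_radius_mm))
    mask = median_smooth(mask, config.smooth_mm, config.resample_mm)
    mask.provenance.update(method=method, n_points_skipped=n_skipped,
                           n_records=len(records),
                           n_fallback=sum(r.used_fallback for r in records))
    return mask, records
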