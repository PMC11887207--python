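"""Overlap and surface-distance evaluation metrics.

Voxelwise confusion counts against a ground-truth mask yield Dice
(2TP / (2TP + FP + FN)), IoU (TP / (TP + FP + FN)), precision (TP / (TP + FP))
and recall (TP / (TP + FN)).  Surface metrics (symmetric Hausdorff and mean
surface distance) are computed between boundary voxel sets in mm.  A lesion
can be evaluated inside an axis-aligned cube (default 8 mm, i.e. 32 voxels at
the 0.25 mm working resolution) centred on the lesion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_erosion
from scipy.spatial import cKDTree

from .errors import GeometryError, MetricError
from .segmentation import SegmentationMask
from .volume import CTVolume

__all__ = [
    "ConfusionCounts",
    "confusion_counts",
    "dice",
    "iou",
    "precision",
    "recall",
    "surface_distances",
    "lesion_cube_roi",
]


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _grid(mask) -> np.ndarray:
    return np.asarray(getattr(mask, "grid", mask)).astype(bool)


def confusion_counts(pred, truth, roi: tuple[slice, ...] | None = None
                     ) -> ConfusionCounts:
    """Voxelwise TP/FP/TN/FN, optionally restricted to an ROI box."""
    p, t = _grid(pred), _grid(truth)
    if p.shape != t.shape:
        raise GeometryError(f"shape mismatch: {p.shape} vs {t.shape}")
    if roi is not None:
        p, t = p[roi], t[roi]
    tp = int(np.sum(p & t))
    fp = int(np.sum(p & ~t))
    fn = int(np.sum(~p & t))
    tn = p.size - tp - fp - fn
    return ConfusionCounts(tp, fp, tn, fn)


def _ratio(num: float, den: float, both_empty: bool) -> float:
    # Convention for degenerate denominators: 1 when both masks are empty,
    # 0 when exactly one is.
    if den == 0:
        return 1.0 if both_empty else 0.0
    return num / den


def dice(c: ConfusionCounts) -> float:
    return _ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn, c.fp + c.fn == 0)


def iou(c: ConfusionCounts) -> float:
    return _ratio(c.tp, c.tp + c.fp + c.fn, c.fp + c.fn == 0)


def precision(c: ConfusionCounts) -> float:
    return _ratio(c.tp, c.tp + c.fp, c.tp + c.fn == 0)


def recall(c: ConfusionCounts) -> float:
    return _ratio(c.tp, c.tp + c.fn, c.tp + c.fp == 0)


def _boundary_points(grid: np.ndarray, spacing: np.ndarray) -> np.ndarray:
    boundary = grid & ~binary_erosion(grid)
    return np.argwhere(boundary) * spacing


def surface_distances(pred, truth, spacing_mm=(0.25, 0.25, 0.25)
                      ) -> tuple[float, float]:
    """Symmetric (Hausdorff, mean surface distance) in mm between the two
    mask boundaries.  Raises :class:`MetricError` if either mask is empty."""
    p, t = _grid(pred), _grid(truth)
    if p.shape != t.shape:
        raise GeometryError(f"shape mismatch: {p.shape} vs {t.shape}")
    if not p.any() or not t.any():
        raise MetricError("surface distances undefined for an empty mask")
    spacing = np.asarray(spacing_mm, dtype=float)
    pa, pb = _boundary_points(p, spacing), _boundary_points(t, spacing)
    d_ab, _ = cKDTree(pb).query(pa)
    d_ba, _ = cKDTree(pa).query(pb)
    hausdorff = float(max(d_ab.max(), d_ba.max()))
    msd = float((d_ab.mean() + d_ba.mean()) / 2)
    return hausdorff, msd


def lesion_cube_roi(center_mm, edge_mm: float, ref: CTVolume
                    ) -> tuple[tuple[slice, slice, slice], bool]:
    """Axis-aligned voxel-index cube of ``edge_mm`` centred on a lesion.

    Returns ``(slices, clipped)``; ``clipped`` is True when the cube had to
    be cut at the volume bounds.  At 0.25 mm spacing an 8 mm cube spans 32
    voxels per edge.
    """
    center = np.asarray(center_mm, dtype=float)
    idx = np.round(ref.index_of(center)).astype(int)
    shape = np.array(ref.shape)
    if np.any(idx < 0) or np.any(idx >= shape):
        raise GeometryError(f"lesion centre {center} is outside the volume")
    edges = np.round(edge_mm / ref.spacing).astype(int)
    lo = idx - edges // 2
    hi = lo + edges
    lo_c, hi_c = np.maximum(lo, 0), np.minimum(hi, shape)
    clipped = bool(np.any(lo_c != lo) or np.any(hi_c != hi))
    return tuple(slice(int(a), int(b)) for a, b in zip(lo_c, hi_c)), clipped


def evaluate_masks(pred, truth, spacing_mm=(0.25, 0.25, 0.25),
                   roi: tuple[slice, ...] | None = None,
                   surfaces: bool = True) -> dict[str, float]:
    """All metrics in one report row."""
    c = confusion_counts(pred, truth, roi)
    out = {"dice": dice(c), "iou": iou(c), "precision": precision(c),
           "recall": recall(c), "tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn}
    if surfaces:
        p, t = _grid(pred), _grid(truth)
        if roi is not None:
            p, t = p[roi], t[roi]
        if p.any() and t.any():
            hd, msd = surface_distances(p, t, spacing_mm)
            out["hausdorff_mm"], out["msd_mm"] = hd, msd
    return out
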