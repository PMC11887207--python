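"""Vessel-centred patch extraction.

Every centerline point yields 32x32-pixel HU patches at 0.25 mm/pixel (an
8 x 8 mm field of view) centred on the point.  Two families exist:

* triaxial -- the three orthogonal grid views (axial z-plane, sagittal
  x-plane, coronal y-plane) through the point; and
* perpendicular -- the true vessel cross-section, sampled on a plane normal
  to the local centerline tangent.

Perpendicular in-plane frames are propagated along a branch by parallel
transport so that patch orientation varies smoothly and never flips.
Intensity clipping to the [100, 600] HU band is a separate, explicit step so
callers control when it happens.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import map_coordinates

from .centerline import Branch
from .errors import GeometryError, MarginError, ParameterError
from .volume import CTVolume

__all__ = [
    "Patch",
    "clip_intensities",
    "extract_triaxial_patches",
    "compute_perpendicular_frame",
    "extract_perpendicular_patch",
]

PATCH_SIZE = 32
PIXEL_MM = 0.25
CENTER_PX = (PATCH_SIZE // 2, PATCH_SIZE // 2)


@dataclass
class Patch:
    """A 32x32 HU grid on an oriented plane through a centerline point.

    ``values[i, j]`` sits at world position
    ``plane_origin + (i - 16) * pixel_mm * b1 + (j - 16) * pixel_mm * b2``.
    """

    values: np.ndarray
    plane_origin: np.ndarray          # world mm of the centre pixel
    plane_basis: np.ndarray           # (2, 3) orthonormal in-plane directions
    view_tag: str                     # axial | sagittal | coronal | perpendicular
    source_point: tuple[int, int] = (0, 0)   # (branch_id, point_index)
    pixel_mm: float = PIXEL_MM
    clip_bounds: tuple[float, float] | None = None

    center_px = CENTER_PX

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.plane_origin = np.asarray(self.plane_origin, dtype=float).reshape(3)
        self.plane_basis = np.asarray(self.plane_basis, dtype=float).reshape(2, 3)
        if self.values.shape != (PATCH_SIZE, PATCH_SIZE):
            raise GeometryError(f"patch must be {PATCH_SIZE}x{PATCH_SIZE}, "
                                f"got {self.values.shape}")
        gram = self.plane_basis @ self.plane_basis.T
        if not np.allclose(gram, np.eye(2), atol=1e-9):
            raise GeometryError("plane basis is not orthonormal")

    def pixel_world(self) -> np.ndarray:
        """(32, 32, 3) world-mm coordinates of every pixel centre."""
        idx = np.arange(PATCH_SIZE) - CENTER_PX[0]
        di, dj = np.meshgrid(idx, idx, indexing="ij")
        return (self.plane_origin
                + di[..., None] * self.pixel_mm * self.plane_basis[0]
                + dj[..., None] * self.pixel_mm * self.plane_basis[1])


def clip_intensities(patch: Patch, hu_low: float = 100.0,
                     hu_high: float = 600.0) -> Patch:
    """Clamp patch HU to [hu_low, hu_high]; geometry unchanged.

    Clipping suppresses intensity variability outside the vessel band so the
    clustering stage does not spend clusters on irrelevant structures.
    """
    if hu_low >= hu_high:
        raise ParameterError(f"hu_low must be < hu_high, got ({hu_low}, {hu_high})")
    return replace(patch, values=np.clip(patch.values, hu_low, hu_high),
                   clip_bounds=(hu_low, hu_high))


def _sample_plane(vol: CTVolume, origin: np.ndarray, basis: np.ndarray,
                  pixel_mm: float) -> np.ndarray:
    idx = np.arange(PATCH_SIZE) - CENTER_PX[0]
    di, dj = np.meshgrid(idx, idx, indexing="ij")
    world = (origin
             + di[..., None] * pixel_mm * basis[0]
             + dj[..., None] * pixel_mm * basis[1])
    coords = (world - vol.origin) / vol.spacing        # continuous voxel index
    lo = coords.min(axis=(0, 1))
    hi = coords.max(axis=(0, 1))
    if np.any(lo < -1e-6) or np.any(hi > np.array(vol.shape) - 1 + 1e-6):
        raise MarginError(
            f"patch at {origin} extends beyond the volume (index range "
            f"{lo.round(2)}..{hi.round(2)} vs shape {vol.shape})")
    return map_coordinates(vol.voxels, coords.transpose(2, 0, 1),
                           order=1, mode="nearest")


_TRIAXIAL_FRAMES = {
    "axial": np.array([[1.0, 0, 0], [0, 1.0, 0]]),     # z = const plane
    "sagittal": np.array([[0, 1.0, 0], [0, 0, 1.0]]),  # x = const plane
    "coronal": np.array([[1.0, 0, 0], [0, 0, 1.0]]),   # y = const plane
}


def extract_triaxial_patches(vol: CTVolume, point: np.ndarray,
                             source_point: tuple[int, int] = (0, 0),
                             pixel_mm: float = PIXEL_MM) -> dict[str, Patch]:
    """The axial, sagittal and coronal 32x32 views through a point.

    Returns a dict keyed by view tag.  Raises :class:`MarginError` if the
    8 mm field of view of any plane leaves the volume.
    """
    point = np.asarray(point, dtype=float)
    return {
        tag: Patch(_sample_plane(vol, point, basis, pixel_mm), point, basis,
                   tag, source_point, pixel_mm)
        for tag, basis in _TRIAXIAL_FRAMES.items()
    }


def compute_perpendicular_frame(branch: Branch) -> np.ndarray:
    """Per-point orthonormal in-plane frames normal to the branch tangent.

    Returns an (n, 2, 3) array.  The first frame picks the world axis least
    aligned with the tangent and projects it into the normal plane; subsequent
    frames are carried along by parallel transport (rotation by the minimal
    rotation mapping one tangent onto the next), which keeps consecutive
    frames within a few degrees of each other and avoids orientation flips.
    """
    tangents = np.asarray(branch.tangents, dtype=float)
    norms = np.linalg.norm(tangents, axis=1)
    if np.any(norms < 1e-12):
        raise GeometryError("zero-length tangent")
    tangents = tangents / norms[:, None]

    frames = np.empty((len(tangents), 2, 3))
    t0 = tangents[0]
    seed_axis = np.eye(3)[np.argmin(np.abs(t0))]
    b1 = seed_axis - (seed_axis @ t0) * t0
    b1 /= np.linalg.norm(b1)
    frames[0] = (b1, np.cross(t0, b1))

    for i in range(1, len(tangents)):
        t_prev, t_cur = tangents[i - 1], tangents[i]
        axis = np.cross(t_prev, t_cur)
        sin_a = np.linalg.norm(axis)
        b1 = frames[i - 1, 0]
        if sin_a > 1e-12:
            axis = axis / sin_a
            cos_a = float(np.clip(t_prev @ t_cur, -1.0, 1.0))
            # Rodrigues rotation of the previous first basis vector
            b1 = (b1 * cos_a + np.cross(axis, b1) * sin_a
                  + axis * (axis @ b1) * (1 - cos_a))
        b1 = b1 - (b1 @ t_cur) * t_cur
        b1 /= np.linalg.norm(b1)
        frames[i] = (b1, np.cross(t_cur, b1))
    return frames


def extract_perpendicular_patch(vol: CTVolume, point: np.ndarray,
                                basis: np.ndarray,
                                source_point: tuple[int, int] = (0, 0),
                                pixel_mm: float = PIXEL_MM) -> Patch:
    """The 32x32 cross-sectional patch on the plane spanned by ``basis``."""
    point = np.asarray(point, dtype=float)
    basis = np.asarray(basis, dtype=float).reshape(2, 3)
    return Patch(_sample_plane(vol, point, basis, pixel_mm), point, basis,
                 "perpendicular", source_point, pixel_mm)
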