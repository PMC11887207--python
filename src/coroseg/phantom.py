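"""Synthetic vascular phantoms with analytic ground truth.

The generator emulates the image regimes a contrast-enhanced coronary CT
presents to the pipeline: contrast-filled lumen (~400 HU) embedded in soft
tissue (~30 HU), myocardium (~100 HU) and fat (~-100 HU) inclusions,
calcified plaque (>700 HU), local stenoses, bifurcations, parallel touching
vessels (the kissing-vessel artifact) and additive Gaussian noise.  Voxels
are assigned by exact membership of their centre (a voxel centre within the
local tube radius is lumen), so the ground-truth mask is analytic and
noise-independent.

Tube axes in the presets are deliberately placed off voxel centres: clinical
centerlines never align with the scanner grid, and grid-aligned axes are a
degenerate case that removes all partial-volume structure from extracted
patches.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .centerline import Branch, Centerline, resample_centerline
from .errors import GeometryError, ParameterError
from .segmentation import SegmentationMask
from .volume import CTVolume

__all__ = [
    "Tube",
    "Blob",
    "PhantomSpec",
    "make_phantom",
    "add_stenosis",
    "add_kissing_vessel",
    "preset_tube",
    "preset_stenosis",
    "preset_kissing",
    "preset_bifurcation",
    "PRESETS",
]


@dataclass
class Tube:
    """A tubular structure along a polyline axis with a per-point radius."""

    branch_id: int
    points: np.ndarray            # (n, 3) axis polyline, world mm
    radii_mm: np.ndarray          # (n,) strictly positive
    hu: float = 400.0
    parent_id: int | None = None
    in_truth: bool = True         # excluded for kissing vessels

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.radii_mm = np.broadcast_to(
            np.asarray(self.radii_mm, dtype=float), (len(self.points),)).copy()
        if np.any(self.radii_mm <= 0):
            raise ParameterError("tube radius profile must be strictly positive")

    def arclengths(self) -> np.ndarray:
        steps = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(steps)])


@dataclass
class Blob:
    """A sphere of uniform HU (tissue inclusion or calcium)."""

    center_mm: np.ndarray
    radius_mm: float
    hu: float

    def __post_init__(self) -> None:
        self.center_mm = np.asarray(self.center_mm, dtype=float).reshape(3)
        if self.radius_mm <= 0:
            raise ParameterError("blob radius must be positive")


@dataclass
class PhantomSpec:
    shape: tuple[int, int, int] = (72, 64, 96)
    spacing_mm: float = 0.25
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    background_hu: float = 30.0
    tubes: list[Tube] = field(default_factory=list)
    inclusions: list[Blob] = field(default_factory=list)   # fat, myocardium
    calcium: list[Blob] = field(default_factory=list)      # hu > 600
    noise_sigma_hu: float = 20.0
    seed: int = 0


def _voxel_axes(spec: PhantomSpec):
    return [spec.origin_mm[d] + np.arange(spec.shape[d]) * spec.spacing_mm
            for d in range(3)]


def _blob_membership(spec: PhantomSpec, blob: Blob) -> np.ndarray:
    ax = _voxel_axes(spec)
    dx = ax[0][:, None, None] - blob.center_mm[0]
    dy = ax[1][None, :, None] - blob.center_mm[1]
    dz = ax[2][None, None, :] - blob.center_mm[2]
    return dx * dx + dy * dy + dz * dz <= blob.radius_mm ** 2


def tube_membership(spec: PhantomSpec, tube: Tube) -> np.ndarray:
    """Exact voxel-centre membership of a tube.

    A voxel belongs to the tube when its centre lies within the local radius
    of the axis *polyline* (point-to-segment distance), so tube ends are
    rounded like a capsule rather than cut flat.
    """
    member = np.zeros(spec.shape, dtype=bool)
    pts, radii = tube.points, tube.radii_mm
    spacing, origin = spec.spacing_mm, np.asarray(spec.origin_mm)
    shape = np.array(spec.shape)
    low, high = origin, origin + (shape - 1) * spacing
    rmax = float(radii.max())
    if np.any(pts - radii[:, None] < low - spacing / 2) or \
            np.any(pts + radii[:, None] > high + spacing / 2):
        raise GeometryError(f"tube {tube.branch_id} exits the volume bounds")
    for k in range(len(pts) - 1):
        p, q = pts[k], pts[k + 1]
        rp, rq = radii[k], radii[k + 1]
        lo = np.maximum(np.ceil((np.minimum(p, q) - rmax - origin) / spacing),
                        0).astype(int)
        hi = np.minimum(np.floor((np.maximum(p, q) + rmax - origin) / spacing),
                        shape - 1).astype(int)
        if np.any(hi < lo):
            continue
        ax = [origin[d] + np.arange(lo[d], hi[d] + 1) * spacing for d in range(3)]
        gx, gy, gz = np.meshgrid(*ax, indexing="ij")
        seg = q - p
        seg_len2 = float(seg @ seg)
        if seg_len2 == 0:
            t = np.zeros_like(gx)
        else:
            t = ((gx - p[0]) * seg[0] + (gy - p[1]) * seg[1]
                 + (gz - p[2]) * seg[2]) / seg_len2
            t = np.clip(t, 0.0, 1.0)
        cx, cy, cz = p[0] + t * seg[0], p[1] + t * seg[1], p[2] + t * seg[2]
        d2 = (gx - cx) ** 2 + (gy - cy) ** 2 + (gz - cz) ** 2
        r = rp + t * (rq - rp)
        box = (slice(lo[0], hi[0] + 1), slice(lo[1], hi[1] + 1),
               slice(lo[2], hi[2] + 1))
        member[box] |= d2 <= r ** 2
    return member


def make_phantom(spec: PhantomSpec
                 ) -> tuple[CTVolume, SegmentationMask, Centerline]:
    """Render a spec into (noisy HU volume, ground-truth lumen mask, centerline).

    Paint order: background, tissue inclusions, tubes, calcium; noise last.
    The truth mask is the union of in-truth tube memberships minus calcium,
    and is independent of the noise.  The centerline is the analytic axes of
    the in-truth tubes, resampled to 0.25 mm.
    """
    vol = np.full(spec.shape, spec.background_hu, dtype=float)
    for blob in spec.inclusions:
        vol[_blob_membership(spec, blob)] = blob.hu

    truth = np.zeros(spec.shape, dtype=bool)
    for tube in spec.tubes:
        member = tube_membership(spec, tube)
        vol[member] = tube.hu
        if tube.in_truth:
            truth |= member
    for blob in spec.calcium:
        member = _blob_membership(spec, blob)
        vol[member] = blob.hu
        truth &= ~member

    if spec.noise_sigma_hu > 0:
        rng = np.random.default_rng(spec.seed)
        vol += rng.normal(0.0, spec.noise_sigma_hu, size=spec.shape)

    ct = CTVolume(vol, np.full(3, spec.spacing_mm), np.asarray(spec.origin_mm))
    branches = [Branch(t.branch_id, t.parent_id, t.points)
                for t in spec.tubes if t.in_truth]
    cl = resample_centerline(Centerline(branches), spec.spacing_mm)
    return ct, SegmentationMask(truth, {"phantom": True}), cl


def add_stenosis(spec: PhantomSpec, branch_id: int, position_mm: float,
                 severity: float, length_mm: float = 6.0) -> PhantomSpec:
    """Multiply a branch's radius profile by a smooth cosine-squared notch
    reaching ``1 - severity`` at ``position_mm`` along the branch."""
    if not 0 < severity < 1:
        raise ParameterError(f"severity must be in (0, 1), got {severity}")
    tubes = []
    found = False
    for tube in spec.tubes:
        if tube.branch_id != branch_id:
            tubes.append(tube)
            continue
        found = True
        s = tube.arclengths()
        if not 0 <= position_mm <= s[-1]:
            raise ParameterError(
                f"position {position_mm} mm outside branch of length {s[-1]:.2f}")
        u = s - position_mm
        notch = np.ones_like(s)
        inside = np.abs(u) <= length_mm / 2
        notch[inside] = 1 - severity * np.cos(np.pi * u[inside] / length_mm) ** 2
        tubes.append(replace(tube, radii_mm=tube.radii_mm * notch))
    if not found:
        raise ParameterError(f"no tube with branch_id {branch_id}")
    return replace(spec, tubes=tubes)


def add_kissing_vessel(spec: PhantomSpec, branch_id: int,
                       gap_mm: float = 0.0) -> PhantomSpec:
    """Add a parallel tube of equal HU at surface separation ``gap_mm`` from
    the named branch (0 = touching).  The new tube is excluded from the truth
    mask and from the centerline."""
    if gap_mm < 0:
        raise ParameterError("gap_mm must be >= 0 (tubes may not overlap)")
    primary = next((t for t in spec.tubes if t.branch_id == branch_id), None)
    if primary is None:
        raise ParameterError(f"no tube with branch_id {branch_id}")
    tangent = primary.points[-1] - primary.points[0]
    tangent /= np.linalg.norm(tangent)
    normal = np.eye(3)[np.argmin(np.abs(tangent))]
    normal = normal - (normal @ tangent) * tangent
    normal /= np.linalg.norm(normal)
    r_b = float(np.median(primary.radii_mm))
    offsets = (primary.radii_mm + r_b + gap_mm)[:, None] * normal
    new_id = max(t.branch_id for t in spec.tubes) + 1
    twin = Tube(new_id, primary.points + offsets, np.full(len(primary.points), r_b),
                hu=primary.hu, parent_id=None, in_truth=False)
    return replace(spec, tubes=spec.tubes + [twin])


# ---------------------------------------------------------------------------
# Presets: the study conditions used by the test-bench and the CLI simulator.
# A 72 x 64 x 96 grid at 0.25 mm (18 x 16 x 24 mm) holds a 15 mm tube of
# radius 1.5 mm with enough margin for the 8 mm patch field of view.
# ---------------------------------------------------------------------------

_AXIS_XY = (8.06, 8.11)     # deliberately off the voxel grid
_Z_RANGE = (4.25, 19.25)


def _base_tube(radius_mm: float = 1.5, lumen_hu: float = 400.0) -> Tube:
    z = np.array(_Z_RANGE)
    pts = np.column_stack([np.full(2, _AXIS_XY[0]), np.full(2, _AXIS_XY[1]), z])
    # densify so radius profiles (stenoses) can vary along the axis
    n = int(round((z[1] - z[0]) / 0.25)) + 1
    dense = np.column_stack([np.full(n, _AXIS_XY[0]), np.full(n, _AXIS_XY[1]),
                             np.linspace(z[0], z[1], n)])
    return Tube(1, dense, np.full(n, radius_mm), hu=lumen_hu)


def _base_spec(seed: int = 0, noise_sigma_hu: float = 20.0) -> PhantomSpec:
    return PhantomSpec(
        tubes=[_base_tube()],
        inclusions=[Blob((3.6, 3.4, 12.0), 2.5, 100.0),    # myocardium
                    Blob((14.3, 12.6, 8.0), 2.0, -100.0)], # fat
        noise_sigma_hu=noise_sigma_hu,
        seed=seed,
    )


def preset_tube(seed: int = 0, noise_sigma_hu: float = 20.0) -> PhantomSpec:
    """A clean straight tube: lumen 400 HU, background 30 HU, r = 1.5 mm."""
    return _base_spec(seed, noise_sigma_hu)


def preset_stenosis(seed: int = 0, severity: float = 0.5,
                    noise_sigma_hu: float = 20.0) -> PhantomSpec:
    """The straight tube with a smooth mid-branch stenosis (default 50%)."""
    spec = _base_spec(seed, noise_sigma_hu)
    mid = float(spec.tubes[0].arclengths()[-1]) / 2
    return add_stenosis(spec, 1, mid, severity, length_mm=6.0)


def preset_kissing(seed: int = 0, gap_mm: float = 0.0,
                   noise_sigma_hu: float = 20.0) -> PhantomSpec:
    """The straight tube with a touching parallel twin of equal brightness."""
    return add_kissing_vessel(_base_spec(seed, noise_sigma_hu), 1, gap_mm)


def preset_bifurcation(seed: int = 0, noise_sigma_hu: float = 20.0) -> PhantomSpec:
    """The straight tube with a thinner child branch leaving at ~35 degrees."""
    spec = _base_spec(seed, noise_sigma_hu)
    parent = spec.tubes[0]
    s = parent.arclengths()
    i0 = int(np.searchsorted(s, s[-1] / 2))
    start = parent.points[i0]
    direction = np.array([np.sin(np.deg2rad(35)), 0.0, np.cos(np.deg2rad(35))])
    length = 6.0
    n = int(round(length / 0.25)) + 1
    pts = start + np.linspace(0, length, n)[:, None] * direction
    child = Tube(2, pts, np.full(n, 1.1), hu=parent.hu, parent_id=1)
    return replace(spec, tubes=spec.tubes + [child])


PRESETS = {
    "tube": preset_tube,
    "stenosis": preset_stenosis,
    "kissing": preset_kissing,
    "bifurcation": preset_bifurcation,
}
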