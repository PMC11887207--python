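"""CT volume container and IO.

Coordinate contract used throughout the package
-----------------------------------------------
Voxel arrays are indexed ``voxels[i, j, k]`` where the three indices map to
world axes (x, y, z).  Voxel indices are 0-based and the world position of a
voxel centre is ``origin + index * spacing`` (right-handed, axis-aligned; no
oblique direction matrices).  All geometry downstream -- patch planes, painting
spheres and brushes, phantom tubes -- is computed in world millimetres under
this convention.

Volumes are stored in Hounsfield Units (HU).  Readers apply only the format's
own slope/intercept (handled by SimpleITK); no further rescaling is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .errors import FormatError, GeometryError, MetadataError, ParameterError

__all__ = [
    "CTVolume",
    "read_volume",
    "write_volume",
    "write_mask",
    "resample_isotropic",
]

_SUPPORTED_SUFFIXES = (".nii", ".nii.gz", ".nrrd")


@dataclass
class CTVolume:
    """A 3D scalar grid of HU with spacing/origin metadata.

    Attributes
    ----------
    voxels : ndarray, shape (nx, ny, nz)
        Scalar HU values, index order (x, y, z).
    spacing : ndarray, shape (3,)
        Per-axis voxel size in mm; strictly positive.
    origin : ndarray, shape (3,)
        World-mm position of voxel (0, 0, 0).
    """

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        self.spacing = np.asarray(self.spacing, dtype=np.float64).reshape(3)
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        if self.voxels.ndim != 3:
            raise GeometryError(f"expected a 3D volume, got ndim={self.voxels.ndim}")
        if not np.all(self.spacing > 0):
            raise ParameterError(f"spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise GeometryError("volume contains non-finite voxel values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def world_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """(low, high) world-mm coordinates of the first and last voxel centres."""
        high = self.origin + (np.array(self.shape) - 1) * self.spacing
        return self.origin.copy(), high

    def index_of(self, world: np.ndarray) -> np.ndarray:
        """Continuous voxel index of a world-mm position."""
        return (np.asarray(world, dtype=float) - self.origin) / self.spacing

    def is_isotropic(self, target_mm: float, atol: float = 1e-6) -> bool:
        return bool(np.allclose(self.spacing, target_mm, atol=atol))


def _check_suffix(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(s) for s in _SUPPORTED_SUFFIXES):
        raise FormatError(f"unsupported volume format: {path.name} "
                          f"(expected one of {_SUPPORTED_SUFFIXES})")


def _from_sitk(img: sitk.Image) -> CTVolume:
    if img.GetDimension() != 3:
        raise FormatError(f"expected a 3D image, got {img.GetDimension()}D")
    direction = np.array(img.GetDirection()).reshape(3, 3)
    if not np.allclose(direction, np.eye(3), atol=1e-6):
        raise MetadataError(
            "only axis-aligned (identity direction) volumes are supported; "
            f"got direction matrix {direction.tolist()}")
    # sitk arrays come back as [z, y, x]; transpose to the (x, y, z) contract.
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return CTVolume(arr, np.array(img.GetSpacing()), np.array(img.GetOrigin()))


def _to_sitk(vol: CTVolume, dtype=None) -> sitk.Image:
    arr = vol.voxels if dtype is None else vol.voxels.astype(dtype)
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in vol.spacing))
    img.SetOrigin(tuple(float(o) for o in vol.origin))
    return img


def read_volume(path: str | Path) -> CTVolume:
    """Read a NIfTI (.nii/.nii.gz) or NRRD (.nrrd) volume as HU."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    _check_suffix(path)
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # sitk raises RuntimeError on unreadable files
        raise FormatError(f"could not read {path}: {exc}") from exc
    return _from_sitk(img)


def write_volume(vol: CTVolume, path: str | Path) -> None:
    """Write a volume to NIfTI or NRRD (format chosen by suffix)."""
    path = Path(path)
    _check_suffix(path)
    sitk.WriteImage(_to_sitk(vol), str(path))


def write_mask(mask, ref: CTVolume, path: str | Path) -> None:
    """Write a binary mask with metadata copied from a reference volume.

    ``mask`` may be a bool/int ndarray or any object exposing a ``grid``
    attribute (a :class:`~coroseg.segmentation.SegmentationMask`).
    """
    grid = np.asarray(getattr(mask, "grid", mask))
    if grid.shape != ref.shape:
        raise GeometryError(
            f"mask shape {grid.shape} does not match reference {ref.shape}")
    out = CTVolume(grid.astype(np.uint8), ref.spacing, ref.origin)
    path = Path(path)
    _check_suffix(path)
    sitk.WriteImage(_to_sitk(out, dtype=np.uint8), str(path))


def resample_isotropic(vol: CTVolume, target_mm: float = 0.25) -> CTVolume:
    """Resample a volume to an isotropic grid by trilinear interpolation.

    The output grid starts at the same origin; its size is chosen so that the
    last voxel centre stays inside the source extent (world extent preserved
    within one voxel).  Already-compliant volumes are returned unchanged.
    """
    if target_mm <= 0:
        raise ParameterError(f"target_mm must be positive, got {target_mm}")
    if vol.is_isotropic(target_mm):
        return vol
    old_n = np.array(vol.shape)
    new_n = np.floor((old_n - 1) * vol.spacing / target_mm + 1e-9).astype(int) + 1
    img = _to_sitk(vol)
    out = sitk.Resample(
        img,
        [int(n) for n in new_n],
        sitk.Transform(),
        sitk.sitkLinear,
        tuple(float(o) for o in vol.origin),
        (float(target_mm),) * 3,
        img.GetDirection(),
        0.0,
        sitk.sitkFloat64,
    )
    return _from_sitk(out)
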