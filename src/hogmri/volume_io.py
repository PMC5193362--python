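"""NIfTI volume I/O and intensity preprocessing.

Two preprocessing steps are implemented here: subject-level z-scoring
(one global mean/SD per subject, over every voxel and — for 4D scans —
every time point) and temporal averaging of a 4D functional scan down to
a single 3D volume.  Spatial preprocessing (motion correction,
registration, smoothing) is out of scope: volumes are assumed to arrive
already resampled onto a common grid.

Arrays are indexed ``(x, y, z[, t])`` exactly as stored in the file; no
reorientation is applied.  Voxel indices are 0-based and the anatomical
mm coordinate of voxel ``(i, j, k)`` is ``origin_mm + voxel_size_mm * (i, j, k)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from .errors import DegenerateInputError, FormatError, ValidationError

#: Default MNI-space grid: 79 x 95 x 68 voxels of 2 mm, bounding box
#: starting at (-78, -112, -50) mm.
CANONICAL_DIMS = (79, 95, 68)
CANONICAL_VOXEL_MM = (2.0, 2.0, 2.0)
CANONICAL_ORIGIN_MM = (-78.0, -112.0, -50.0)


@dataclass(frozen=True)
class GridGeometry:
    """Sampling grid of a volume: shape, voxel size and mm origin."""

    dims: tuple[int, ...] = CANONICAL_DIMS
    voxel_size_mm: tuple[float, ...] = CANONICAL_VOXEL_MM
    origin_mm: tuple[float, ...] = CANONICAL_ORIGIN_MM

    def voxel_to_mm(self, voxel: np.ndarray | tuple) -> np.ndarray:
        """Anatomical mm coordinate of a (possibly fractional) voxel index."""
        return np.asarray(self.origin_mm) + np.asarray(self.voxel_size_mm) * np.asarray(voxel, dtype=float)


def _check_finite(arr: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{what} contains non-finite intensities")


@dataclass
class Volume3D:
    """A 3D intensity volume ``f(x, y, z)`` with its grid geometry."""

    intensities: np.ndarray
    voxel_size_mm: tuple[float, float, float] = CANONICAL_VOXEL_MM
    origin_mm: tuple[float, float, float] = CANONICAL_ORIGIN_MM

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3:
            raise ValidationError(f"Volume3D needs a 3-axis array, got {self.intensities.ndim} axes")
        _check_finite(self.intensities, "Volume3D")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.intensities.shape

    @property
    def geometry(self) -> GridGeometry:
        return GridGeometry(self.dims, tuple(self.voxel_size_mm), tuple(self.origin_mm))


@dataclass
class Scan4D:
    """A 4D functional scan ``f(x, y, z, t)`` with ``k`` time points."""

    intensities: np.ndarray
    voxel_size_mm: tuple[float, float, float] = CANONICAL_VOXEL_MM
    origin_mm: tuple[float, float, float] = CANONICAL_ORIGIN_MM

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 4:
            raise ValidationError(f"Scan4D needs a 4-axis array, got {self.intensities.ndim} axes")
        if self.intensities.shape[3] < 1:
            raise ValidationError("Scan4D needs at least one time point")
        _check_finite(self.intensities, "Scan4D")

    @property
    def dims(self) -> tuple[int, int, int, int]:
        return self.intensities.shape

    @property
    def k(self) -> int:
        """Number of time points."""
        return self.intensities.shape[3]


def _affine(voxel_size_mm, origin_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(voxel_size_mm)
    aff[:3, 3] = origin_mm
    return aff


def read_volume(path) -> Volume3D | Scan4D:
    """Read a NIfTI-1 file into a :class:`Volume3D` (3D) or :class:`Scan4D` (4D).

    Voxel size is taken from the header zooms and the origin from the
    affine translation; the data array is used in its stored (x, y, z[, t])
    order without reorientation.
    """
    try:
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata(), dtype=float)
    except Exception as exc:  # nibabel raises a mix of its own and OS errors
        raise FormatError(f"cannot read NIfTI file {path!r}: {exc}") from exc
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(o) for o in img.affine[:3, 3])
    if data.ndim == 3:
        return Volume3D(data, zooms, origin)
    if data.ndim == 4:
        return Scan4D(data, zooms, origin)
    raise FormatError(f"{path!r}: expected 3 or 4 axes, found {data.ndim}")


def write_volume(vol: Volume3D | Scan4D, path) -> None:
    """Write a volume or scan as NIfTI-1 (.nii or .nii.gz by extension)."""
    img = nib.Nifti1Image(vol.intensities, _affine(vol.voxel_size_mm, vol.origin_mm))
    img.header.set_zooms(tuple(vol.voxel_size_mm) + ((1.0,) if vol.intensities.ndim == 4 else ()))
    nib.save(img, str(path))


def time_average(scan: Scan4D) -> Volume3D:
    """Average a 4D scan over time: ``f(x,y,z) = (1/k) sum_t f(x,y,z,t)``."""
    return Volume3D(scan.intensities.mean(axis=3), scan.voxel_size_mm, scan.origin_mm)


def znormalize(vol: Volume3D | Scan4D):
    """Replace every intensity by its subject-level z-score.

    One global mean and standard deviation are computed over *all*
    entries of the image (all voxels, and all time points for a 4D
    scan), then subtracted/divided.  A constant image has no meaningful
    z-score and is rejected.
    """
    data = vol.intensities
    mu = data.mean()
    sd = data.std()
    # constant images have sd 0 up to accumulation round-off
    if sd <= 1e-12 * max(1.0, abs(mu)):
        raise DegenerateInputError("cannot z-score a constant image (zero variance)")
    return type(vol)((data - mu) / sd, vol.voxel_size_mm, vol.origin_mm)
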