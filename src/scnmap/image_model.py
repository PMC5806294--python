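"""Volume image abstraction for voxel-based morphometry inputs.

A :class:`VolumeImage` pairs a 3-D scalar field (modulated gray-matter
density, dimensionless volume fraction) with a 4x4 affine mapping 0-based
voxel indices to world (MNI-style) millimetre coordinates, following the
NIfTI-1 convention.  This module provides NIfTI I/O, world<->voxel
coordinate transforms, Gaussian smoothing parameterised by FWHM, and the
global volume summaries (total intracranial volume, cluster volume) used
downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "VolumeImage",
    "read_volume",
    "write_volume",
    "voxel_to_world",
    "world_to_voxel",
    "fwhm_to_sigma",
    "gaussian_smooth",
    "compute_tiv",
    "cluster_volume_mm3",
]

#: FWHM of a Gaussian equals sigma * 2*sqrt(2*ln 2)
_FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class VolumeImage:
    """A single 3-D scalar volume with its voxel-to-world affine.

    Parameters
    ----------
    data
        3-D array of voxel values (gray-matter density / modulated volume
        fraction). Must be finite.
    affine
        4x4 invertible matrix mapping homogeneous 0-based voxel indices to
        world coordinates in mm (RAS-oriented, as stored).
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(
                f"expected a 3-D volume, got shape {self.data.shape}"
            )
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine is singular")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_dims_mm(self) -> np.ndarray:
        """Per-axis voxel edge lengths in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        """Volume of one voxel, |det| of the spatial affine block."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))


def read_volume(path: str | Path) -> VolumeImage:
    """Load a single 3-D NIfTI-1 volume.

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    ValueError
        If the file holds anything other than a single 3-D volume (the
        offending shape is named in the message), or is not NIfTI.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    try:
        img = nib.load(str(path))
    except nib.filebasedimages.ImageFileError as exc:
        raise ValueError(f"not a readable NIfTI file: {path}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(
            f"{path} has shape {data.shape}; expected a single 3-D volume"
        )
    return VolumeImage(data=np.asarray(data, dtype=float), affine=img.affine)


def write_volume(image: VolumeImage, path: str | Path) -> None:
    """Write *image* as NIfTI-1; round-trips data (float64) and affine."""
    nii = nib.Nifti1Image(image.data.astype(np.float64), image.affine)
    nib.save(nii, str(path))


def voxel_to_world(image: VolumeImage, ijk: Sequence[float]) -> np.ndarray:
    """Map a voxel index to world mm coordinates via the affine."""
    ijk = np.asarray(ijk, dtype=float)
    return image.affine[:3, :3] @ ijk + image.affine[:3, 3]


def _round_half_away(x: np.ndarray) -> np.ndarray:
    # symmetric rounding: .5 always rounds away from zero
    return np.trunc(x + np.copysign(0.5, x))


def world_to_voxel(image: VolumeImage, xyz: Sequence[float]) -> tuple[int, int, int]:
    """Map world mm coordinates to the nearest 0-based voxel index.

    Applies the inverse affine then rounds half-away-from-zero, making the
    mapping the exact inverse of :func:`voxel_to_world` on lattice points.

    Raises
    ------
    ValueError
        If the rounded index falls outside the image grid; the offending
        world coordinate is named.
    """
    xyz = np.asarray(xyz, dtype=float)
    ijk = np.linalg.solve(image.affine[:3, :3], xyz - image.affine[:3, 3])
    idx = _round_half_away(ijk).astype(int)
    if np.any(idx < 0) or np.any(idx >= np.asarray(image.shape)):
        raise ValueError(
            f"world coordinate {tuple(xyz)} maps to voxel {tuple(idx)} "
            f"outside grid {image.shape}"
        )
    return tuple(int(v) for v in idx)  # type: ignore[return-value]


def fwhm_to_sigma(fwhm_mm: float) -> float:
    """Convert Gaussian full-width-at-half-maximum to sigma (both in mm)."""
    if fwhm_mm < 0:
        raise ValueError("FWHM must be non-negative")
    return fwhm_mm / _FWHM_PER_SIGMA


def gaussian_smooth(image: VolumeImage, fwhm_mm: float) -> VolumeImage:
    """Smooth with an isotropic-in-mm Gaussian kernel of the given FWHM.

    Sigma is converted to voxel units per axis, so anisotropic voxels are
    handled correctly.  Boundaries use reflection, which preserves total
    mass (and hence the image mean) on small grids.  ``fwhm_mm == 0`` is
    the identity.
    """
    sigma_mm = fwhm_to_sigma(float(fwhm_mm))
    if sigma_mm == 0.0:
        return VolumeImage(image.data.copy(), image.affine.copy())
    sigma_vox = sigma_mm / image.voxel_dims_mm
    smoothed = ndi.gaussian_filter(image.data, sigma=sigma_vox, mode="reflect")
    return VolumeImage(smoothed, image.affine.copy())


def compute_tiv(segment_images: Sequence[VolumeImage]) -> float:
    """Total intracranial volume in mm^3 from aligned tissue-fraction maps.

    Sums tissue fractions over all supplied maps and multiplies by the
    voxel volume. With a single modulated map this is simply its integral.
    """
    if len(segment_images) == 0:
        raise ValueError("need at least one tissue map")
    ref = segment_images[0]
    total = 0.0
    for seg in segment_images:
        if seg.shape != ref.shape:
            raise ValueError(
                f"tissue map shape {seg.shape} does not match {ref.shape}"
            )
        total += float(seg.data.sum())
    return total * ref.voxel_volume_mm3


def cluster_volume_mm3(n_voxels: int, voxel_dims_mm: Sequence[float]) -> float:
    """Volume of *n_voxels* voxels, e.g. 100 voxels at 1.5 mm -> 337.5 mm^3."""
    if n_voxels < 0:
        raise ValueError("voxel count must be non-negative")
    return float(n_voxels) * float(np.prod(np.asarray(voxel_dims_mm, dtype=float)))
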