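"""Voxel grid geometry and NIfTI-1 I/O.

The analysis grid is a regular 3D lattice with isotropic-or-not voxel
sizes and an origin at the grid centre.  Internally volumes are stored in
RAS+ world coordinates (the NIfTI convention); reported coordinates use
the RAI sign convention common in AFNI outputs, in which negative x, y, z
denote subject right, anterior and inferior respectively.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np

__all__ = ["GridSpec", "save_nifti", "load_nifti"]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the analysis grid.

    Parameters
    ----------
    shape
        Number of voxels along x, y, z.  All dimensions must be >= 8.
    voxel_size
        Voxel edge lengths in mm per axis, all > 0.
    """

    shape: tuple[int, int, int] = (24, 28, 24)
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or len(self.voxel_size) != 3:
            raise ValueError("GridSpec is three-dimensional")
        if any(int(n) < 8 for n in self.shape):
            raise ValueError(f"all grid dimensions must be >= 8, got {self.shape}")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel sizes must be positive, got {self.voxel_size}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))

    @property
    def affine(self) -> np.ndarray:
        """RAS+ affine with the world origin at the grid centre."""
        aff = np.eye(4)
        for k in range(3):
            aff[k, k] = self.voxel_size[k]
            aff[k, 3] = -self.voxel_size[k] * (self.shape[k] - 1) / 2.0
        return aff

    def ras_from_index(self, ijk: np.ndarray) -> np.ndarray:
        """Map voxel indices (..., 3) to RAS+ mm coordinates."""
        ijk = np.asarray(ijk, dtype=float)
        aff = self.affine
        return ijk * np.diag(aff)[:3] + aff[:3, 3]

    def rai_from_index(self, ijk: np.ndarray) -> np.ndarray:
        """Map voxel indices to RAI mm (negative x/y/z = right/anterior/inferior)."""
        ras = self.ras_from_index(ijk)
        rai = ras.copy()
        rai[..., 0] *= -1.0
        rai[..., 1] *= -1.0
        return rai

    def brain_mask(self, fill: float = 0.96) -> np.ndarray:
        """Default ellipsoidal brain mask inscribed in the grid.

        ``fill`` scales the semi-axes relative to half the grid extent.
        """
        idx = np.indices(self.shape, dtype=float)
        centre = (np.asarray(self.shape, dtype=float) - 1) / 2.0
        semi = fill * np.asarray(self.shape, dtype=float) / 2.0
        r2 = sum(((idx[k] - centre[k]) / semi[k]) ** 2 for k in range(3))
        return r2 <= 1.0


def save_nifti(data: np.ndarray, grid: GridSpec, path) -> None:
    """Write a 3D or 4D volume on ``grid`` as NIfTI-1 (float64, lossless)."""
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), grid.affine)
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def load_nifti(path) -> tuple[np.ndarray, GridSpec]:
    """Read a NIfTI-1 volume and recover its :class:`GridSpec`.

    Only axis-aligned (diagonal-affine) images are supported, which covers
    everything this package writes.
    """
    img = nib.load(str(path))
    aff = img.affine
    if not np.allclose(aff[:3, :3], np.diag(np.diag(aff[:3, :3]))):
        raise ValueError(f"{path}: non-diagonal affine; image is not on an axis-aligned grid")
    shape = img.shape[:3]
    voxel = tuple(float(abs(aff[k, k])) for k in range(3))
    return np.asarray(img.dataobj, dtype=np.float64), GridSpec(tuple(shape), voxel)
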