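"""Minimal 3-D image container used across the pipeline.

Every volume carries its voxel-to-mm affine so that geometric operations
(Hessian scales, sphere ROIs, component moments) can be expressed in
millimetres regardless of grid resolution.  I/O goes through nibabel and
preserves the affine bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["ImageVolume"]


@dataclass
class ImageVolume:
    """A 3-D scalar grid plus a 4x4 voxel-to-mm affine.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar values (intensity, vesselness, or a binary mask).
    affine : ndarray, shape (4, 4)
        Homogeneous voxel-index -> mm coordinate map.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D volume, got shape {self.data.shape}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_size(self) -> np.ndarray:
        """Edge lengths of a voxel in mm (norms of the affine columns)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def same_grid(self, other: "ImageVolume", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    def require_same_grid(self, other: "ImageVolume", what: str = "volumes") -> None:
        if not self.same_grid(other):
            raise ValueError(
                f"{what} must share grid and affine: "
                f"{self.shape} vs {other.shape}"
            )

    def copy_with(self, data: np.ndarray) -> "ImageVolume":
        return ImageVolume(data=data, affine=self.affine.copy())

    # --- I/O -------------------------------------------------------------

    def to_nifti(self, path: str | Path) -> None:
        img = nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), self.affine)
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path: str | Path) -> "ImageVolume":
        img = nib.load(str(path))
        return cls(data=np.asanyarray(img.dataobj), affine=np.asarray(img.affine))
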