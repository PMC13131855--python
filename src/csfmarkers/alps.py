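"""DTI-ALPS: diffusivity along the perivascular space.

At the level of the lateral ventricles, medullary vessels and their
perivascular spaces run left-right (the x axis), perpendicular to both the
projection fibers (z-oriented, corona radiata) and the association fibers
(y-oriented, superior longitudinal fasciculus).  The ALPS index is the
ratio of x-axis diffusivity to the diffusivity perpendicular to the fibers,

    ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc),

computed per hemisphere from 5 mm spherical ROIs fixed in 1 mm template
(MNI) space — projection ROIs at (+-25, -20, 28), association ROIs at
(+-39, -20, 28) — and then averaged across hemispheres.  An index near 1
means no preferential perivascular diffusion; healthy white matter is
typically ~1.3-1.8.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TensorField",
    "AlpsROISet",
    "AlpsResult",
    "make_sphere_roi",
    "compute_alps",
    "PROJ_CENTER_MM",
    "ASSOC_CENTER_MM",
    "ROI_DIAMETER_MM",
]

#: Template-space ROI centers (mm); x is mirrored for the left hemisphere.
PROJ_CENTER_MM: tuple[float, float, float] = (25.0, -20.0, 28.0)
ASSOC_CENTER_MM: tuple[float, float, float] = (39.0, -20.0, 28.0)
ROI_DIAMETER_MM: float = 5.0


@dataclass
class TensorField:
    """Diagonal diffusion-tensor element maps on a shared template grid.

    dxx, dyy, dzz are in mm^2/s; off-diagonal elements are not needed by
    the ALPS index and are accepted but ignored by the pipeline.
    """

    dxx: np.ndarray
    dyy: np.ndarray
    dzz: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.dxx = np.asarray(self.dxx, dtype=float)
        self.dyy = np.asarray(self.dyy, dtype=float)
        self.dzz = np.asarray(self.dzz, dtype=float)
        if not (self.dxx.shape == self.dyy.shape == self.dzz.shape):
            raise ValueError("tensor element maps must share one grid")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.dxx.shape  # type: ignore[return-value]


def make_sphere_roi(
    center_mm: tuple[float, float, float],
    diameter_mm: float,
    affine: np.ndarray,
    grid_shape: tuple[int, int, int],
) -> np.ndarray:
    """Voxel indices whose centers lie within a sphere, as an (n, 3) array.

    Membership is by Euclidean distance of the voxel center to the sphere
    center in mm space (no partial volumes).
    """
    if diameter_mm <= 0:
        raise ValueError("diameter must be positive")
    inv = np.linalg.inv(np.asarray(affine, dtype=float))
    c_vox = inv @ np.array([*center_mm, 1.0])
    # search a bounding box around the center in voxel space
    vs = np.linalg.norm(np.asarray(affine, dtype=float)[:3, :3], axis=0)
    half = diameter_mm / 2.0
    lo = np.maximum(np.floor(c_vox[:3] - half / vs - 1), 0).astype(int)
    hi = np.minimum(np.ceil(c_vox[:3] + half / vs + 1), np.array(grid_shape) - 1).astype(int)
    if np.any(lo > hi):
        raise ValueError(f"sphere at {center_mm} mm does not intersect the grid")
    rng = [np.arange(lo[i], hi[i] + 1) for i in range(3)]
    ii, jj, kk = np.meshgrid(*rng, indexing="ij")
    vox = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
    mm = vox @ np.asarray(affine, dtype=float)[:3, :3].T + np.asarray(affine)[:3, 3]
    dist2 = ((mm - np.asarray(center_mm)) ** 2).sum(axis=1)
    inside = vox[dist2 <= half**2]
    if inside.size == 0:
        raise ValueError(f"sphere ROI at {center_mm} mm is empty on this grid")
    return inside


@dataclass
class AlpsROISet:
    """The four spherical ALPS ROIs as (n, 3) voxel-index arrays."""

    proj_left: np.ndarray
    proj_right: np.ndarray
    assoc_left: np.ndarray
    assoc_right: np.ndarray

    @classmethod
    def standard(
        cls, affine: np.ndarray, grid_shape: tuple[int, int, int]
    ) -> "AlpsROISet":
        """ROIs at the template-space coordinates, 5 mm diameter."""
        px, py, pz = PROJ_CENTER_MM
        ax, ay, az = ASSOC_CENTER_MM
        return cls(
            proj_left=make_sphere_roi((-px, py, pz), ROI_DIAMETER_MM, affine, grid_shape),
            proj_right=make_sphere_roi((px, py, pz), ROI_DIAMETER_MM, affine, grid_shape),
            assoc_left=make_sphere_roi((-ax, ay, az), ROI_DIAMETER_MM, affine, grid_shape),
            assoc_right=make_sphere_roi((ax, ay, az), ROI_DIAMETER_MM, affine, grid_shape),
        )


@dataclass
class AlpsResult:
    """Hemispheric and bilateral ALPS indices plus the per-ROI means."""

    left_index: float
    right_index: float
    bilateral_index: float
    roi_means: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "left_index": self.left_index,
            "right_index": self.right_index,
            "bilateral_index": self.bilateral_index,
            "roi_means": dict(self.roi_means),
        }


def _roi_mean(arr: np.ndarray, vox: np.ndarray) -> float:
    return float(arr[vox[:, 0], vox[:, 1], vox[:, 2]].mean())


def compute_alps(field: TensorField, rois: AlpsROISet) -> AlpsResult:
    """ALPS index from tensor-element maps and the four spherical ROIs.

    Per hemisphere: index = mean(Dxx over projection ROI, Dxx over
    association ROI) / mean(Dyy over projection ROI, Dzz over association
    ROI); the bilateral index is the average of the two hemispheres.  The
    index is invariant under global positive scaling of the tensor.
    """
    means = {}
    for hemi, proj, assoc in (
        ("left", rois.proj_left, rois.assoc_left),
        ("right", rois.proj_right, rois.assoc_right),
    ):
        means[f"dxx_proj_{hemi}"] = _roi_mean(field.dxx, proj)
        means[f"dxx_assoc_{hemi}"] = _roi_mean(field.dxx, assoc)
        means[f"dyy_proj_{hemi}"] = _roi_mean(field.dyy, proj)
        means[f"dzz_assoc_{hemi}"] = _roi_mean(field.dzz, assoc)

    indices = {}
    for hemi in ("left", "right"):
        num = 0.5 * (means[f"dxx_proj_{hemi}"] + means[f"dxx_assoc_{hemi}"])
        den = 0.5 * (means[f"dyy_proj_{hemi}"] + means[f"dzz_assoc_{hemi}"])
        if den <= 0:
            raise ValueError(f"non-positive perpendicular diffusivity in {hemi} hemisphere")
        indices[hemi] = num / den

    return AlpsResult(
        left_index=indices["left"],
        right_index=indices["right"],
        bilateral_index=0.5 * (indices["left"] + indices["right"]),
        roi_means=means,
    )
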