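"""Synthetic inputs with known ground truth for every pipeline stage.

Four generators, all bit-reproducible under a fixed seed:

* PVS phantoms — paired T1-like/T2-like volumes containing dark tubular
  inclusions of known count, volume and diameter inside labeled
  white-matter boxes, with optional Gaussian (high-SNR Rician
  approximation) or Rician noise;
* diffusion-tensor element fields with prescribed Dxx/Dyy/Dzz means inside
  the four ALPS ROI spheres, with the analytically expected index;
* two-group cohorts with prescribed group, age, and group-by-age effects
  on a synthetic outcome plus Gaussian residual noise (defaults follow the
  study design these tools target: 49 cases vs 61 controls, ages 30-73);
* flat volumetric stats tables (ventricle/choroid-plexus/eTIV rows).

The phantoms emulate contrast polarity and geometry only — CSF-like tubes
are dark on T1-like and bright on T2-like images, hence dark on the
T1/T2 ratio — not MRI physics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alps import ASSOC_CENTER_MM, PROJ_CENTER_MM, ROI_DIAMETER_MM, AlpsROISet, TensorField, make_sphere_roi
from .atlas import HEMISPHERES, LOBES, RegionAtlas, RegionMask
from .image import ImageVolume

__all__ = [
    "PhantomTruth",
    "CohortSpec",
    "TubePlacementError",
    "generate_pvs_phantom",
    "generate_tensor_field",
    "generate_cohort",
    "generate_volumetric_table",
    "default_phantom_regions",
]

# Phantom intensity conventions (documented defaults, not calibrated MRI):
BACKGROUND_T1 = 1.0
BACKGROUND_T2 = 1.0
TUBE_T1 = 0.5
TUBE_T2 = 2.0


class TubePlacementError(RuntimeError):
    """A tube could not be placed inside its region."""


@dataclass
class PhantomTruth:
    """Ground truth for the tubes rasterized into one region."""

    region_name: str
    true_count: int
    true_volume: float  # mm^3, rasterized voxel volume
    true_mean_diameter: float  # mm, mean of 2r over tubes (NaN if none)
    tube_axes: list[tuple[np.ndarray, np.ndarray, float, float]] = field(
        default_factory=list
    )  # (center mm, unit direction, radius mm, length mm)


@dataclass
class CohortSpec:
    """Design of a simulated two-group cohort.

    The outcome is b0 + beta_group*group + beta_age*age_c +
    beta_interaction*group*age_c + N(0, noise_sd^2), with group coded 0/1
    and ages uniform on ``age_range``.
    """

    n_group1: int = 61  # controls (group 0)
    n_group2: int = 49  # cases (group 1)
    age_range: tuple[float, float] = (30.0, 73.0)
    beta0: float = 0.0
    beta_group: float = 0.0
    beta_age: float = 0.0
    beta_interaction: float = 0.0
    noise_sd: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_group1 < 2 or self.n_group2 < 2:
            raise ValueError("each group needs at least 2 subjects")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        lo, hi = self.age_range
        if not (0 < lo < hi < 120):
            raise ValueError("age_range must be plausible adult years")


def default_phantom_regions(
    grid_shape: tuple[int, int, int],
    n_regions: int = 4,
    margin: int = 4,
) -> list[tuple[str, str, str, tuple[slice, slice, slice]]]:
    """A simple region layout: disjoint boxes stacked along the first axis.

    Returns (name, hemisphere, lobe, box) tuples cycling through the four
    lobes and alternating hemispheres.
    """
    nx, ny, nz = grid_shape
    if n_regions < 1:
        raise ValueError("need at least one region")
    step = nx // n_regions
    out = []
    for i in range(n_regions):
        lo = i * step + (margin if i else margin)
        hi = (i + 1) * step - margin
        if hi - lo < 8:
            raise ValueError("grid too small for the requested region count")
        box = (slice(lo, hi), slice(margin, ny - margin), slice(margin, nz - margin))
        out.append(
            (
                f"phantom{i:02d}",
                HEMISPHERES[i % 2],
                LOBES[i % len(LOBES)],
                box,
            )
        )
    return out


def _segment_distance(p1, d1, l1, p2, d2, l2) -> float:
    """Minimum distance between two finite 3-D segments (sampled)."""
    t1 = np.linspace(-l1 / 2, l1 / 2, 25)
    t2 = np.linspace(-l2 / 2, l2 / 2, 25)
    a = p1[None, :] + t1[:, None] * d1[None, :]
    b = p2[None, :] + t2[:, None] * d2[None, :]
    return float(np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(-1)).min())


def generate_pvs_phantom(
    grid_shape: tuple[int, int, int] = (96, 48, 48),
    voxel_size: float = 1.0,
    regions: list[tuple[str, str, str, tuple[slice, slice, slice]]] | None = None,
    tubes_per_region: int = 3,
    radius_range: tuple[float, float] = (1.8, 2.2),
    tube_length: tuple[float, float] = (12.0, 18.0),
    snr: float | None = None,
    seed: int | None = None,
    min_separation: float = 6.0,
    max_attempts: int = 500,
    noise_model: str = "gaussian",
) -> tuple[ImageVolume, ImageVolume, RegionAtlas, dict[str, PhantomTruth]]:
    """Paired T1-like/T2-like phantom volumes with known tubular inclusions.

    Tubes (cylinders of random orientation) are placed wholly inside their
    region box, pairwise separated by at least ``min_separation`` mm of
    axis distance so counts are unambiguous.  A voxel belongs to a tube
    when its center lies within the tube radius of the axis segment.
    ``snr=None`` means noise-free; otherwise additive noise with
    sd = background / snr ("gaussian", a high-SNR Rician approximation) or
    magnitude-Rician noise ("rician").

    Returns (t1_like, t2_like, atlas, truth-per-region).
    """
    if radius_range[0] < voxel_size / 2:
        raise ValueError("tube radius must be at least half a voxel")
    rng = np.random.default_rng(seed)
    regions = regions if regions is not None else default_phantom_regions(grid_shape)
    affine = np.diag([voxel_size] * 3 + [1.0])

    t1 = np.full(grid_shape, BACKGROUND_T1, dtype=float)
    t2 = np.full(grid_shape, BACKGROUND_T2, dtype=float)
    tube_mask = np.zeros(grid_shape, dtype=bool)

    masks: list[RegionMask] = []
    truth: dict[str, PhantomTruth] = {}

    for name, hemi, lobe, box in regions:
        region_mask = np.zeros(grid_shape, dtype=bool)
        region_mask[box] = True
        masks.append(
            RegionMask(
                name=name,
                hemisphere=hemi,
                lobe=lobe,
                mask=ImageVolume(region_mask, affine),
            )
        )

        placed: list[tuple[np.ndarray, np.ndarray, float, float]] = []
        region_tube = np.zeros(grid_shape, dtype=bool)
        lo_mm = np.array([s.start for s in box]) * voxel_size
        hi_mm = np.array([s.stop - 1 for s in box]) * voxel_size

        for _ in range(tubes_per_region):
            ok = False
            for _attempt in range(max_attempts):
                radius = rng.uniform(*radius_range)
                length = rng.uniform(*tube_length)
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                center = rng.uniform(lo_mm, hi_mm)
                half = direction * length / 2
                ends = np.stack([center - half, center + half])
                pad = radius + voxel_size
                if np.any(ends - pad < lo_mm) or np.any(ends + pad > hi_mm):
                    continue
                if any(
                    _segment_distance(center, direction, length, p, d, l)
                    < min_separation
                    for p, d, _r, l in placed
                ):
                    continue
                placed.append((center, direction, radius, length))
                ok = True
                break
            if not ok:
                raise TubePlacementError(
                    f"could not place tube {len(placed) + 1} in region {name!r}"
                )

        # rasterize this region's tubes
        for center, direction, radius, length in placed:
            pad = radius + 2 * voxel_size
            lo_v = np.maximum(((center - length / 2 - pad) / voxel_size).astype(int), 0)
            hi_v = np.minimum(
                ((center + length / 2 + pad) / voxel_size).astype(int) + 2,
                np.array(grid_shape),
            )
            rr = [np.arange(lo_v[i], hi_v[i]) for i in range(3)]
            ii, jj, kk = np.meshgrid(*rr, indexing="ij")
            pts = np.stack([ii, jj, kk], axis=-1) * voxel_size
            rel = pts - center
            t_ax = rel @ direction
            t_clamped = np.clip(t_ax, -length / 2, length / 2)
            closest = t_clamped[..., None] * direction
            dist = np.linalg.norm(rel - closest, axis=-1)
            inside = (dist <= radius) & (np.abs(t_ax) <= length / 2)
            sub = tuple(np.meshgrid(*rr, indexing="ij"))
            region_tube[sub[0][inside], sub[1][inside], sub[2][inside]] = True

        tube_mask |= region_tube
        n_vox = int(region_tube.sum())
        truth[name] = PhantomTruth(
            region_name=name,
            true_count=len(placed),
            true_volume=n_vox * voxel_size**3,
            true_mean_diameter=(
                float(np.mean([2 * r for _, _, r, _ in placed])) if placed else float("nan")
            ),
            tube_axes=placed,
        )

    t1[tube_mask] = TUBE_T1
    t2[tube_mask] = TUBE_T2

    if snr is not None:
        if snr <= 0:
            raise ValueError("snr must be positive")
        sd1 = BACKGROUND_T1 / snr
        sd2 = BACKGROUND_T2 / snr
        if noise_model == "gaussian":
            t1 = t1 + rng.normal(0.0, sd1, grid_shape)
            t2 = t2 + rng.normal(0.0, sd2, grid_shape)
        elif noise_model == "rician":
            t1 = np.hypot(t1 + rng.normal(0.0, sd1, grid_shape), rng.normal(0.0, sd1, grid_shape))
            t2 = np.hypot(t2 + rng.normal(0.0, sd2, grid_shape), rng.normal(0.0, sd2, grid_shape))
        else:
            raise ValueError("noise_model must be 'gaussian' or 'rician'")

    atlas = RegionAtlas(masks)
    return (
        ImageVolume(t1, affine),
        ImageVolume(t2, affine),
        atlas,
        truth,
    )


def _template_grid() -> tuple[tuple[int, int, int], np.ndarray]:
    """A compact 1 mm grid covering the four ALPS ROI spheres."""
    shape = (100, 28, 28)
    affine = np.eye(4)
    affine[:3, 3] = (-50.0, -34.0, 14.0)  # x in [-50,49], y in [-34,-7], z in [14,41]
    return shape, affine


def generate_tensor_field(
    grid_shape: tuple[int, int, int] | None = None,
    affine: np.ndarray | None = None,
    dxx_proj: float = 1.2e-3,
    dyy_proj: float = 0.7e-3,
    dzz_proj: float = 0.9e-3,
    dxx_assoc: float = 1.1e-3,
    dyy_assoc: float = 0.9e-3,
    dzz_assoc: float = 0.6e-3,
    background: float = 0.8e-3,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> tuple[TensorField, AlpsROISet, float]:
    """Tensor element maps with prescribed means inside the ALPS ROIs.

    The six prescribed diffusivities (mm^2/s) are written into the
    projection and association ROI spheres of both hemispheres; the
    expected ALPS index is computed analytically from the prescribed means:
    mean(dxx_proj, dxx_assoc) / mean(dyy_proj, dzz_assoc).  Optional
    i.i.d. Gaussian noise is added to every element map.

    Returns (field, rois, expected_alps).
    """
    for name, v in (
        ("dxx_proj", dxx_proj), ("dyy_proj", dyy_proj), ("dzz_proj", dzz_proj),
        ("dxx_assoc", dxx_assoc), ("dyy_assoc", dyy_assoc), ("dzz_assoc", dzz_assoc),
        ("background", background),
    ):
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    if grid_shape is None or affine is None:
        grid_shape, affine = _template_grid()
    affine = np.asarray(affine, dtype=float)

    dxx = np.full(grid_shape, background)
    dyy = np.full(grid_shape, background)
    dzz = np.full(grid_shape, background)

    rois = AlpsROISet.standard(affine, grid_shape)
    for vox in (rois.proj_left, rois.proj_right):
        dxx[vox[:, 0], vox[:, 1], vox[:, 2]] = dxx_proj
        dyy[vox[:, 0], vox[:, 1], vox[:, 2]] = dyy_proj
        dzz[vox[:, 0], vox[:, 1], vox[:, 2]] = dzz_proj
    for vox in (rois.assoc_left, rois.assoc_right):
        dxx[vox[:, 0], vox[:, 1], vox[:, 2]] = dxx_assoc
        dyy[vox[:, 0], vox[:, 1], vox[:, 2]] = dyy_assoc
        dzz[vox[:, 0], vox[:, 1], vox[:, 2]] = dzz_assoc

    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        dxx = dxx + rng.normal(0.0, noise_sd, grid_shape)
        dyy = dyy + rng.normal(0.0, noise_sd, grid_shape)
        dzz = dzz + rng.normal(0.0, noise_sd, grid_shape)

    expected = (0.5 * (dxx_proj + dxx_assoc)) / (0.5 * (dyy_proj + dzz_assoc))
    return TensorField(dxx=dxx, dyy=dyy, dzz=dzz, affine=affine), rois, float(expected)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate a two-group cohort table.

    Columns: subject_id, group (0 control / 1 case), sex, age, outcome.
    Ages are uniform on ``spec.age_range``; the outcome follows the linear
    model in :class:`CohortSpec` with age centered at the sample mean.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_group1 + spec.n_group2
    group = np.concatenate([np.zeros(spec.n_group1), np.ones(spec.n_group2)])
    age = rng.uniform(*spec.age_range, size=n)
    sex = rng.choice(["M", "F"], size=n)
    age_c = age - age.mean()
    eps = rng.normal(0.0, spec.noise_sd, size=n)
    outcome = (
        spec.beta0
        + spec.beta_group * group
        + spec.beta_age * age_c
        + spec.beta_interaction * group * age_c
        + eps
    )
    return pd.DataFrame(
        {
            "subject_id": [f"sub-{i:04d}" for i in range(n)],
            "group": group.astype(int),
            "sex": sex,
            "age": age,
            "outcome": outcome,
        }
    )


def generate_volumetric_table(
    n_subjects: int = 20,
    ventricle_mean: float = 15000.0,
    ventricle_sd: float = 6000.0,
    cp_mean: float = 1600.0,
    cp_sd: float = 400.0,
    etiv_mean: float = 1.5e6,
    etiv_sd: float = 1.5e5,
    seed: int | None = None,
) -> pd.DataFrame:
    """Flat volumetric stats table (one row per structure per hemisphere).

    Volumes are drawn from truncated normals (redrawn while non-positive)
    so every volume is positive; sd = 0 gives exactly the means.  Columns
    match the flat dialect of :func:`csfmarkers.volumetrics.read_aseg_table`.
    """
    if min(ventricle_mean, cp_mean, etiv_mean) <= 0:
        raise ValueError("means must be positive")
    if min(ventricle_sd, cp_sd, etiv_sd) < 0:
        raise ValueError("sds must be non-negative")
    rng = np.random.default_rng(seed)

    def draw(mean: float, sd: float, size: int) -> np.ndarray:
        if sd == 0:
            return np.full(size, mean)
        x = rng.normal(mean, sd, size)
        while np.any(x <= 0):
            bad = x <= 0
            x[bad] = rng.normal(mean, sd, int(bad.sum()))
        return x

    rows = []
    etiv = draw(etiv_mean, etiv_sd, n_subjects)
    for structure, mean, sd in (
        ("lateral_ventricle", ventricle_mean, ventricle_sd),
        ("choroid_plexus", cp_mean, cp_sd),
    ):
        for hemi in ("L", "R"):
            vols = draw(mean, sd, n_subjects)
            for i in range(n_subjects):
                rows.append(
                    {
                        "subject": f"sub-{i:04d}",
                        "structure": structure,
                        "hemi": hemi,
                        "volume_mm3": vols[i],
                        "etiv_mm3": etiv[i],
                    }
                )
    table = pd.DataFrame(rows).sort_values(["subject", "structure", "hemi"], kind="stable")
    return table.reset_index(drop=True)
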