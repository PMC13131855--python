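"""Perivascular-space segmentation on enhanced perivascular contrast images.

The pipeline is: (1) EPC image as the voxel-wise T1w/T2w ratio, in which
CSF-filled perivascular spaces are dark; (2) multiscale Frangi vesselness
filtering of the EPC image inside a white-matter analysis mask, enhancing
tubular structures; (3) percentile thresholding of the vesselness map to a
binary PVS mask.

Vesselness at one scale sigma is built from the eigenvalues of the
gamma-normalized Gaussian Hessian (gamma = 1), ordered |l1| <= |l2| <= |l3|:

    R_A = |l2| / |l3|          (plate vs line)
    R_B = |l1| / sqrt(|l2 l3|) (blob vs line)
    S   = sqrt(l1^2 + l2^2 + l3^2)

    V = (1 - exp(-R_A^2 / 2 a^2)) * exp(-R_B^2 / 2 b^2) * (1 - exp(-S^2 / 2 c^2))

with V = 0 wherever the dark-tube sign condition (l2 > 0 and l3 > 0) fails.
Default parameters are a = b = 0.5 with c set per scale to half the maximum
Hessian (Frobenius) norm inside the analysis mask.  The final map is the
voxel-wise maximum over scales.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .image import ImageVolume

logger = logging.getLogger(__name__)

__all__ = [
    "FrangiParams",
    "VesselnessMap",
    "compute_epc",
    "hessian_eigenvalues",
    "frangi_vesselness",
    "threshold_vesselness",
]


@dataclass
class FrangiParams:
    """Parameters of the multiscale Frangi vesselness filter.

    alpha, beta : sensitivity of the plate- and blob-rejection terms.
    c : "half_max_hessian_norm" (computed per scale inside the analysis
        mask) or an explicit positive float.
    sigmas : Gaussian scales in mm.  The default targets 1-3 voxel wide
        tubules on 0.8 mm isotropic input.
    polarity : "dark" for hypointense tubes (PVS on an EPC image) or
        "bright".
    """

    alpha: float = 0.5
    beta: float = 0.5
    c: float | str = "half_max_hessian_norm"
    sigmas: tuple[float, ...] = (0.4, 0.6, 0.8)
    polarity: str = "dark"

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if not self.sigmas or any(s <= 0 for s in self.sigmas):
            raise ValueError("sigmas must be a non-empty list of positive scales")
        if isinstance(self.c, str):
            if self.c != "half_max_hessian_norm":
                raise ValueError(f"unknown c rule {self.c!r}")
        elif self.c <= 0:
            raise ValueError("explicit c must be positive")
        if self.polarity not in ("dark", "bright"):
            raise ValueError("polarity must be 'dark' or 'bright'")


@dataclass
class VesselnessMap:
    """Per-voxel vesselness in [0, 1] plus the scale (mm) of the maximum."""

    values: ImageVolume
    scale_of_max: ImageVolume
    c_per_scale: dict[float, float] = field(default_factory=dict)


def compute_epc(
    t1: ImageVolume,
    t2: ImageVolume,
    mask: ImageVolume | np.ndarray | None = None,
    floor: float | None = None,
) -> ImageVolume:
    """Enhanced perivascular contrast: voxel-wise T1w / T2w ratio.

    The T2w denominator is clamped at ``floor`` (default 1e-6 times the
    in-mask median of T2w) so the ratio stays finite.  Values outside the
    mask are zero.
    """
    t1.require_same_grid(t2, "t1 and t2")
    if mask is None:
        m = np.ones(t1.shape, dtype=bool)
    else:
        marr = mask.data if isinstance(mask, ImageVolume) else mask
        m = np.asarray(marr).astype(bool)
        if m.shape != t1.shape:
            raise ValueError("mask shape does not match image grid")
    if floor is None:
        med = float(np.median(t2.data[m])) if m.any() else 1.0
        floor = 1e-6 * abs(med) if med != 0 else 1e-6
    if floor <= 0:
        raise ValueError("floor must be positive")
    epc = np.zeros(t1.shape, dtype=float)
    denom = np.maximum(t2.data.astype(float), floor)
    epc[m] = t1.data.astype(float)[m] / denom[m]
    return t1.copy_with(epc)


def hessian_eigenvalues(
    volume: ImageVolume, sigma: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Eigenvalues of the gamma-normalized Gaussian Hessian at scale sigma.

    Second derivatives are taken on the Gaussian-smoothed volume in mm
    units (the per-axis smoothing sigma is ``sigma / voxel_size``) and
    multiplied by sigma^2 (gamma = 1) so responses are comparable across
    scales.  Returns three maps ordered by absolute value,
    |l1| <= |l2| <= |l3|, at every voxel.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    data = np.asarray(volume.data, dtype=float)
    vs = volume.voxel_size
    sig_vox = sigma / vs

    # Second derivatives via Gaussian derivative filters, scaled to mm.
    h = np.empty(data.shape + (3, 3), dtype=float)
    for i in range(3):
        for j in range(i, 3):
            order = [0, 0, 0]
            order[i] += 1
            order[j] += 1
            # truncate=6 keeps the derivative-kernel discretization error
            # below ~1e-8 so flat regions stay numerically flat
            d = ndi.gaussian_filter(
                data, sigma=sig_vox, order=order, mode="nearest", truncate=6.0
            )
            d /= vs[i] * vs[j]  # voxel-index derivatives -> mm derivatives
            d *= sigma**2  # gamma-normalization, gamma = 1
            h[..., i, j] = d
            h[..., j, i] = d

    eigs = np.linalg.eigvalsh(h)  # ascending by value
    order_idx = np.argsort(np.abs(eigs), axis=-1)
    eigs = np.take_along_axis(eigs, order_idx, axis=-1)
    return eigs[..., 0], eigs[..., 1], eigs[..., 2]


def _vesselness_single_scale(
    volume: ImageVolume,
    mask: np.ndarray,
    sigma: float,
    params: FrangiParams,
) -> tuple[np.ndarray, float]:
    l1, l2, l3 = hessian_eigenvalues(volume, sigma)

    if params.polarity == "dark":
        sign_ok = (l2 > 0) & (l3 > 0)
    else:
        sign_ok = (l2 < 0) & (l3 < 0)

    a1, a2, a3 = np.abs(l1), np.abs(l2), np.abs(l3)
    s = np.sqrt(a1**2 + a2**2 + a3**2)

    if isinstance(params.c, str):
        s_in = s[mask]
        c = 0.5 * float(s_in.max()) if s_in.size else 0.0
    else:
        c = float(params.c)
    if c == 0.0:
        logger.warning(
            "all Hessian norms are zero at sigma=%.3g mm; scale contributes 0",
            sigma,
        )
        return np.zeros(volume.shape), 0.0

    with np.errstate(divide="ignore", invalid="ignore"):
        ra2 = np.where(a3 > 0, (a2 / np.where(a3 > 0, a3, 1.0)) ** 2, 0.0)
        rb2 = np.where(
            (a2 > 0) & (a3 > 0), a1**2 / np.where(a2 * a3 > 0, a2 * a3, 1.0), 0.0
        )
    v = (
        (1.0 - np.exp(-ra2 / (2.0 * params.alpha**2)))
        * np.exp(-rb2 / (2.0 * params.beta**2))
        * (1.0 - np.exp(-(s**2) / (2.0 * c**2)))
    )
    v = np.where(sign_ok & (a3 > 0) & mask, v, 0.0)
    return v, c


def frangi_vesselness(
    volume: ImageVolume,
    mask: ImageVolume | np.ndarray,
    params: FrangiParams | None = None,
) -> VesselnessMap:
    """Multiscale Frangi vesselness of ``volume`` inside ``mask``.

    Per scale the response is computed as described in the module docstring;
    the output value at a voxel is the maximum over scales and
    ``scale_of_max`` records the argmax scale in mm (0 where vesselness is
    zero).  The map is identically zero outside the mask.
    """
    params = params or FrangiParams()
    marr = mask.data if isinstance(mask, ImageVolume) else mask
    m = np.asarray(marr).astype(bool)
    if m.shape != volume.shape:
        raise ValueError("mask shape does not match image grid")
    if not m.any():
        raise ValueError("analysis mask is empty")

    best = np.zeros(volume.shape, dtype=float)
    best_scale = np.zeros(volume.shape, dtype=float)
    c_per_scale: dict[float, float] = {}
    for sigma in params.sigmas:
        v, c = _vesselness_single_scale(volume, m, sigma, params)
        c_per_scale[float(sigma)] = c
        take = v > best
        best[take] = v[take]
        best_scale[take] = sigma
    return VesselnessMap(
        values=volume.copy_with(best),
        scale_of_max=volume.copy_with(best_scale),
        c_per_scale=c_per_scale,
    )


def threshold_vesselness(
    v: VesselnessMap | ImageVolume,
    analysis_mask: ImageVolume | np.ndarray,
    percentile: float,
) -> ImageVolume:
    """Binary PVS mask from a vesselness map by percentile thresholding.

    A voxel enters the PVS mask iff it lies in the analysis mask, its
    vesselness is positive, and strictly more than ``percentile`` percent
    of the positive in-mask vesselness values are <= its value.  At
    percentile 100 the mask is empty (no value exceeds the whole sample);
    masks are nested: a higher percentile always yields a subset.
    """
    if not (0.0 < percentile <= 100.0):
        raise ValueError("percentile must be in (0, 100]")
    vol = v.values if isinstance(v, VesselnessMap) else v
    marr = analysis_mask.data if isinstance(analysis_mask, ImageVolume) else analysis_mask
    m = np.asarray(marr).astype(bool)
    if m.shape != vol.shape:
        raise ValueError("analysis mask shape does not match vesselness grid")
    if not m.any():
        raise ValueError("analysis mask is empty")

    vals = vol.data[m]
    pos = np.sort(vals[vals > 0])
    out = np.zeros(vol.shape, dtype=bool)
    if pos.size:
        # empirical CDF (fraction of positive values <= v) must exceed p/100
        frac = np.searchsorted(pos, vol.data, side="right") / pos.size
        out = m & (vol.data > 0) & (frac > percentile / 100.0)
    return vol.copy_with(out)
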