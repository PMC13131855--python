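"""End-to-end convenience wrappers over the pipeline stages."""

from __future__ import annotations

import numpy as np

from .atlas import RegionAtlas
from .image import ImageVolume
from .morphometry import PVSRegionMetrics, regional_pvs_metrics
from .segmentation import (
    FrangiParams,
    compute_epc,
    frangi_vesselness,
    threshold_vesselness,
)

__all__ = ["segment_pvs"]


def segment_pvs(
    t1: ImageVolume,
    t2: ImageVolume,
    atlas: RegionAtlas,
    lesion_mask: ImageVolume | np.ndarray | None = None,
    params: FrangiParams | None = None,
    percentile: float = 98.0,
    connectivity: int = 26,
) -> tuple[ImageVolume, list[PVSRegionMetrics], dict]:
    """EPC -> Frangi vesselness -> percentile threshold -> regional metrics.

    The analysis mask is the union of the atlas region masks minus the
    lesion mask (non-PVS white-matter lesions are excluded before
    filtering).  Returns the binary PVS mask, the per-region metrics, and
    a metadata dict recording every filter parameter actually used.
    """
    params = params or FrangiParams()
    analysis_mask = atlas.union_mask()
    if lesion_mask is not None:
        larr = lesion_mask.data if isinstance(lesion_mask, ImageVolume) else lesion_mask
        analysis_mask = analysis_mask & ~np.asarray(larr).astype(bool)

    epc = compute_epc(t1, t2, analysis_mask)
    vm = frangi_vesselness(epc, analysis_mask, params)
    pvs_mask = threshold_vesselness(vm, analysis_mask, percentile)
    metrics = regional_pvs_metrics(pvs_mask, atlas, connectivity=connectivity)

    metadata = {
        "alpha": params.alpha,
        "beta": params.beta,
        "c_rule": params.c if isinstance(params.c, str) else "explicit",
        "c_per_scale": vm.c_per_scale,
        "sigmas_mm": list(params.sigmas),
        "polarity": params.polarity,
        "percentile": percentile,
        "connectivity": connectivity,
        "n_pvs_voxels": int(pvs_mask.data.sum()),
    }
    return pvs_mask, metrics, metadata
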