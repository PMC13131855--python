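"""Morphometry of segmented perivascular spaces.

Connected components of the binary PVS mask are measured individually
(volume, principal-axis lengths, diameter), assigned to white-matter
regions by majority overlap, and aggregated per region into count, total
volume, mean diameter, and the count/volume fractions normalized by the
regional white-matter volume.  Per-subject regional metrics over the
canonical 56-mask atlas assemble into a 168-column feature table
(56 regions x {VF, CF, DM}).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .atlas import RegionAtlas, canonical_region_keys, lobe_of
from .image import ImageVolume

logger = logging.getLogger(__name__)

__all__ = [
    "PVSRegionMetrics",
    "label_components",
    "component_metrics",
    "regional_pvs_metrics",
    "assemble_feature_table",
    "METRIC_ORDER",
]

#: Feature-table metric suffixes, in canonical column order.
METRIC_ORDER: tuple[str, ...] = ("VF", "CF", "DM")

_STRUCTURES = {
    6: ndi.generate_binary_structure(3, 1),
    18: ndi.generate_binary_structure(3, 2),
    26: ndi.generate_binary_structure(3, 3),
}


@dataclass
class PVSRegionMetrics:
    """Aggregate PVS measures for one white-matter region.

    ``mean_diameter`` is NaN when no component is assigned (count 0);
    ``count_fraction`` is per mm^3 of regional white matter and
    ``volume_fraction`` is dimensionless in [0, 1].
    """

    region_key: str
    count: int
    total_volume: float
    mean_diameter: float
    count_fraction: float
    volume_fraction: float


def label_components(
    pvs_mask: ImageVolume | np.ndarray, connectivity: int = 26
) -> tuple[np.ndarray, int]:
    """Label maximal connected components of a binary mask.

    ``connectivity`` is 6 (faces), 18 (faces+edges) or 26 (full).  Labels
    are dense from 1; background is 0.  Returns (label volume, n_components).
    """
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 6, 18 or 26")
    arr = pvs_mask.data if isinstance(pvs_mask, ImageVolume) else pvs_mask
    labels, n = ndi.label(np.asarray(arr).astype(bool), structure=_STRUCTURES[connectivity])
    return labels, int(n)


def component_metrics(
    voxel_indices: np.ndarray, voxel_size: float | np.ndarray
) -> tuple[float, np.ndarray, float]:
    """Volume, principal-axis lengths and diameter of one component.

    Parameters
    ----------
    voxel_indices : (n, 3) integer array of voxel coordinates.
    voxel_size : scalar or per-axis voxel edge length in mm.

    The second-moment matrix of the voxel centers (in mm, with the 1/12
    diagonal term of a uniform cube so single-voxel components have finite
    extent) is converted to equivalent-ellipsoid principal-axis lengths
    ``4 * sqrt(eigenvalue)``; the diameter — the cross-sectional width of a
    tubular component — is the mean of the two smaller lengths.  For a
    solid cylinder of radius r this recovers 2r exactly in the continuum.
    """
    idx = np.asarray(voxel_indices, dtype=float)
    if idx.ndim != 2 or idx.shape[1] != 3 or idx.shape[0] == 0:
        raise ValueError("voxel_indices must be a non-empty (n, 3) array")
    vs = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,))
    pts = idx * vs
    volume = idx.shape[0] * float(np.prod(vs))

    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered / idx.shape[0]
    cov += np.diag(vs**2) / 12.0  # continuous-voxel correction
    evals = np.linalg.eigvalsh(cov)  # ascending
    lengths = 4.0 * np.sqrt(np.maximum(evals, 0.0))[::-1]  # descending
    diameter = float(lengths[1:].mean())
    return volume, lengths, diameter


def regional_pvs_metrics(
    pvs_mask: ImageVolume,
    atlas: RegionAtlas,
    connectivity: int = 26,
) -> list[PVSRegionMetrics]:
    """Per-region PVS count, volume, mean diameter, and fractions.

    Each connected component is assigned to the region containing the
    majority of its voxels (ties break to the lexicographically smallest
    region key); components with no majority region are dropped and logged.
    """
    pvs_mask.require_same_grid(atlas.grid, "PVS mask and atlas")
    vs = pvs_mask.voxel_size
    labels, n = label_components(pvs_mask, connectivity)

    region_masks = {r.key: r.mask.data.astype(bool) for r in atlas}
    assigned: dict[str, list[tuple[float, float]]] = {r.key: [] for r in atlas}
    n_dropped = 0

    if n > 0:
        objects = ndi.find_objects(labels)
        for comp_id, sl in enumerate(objects, start=1):
            if sl is None:
                continue
            local = labels[sl] == comp_id
            coords = np.argwhere(local) + np.array([s.start for s in sl])
            volume, _lengths, diameter = component_metrics(coords, vs)
            # plurality-overlap assignment; ties break to the
            # lexicographically smallest region key via sorted iteration
            best_key, best_overlap = None, 0
            for key in sorted(region_masks):
                ov = int(region_masks[key][sl][local].sum())
                if ov > best_overlap:
                    best_key, best_overlap = key, ov
            if best_key is None or best_overlap * 2 < coords.shape[0]:
                n_dropped += 1  # majority of voxels outside every region
                continue
            assigned[best_key].append((volume, diameter))
    if n_dropped:
        logger.info("%d components fell majority-outside all regions", n_dropped)

    out = []
    for r in atlas:
        comps = assigned[r.key]
        count = len(comps)
        total_volume = float(sum(v for v, _ in comps))
        mean_diameter = float(np.mean([d for _, d in comps])) if count else float("nan")
        out.append(
            PVSRegionMetrics(
                region_key=r.key,
                count=count,
                total_volume=total_volume,
                mean_diameter=mean_diameter,
                count_fraction=count / r.wm_volume,
                volume_fraction=total_volume / r.wm_volume,
            )
        )
    return out


def feature_columns() -> list[str]:
    """The 168 canonical feature-column names: ``<key>_<metric>``.

    Order is lobe, region, hemisphere, metric (VF, CF, DM).
    """
    return [f"{key}_{m}" for key in canonical_region_keys() for m in METRIC_ORDER]


def assemble_feature_table(
    per_subject_metrics: dict[str, list[PVSRegionMetrics]],
) -> pd.DataFrame:
    """Wide per-subject feature table over the canonical 56-region set.

    ``per_subject_metrics`` maps subject id to that subject's regional
    metrics; every subject must cover all 56 canonical regions.  Columns
    are the 168 region x metric features in deterministic order, indexed
    by subject id.
    """
    cols = feature_columns()
    want = set(canonical_region_keys())
    rows = {}
    for sid, metrics in per_subject_metrics.items():
        by_key = {m.region_key: m for m in metrics}
        missing = want - set(by_key)
        if missing:
            raise ValueError(
                f"subject {sid!r} is missing region(s): {sorted(missing)[:5]}"
            )
        extra = set(by_key) - want
        if extra:
            logger.warning(
                "subject %s: ignoring %d non-canonical region(s)", sid, len(extra)
            )
        row = {}
        for key in canonical_region_keys():
            m = by_key[key]
            row[f"{key}_VF"] = m.volume_fraction
            row[f"{key}_CF"] = m.count_fraction
            row[f"{key}_DM"] = m.mean_diameter
        rows[sid] = row
    table = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    table.index.name = "subject_id"
    return table


def feature_metadata() -> pd.DataFrame:
    """Lobe/hemisphere/metric annotation for each canonical feature column."""
    records = []
    for key in canonical_region_keys():
        hemi, name = key.split("-", 1)
        for m in METRIC_ORDER:
            records.append(
                {
                    "column": f"{key}_{m}",
                    "region": name,
                    "hemisphere": hemi,
                    "lobe": lobe_of(name),
                    "metric": m,
                }
            )
    return pd.DataFrame.from_records(records)
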