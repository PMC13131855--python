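"""White-matter region atlas with lobe grouping.

The analysis set is the 28 bilateral Desikan-Killiany white-matter regions
grouped into four lobes — frontal (11), parietal (5), temporal (8), and
occipital (4) — giving 56 region masks (L/R) and, with three perivascular
metrics each, 168 feature columns per subject.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .image import ImageVolume

logger = logging.getLogger(__name__)

__all__ = [
    "LOBE_REGIONS",
    "LOBES",
    "HEMISPHERES",
    "CANONICAL_REGIONS",
    "RegionMask",
    "RegionAtlas",
]

#: Region names per lobe, in canonical (reporting) order.
LOBE_REGIONS: dict[str, tuple[str, ...]] = {
    "frontal": (
        "superiorfrontal",
        "rostralmiddlefrontal",
        "caudalmiddlefrontal",
        "parsopercularis",
        "parsorbitalis",
        "parstriangularis",
        "lateralorbitofrontal",
        "medialorbitofrontal",
        "precentral",
        "paracentral",
        "frontalpole",
    ),
    "parietal": (
        "postcentral",
        "supramarginal",
        "superiorparietal",
        "inferiorparietal",
        "precuneus",
    ),
    "temporal": (
        "entorhinal",
        "parahippocampal",
        "fusiform",
        "superiortemporal",
        "middletemporal",
        "inferiortemporal",
        "transversetemporal",
        "temporalpole",
    ),
    "occipital": (
        "lingual",
        "pericalcarine",
        "cuneus",
        "lateraloccipital",
    ),
}

LOBES: tuple[str, ...] = tuple(LOBE_REGIONS)
HEMISPHERES: tuple[str, ...] = ("L", "R")

#: All 28 bilateral region names in canonical lobe order.
CANONICAL_REGIONS: tuple[str, ...] = tuple(
    name for lobe in LOBES for name in LOBE_REGIONS[lobe]
)

_REGION_TO_LOBE: dict[str, str] = {
    name: lobe for lobe in LOBES for name in LOBE_REGIONS[lobe]
}


def lobe_of(region_name: str) -> str:
    """Lobe a canonical region belongs to."""
    try:
        return _REGION_TO_LOBE[region_name]
    except KeyError:
        raise KeyError(f"unknown region name: {region_name!r}") from None


@dataclass
class RegionMask:
    """A single named binary white-matter mask.

    ``wm_volume`` is the mask volume in mm^3 and is the denominator of the
    count- and volume-fraction normalizations.
    """

    name: str
    hemisphere: str  # "L" | "R"
    lobe: str
    mask: ImageVolume
    wm_volume: float | None = None

    def __post_init__(self) -> None:
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(f"hemisphere must be L or R, got {self.hemisphere!r}")
        if self.lobe not in LOBES:
            raise ValueError(f"unknown lobe {self.lobe!r}")
        if self.wm_volume is None:
            self.wm_volume = float(
                np.count_nonzero(self.mask.data) * self.mask.voxel_volume
            )
        if self.wm_volume <= 0:
            raise ValueError(
                f"region {self.key} has non-positive white-matter volume"
            )

    @property
    def key(self) -> str:
        """Hemisphere-qualified label, e.g. ``L-precuneus``."""
        return f"{self.hemisphere}-{self.name}"


class RegionAtlas:
    """An ordered collection of named, lobe-tagged binary region masks.

    Phantom atlases may carry arbitrary region names; the canonical 56-mask
    Desikan-Killiany analysis set is enforced only where the full feature
    table is assembled.
    """

    def __init__(self, regions: list[RegionMask]):
        if not regions:
            raise ValueError("atlas needs at least one region")
        keys = [r.key for r in regions]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate region keys in atlas")
        grid0 = regions[0].mask
        for r in regions[1:]:
            grid0.require_same_grid(r.mask, "atlas masks")
        self.regions: list[RegionMask] = list(regions)

    def __iter__(self):
        return iter(self.regions)

    def __len__(self) -> int:
        return len(self.regions)

    def __getitem__(self, key: str) -> RegionMask:
        for r in self.regions:
            if r.key == key:
                return r
        raise KeyError(key)

    @property
    def keys(self) -> list[str]:
        return [r.key for r in self.regions]

    @property
    def grid(self) -> ImageVolume:
        return self.regions[0].mask

    def union_mask(self) -> np.ndarray:
        out = np.zeros(self.grid.shape, dtype=bool)
        for r in self.regions:
            out |= r.mask.data.astype(bool)
        return out

    def is_canonical(self) -> bool:
        """True when the atlas is exactly the 56-mask bilateral analysis set."""
        want = {f"{h}-{n}" for n in CANONICAL_REGIONS for h in HEMISPHERES}
        return set(self.keys) == want


def canonical_region_keys() -> list[str]:
    """The 56 hemisphere-qualified region keys in canonical order.

    Order is lobe, then region within lobe, then hemisphere (L before R).
    """
    return [
        f"{h}-{name}"
        for lobe in LOBES
        for name in LOBE_REGIONS[lobe]
        for h in HEMISPHERES
    ]
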