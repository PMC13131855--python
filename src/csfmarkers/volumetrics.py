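"""eTIV-normalized lateral-ventricle and choroid-plexus volumetrics.

Consumes segmentation-statistics tables (either a flat multi-subject
TSV/CSV with columns subject, structure, hemi, volume_mm3, etiv_mm3, or a
single-subject FreeSurfer ``aseg.stats`` file) and produces per-subject
normalized volumes: structure volume divided by the estimated total
intracranial volume (eTIV), which removes head-size differences.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "VolumetricRecord",
    "VolumetricsParseError",
    "read_aseg_table",
    "normalize_volume",
    "records_to_frame",
]

STRUCTURES: tuple[str, ...] = ("lateral_ventricle", "choroid_plexus")

#: FreeSurfer aseg StructName -> (structure, hemisphere)
_ASEG_NAMES = {
    "Left-Lateral-Ventricle": ("lateral_ventricle", "L"),
    "Right-Lateral-Ventricle": ("lateral_ventricle", "R"),
    "Left-choroid-plexus": ("choroid_plexus", "L"),
    "Right-choroid-plexus": ("choroid_plexus", "R"),
}


class VolumetricsParseError(ValueError):
    """A required structure row or eTIV entry is missing or invalid."""


@dataclass
class VolumetricRecord:
    subject_id: str
    structure: str  # lateral_ventricle | choroid_plexus
    hemisphere: str  # L | R
    volume: float  # mm^3
    etiv: float  # mm^3

    def __post_init__(self) -> None:
        if self.structure not in STRUCTURES:
            raise ValueError(f"unknown structure {self.structure!r}")
        if self.hemisphere not in ("L", "R"):
            raise ValueError("hemisphere must be L or R")
        if self.volume <= 0:
            raise ValueError(f"non-positive volume for {self.subject_id}")
        if self.etiv <= 0:
            raise ValueError(f"non-positive eTIV for {self.subject_id}")

    @property
    def normalized_volume(self) -> float:
        nv = normalize_volume(self.volume, self.etiv)
        if nv >= 1:
            logger.warning(
                "implausible normalized volume %.3g for %s %s/%s",
                nv, self.subject_id, self.structure, self.hemisphere,
            )
        return nv


def normalize_volume(volume: float, etiv: float) -> float:
    """Structure volume as a fraction of eTIV (dimensionless)."""
    if etiv <= 0:
        raise ValueError("eTIV must be positive")
    if volume <= 0:
        raise ValueError("volume must be positive")
    return volume / etiv


def _read_flat(path: Path) -> list[VolumetricRecord]:
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else None
    table = pd.read_csv(path, sep=sep, engine="python")
    table.columns = [c.strip().lower() for c in table.columns]
    required = {"subject", "structure", "hemi", "volume_mm3", "etiv_mm3"}
    if not required.issubset(table.columns):
        raise VolumetricsParseError(
            f"flat table missing columns: {sorted(required - set(table.columns))}"
        )
    records: list[VolumetricRecord] = []
    for sid, sub in table.groupby("subject", sort=False):
        found = set()
        for _, row in sub.iterrows():
            structure = str(row["structure"]).strip()
            if structure not in STRUCTURES:
                logger.debug("ignoring row with structure %r", structure)
                continue
            hemi = str(row["hemi"]).strip().upper()[:1]
            records.append(
                VolumetricRecord(
                    subject_id=str(sid),
                    structure=structure,
                    hemisphere=hemi,
                    volume=float(row["volume_mm3"]),
                    etiv=float(row["etiv_mm3"]),
                )
            )
            found.add((structure, hemi))
        for structure in STRUCTURES:
            for hemi in ("L", "R"):
                if (structure, hemi) not in found:
                    raise VolumetricsParseError(
                        f"subject {sid}: missing {structure}/{hemi} row"
                    )
    return records


def _read_aseg_stats(path: Path, subject_id: str | None) -> list[VolumetricRecord]:
    """Single-subject FreeSurfer aseg.stats dialect."""
    text = path.read_text()
    sid = subject_id
    etiv = None
    for line in text.splitlines():
        if line.startswith("# subjectname") and sid is None:
            sid = line.split()[-1]
        m = re.match(
            r"#\s*Measure\s+EstimatedTotalIntraCranialVol.*?,\s*([\d.eE+-]+)\s*,\s*mm\^3",
            line,
        )
        if m:
            etiv = float(m.group(1))
    sid = sid or path.stem
    if etiv is None:
        raise VolumetricsParseError(f"subject {sid}: missing eTIV measure")

    volumes: dict[tuple[str, str], float] = {}
    for line in text.splitlines():
        if line.startswith("#") or not line.strip():
            continue
        parts = line.split()
        # aseg body: Index SegId NVoxels Volume_mm3 StructName ...
        if len(parts) < 5:
            continue
        name = parts[4]
        if name in _ASEG_NAMES:
            volumes[_ASEG_NAMES[name]] = float(parts[3])
        else:
            logger.debug("ignoring aseg row %r", name)

    records = []
    for structure in STRUCTURES:
        for hemi in ("L", "R"):
            if (structure, hemi) not in volumes:
                raise VolumetricsParseError(
                    f"subject {sid}: missing {structure}/{hemi} row"
                )
            records.append(
                VolumetricRecord(
                    subject_id=sid,
                    structure=structure,
                    hemisphere=hemi,
                    volume=volumes[(structure, hemi)],
                    etiv=etiv,
                )
            )
    return records


def read_aseg_table(
    path: str | Path, subject_id: str | None = None
) -> list[VolumetricRecord]:
    """Parse a volumetric stats table into records.

    The dialect is auto-detected: files whose header contains a
    ``# Measure`` line are treated as single-subject FreeSurfer
    ``aseg.stats``; otherwise a flat multi-subject table with columns
    subject/structure/hemi/volume_mm3/etiv_mm3 is expected.
    """
    path = Path(path)
    head = path.read_text()[:4096]
    if "# Measure" in head or head.startswith("# Title"):
        return _read_aseg_stats(path, subject_id)
    return _read_flat(path)


def records_to_frame(records: list[VolumetricRecord]) -> pd.DataFrame:
    """Wide per-subject frame of normalized volumes.

    Columns: ``{L,R}_lateral_ventricle_norm``, ``{L,R}_choroid_plexus_norm``
    plus ``etiv_mm3``; one row per subject.
    """
    rows: dict[str, dict[str, float]] = {}
    for rec in records:
        row = rows.setdefault(rec.subject_id, {})
        row[f"{rec.hemisphere}_{rec.structure}_norm"] = rec.normalized_volume
        row["etiv_mm3"] = rec.etiv
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "subject_id"
    cols = [
        "L_lateral_ventricle_norm",
        "R_lateral_ventricle_norm",
        "L_choroid_plexus_norm",
        "R_choroid_plexus_norm",
        "etiv_mm3",
    ]
    return frame[[c for c in cols if c in frame.columns]]
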