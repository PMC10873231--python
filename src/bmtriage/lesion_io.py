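"""Masks, lesions and tables: the data layer of the pipeline.

A patient's brain-metastasis burden is represented either as a 3D label
mask on a voxel grid with physical spacing (NIfTI), or as a flat table of
per-lesion scalars (CSV).  This module reads and writes both, extracts
connected enhancing components ("lesions") from masks, and computes the
per-lesion geometry the triage algorithm consumes: physical volume in
mm^3 and the equivalent spherical diameter in mm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "TREATMENTS",
    "VoxelGrid",
    "Lesion",
    "PatientScan",
    "ClinicalRecord",
    "sphere_volume",
    "equivalent_diameter",
    "read_mask",
    "write_mask",
    "extract_lesions",
    "read_lesion_table",
    "write_lesion_table",
    "read_clinical_table",
    "write_clinical_table",
]

#: Valid actual-treatment categories in clinical records.
TREATMENTS = ("follow_up", "surgery", "srs", "chemo", "wbrt")

_SOURCES = ("ground_truth", "detector")


def sphere_volume(diameter_mm: float) -> float:
    """Volume in mm^3 of a sphere with the given diameter in mm.

    V = (4/3) * pi * r^3 with r = diameter/2.  At 5 mm this gives
    65.45 mm^3, whose integer part is the 65 mm^3 follow-up-group
    volume cap used by the triage rules.
    """
    if diameter_mm < 0:
        raise ValueError(f"diameter must be non-negative, got {diameter_mm}")
    return (4.0 / 3.0) * math.pi * (diameter_mm / 2.0) ** 3


def equivalent_diameter(volume_mm3: float) -> float:
    """Diameter in mm of the sphere with the given volume in mm^3.

    Inverse of :func:`sphere_volume`: d = (6 V / pi)^(1/3).
    """
    if volume_mm3 < 0:
        raise ValueError(f"volume must be non-negative, got {volume_mm3}")
    return (6.0 * volume_mm3 / math.pi) ** (1.0 / 3.0)


@dataclass(frozen=True)
class VoxelGrid:
    """A 3D integer label image with physical voxel spacing in mm.

    Label 0 is background; positive labels are foreground.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 3:
            raise ValueError(f"expected a 3D volume, got {values.ndim} dimensions")
        if not np.issubdtype(values.dtype, np.integer):
            raise ValueError(f"label values must be integers, got dtype {values.dtype}")
        if values.size and values.min() < 0:
            raise ValueError("label values must be non-negative")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 positive lengths in mm, got {self.spacing}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class Lesion:
    """One connected enhancing component.

    ``volume_mm3`` is the physical volume; ``equivalent_diameter_mm`` is
    the diameter of the equal-volume sphere.  ``voxel_indices`` is present
    for mask-derived lesions and absent for table-derived ones.
    ``confidence`` is the detector score (absent for ground truth).
    ``source_gt_id`` records, for simulated detections, which ground-truth
    lesion the detection originated from (None for false positives).
    """

    lesion_id: int
    volume_mm3: float
    equivalent_diameter_mm: float
    centroid_mm: Optional[tuple[float, float, float]] = None
    confidence: Optional[float] = None
    voxel_indices: Optional[frozenset] = None
    source_gt_id: Optional[int] = None

    def __post_init__(self) -> None:
        if self.volume_mm3 < 0:
            raise ValueError(f"lesion {self.lesion_id}: negative volume {self.volume_mm3}")
        if self.confidence is not None and not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"lesion {self.lesion_id}: confidence outside [0, 1]")


@dataclass
class PatientScan:
    """One patient's lesion set from one source (ground truth or detector)."""

    patient_id: str
    source: str
    lesions: list[Lesion] = field(default_factory=list)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.source not in _SOURCES:
            raise ValueError(f"source must be one of {_SOURCES}, got {self.source!r}")
        ids = [les.lesion_id for les in self.lesions]
        if len(ids) != len(set(ids)):
            raise ValueError(f"patient {self.patient_id}: duplicate lesion ids")

    @property
    def n_lesions(self) -> int:
        return len(self.lesions)

    @property
    def total_volume_mm3(self) -> float:
        return float(sum(les.volume_mm3 for les in self.lesions))

    @property
    def max_lesion_volume_mm3(self) -> float:
        return max((les.volume_mm3 for les in self.lesions), default=0.0)


@dataclass
class ClinicalRecord:
    """Actual treatment and targeted-therapy flags for one patient."""

    patient_id: str
    actual_treatment: str
    egfr_alk_mutant: bool = False
    symptomatic: bool = False
    primary_site: Optional[str] = None

    def __post_init__(self) -> None:
        if self.actual_treatment not in TREATMENTS:
            raise ValueError(
                f"patient {self.patient_id}: unknown treatment "
                f"{self.actual_treatment!r}; expected one of {TREATMENTS}"
            )


# ---------------------------------------------------------------------------
# NIfTI masks


def read_mask(path) -> VoxelGrid:
    """Read a 3D NIfTI label mask, taking voxel spacing from the header."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mask file not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if not np.allclose(data, rounded, atol=1e-6):
            raise ValueError(f"{path}: mask contains non-integer labels")
        data = rounded.astype(np.int32)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(s <= 0 for s in spacing):
        raise ValueError(f"{path}: non-positive voxel spacing {spacing}")
    return VoxelGrid(values=data, spacing=spacing)


def write_mask(grid: VoxelGrid, path) -> None:
    """Write a label grid as NIfTI with a diagonal spacing affine."""
    affine = np.diag(list(grid.spacing) + [1.0])
    img = nib.Nifti1Image(grid.values.astype(np.int16), affine)
    img.header.set_zooms(grid.spacing)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Connected components

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def _lesion_from_voxels(idx: np.ndarray, spacing, lesion_id: int) -> Lesion:
    # idx: (n, 3) voxel indices of one component
    vol = idx.shape[0] * float(np.prod(spacing))
    centroid = tuple(float(c) for c in (idx.mean(axis=0) * np.asarray(spacing)))
    return Lesion(
        lesion_id=lesion_id,
        volume_mm3=vol,
        equivalent_diameter_mm=equivalent_diameter(vol),
        centroid_mm=centroid,
        voxel_indices=frozenset(map(tuple, idx.tolist())),
    )


def extract_lesions(
    grid: VoxelGrid,
    connectivity: int = 26,
    patient_id: str = "",
    source: str = "ground_truth",
) -> PatientScan:
    """Split a mask into connected components and measure each one.

    Binary masks are labeled under the requested 3D connectivity (6, 18
    or 26 neighbours).  Masks that already carry distinct positive labels
    are taken as pre-individuated: each label becomes one lesion.
    Lesions are ordered by descending volume (ties broken by lexicographic
    centroid) and renumbered 1..n so output is deterministic.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be 6, 18 or 26, got {connectivity}")
    values = grid.values
    if values.size == 0 or values.max() == 0:
        return PatientScan(patient_id=patient_id, source=source, lesions=[], spacing=grid.spacing)
    if values.max() > 1:
        labeled = values
        n_comp = int(values.max())
        label_ids = [k for k in range(1, n_comp + 1) if np.any(labeled == k)]
    else:
        labeled, n_comp = ndimage.label(values > 0, structure=_STRUCTURES[connectivity])
        label_ids = list(range(1, n_comp + 1))
    lesions = []
    for k in label_ids:
        idx = np.argwhere(labeled == k)
        lesions.append(_lesion_from_voxels(idx, grid.spacing, lesion_id=k))
    lesions.sort(key=lambda les: (-les.volume_mm3, les.centroid_mm))
    lesions = [replace(les, lesion_id=i + 1) for i, les in enumerate(lesions)]
    return PatientScan(patient_id=patient_id, source=source, lesions=lesions, spacing=grid.spacing)


# ---------------------------------------------------------------------------
# Lesion tables (CSV)

_TABLE_COLUMNS = [
    "patient_id",
    "source",
    "lesion_id",
    "volume_mm3",
    "equivalent_diameter_mm",
    "confidence",
    "source_gt_id",
]
_REQUIRED_COLUMNS = ["patient_id", "source", "lesion_id", "volume_mm3"]


def write_lesion_table(scans: Sequence[PatientScan], path) -> None:
    """Write per-lesion scalar attributes as CSV (voxel sets are not serialized)."""
    rows = []
    for scan in scans:
        if not scan.lesions:
            continue
        for les in scan.lesions:
            rows.append(
                {
                    "patient_id": scan.patient_id,
                    "source": scan.source,
                    "lesion_id": les.lesion_id,
                    "volume_mm3": les.volume_mm3,
                    "equivalent_diameter_mm": les.equivalent_diameter_mm,
                    "confidence": les.confidence,
                    "source_gt_id": les.source_gt_id,
                }
            )
    df = pd.DataFrame(rows, columns=_TABLE_COLUMNS)
    # keep zero-lesion patients recoverable as explicit rows with lesion_id = 0
    empties = [
        {"patient_id": s.patient_id, "source": s.source, "lesion_id": 0, "volume_mm3": 0.0}
        for s in scans
        if not s.lesions
    ]
    if empties:
        df = pd.concat([df, pd.DataFrame(empties)], ignore_index=True)
    df.to_csv(path, index=False)


def read_lesion_table(path) -> list[PatientScan]:
    """Read a per-lesion CSV back into a list of PatientScan.

    Patients appear in file order; rows with ``lesion_id`` 0 denote a
    patient with no lesions.  Negative volumes are rejected with the
    offending row number.
    """
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    scans: dict[tuple[str, str], PatientScan] = {}
    for i, row in df.iterrows():
        pid, source = str(row["patient_id"]), str(row["source"])
        key = (pid, source)
        if key not in scans:
            scans[key] = PatientScan(patient_id=pid, source=source, lesions=[])
        if int(row["lesion_id"]) == 0:
            continue
        vol = float(row["volume_mm3"])
        if vol < 0:
            raise ValueError(f"{path}: row {i + 2} (patient {pid}): negative volume {vol}")
        conf = row.get("confidence")
        conf = None if conf is None or pd.isna(conf) else float(conf)
        src_gt = row.get("source_gt_id")
        src_gt = None if src_gt is None or pd.isna(src_gt) else int(src_gt)
        diam = row.get("equivalent_diameter_mm")
        diam = equivalent_diameter(vol) if diam is None or pd.isna(diam) else float(diam)
        scans[key].lesions.append(
            Lesion(
                lesion_id=int(row["lesion_id"]),
                volume_mm3=vol,
                equivalent_diameter_mm=diam,
                confidence=conf,
                source_gt_id=src_gt,
            )
        )
    out = list(scans.values())
    for scan in out:
        ids = [l.lesion_id for l in scan.lesions]
        if len(ids) != len(set(ids)):
            raise ValueError(f"{path}: duplicate lesion ids for patient {scan.patient_id}")
    return out


# ---------------------------------------------------------------------------
# Clinical records (CSV)


def write_clinical_table(records: Sequence[ClinicalRecord], path) -> None:
    df = pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "actual_treatment": [r.actual_treatment for r in records],
            "egfr_alk_mutant": [r.egfr_alk_mutant for r in records],
            "symptomatic": [r.symptomatic for r in records],
            "primary_site": [r.primary_site for r in records],
        }
    )
    df.to_csv(path, index=False)


def read_clinical_table(path) -> list[ClinicalRecord]:
    df = pd.read_csv(path)
    required = ["patient_id", "actual_treatment"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    def _flag(row, name):
        val = row.get(name)
        if val is None or pd.isna(val):
            return False
        if isinstance(val, str):
            return val.strip().lower() in ("true", "1", "yes")
        return bool(val)

    records = []
    for _, row in df.iterrows():
        site = row.get("primary_site")
        records.append(
            ClinicalRecord(
                patient_id=str(row["patient_id"]),
                actual_treatment=str(row["actual_treatment"]),
                egfr_alk_mutant=_flag(row, "egfr_alk_mutant"),
                symptomatic=_flag(row, "symptomatic"),
                primary_site=None if site is None or pd.isna(site) else str(site),
            )
        )
    return records
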