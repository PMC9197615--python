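"""Six cross-sectional morphometric parameters and their standardization.

Per section the pipeline reports: total cross-sectional area (CSA, mm^2),
area of cortical bone (ACB, mm^2), cortical index (CI = ACB / CSA),
periosteal border length (PBL, mm) and the mean and maximum cortical bone
thickness (CBT, mm).  Areas follow the point-counting convention (pixel
count x pitch^2); PBL counts periosteal surface points x pitch, with a
geometric (Crofton) perimeter logged alongside for diagnostics; thickness
at each periosteal point is its minimum Euclidean distance to the endosteal
surface.  Raw values may additionally be standardized by a stated reference
length, the femoral total length or the diaphyseal length.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from skimage.measure import perimeter_crofton

from .segmentation import CortexMask

__all__ = [
    "MorphometricRecord",
    "ThicknessProfile",
    "cross_sectional_area",
    "cortical_bone_area",
    "cortical_index",
    "periosteal_border_length",
    "geometric_perimeter",
    "thickness_profile",
    "standardize",
    "measure_specimen",
    "records_to_frame",
    "SolidSectionError",
]

#: levels measured by default; the proximal- and distal-most levels sit on
#: the landmarks themselves and are reserved for curvature
DEFAULT_MORPHOMETRIC_LEVELS = tuple(range(2, 10))


class SolidSectionError(ValueError):
    """Thickness requested on a section without a medullary cavity."""


@dataclass(frozen=True)
class ThicknessProfile:
    """Per-periosteal-point minimum distances to the endosteal surface."""

    per_point_mm: np.ndarray
    mean_mm: float
    max_mm: float


@dataclass(frozen=True)
class MorphometricRecord:
    """The six parameters of one cross-section (raw, physical units)."""

    specimen_id: str
    level: int
    csa: float  # mm^2
    acb: float  # mm^2
    ci: float
    pbl: float  # mm, point-count convention
    mean_cbt: Optional[float]  # mm; None for solid sections
    max_cbt: Optional[float]  # mm; None for solid sections
    pbl_geometric: float = float("nan")  # mm, polygonal (Crofton) perimeter
    threshold_hu: float = float("nan")
    solid: bool = False
    reference_length_mm: Optional[float] = None
    reference_length_kind: Optional[str] = None


def cross_sectional_area(mask: CortexMask) -> float:
    """Pixels enclosed by the periosteal perimeter x pitch^2 (mm^2)."""
    return float(mask.section_region.sum()) * mask.spacing**2


def cortical_bone_area(mask: CortexMask) -> float:
    """Pixels between the periosteal and endosteal perimeters x pitch^2."""
    return float(mask.cortex_region.sum()) * mask.spacing**2


def cortical_index(acb: float, csa: float) -> float:
    """Cortical bone occupancy ACB / CSA; 1.0 for a solid section."""
    if csa <= 0:
        raise ValueError("cross-sectional area must be positive")
    return acb / csa


def periosteal_border_length(mask: CortexMask) -> float:
    """Number of distinct periosteal surface points x pixel pitch (mm).

    The point-count convention undershoots oblique arcs by up to ~10 %
    (chessboard metric); use :func:`geometric_perimeter` for a
    length-faithful alternative.
    """
    pts = np.unique(mask.periosteal_points, axis=0)
    return float(len(pts)) * mask.spacing


def geometric_perimeter(mask: CortexMask) -> float:
    """Crofton-formula perimeter of the section region (mm)."""
    return float(perimeter_crofton(mask.section_region, directions=4)) * mask.spacing


def thickness_profile(mask: CortexMask) -> ThicknessProfile:
    """Minimum periosteal-to-endosteal distance at every periosteal point.

    For each periosteal point the Euclidean distances to *all* endosteal
    points are considered and the minimum is that point's cortical bone
    thickness; the mean and maximum over the periosteal surface summarize
    the section.  Distances are between pixel centres (no sub-pixel
    interpolation), queried through a k-d tree; a brute-force all-pairs
    scan gives identical values.
    """
    if mask.solid or len(mask.endosteal_points) == 0:
        raise SolidSectionError(
            f"{mask.specimen_id} level {mask.level}: no endosteal surface; "
            "thickness is undefined for solid sections"
        )
    peri = np.unique(mask.periosteal_points, axis=0).astype(float)
    endo = np.unique(mask.endosteal_points, axis=0).astype(float)
    dists, _ = cKDTree(endo).query(peri, k=1)
    per_point = dists * mask.spacing
    return ThicknessProfile(
        per_point_mm=per_point,
        mean_mm=float(per_point.mean()),
        max_mm=float(per_point.max()),
    )


def measure_section(mask: CortexMask) -> MorphometricRecord:
    """All six parameters for one segmented cross-section."""
    csa = cross_sectional_area(mask)
    acb = cortical_bone_area(mask)
    if mask.solid:
        mean_cbt = max_cbt = None
    else:
        prof = thickness_profile(mask)
        mean_cbt, max_cbt = prof.mean_mm, prof.max_mm
    return MorphometricRecord(
        specimen_id=mask.specimen_id,
        level=mask.level,
        csa=csa,
        acb=acb,
        ci=cortical_index(acb, csa),
        pbl=periosteal_border_length(mask),
        mean_cbt=mean_cbt,
        max_cbt=max_cbt,
        pbl_geometric=geometric_perimeter(mask),
        threshold_hu=mask.threshold_used,
        solid=mask.solid,
    )


def standardize(
    record: MorphometricRecord, reference_length: float, kind: str = "diaphyseal"
) -> MorphometricRecord:
    """Divide every parameter by a reference length (mm).

    ``kind`` records whether the femoral ``total`` length or the
    ``diaphyseal`` length was used.  Areas are divided directly as well, so
    standardized areas keep one leftover length dimension (mm^2/mm).  CI is
    dimensionless and is left untouched.
    """
    if reference_length <= 0:
        raise ValueError("reference length must be positive")
    if kind not in ("total", "diaphyseal"):
        raise ValueError("kind must be 'total' or 'diaphyseal'")
    scale = 1.0 / reference_length
    return replace(
        record,
        csa=record.csa * scale,
        acb=record.acb * scale,
        pbl=record.pbl * scale,
        mean_cbt=None if record.mean_cbt is None else record.mean_cbt * scale,
        max_cbt=None if record.max_cbt is None else record.max_cbt * scale,
        pbl_geometric=record.pbl_geometric * scale,
        reference_length_mm=float(reference_length),
        reference_length_kind=kind,
    )


def measure_specimen(
    sections,
    threshold: float,
    levels: Sequence[int] = DEFAULT_MORPHOMETRIC_LEVELS,
    reference_length: Optional[float] = None,
    reference_length_kind: str = "diaphyseal",
) -> list:
    """Segment and measure the requested levels of one specimen.

    ``sections`` maps level -> :class:`~femora.imaging.CrossSection` or is
    the list returned by :func:`~femora.imaging.extract_sections`.  Returns
    one raw :class:`MorphometricRecord` per requested level; when a
    reference length is given, standardized records are attached via
    :func:`records_to_frame`'s caller instead (standardize separately).
    """
    from .segmentation import segment_cortex

    by_level = (
        sections
        if isinstance(sections, dict)
        else {s.level: s for s in sections}
    )
    records = []
    for level in levels:
        if level not in by_level:
            raise KeyError(f"no section extracted for level {level}")
        mask = segment_cortex(by_level[level], threshold)
        records.append(measure_section(mask))
    return records


def records_to_frame(records: Iterable[MorphometricRecord]) -> pd.DataFrame:
    """Tidy table: one row per (specimen, level), columns in stated units."""
    rows = []
    for r in records:
        rows.append(
            {
                "specimen_id": r.specimen_id,
                "level": r.level,
                "csa_mm2": r.csa,
                "acb_mm2": r.acb,
                "ci": r.ci,
                "pbl_mm": r.pbl,
                "mean_cbt_mm": r.mean_cbt,
                "max_cbt_mm": r.max_cbt,
                "pbl_geometric_mm": r.pbl_geometric,
                "threshold_hu": r.threshold_hu,
                "solid": r.solid,
                "reference_length_mm": r.reference_length_mm,
                "reference_length_kind": r.reference_length_kind,
            }
        )
    return pd.DataFrame(rows)
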