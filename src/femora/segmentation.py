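"""Histogram-derived cortical threshold and per-section cortex masks.

The HU values of all ten diaphyseal cross-sections are pooled into one
frequency table.  In a single-bone scan this histogram is bimodal: a large
air peak near -1000 HU and a bone peak well above zero.  The cortical
threshold is the midpoint of the two peak means; pixels at or above it are
bone.  The cortex is the largest 8-connected bone component, the section is
that component with its interior filled, and the medullary cavity is the
largest interior hole (4-connected), so that small trabecular voids are
absorbed into the cortex.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from ._tracing import inner_boundary, moore_trace
from .imaging import CrossSection

__all__ = [
    "HUHistogram",
    "CortexMask",
    "pool_histogram",
    "derive_threshold",
    "segment_cortex",
    "UnimodalHistogramError",
    "SegmentationError",
]

#: everything below this HU is considered candidate air when locating peaks
AIR_SEARCH_MAX_HU = -500.0
#: everything above this HU is considered candidate bone when locating peaks
BONE_SEARCH_MIN_HU = 200.0
#: half-width, in bins, of the window used to refine each peak mean
PEAK_REFINE_BINS = 5


class UnimodalHistogramError(ValueError):
    """Pooled histogram has no separate bone peak (no bone in the scan?)."""


class SegmentationError(ValueError):
    """Thresholding produced no usable cortical region."""


@dataclass
class HUHistogram:
    """Pooled HU frequency table of the ten levels with its two peak means."""

    bin_width: float
    bin_edges: np.ndarray
    counts: np.ndarray
    peak1_mean: float  # air
    peak2_mean: float  # bone

    def __post_init__(self) -> None:
        if self.peak1_mean >= self.peak2_mean:
            raise UnimodalHistogramError(
                "air peak must lie below bone peak "
                f"({self.peak1_mean} >= {self.peak2_mean})"
            )
        if not -1150 <= self.peak1_mean <= -850:
            raise UnimodalHistogramError(
                f"air peak at {self.peak1_mean:.0f} HU is not within "
                "-1000 +/- 150; the background is not air"
            )


@dataclass
class CortexMask:
    """Per-section segmentation result.

    ``section_region`` is everything enclosed by the periosteal perimeter
    (cavity filled); ``cortex_region`` is the bone between the periosteal
    and endosteal perimeters.  Boundary point lists are ordered clockwise
    (row, col) pixel coordinates forming closed 8-connected loops;
    ``endosteal_points`` is empty for solid sections.
    """

    section_region: np.ndarray
    cortex_region: np.ndarray
    periosteal_points: np.ndarray
    endosteal_points: np.ndarray
    spacing: float
    threshold_used: float
    solid: bool = False
    level: int = 0
    specimen_id: str = "specimen"
    z_index: int = 0
    slice_thickness: float = 0.5

    @property
    def cavity_region(self) -> np.ndarray:
        return self.section_region & ~self.cortex_region

    @property
    def z_mm(self) -> float:
        return self.z_index * self.slice_thickness


def _refine_peak(centers: np.ndarray, counts: np.ndarray, idx: int) -> float:
    lo = max(0, idx - PEAK_REFINE_BINS)
    hi = min(len(centers), idx + PEAK_REFINE_BINS + 1)
    w = counts[lo:hi].astype(float)
    return float(np.average(centers[lo:hi], weights=w))


def pool_histogram(sections, bin_width: float = 10.0) -> HUHistogram:
    """Pool all pixels of all sections into one HU frequency table.

    The air peak is the highest-count bin below -500 HU and the bone peak
    the highest-count bin above +200 HU; each mean is refined as the
    count-weighted bin-centre average over +/-5 bins, which keeps the
    estimate robust to marrow and soft-tissue mass in the mid range.
    """
    if len(sections) == 0:
        raise ValueError("at least one cross-section is required")
    vals = np.concatenate([np.asarray(s.pixels).ravel() for s in sections])
    lo = np.floor(vals.min() / bin_width) * bin_width
    # one spare bin above the maximum so the top value is not absorbed into
    # a right-closed final bin (which would bias the bone peak low)
    hi = np.ceil(vals.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, edges = np.histogram(vals, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])

    air_bins = centers < AIR_SEARCH_MAX_HU
    bone_bins = centers > BONE_SEARCH_MIN_HU
    if not air_bins.any() or counts[air_bins].max() == 0:
        raise UnimodalHistogramError("no air peak below -500 HU")
    if not bone_bins.any() or counts[bone_bins].max() == 0:
        raise UnimodalHistogramError(
            "no bone peak above +200 HU: histogram is unimodal"
        )
    air_idx = int(np.flatnonzero(air_bins)[np.argmax(counts[air_bins])])
    bone_idx = int(np.flatnonzero(bone_bins)[np.argmax(counts[bone_bins])])
    return HUHistogram(
        bin_width=float(bin_width),
        bin_edges=edges,
        counts=counts,
        peak1_mean=_refine_peak(centers, counts, air_idx),
        peak2_mean=_refine_peak(centers, counts, bone_idx),
    )


def derive_threshold(hist: HUHistogram) -> float:
    """Cortical threshold: midpoint of the air and bone peak means."""
    return 0.5 * (hist.peak1_mean + hist.peak2_mean)


def segment_cortex(section: CrossSection, threshold: float) -> CortexMask:
    """Threshold one cross-section and extract cortex, section and cavity.

    Foreground is ``pixels >= threshold``; the cortex is its largest
    8-connected component (isolated specks discarded); the section region
    fills all interior holes; the medullary cavity is the largest
    4-connected hole, smaller holes being merged into the cortex.  Sections
    without any interior hole are flagged ``solid`` and carry no endosteal
    boundary, leaving their thickness undefined.
    """
    fg = np.asarray(section.pixels) >= threshold
    if not fg.any():
        raise SegmentationError(
            f"no pixels at or above threshold {threshold:.1f} HU"
        )
    labels, n = ndi.label(fg, structure=np.ones((3, 3), dtype=bool))
    sizes = np.bincount(labels.ravel())[1:]
    cortex = labels == (int(np.argmax(sizes)) + 1)

    # holes under 4-connected background duality
    section_region = ndi.binary_fill_holes(
        cortex, structure=ndi.generate_binary_structure(2, 1)
    )
    holes = section_region & ~cortex
    solid = not holes.any()
    if solid:
        cavity = np.zeros_like(cortex)
        endo_pts = np.empty((0, 2), dtype=np.intp)
        warnings.warn(
            f"{section.specimen_id} level {section.level}: solid section "
            "(no medullary cavity); thickness undefined",
            stacklevel=2,
        )
    else:
        hlabels, hn = ndi.label(holes, structure=ndi.generate_binary_structure(2, 1))
        hsizes = np.bincount(hlabels.ravel())[1:]
        cavity = hlabels == (int(np.argmax(hsizes)) + 1)
        endo_pts = moore_trace(cavity)
    cortex_region = section_region & ~cavity
    peri_pts = moore_trace(section_region)
    return CortexMask(
        section_region=section_region,
        cortex_region=cortex_region,
        periosteal_points=peri_pts,
        endosteal_points=endo_pts,
        spacing=section.spacing,
        threshold_used=float(threshold),
        solid=solid,
        level=section.level,
        specimen_id=section.specimen_id,
        z_index=section.z_index,
        slice_thickness=section.slice_thickness,
    )


def boundary_points_mm(points: np.ndarray, spacing: float) -> np.ndarray:
    """Convert (row, col) boundary pixels to (x_mm, y_mm) columns."""
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        return np.empty((0, 2))
    return np.column_stack([pts[:, 1] * spacing, pts[:, 0] * spacing])


def surface_layer(mask: np.ndarray) -> np.ndarray:
    """Foreground pixels with a 4-connected background neighbour."""
    return inner_boundary(mask)
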