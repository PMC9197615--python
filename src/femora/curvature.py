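"""Central mass distribution (CMD), deviation profiles and lateral patterns.

The CMD of a cross-section is the intersection of the vertical and
horizontal lines that each split the section area into two equal halves —
an equal-area centre, which differs from the centroid for asymmetric
sections.  Connecting the CMDs of levels 1..9 gives the CMD curve; per-level
x (lateral) and y (anterior) shifts are measured from the straight baseline
through the level-1 and level-9 CMDs, so the shifts vanish at both
endpoints by construction.  The sign pattern of the lateral shifts over the
interior levels classifies each femur as primary-lateral, primary-medial or
one of the two S-shaped curvature types.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .segmentation import CortexMask

__all__ = [
    "CMDPoint",
    "DeviationProfile",
    "compute_cmd",
    "equal_area_coordinate",
    "deviation_profile",
    "classify_lateral_pattern",
    "pattern_table",
    "PATTERNS",
]

#: the four published lateral-curvature types plus the undecidable class
PATTERNS = (
    "primary_lateral",
    "primary_medial",
    "s_lateral_medial",
    "s_medial_lateral",
    "indeterminate",
)

#: default deadband (mm): |dx| below this is treated as on-axis
DEFAULT_EPSILON_MM = 0.3

#: levels whose CMDs define the curve (level 10 is excluded)
CURVATURE_LEVELS = tuple(range(1, 10))


@dataclass(frozen=True)
class CMDPoint:
    """Equal-area centre of one level, in mm (x lateral+, y anterior+)."""

    level: int
    x: float
    y: float
    z: float


@dataclass
class DeviationProfile:
    """Per-level CMD shifts from the level-1 -> level-9 baseline."""

    levels: np.ndarray
    dx: np.ndarray  # mm, lateral+ / medial-
    dy: np.ndarray  # mm, anterior+ / posterior-
    normalized_dx: np.ndarray
    normalized_dy: np.ndarray
    reference_length_mm: float
    anterior_degree: float  # max normalized dy over levels
    pattern: Optional[str] = None
    specimen_id: str = "specimen"


def equal_area_coordinate(weights: np.ndarray) -> float:
    """Sub-pixel coordinate splitting a 1-D mass profile into equal halves.

    Pixel ``j`` spans ``[j - 0.5, j + 0.5]``.  The cumulative sum is
    linearly interpolated within the column where it crosses half the total
    mass.  When the half-mass point falls exactly on a run of empty columns
    (e.g. two disjoint equal blobs) the split line is placed at the middle
    of the ambiguous interval, which also makes the result exactly
    mirror-symmetric.
    """
    a = np.asarray(weights, dtype=float)
    total = a.sum()
    if total <= 0:
        raise ValueError("empty region: no mass to split")
    half = total / 2.0

    def one_sided(arr: np.ndarray) -> float:
        c = np.cumsum(arr)
        j = int(np.searchsorted(c, half, side="left"))
        prev = c[j - 1] if j > 0 else 0.0
        f = (half - prev) / arr[j] if arr[j] > 0 else 0.0
        return j - 0.5 + f

    lo = one_sided(a)
    # mirror the right-hand scan back into left-hand coordinates
    hi = len(a) - 1 - one_sided(a[::-1])
    return 0.5 * (lo + hi)


def compute_cmd(mask: CortexMask, region: str = "section") -> CMDPoint:
    """Equal-area centre of one segmented section, in mm.

    ``region`` selects the mass over which the split is computed: the
    filled ``"section"`` region (default — the whole cross-sectional
    figure) or the ``"cortex"`` pixels only.
    """
    grid = mask.section_region if region == "section" else mask.cortex_region
    if not grid.any():
        raise ValueError("empty section region")
    x_px = equal_area_coordinate(grid.sum(axis=0))  # column masses
    y_px = equal_area_coordinate(grid.sum(axis=1))  # row masses
    return CMDPoint(
        level=mask.level,
        x=x_px * mask.spacing,
        y=y_px * mask.spacing,
        z=mask.z_mm,
    )


def deviation_profile(
    cmds: Sequence[CMDPoint],
    reference_length: float,
    specimen_id: str = "specimen",
) -> DeviationProfile:
    """Shifts of the level 1..9 CMDs from the 1 -> 9 straight baseline.

    The baseline is the 3-D line through the level-1 and level-9 CMDs
    parameterized by z; ``dx``/``dy`` are the per-axis residuals, exactly
    zero at both endpoints.  ``anterior_degree`` is the maximum normalized
    anterior shift, the scalar summary of the anterior bow.
    """
    if reference_length <= 0:
        raise ValueError("reference length must be positive")
    cmds = sorted(cmds, key=lambda c: c.level)
    levels = [c.level for c in cmds]
    if levels != list(CURVATURE_LEVELS):
        raise ValueError(
            f"curvature needs the nine CMDs of levels 1..9, got {levels}"
        )
    z = np.array([c.z for c in cmds])
    x = np.array([c.x for c in cmds])
    y = np.array([c.y for c in cmds])
    if z[-1] == z[0]:
        raise ValueError("level-1 and level-9 sections are at the same z")
    t = (z - z[0]) / (z[-1] - z[0])
    dx = x - (x[0] + t * (x[-1] - x[0]))
    dy = y - (y[0] + t * (y[-1] - y[0]))
    # the endpoints are zero by construction; make it exact against rounding
    dx[0] = dx[-1] = 0.0
    dy[0] = dy[-1] = 0.0
    ndx = dx / reference_length
    ndy = dy / reference_length
    return DeviationProfile(
        levels=np.array(levels),
        dx=dx,
        dy=dy,
        normalized_dx=ndx,
        normalized_dy=ndy,
        reference_length_mm=float(reference_length),
        anterior_degree=float(ndy.max()),
        specimen_id=specimen_id,
    )


def classify_lateral_pattern(
    profile: DeviationProfile, epsilon: float = DEFAULT_EPSILON_MM
) -> str:
    """Four-way lateral-curvature taxonomy from the signs of dx.

    Lateral shifts at the interior levels 2..8 are sign-quantized with an
    ``epsilon`` deadband (mm).  All non-negative with at least one positive
    -> primary lateral bow; all non-positive with at least one negative ->
    primary medial bow; exactly one sign change -> S-shaped, named by the
    proximal limb (lateral-at-top or medial-at-top); everything else
    (all on-axis, or more than one sign change) is indeterminate.
    """
    interior = profile.dx[1:-1]
    signs = np.sign(np.where(np.abs(interior) < epsilon, 0.0, interior))
    nonzero = signs[signs != 0]
    if nonzero.size == 0:
        pattern = "indeterminate"
    elif (signs >= 0).all():
        pattern = "primary_lateral"
    elif (signs <= 0).all():
        pattern = "primary_medial"
    else:
        changes = int(np.count_nonzero(np.diff(nonzero) != 0))
        if changes == 1:
            pattern = "s_lateral_medial" if nonzero[0] > 0 else "s_medial_lateral"
        else:
            pattern = "indeterminate"
    profile.pattern = pattern
    return pattern


def pattern_table(profiles_by_cohort: Mapping[str, Iterable]) -> pd.DataFrame:
    """Cohort x pattern contingency table of classified profiles.

    Accepts a mapping of cohort -> iterable of classified
    :class:`DeviationProfile` (or plain pattern strings).  Indeterminate
    profiles are counted in their own column rather than silently dropped.
    """
    table = pd.DataFrame(
        0, index=list(profiles_by_cohort), columns=list(PATTERNS), dtype=int
    )
    for cohort, profiles in profiles_by_cohort.items():
        for item in profiles:
            pattern = item if isinstance(item, str) else item.pattern
            if pattern is None:
                raise ValueError("profile has not been classified yet")
            if pattern not in PATTERNS:
                raise ValueError(f"unknown pattern {pattern!r}")
            table.loc[cohort, pattern] += 1
    return table
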