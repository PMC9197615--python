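"""CT volume loading, diaphyseal level planning and cross-section extraction.

A femur is scanned as a stack of axial slices in Hounsfield units (HU).  The
diaphyseal span between two user-supplied landmarks — the lower end of the
lesser trochanter proximally and the adductor tubercle distally — is divided
into nine equal segments, and the ten bounding cross-sections are labelled
level 1 (proximal) to level 10 (distal).

Axis convention after loading: axis 0 is z (proximal -> distal), axis 1 is y
(posterior -> anterior), axis 2 is x (medial -> lateral).  Left femurs are
mirrored about the sagittal plane on load so that +x is lateral for every
specimen and left/right cohorts can be pooled.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "CTVolume",
    "LevelPlan",
    "CrossSection",
    "load_volume",
    "plan_levels",
    "extract_sections",
]

#: in-plane pixel pitch range (mm) of the clinical protocol the pipeline
#: was designed around; loaders warn outside it
TYPICAL_SPACING_MM = (0.158, 0.292)
#: hard plausibility bounds for clinical femur CT in-plane spacing (mm)
PLAUSIBLE_SPACING_MM = (0.1, 0.5)


class VolumeFormatError(ValueError):
    """Raised when a CT input cannot be loaded consistently."""


@dataclass
class CTVolume:
    """A 3-D Hounsfield-unit grid with physical voxel spacing.

    ``intensities`` is indexed ``[z, y, x]``; ``in_plane_spacing`` is the
    (isotropic) pixel pitch within a slice in mm and ``slice_thickness`` the
    z step in mm.
    """

    intensities: np.ndarray
    in_plane_spacing: float
    slice_thickness: float
    side: str = "right"
    specimen_id: str = "specimen"

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3:
            raise VolumeFormatError("intensities must be a 3-D array")
        if self.in_plane_spacing <= 0 or self.slice_thickness <= 0:
            raise VolumeFormatError("voxel spacing must be positive")
        if self.side not in ("left", "right"):
            raise VolumeFormatError(f"side must be left or right, got {self.side!r}")
        lo, hi = PLAUSIBLE_SPACING_MM
        if not lo <= self.in_plane_spacing <= hi:
            warnings.warn(
                f"in-plane spacing {self.in_plane_spacing} mm is outside the "
                f"plausible clinical range [{lo}, {hi}] mm",
                stacklevel=2,
            )
        elif not TYPICAL_SPACING_MM[0] <= self.in_plane_spacing <= TYPICAL_SPACING_MM[1]:
            warnings.warn(
                f"in-plane spacing {self.in_plane_spacing} mm is outside the "
                f"protocol range [{TYPICAL_SPACING_MM[0]}, {TYPICAL_SPACING_MM[1]}] mm",
                stacklevel=2,
            )

    @property
    def n_slices(self) -> int:
        return self.intensities.shape[0]

    def check_air_background(self) -> float:
        """Mode of the HU histogram (10-HU bins); warn unless near -1000.

        Air dominates a single-bone scan, so the global mode should sit at
        the air attenuation value.  Returns the modal HU.
        """
        vals = self.intensities.ravel()
        lo = np.floor(vals.min() / 10) * 10
        hi = np.ceil(vals.max() / 10) * 10 + 10
        edges = np.arange(lo, hi + 1, 10.0)
        counts, _ = np.histogram(vals, bins=edges)
        mode = float(edges[int(np.argmax(counts))] + 5.0)
        if not -1100 <= mode <= -900:
            warnings.warn(
                f"background HU mode {mode:.0f} is not within -1000 +/- 100; "
                "check HU rescale metadata",
                stacklevel=2,
            )
        return mode


@dataclass(frozen=True)
class LevelPlan:
    """Slice indices of the ten diaphyseal levels (level 1 proximal)."""

    z_upper: int
    z_lower: int
    level_positions: tuple = field(default=())

    def position(self, level: int) -> int:
        if not 1 <= level <= 10:
            raise ValueError(f"level must be in 1..10, got {level}")
        return self.level_positions[level - 1]


@dataclass
class CrossSection:
    """A single axial HU slice at one diaphyseal level."""

    pixels: np.ndarray
    spacing: float
    level: int
    specimen_id: str = "specimen"
    z_index: int = 0
    slice_thickness: float = 0.5

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("section pixels must be 2-D")
        if not 1 <= self.level <= 10:
            raise ValueError(f"level must be in 1..10, got {self.level}")

    @property
    def z_mm(self) -> float:
        return self.z_index * self.slice_thickness


def _load_bundle(path: Path) -> CTVolume:
    meta_path = path / "meta.json"
    with open(meta_path) as fh:
        meta = json.load(fh)
    for key in ("spacing_mm", "slice_thickness_mm"):
        if key not in meta:
            raise VolumeFormatError(f"raw bundle missing {key!r} in {meta_path}")
    arr = np.load(path / meta.get("array", "volume.npy"))
    return CTVolume(
        intensities=arr,
        in_plane_spacing=float(meta["spacing_mm"]),
        slice_thickness=float(meta["slice_thickness_mm"]),
        side=meta.get("side", "right"),
        specimen_id=meta.get("specimen_id", path.name),
    )


def _load_dicom(path: Path) -> CTVolume:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".dcm", ".ima"))
    if not files:
        files = sorted(p for p in path.iterdir() if p.is_file())
    datasets = [pydicom.dcmread(str(p)) for p in files]
    if not datasets:
        raise VolumeFormatError(f"no DICOM slices found in {path}")

    series = {getattr(ds, "SeriesInstanceUID", None) for ds in datasets}
    if len(series) > 1:
        raise VolumeFormatError("mixed DICOM series in one directory")

    spacings = set()
    for ds in datasets:
        if "PixelSpacing" not in ds:
            raise VolumeFormatError("DICOM slice lacks PixelSpacing metadata")
        spacings.add((float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1])))
    if len(spacings) > 1:
        raise VolumeFormatError("inconsistent in-plane spacing across slices")
    sp_row, sp_col = spacings.pop()
    if abs(sp_row - sp_col) > 1e-6 * max(sp_row, sp_col):
        raise VolumeFormatError("anisotropic in-plane spacing is not supported")

    def z_of(ds):
        if "ImagePositionPatient" in ds:
            return float(ds.ImagePositionPatient[2])
        return float(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=z_of)
    zs = np.array([z_of(ds) for ds in datasets])
    if len(zs) > 1:
        gaps = np.diff(zs)
        thickness = float(np.median(np.abs(gaps)))
        if thickness <= 0 or np.any(np.abs(np.abs(gaps) - thickness) > 0.01 * thickness):
            raise VolumeFormatError("slice spacing varies by more than 1%")
    else:
        thickness = float(getattr(datasets[0], "SliceThickness", 0.5))

    slices = []
    for ds in datasets:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(ds.pixel_array.astype(np.float32) * slope + intercept)
    vol = np.stack(slices, axis=0)

    side = "right"
    meta_path = path / "meta.json"
    if meta_path.exists():
        with open(meta_path) as fh:
            side = json.load(fh).get("side", "right")
    return CTVolume(
        intensities=vol,
        in_plane_spacing=sp_row,
        slice_thickness=thickness,
        side=side,
        specimen_id=path.name,
    )


def load_volume(path, check_background: bool = True) -> CTVolume:
    """Load a CT volume from a DICOM series directory or a raw bundle.

    A raw bundle is a directory holding ``volume.npy`` (HU, ``[z, y, x]``)
    plus a ``meta.json`` sidecar with ``spacing_mm``, ``slice_thickness_mm``
    and optionally ``side`` and ``specimen_id``.  DICOM slices are sorted
    proximal -> distal and RescaleSlope/RescaleIntercept are applied.  Left
    femurs are mirrored about the sagittal axis so that +x is lateral.
    """
    path = Path(path)
    if not path.is_dir():
        raise VolumeFormatError(f"{path} is not a directory")
    if (path / "meta.json").exists() and (
        (path / "volume.npy").exists()
        or any(p.suffix == ".npy" for p in path.iterdir())
    ):
        vol = _load_bundle(path)
    else:
        vol = _load_dicom(path)
    if vol.side == "left":
        vol.intensities = vol.intensities[:, :, ::-1].copy()
    if check_background:
        vol.check_air_background()
    return vol


def plan_levels(volume: CTVolume, z_upper: int, z_lower: int) -> LevelPlan:
    """Place ten equally spaced levels between the two diaphyseal landmarks.

    ``position(k) = round(z_upper + (k - 1) * (z_lower - z_upper) / 9)``,
    half-up, so level 1 sits on the lesser-trochanter landmark and level 10
    on the adductor-tubercle landmark.
    """
    if not (0 <= z_upper < volume.n_slices and 0 <= z_lower < volume.n_slices):
        raise ValueError("landmarks must lie inside the volume")
    if z_upper >= z_lower:
        raise ValueError(
            f"proximal landmark (z={z_upper}) must be above distal (z={z_lower})"
        )
    if z_lower - z_upper < 18:
        raise ValueError(
            "landmark span is too short to place 10 distinct levels "
            f"({z_lower - z_upper} slices < 18)"
        )
    span = z_lower - z_upper
    positions = tuple(
        int(np.floor(z_upper + (k - 1) * span / 9 + 0.5)) for k in range(1, 11)
    )
    return LevelPlan(z_upper=z_upper, z_lower=z_lower, level_positions=positions)


def extract_sections(volume: CTVolume, plan: LevelPlan) -> list:
    """One :class:`CrossSection` per level 1..10, spacing propagated."""
    sections = []
    for level, z in enumerate(plan.level_positions, start=1):
        sections.append(
            CrossSection(
                pixels=volume.intensities[z].copy(),
                spacing=volume.in_plane_spacing,
                level=level,
                specimen_id=volume.specimen_id,
                z_index=z,
                slice_thickness=volume.slice_thickness,
            )
        )
    return sections
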