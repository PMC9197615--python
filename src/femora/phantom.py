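"""Synthetic femur-diaphysis CT phantoms with analytic ground truth.

Each phantom is a bent hollow cortical tube in air: every axial slice is an
annulus (circular by default, optionally elliptical) of cortical-bone HU
around a marrow-filled cavity, centred on a curved centreline.  The
anterior bow is a half-sine over the level-1..level-9 span — a primary
curve with its apex mid-diaphysis — and the lateral curvature follows one
of four modes: primary lateral / primary medial (signed half-sine) or the
two S shapes (signed full sine).  A posterior angular thickening of the
cortex emulates the linea aspera.  Ground truth (areas, thicknesses, CMD
centreline, deviation profile, pattern label) is evaluated from the closed
forms of the specification, never from the rendered voxels, so rendering
followed by measurement is a genuine recovery test.

HU defaults mimic the bimodal single-bone histogram: air -1000, marrow
+100, cortical bone +1200, Gaussian noise SD 50.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .imaging import CTVolume, plan_levels

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "render_phantom",
    "render_cohort",
    "annulus_section",
    "save_bundle",
    "LATERAL_MODES",
]

LATERAL_MODES = (
    "none",
    "primary_lateral",
    "primary_medial",
    "s_lateral_medial",
    "s_medial_lateral",
)

#: pattern expected from a noiseless classification of each lateral mode
MODE_TO_PATTERN = {
    "none": "indeterminate",
    "primary_lateral": "primary_lateral",
    "primary_medial": "primary_medial",
    "s_lateral_medial": "s_lateral_medial",
    "s_medial_lateral": "s_medial_lateral",
}


@dataclass(frozen=True)
class PhantomSpec:
    """Generator parameters for one phantom femur.

    Radii and thickness may be scalars or per-slice arrays (mm).  The
    centreline offsets are parameterized by ``s = (z - z1) / (z9 - z1)``
    where z1/z9 are the planned level-1/level-9 slice positions, so both
    curvature components vanish exactly at the baseline endpoints.
    """

    n_slices: int = 91
    in_plane_spacing: float = 0.2  # mm / pixel
    slice_thickness: float = 0.5  # mm
    outer_rx: object = 13.0  # mm, semi-axis along x
    outer_ry: object = 13.0  # mm, semi-axis along y
    thickness: object = 5.0  # mm cortical thickness
    ridge_angle_deg: float = 270.0  # posterior (-y) linea-aspera centre
    ridge_width_deg: float = 0.0  # 0 disables the ridge
    ridge_extra_mm: float = 0.0
    bow_mm: float = 4.0  # anterior half-sine amplitude
    lateral_mode: str = "none"
    lateral_mm: float = 2.0
    cavity_offset_mm: tuple = (0.0, 0.0)  # (x, y) endosteal eccentricity
    hu_air: float = -1000.0
    hu_marrow: float = 100.0
    hu_bone: float = 1200.0
    noise_sd: float = 50.0
    seed: int = 0
    side: str = "right"
    specimen_id: str = "phantom"
    z_upper: int = 0
    z_lower: Optional[int] = None  # default: last slice

    def __post_init__(self):
        if self.lateral_mode not in LATERAL_MODES:
            raise ValueError(f"unknown lateral mode {self.lateral_mode!r}")
        if not (self.hu_bone > self.hu_marrow > self.hu_air):
            raise ValueError("HU ordering must be bone > marrow > air")
        if self.bow_mm < 0 or self.lateral_mm < 0:
            raise ValueError("curvature amplitudes must be nonnegative")

    def landmarks(self):
        z_lo = self.n_slices - 1 if self.z_lower is None else self.z_lower
        return self.z_upper, z_lo

    def per_slice(self, value) -> np.ndarray:
        arr = np.asarray(value, dtype=float)
        if arr.ndim == 0:
            return np.full(self.n_slices, float(arr))
        if arr.shape != (self.n_slices,):
            raise ValueError("per-slice profile must have one value per slice")
        return arr


@dataclass
class PhantomTruth:
    """Analytic per-level ground truth of a rendered phantom."""

    per_level: pd.DataFrame
    pattern: str
    anterior_degree_mm: float  # max true anterior deviation over levels 1..9
    spec: PhantomSpec = field(repr=False, default=None)


def _lateral_shape(mode: str, s: np.ndarray) -> np.ndarray:
    if mode == "none":
        return np.zeros_like(s)
    if mode == "primary_lateral":
        return np.sin(np.pi * s)
    if mode == "primary_medial":
        return -np.sin(np.pi * s)
    if mode == "s_lateral_medial":
        return np.sin(2 * np.pi * s)
    if mode == "s_medial_lateral":
        return -np.sin(2 * np.pi * s)
    raise ValueError(mode)


def _centerline(spec: PhantomSpec, z: np.ndarray):
    z_up, z_lo = spec.landmarks()
    span = z_lo - z_up
    if span < 18:
        raise ValueError("landmark span too short for a level plan")
    # level-1 / level-9 planned positions (half-up rounding, as in planning)
    z1 = int(np.floor(z_up + 0.5))
    z9 = int(np.floor(z_up + 8 * span / 9 + 0.5))
    s = (z - z1) / (z9 - z1)
    cx = spec.lateral_mm * _lateral_shape(spec.lateral_mode, s)
    cy = spec.bow_mm * np.sin(np.pi * s)
    return cx, cy


def _grid_half_extent(spec: PhantomSpec) -> float:
    rx = spec.per_slice(spec.outer_rx).max()
    ry = spec.per_slice(spec.outer_ry).max()
    wobble = max(spec.bow_mm, spec.lateral_mm) + max(
        abs(spec.cavity_offset_mm[0]), abs(spec.cavity_offset_mm[1])
    )
    return max(rx, ry) + wobble + 3.0


def render_phantom(spec: PhantomSpec):
    """Render a phantom volume and derive its analytic truth table.

    Returns ``(CTVolume, PhantomTruth)``.  Pixel membership is decided at
    pixel centres; noise is Gaussian with the spec's seed, so a fixed spec
    renders bit-identically.
    """
    sp = spec.in_plane_spacing
    half = _grid_half_extent(spec)
    n_half = int(np.ceil(half / sp))
    n_px = 2 * n_half + 1
    coords = (np.arange(n_px) - n_half) * sp
    X, Y = np.meshgrid(coords, coords)  # Y along rows (anterior+), X cols

    z = np.arange(spec.n_slices)
    cx, cy = _centerline(spec, z.astype(float))
    rxs = spec.per_slice(spec.outer_rx)
    rys = spec.per_slice(spec.outer_ry)
    ts = spec.per_slice(spec.thickness)
    if np.any(ts >= np.minimum(rxs, rys)):
        raise ValueError("cortical thickness must be below the outer radii")
    offx, offy = spec.cavity_offset_mm

    theta_c = np.deg2rad(spec.ridge_angle_deg)
    half_w = np.deg2rad(spec.ridge_width_deg) / 2.0
    use_ridge = spec.ridge_extra_mm > 0 and spec.ridge_width_deg > 0

    vol = np.full((spec.n_slices, n_px, n_px), spec.hu_air, dtype=np.float32)
    for k in range(spec.n_slices):
        dx = X - cx[k]
        dy = Y - cy[k]
        outer = (dx / rxs[k]) ** 2 + (dy / rys[k]) ** 2 <= 1.0
        ex = dx - offx
        ey = dy - offy
        if rxs[k] == rys[k] and (use_ridge or offx or offy):
            # circular slice with angular thickness profile and/or offset
            r = np.hypot(ex, ey)
            t_eff = np.full_like(r, ts[k])
            if use_ridge:
                ang = np.arctan2(ey, ex)
                d = np.abs((ang - theta_c + np.pi) % (2 * np.pi) - np.pi)
                t_eff = t_eff + np.where(d <= half_w, spec.ridge_extra_mm, 0.0)
            inner = r <= rxs[k] - t_eff
        else:
            inner = (ex / (rxs[k] - ts[k])) ** 2 + (ey / (rys[k] - ts[k])) ** 2 <= 1.0
        sl = vol[k]
        sl[outer] = spec.hu_bone
        sl[outer & inner] = spec.hu_marrow
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        vol += rng.normal(0.0, spec.noise_sd, size=vol.shape).astype(np.float32)

    volume = CTVolume(
        intensities=vol,
        in_plane_spacing=sp,
        slice_thickness=spec.slice_thickness,
        side=spec.side,
        specimen_id=spec.specimen_id,
    )
    truth = _phantom_truth(spec, n_half)
    if spec.side == "left":
        # the loader mirrors left volumes; truth is stated in the
        # side-normalized (+x lateral) frame already, nothing to do
        pass
    return volume, truth


def _phantom_truth(spec: PhantomSpec, n_half: int) -> PhantomTruth:
    sp = spec.in_plane_spacing
    z_up, z_lo = spec.landmarks()
    span = z_lo - z_up
    zpos = np.array(
        [int(np.floor(z_up + (k - 1) * span / 9 + 0.5)) for k in range(1, 11)]
    )
    cx, cy = _centerline(spec, zpos.astype(float))
    rxs = spec.per_slice(spec.outer_rx)[zpos]
    rys = spec.per_slice(spec.outer_ry)[zpos]
    ts = spec.per_slice(spec.thickness)[zpos]
    offx, offy = spec.cavity_offset_mm
    off = float(np.hypot(offx, offy))
    circular = np.all(rxs == rys)
    use_ridge = spec.ridge_extra_mm > 0 and spec.ridge_width_deg > 0

    rows = []
    for i, level in enumerate(range(1, 11)):
        rx, ry, t = rxs[i], rys[i], ts[i]
        csa = np.pi * rx * ry
        acb = np.pi * rx * ry - np.pi * (rx - t) * (ry - t)
        mean_cbt = max_cbt = min_cbt = np.nan
        if circular:
            frac = spec.ridge_width_deg / 360.0 if use_ridge else 0.0
            extra = spec.ridge_extra_mm if use_ridge else 0.0
            # angular-average thickness; cavity area follows the same profile
            acb = np.pi * rx**2 - (
                np.pi * (rx - t) ** 2 * (1 - frac) + np.pi * (rx - t - extra) ** 2 * frac
            )
            if off == 0:
                mean_cbt = t + extra * frac
                max_cbt = t + extra
                min_cbt = t
            else:
                # eccentric annulus, uniform thickness profile only
                min_cbt = t - off
                max_cbt = t + off
        pbl_true = 2 * np.pi * rx if circular else np.nan
        rows.append(
            {
                "level": level,
                "z_index": int(zpos[i]),
                "z_mm": zpos[i] * spec.slice_thickness,
                "csa_mm2": csa,
                "acb_mm2": acb,
                "ci": acb / csa,
                "mean_cbt_mm": mean_cbt,
                "max_cbt_mm": max_cbt,
                "min_cbt_mm": min_cbt,
                "perimeter_mm": pbl_true,
                "cmd_x_mm": cx[i] + n_half * sp,
                "cmd_y_mm": cy[i] + n_half * sp,
            }
        )
    per_level = pd.DataFrame(rows)
    # deviations of levels 1..9 from the 1->9 baseline: the centreline shape
    # functions vanish at both endpoints, so the baseline is constant and
    # the true deviations are the shape values themselves
    s = (zpos[:9] - zpos[0]) / (zpos[8] - zpos[0])
    per_level["dx_mm"] = np.nan
    per_level["dy_mm"] = np.nan
    per_level.loc[:8, "dx_mm"] = spec.lateral_mm * _lateral_shape(
        spec.lateral_mode, s
    )
    per_level.loc[:8, "dy_mm"] = spec.bow_mm * np.sin(np.pi * s)
    return PhantomTruth(
        per_level=per_level,
        pattern=MODE_TO_PATTERN[spec.lateral_mode],
        anterior_degree_mm=float(per_level["dy_mm"].iloc[:9].max()),
        spec=spec,
    )


def render_cohort(cohort_specs, seed: int = 0):
    """Render reproducible cohorts of phantoms.

    ``cohort_specs`` maps cohort name -> ``(template_spec, n)``.  Each
    specimen gets a deterministic child seed derived from ``seed`` and a
    unique id, so the same call renders bit-identical volumes.  Returns a
    list of ``(cohort, CTVolume, PhantomTruth)``.
    """
    out = []
    ss = np.random.SeedSequence(seed)
    for cohort, (template, n) in cohort_specs.items():
        children = ss.spawn(n)
        for i, child in enumerate(children):
            child_seed = int(child.generate_state(1)[0] % (2**31))
            spec = replace(
                template,
                seed=child_seed,
                specimen_id=f"{cohort}_{i + 1:03d}",
            )
            out.append((cohort, *render_phantom(spec)))
    return out


def annulus_section(
    outer_mm: float,
    inner_mm: float,
    spacing: float = 0.2,
    inner_offset_mm: tuple = (0.0, 0.0),
    hu_bone: float = 1200.0,
    hu_background: float = -1000.0,
    hu_cavity: Optional[float] = None,
    level: int = 5,
    specimen_id: str = "annulus",
):
    """A single analytic annulus rendered as a :class:`CrossSection`.

    The cavity defaults to the background HU (a dry bone in air).  Used as
    the closed-form oracle for area, index and thickness checks.
    """
    from .imaging import CrossSection

    if hu_cavity is None:
        hu_cavity = hu_background
    if inner_mm >= outer_mm:
        raise ValueError("inner radius must be below outer radius")
    half = outer_mm + 2.0
    n_half = int(np.ceil(half / spacing))
    n_px = 2 * n_half + 1
    coords = (np.arange(n_px) - n_half) * spacing
    X, Y = np.meshgrid(coords, coords)
    r_out = np.hypot(X, Y)
    r_in = np.hypot(X - inner_offset_mm[0], Y - inner_offset_mm[1])
    img = np.full((n_px, n_px), hu_background, dtype=np.float32)
    img[r_out <= outer_mm] = hu_bone
    img[(r_out <= outer_mm) & (r_in <= inner_mm)] = hu_cavity
    return CrossSection(
        pixels=img, spacing=spacing, level=level, specimen_id=specimen_id
    )


def save_bundle(volume: CTVolume, directory) -> Path:
    """Write a CT volume as the raw bundle accepted by ``load_volume``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.save(directory / "volume.npy", volume.intensities)
    meta = {
        "spacing_mm": volume.in_plane_spacing,
        "slice_thickness_mm": volume.slice_thickness,
        "side": volume.side,
        "specimen_id": volume.specimen_id,
    }
    with open(directory / "meta.json", "w") as fh:
        json.dump(meta, fh, indent=2)
    return directory
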