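"""Synthetic layered-retina phantom: geometry, rendering, motion, cohorts.

Generates curved 10-layer volumes with an optic-nerve-head pit, multiplicative
gamma speckle, vessel shadow artifacts, per-B-scan axial jitter and
longitudinal paired-eye cohorts with known injected per-layer effects, so the
whole downstream pipeline is testable without any acquired data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import CohortConfig, EffectProfile, PhantomConfig
from .types import (
    DAYS,
    EYES,
    LAYER_NAMES,
    LabelVolume,
    MotionProfile,
    N_BOUNDARIES,
    OCTVolume,
    SurfaceStack,
)

CHOROID_CLASS = 11


class GeometryOverflowError(ValueError):
    """Raised when the cumulative layer stack does not fit in the axial FOV."""


def _lateral_grids(config: PhantomConfig) -> tuple[np.ndarray, np.ndarray]:
    n_c, n_x, _ = config.volume_shape
    u = np.linspace(-1.0, 1.0, n_c)[:, None]  # slow axis
    v = np.linspace(-1.0, 1.0, n_x)[None, :]  # fast axis
    return u, v


def _dome(config: PhantomConfig) -> np.ndarray:
    """Polynomial dome height (µm) on the lateral grid."""
    u, v = _lateral_grids(config)
    n_c, n_x, _ = config.volume_shape
    dome = np.zeros((n_c, n_x))
    for i, row in enumerate(config.curvature_coeffs):
        for j, coeff in enumerate(row):
            if coeff != 0.0:
                dome = dome + coeff * (u ** i) * (v ** j)
    return dome


def _onh_weight(config: PhantomConfig) -> np.ndarray:
    """Smooth 0..1 weight collapsing layer thicknesses inside the ONH pit."""
    n_c, n_x, _ = config.volume_shape
    dc, dx, _ = config.spacing_um
    cc = np.arange(n_c)[:, None] * dc - (n_c - 1) * dc / 2.0
    xx = np.arange(n_x)[None, :] * dx - (n_x - 1) * dx / 2.0
    r = np.hypot(cc, xx)
    if config.onh_radius_um <= 0:
        return np.ones((n_c, n_x))
    s = np.clip(r / config.onh_radius_um, 0.0, 1.0)
    return 3.0 * s**2 - 2.0 * s**3  # smoothstep


def make_geometry(config: PhantomConfig, onh_center_um: tuple[float, float] | None = None) -> SurfaceStack:
    """Ground-truth boundary height maps (µm) for the configured phantom.

    Returns 11 ordered surfaces, vitreous/ILM down to BM/choroid, equal to a
    polynomial dome plus cumulative layer thicknesses, with the layer stack
    collapsing smoothly inside the ONH pit.
    """
    dc, dx, dz = config.spacing_um
    dome = _dome(config)
    if onh_center_um is None:
        w = _onh_weight(config)
    else:
        n_c, n_x, _ = config.volume_shape
        cc = np.arange(n_c)[:, None] * dc - (n_c - 1) * dc / 2.0 - onh_center_um[0]
        xx = np.arange(n_x)[None, :] * dx - (n_x - 1) * dx / 2.0 - onh_center_um[1]
        s = np.clip(np.hypot(cc, xx) / max(config.onh_radius_um, 1e-9), 0.0, 1.0)
        w = 3.0 * s**2 - 2.0 * s**3

    b0 = config.ilm_offset_um + dome
    heights = np.empty((N_BOUNDARIES,) + b0.shape)
    heights[0] = b0
    acc = b0.copy()
    for k, t in enumerate(config.layer_thicknesses_um):
        acc = acc + t * w
        heights[k + 1] = acc

    fov_z_um = config.fov_mm[2] * 1000.0
    if heights[-1].max() >= fov_z_um:
        raise GeometryOverflowError(
            f"layer stack reaches {heights[-1].max():.1f} µm, beyond the "
            f"{fov_z_um:.1f} µm axial FOV"
        )
    return SurfaceStack(
        heights=heights,
        lateral_spacing_um=(dc, dx),
        axial_spacing_um=dz,
        units="um",
    )


def rasterize_labels(surfaces: SurfaceStack, config: PhantomConfig) -> LabelVolume:
    """Dense per-voxel classes from boundary heights.

    A voxel at axial index ``iz`` belongs to the class whose span contains its
    top face ``z = iz * dz`` (half-open intervals; boundaries sit on voxel top
    faces, making surface recovery exact to one voxel).
    """
    n_c, n_x, n_z = config.volume_shape
    dz = config.spacing_um[2]
    z_faces = np.arange(n_z) * dz
    h = surfaces.to_um().heights
    counts = np.zeros((n_c, n_x, n_z), dtype=np.int8)
    for k in range(N_BOUNDARIES):
        counts += z_faces[None, None, :] >= h[k][:, :, None]
    classes = counts.astype(np.int16)  # 0 bg, 1..10 layers, 11 choroid
    below = z_faces[None, None, :] >= (h[-1] + config.choroid_thickness_um)[:, :, None]
    classes[below] = 0
    return LabelVolume(classes=classes, spacing_um=config.spacing_um)


def render_volume(
    surfaces: SurfaceStack,
    config: PhantomConfig,
    rng: np.random.Generator,
) -> tuple[OCTVolume, LabelVolume]:
    """Render an intensity volume (reflectivity x gamma speckle + vessel shadows)
    and its aligned label volume."""
    labels = rasterize_labels(surfaces, config)
    refl = np.asarray(config.layer_reflectivity, dtype=np.float64)
    intensity = refl[labels.classes]
    if not config.noiseless:
        k = config.speckle_shape
        intensity = intensity * rng.gamma(shape=k, scale=1.0 / k, size=intensity.shape)

    if config.vessel_density > 0:
        n_c, n_x, n_z = config.volume_shape
        dc, dx, dz = config.spacing_um
        h = surfaces.to_um().heights
        z_faces = np.arange(n_z) * dz
        cc = np.arange(n_c)[:, None] * dc
        xx = np.arange(n_x)[None, :] * dx
        for _ in range(config.vessel_density):
            c0 = rng.uniform(0, (n_c - 1) * dc)
            x0 = rng.uniform(0, (n_x - 1) * dx)
            radius = rng.uniform(*config.vessel_radius_um)
            disc = np.hypot(cc - c0, xx - x0) <= radius
            if not disc.any():
                continue
            below = z_faces[None, None, :] >= h[1][:, :, None]  # beneath RNFL
            shadow = disc[:, :, None] & below
            intensity = np.where(shadow, intensity * config.vessel_attenuation, intensity)

    volume = OCTVolume(intensity=intensity.astype(np.float32), spacing_um=config.spacing_um)
    return volume, labels


def random_walk_profile(
    n_bscans: int,
    sigma_px: float,
    rng: np.random.Generator,
    integer: bool = False,
) -> MotionProfile:
    """Cumulative random-walk axial jitter (first B-scan at 0)."""
    steps = rng.normal(0.0, sigma_px, size=n_bscans)
    steps[0] = 0.0
    shifts = np.cumsum(steps)
    if integer:
        shifts = np.round(shifts)
    return MotionProfile(shifts_px=shifts)


def apply_motion(
    volume: OCTVolume,
    profile: MotionProfile,
    mode: str = "linear",
    rng: np.random.Generator | None = None,
    fill_value: float = 0.0,
) -> OCTVolume:
    """Shift each B-scan axially by its profile value (positive = deeper).

    ``mode='linear'`` interpolates subvoxel shifts; ``mode='integer'`` rounds
    shifts for an exactly invertible transform.  Out-of-range voxels are filled
    with ``fill_value`` (or low-level noise when ``rng`` is given).
    """
    if len(profile) != volume.n_bscans:
        raise ValueError("profile length must match B-scan count")
    n_z = volume.shape[2]
    shifts = profile.shifts_px
    if np.any(np.abs(shifts) >= n_z):
        raise ValueError("shift magnitude must be smaller than the axial extent")

    out = np.empty_like(volume.intensity)
    z = np.arange(n_z, dtype=float)
    for i, s in enumerate(shifts):
        if mode == "integer":
            s = round(float(s))
            shifted = np.full_like(volume.intensity[i], fill_value)
            if s >= 0:
                if s < n_z:
                    shifted[:, s:] = volume.intensity[i][:, : n_z - s]
            else:
                shifted[:, :n_z + s] = volume.intensity[i][:, -s:]
            out[i] = shifted
        elif mode == "linear":
            src = z - s  # sample position in the source B-scan
            inside = (src >= 0) & (src <= n_z - 1)
            lo_c = np.clip(np.floor(src).astype(int), 0, n_z - 2)
            frac = src - lo_c
            plane = volume.intensity[i]
            interp = plane[:, lo_c] * (1 - frac) + plane[:, lo_c + 1] * frac
            out[i] = np.where(inside[None, :], interp, fill_value)
        else:
            raise ValueError(f"unknown mode {mode!r}")

    if rng is not None:
        # replace the fill margins with background-level noise
        missing = out == fill_value
        if fill_value == 0.0 and missing.any():
            out[missing] = rng.gamma(2.0, 2.0, size=int(missing.sum()))
    return OCTVolume(intensity=out, spacing_um=volume.spacing_um, meta=dict(volume.meta))


@dataclass
class Scan:
    """One simulated acquisition with full ground truth retained."""

    volume: OCTVolume | None
    labels: LabelVolume
    surfaces: SurfaceStack
    motion: MotionProfile
    layer_thicknesses_um: np.ndarray   # effective per-layer ground truth


@dataclass
class Cohort:
    """(subject, eye, day) -> Scan mapping plus generating configuration."""

    scans: dict[tuple[int, str, int], Scan]
    config: PhantomConfig
    effects: EffectProfile
    n_subjects: int

    def keys(self):
        return self.scans.keys()

    def __getitem__(self, key) -> Scan:
        return self.scans[key]

    def __len__(self) -> int:
        return len(self.scans)


def generate_cohort(
    config: PhantomConfig,
    effects: EffectProfile,
    n_subjects: int,
    rng: np.random.Generator,
    cohort_cfg: CohortConfig | None = None,
) -> Cohort:
    """Simulate a paired-eye longitudinal cohort.

    Injected-eye layer thicknesses are scaled by the effect multipliers; both
    eyes share a per-subject lognormal anatomy factor, and each acquisition
    draws an independent lognormal (eye, day) factor.  Axial jitter, when
    enabled, is applied to the intensity volume only; labels and surfaces stay
    in motion-free coordinates and the injected profile is retained.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    cc = cohort_cfg or CohortConfig()
    base = np.asarray(config.layer_thicknesses_um)

    subj_factor = np.exp(rng.normal(0.0, cc.subject_sigma, size=(n_subjects, len(base)))) \
        if cc.subject_sigma > 0 else np.ones((n_subjects, len(base)))

    scans: dict[tuple[int, str, int], Scan] = {}
    for s in range(n_subjects):
        for eye in EYES:
            for day in DAYS:
                eff = effects.as_array(day, eye)
                eyeday = (
                    np.exp(rng.normal(0.0, cc.eye_day_sigma, size=len(base)))
                    if cc.eye_day_sigma > 0 else np.ones(len(base))
                )
                thick = base * subj_factor[s] * eff * eyeday
                scan_cfg = config.model_copy(
                    update={"layer_thicknesses_um": tuple(float(t) for t in thick)}
                )
                surfaces = make_geometry(scan_cfg)
                meta = {"subject": s, "eye": eye, "day": day}
                if cc.render_intensity:
                    volume, labels = render_volume(surfaces, scan_cfg, rng)
                else:
                    volume, labels = None, rasterize_labels(surfaces, scan_cfg)
                labels.meta.update(meta)

                if cc.motion_sigma_px > 0:
                    motion = random_walk_profile(
                        config.volume_shape[0], cc.motion_sigma_px, rng, integer=True
                    )
                    if volume is not None:
                        volume = apply_motion(volume, motion, mode="integer", rng=rng)
                else:
                    motion = MotionProfile(np.zeros(config.volume_shape[0]))
                if volume is not None:
                    volume.meta.update(meta)
                scans[(s, eye, day)] = Scan(
                    volume=volume,
                    labels=labels,
                    surfaces=surfaces,
                    motion=motion,
                    layer_thicknesses_um=thick,
                )
    return Cohort(scans=scans, config=config, effects=effects, n_subjects=n_subjects)
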