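"""Pipeline configuration models (validated, serializable, unknown keys rejected)."""

from __future__ import annotations

import math
from importlib import resources
from typing import Literal

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from .types import DAYS, LAYER_NAMES, N_CLASSES


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class PhantomConfig(_Model):
    """Geometry, optics and noise parameters of the synthetic layered retina."""

    volume_shape: tuple[int, int, int] = (48, 48, 256)   # (n_bscans, width, depth)
    fov_mm: tuple[float, float, float] = (0.48, 0.48, 0.64)  # (c, x, z)
    layer_thicknesses_um: tuple[float, ...] = (
        18.0, 14.0, 50.0, 22.0, 14.0, 60.0, 6.0, 28.0, 12.0, 6.0,
    )
    choroid_thickness_um: float = 60.0
    ilm_offset_um: float = 60.0
    curvature_coeffs: tuple[tuple[float, ...], ...] = ((0.0, 0.0, 25.0), (0.0,), (25.0,))
    onh_radius_um: float = 60.0
    layer_reflectivity: tuple[float, ...] = (
        4.0, 95.0, 45.0, 70.0, 35.0, 65.0, 25.0, 80.0, 55.0, 110.0, 88.0, 50.0,
    )
    speckle_shape: float = 16.0     # gamma shape; inf -> noiseless
    vessel_density: int = 6
    vessel_radius_um: tuple[float, float] = (8.0, 20.0)
    vessel_attenuation: float = 0.35
    seed: int = 0

    @field_validator("volume_shape")
    @classmethod
    def _shape_positive(cls, v):
        if any(s <= 0 for s in v):
            raise ValueError("volume_shape must be positive")
        return v

    @field_validator("fov_mm")
    @classmethod
    def _fov_positive(cls, v):
        if any(s <= 0 for s in v):
            raise ValueError("fov_mm must be positive")
        return v

    @field_validator("layer_thicknesses_um")
    @classmethod
    def _thicknesses(cls, v):
        if len(v) != 10:
            raise ValueError("exactly 10 layer thicknesses required")
        if any(t <= 0 for t in v):
            raise ValueError("layer thicknesses must be > 0")
        return v

    @field_validator("layer_reflectivity")
    @classmethod
    def _reflectivity(cls, v):
        if len(v) != N_CLASSES:
            raise ValueError(f"need {N_CLASSES} per-class reflectivities")
        return v

    @field_validator("speckle_shape")
    @classmethod
    def _speckle(cls, v):
        if not (v > 0):
            raise ValueError("speckle_shape must be > 0 (may be inf)")
        return v

    @property
    def spacing_um(self) -> tuple[float, float, float]:
        """Voxel spacing (c, x, z) in µm derived from FOV and grid size."""
        return tuple(
            1000.0 * f / n for f, n in zip(self.fov_mm, self.volume_shape)
        )

    @property
    def noiseless(self) -> bool:
        return math.isinf(self.speckle_shape)


def paper_geometry() -> PhantomConfig:
    """Phantom config with the native acquisition geometry (400x400x1024, 1.6x1.6x1.64 mm)."""
    return PhantomConfig(volume_shape=(400, 400, 1024), fov_mm=(1.6, 1.6, 1.64),
                         onh_radius_um=160.0, curvature_coeffs=((0.0, 0.0, 40.0), (0.0,), (40.0,)),
                         ilm_offset_um=150.0)


class EffectProfile(_Model):
    """Per-layer fractional thickness multipliers for the injected eye by day.

    The control eye is implicitly 1.0 at every day; day 0 is 1.0 for both eyes.
    """

    multipliers: dict[str, dict[int, float]]

    @model_validator(mode="after")
    def _check(self):
        for layer, by_day in self.multipliers.items():
            if layer not in LAYER_NAMES:
                raise ValueError(f"unknown layer {layer!r}")
            for day, m in by_day.items():
                if day not in DAYS:
                    raise ValueError(f"unknown day {day}")
                if m <= 0:
                    raise ValueError("multipliers must be > 0")
            if by_day.get(0, 1.0) != 1.0:
                raise ValueError("day-0 multiplier must be 1.0")
        return self

    def multiplier(self, layer: str, day: int, eye: str) -> float:
        if eye == "control" or day == 0:
            return 1.0
        return self.multipliers.get(layer, {}).get(day, 1.0)

    def as_array(self, day: int, eye: str) -> np.ndarray:
        """Multipliers for the 10 layers in anatomical order."""
        return np.array([self.multiplier(name, day, eye) for name in LAYER_NAMES])

    @classmethod
    def null(cls) -> "EffectProfile":
        return cls(multipliers={name: {d: 1.0 for d in DAYS} for name in LAYER_NAMES})


def paper_effects() -> EffectProfile:
    """The packaged longitudinal effect profile (injected-eye multipliers)."""
    with resources.files("retoct").joinpath("data/paper_effects.yaml").open() as fh:
        payload = yaml.safe_load(fh)
    return EffectProfile(multipliers={
        layer: {int(d): float(m) for d, m in by_day.items()}
        for layer, by_day in payload["multipliers"].items()
    })


def load_effects(path_or_name: str) -> EffectProfile:
    """Load an effect profile from YAML; the names 'paper' / 'null' are built-in."""
    if path_or_name == "paper":
        return paper_effects()
    if path_or_name == "null":
        return EffectProfile.null()
    with open(path_or_name) as fh:
        payload = yaml.safe_load(fh)
    return EffectProfile(multipliers={
        layer: {int(d): float(m) for d, m in by_day.items()}
        for layer, by_day in payload["multipliers"].items()
    })


class CohortConfig(_Model):
    """Biological / measurement variability of a simulated paired-eye cohort."""

    subject_sigma: float = 0.03     # lognormal sd, shared between fellow eyes
    eye_day_sigma: float = 0.01     # lognormal sd per (eye, day) acquisition
    motion_sigma_px: float = 0.0    # random-walk axial jitter, px / B-scan step
    render_intensity: bool = True

    @field_validator("subject_sigma", "eye_day_sigma", "motion_sigma_px")
    @classmethod
    def _nonneg(cls, v):
        if v < 0:
            raise ValueError("sigmas must be >= 0")
        return v


class PreprocessConfig(_Model):
    max_shift_px: int = 12
    poly_order: int = 2
    subpixel: bool = True
    denoise: bool = False
    tv_weight: float = 8.0
    tv_max_iter: int = 100
    tv_tol: float = 2e-4


class SegModelConfig(_Model):
    """Small trainable U-Net configuration (reduced 'desk' scale)."""

    base_channels: int = 8
    cascade: bool = False
    n_classes: int = N_CLASSES
    lr_frozen: float = 0.05
    lr_finetune: float = 0.015
    epochs_frozen: int = 4
    epochs_finetune: int = 80
    epochs_pseudo: int = 15
    batch_size: int = 8
    augment: bool = True
    augment_scale: float = 1.0   # shrink transform magnitudes for small B-scans
    seed: int = 0

    @field_validator("base_channels", "n_classes", "batch_size",
                     "epochs_frozen", "epochs_finetune", "epochs_pseudo")
    @classmethod
    def _positive(cls, v):
        if v <= 0:
            raise ValueError("must be positive")
        return v


class ROIConfig(_Model):
    r_onh_um: float = 90.0   # wide margin: pit radius + NN search window
    r_mid_um: float = 150.0
    r_outer_um: float = 220.0
    center: Literal["auto", "grid"] = "auto"

    @model_validator(mode="after")
    def _ordered(self):
        if not (0 <= self.r_onh_um < self.r_mid_um < self.r_outer_um):
            raise ValueError("require 0 <= r_onh < r_mid < r_outer")
        return self


def paper_roi() -> ROIConfig:
    """ROI radii for the native 1.6 mm field of view."""
    return ROIConfig(r_onh_um=160.0, r_mid_um=460.0, r_outer_um=760.0)


class StatsConfig(_Model):
    fdr_q: float = 0.1
    alpha: float = 0.05
    family: Literal["panel", "global"] = "panel"


class PipelineConfig(_Model):
    """Top-level configuration tying all stages together."""

    phantom: PhantomConfig = PhantomConfig()
    cohort: CohortConfig = CohortConfig()
    preprocess: PreprocessConfig = PreprocessConfig()
    segment: SegModelConfig = SegModelConfig()
    roi: ROIConfig = ROIConfig()
    stats: StatsConfig = StatsConfig()
    resample_um: float = 5.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.model_validate(payload)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=False)
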