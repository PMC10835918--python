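"""Core data containers shared across the pipeline.

Axis convention for all volumes: ``(c, x, z)`` — slow-scan (B-scan index),
lateral (fast-scan), axial (depth).  Height maps are indexed ``(c, x)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

#: Integer class map for dense label volumes.
CLASS_NAMES: dict[int, str] = {
    0: "background",
    1: "ILM-RNFL",
    2: "GCL",
    3: "IPL",
    4: "INL",
    5: "OPL",
    6: "ONL",
    7: "ELM",
    8: "PRL",
    9: "RPE",
    10: "BM",
    11: "choroid",
}

#: The ten retinal layers in anatomical (inner -> outer) order.
LAYER_NAMES: tuple[str, ...] = tuple(CLASS_NAMES[k] for k in range(1, 11))

#: Class index of each retinal layer.
LAYER_CLASS: dict[str, int] = {name: k for k, name in CLASS_NAMES.items()}

N_CLASSES = len(CLASS_NAMES)
N_LAYERS = len(LAYER_NAMES)
N_BOUNDARIES = N_LAYERS + 1  # vitreous/ILM down to BM/choroid

#: Boundary names; boundary ``k`` is the upper surface of layer ``k+1``
#: (class ``k+1``) for ``k < 10``; boundary 10 is the BM/choroid interface.
BOUNDARY_NAMES: tuple[str, ...] = tuple(
    f"top:{LAYER_NAMES[k]}" for k in range(N_LAYERS)
) + ("BM/choroid",)

#: Composite spans as (first boundary index, last boundary index).
COMPOSITE_SPANS: dict[str, tuple[int, int]] = {
    "total": (0, 10),   # ILM -> BM
    "inner": (0, 6),    # ILM-RNFL .. ONL
    "outer": (6, 10),   # ELM .. BM
}

MEASURE_NAMES: tuple[str, ...] = LAYER_NAMES + ("total", "inner", "outer")

DAYS: tuple[int, ...] = (0, 3, 7, 28)
EYES: tuple[str, ...] = ("injected", "control")


@dataclass
class OCTVolume:
    """3D OCT intensity volume with anisotropic voxel spacing."""

    intensity: np.ndarray              # (c, x, z) float32
    spacing_um: tuple[float, float, float]  # (c, x, z) µm / voxel
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity)
        if self.intensity.ndim != 3:
            raise ValueError("intensity must be a 3D (c, x, z) array")
        if any(s <= 0 for s in self.spacing_um):
            raise ValueError("voxel spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensity.shape

    @property
    def n_bscans(self) -> int:
        return self.intensity.shape[0]

    def copy(self) -> "OCTVolume":
        return replace(self, intensity=self.intensity.copy(), meta=dict(self.meta))


@dataclass
class LabelVolume:
    """Per-voxel integer layer classes aligned with an :class:`OCTVolume`."""

    classes: np.ndarray                # (c, x, z) integer
    spacing_um: tuple[float, float, float]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes)
        if self.classes.ndim != 3:
            raise ValueError("classes must be a 3D (c, x, z) array")
        if not np.issubdtype(self.classes.dtype, np.integer):
            raise ValueError("classes must be an integer array")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.classes.shape

    def copy(self) -> "LabelVolume":
        return replace(self, classes=self.classes.copy(), meta=dict(self.meta))


@dataclass
class MotionProfile:
    """Per-B-scan axial displacement in pixels (real-valued)."""

    shifts_px: np.ndarray

    def __post_init__(self) -> None:
        self.shifts_px = np.asarray(self.shifts_px, dtype=float)
        if self.shifts_px.ndim != 1:
            raise ValueError("shifts_px must be 1D")

    def __len__(self) -> int:
        return len(self.shifts_px)


@dataclass
class SurfaceStack:
    """Ordered boundary height maps z(c, x) for the 11 retinal boundaries.

    ``heights`` has shape ``(11, n_c, n_x)``; units are axial pixels
    (``units == 'px'``) or micrometres (``units == 'um'``).
    """

    heights: np.ndarray
    lateral_spacing_um: tuple[float, float]   # (c, x)
    axial_spacing_um: float
    units: str = "px"
    valid: Optional[np.ndarray] = None        # (11, n_c, n_x) bool

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 3 or self.heights.shape[0] != N_BOUNDARIES:
            raise ValueError(f"heights must have shape ({N_BOUNDARIES}, n_c, n_x)")
        if self.units not in ("px", "um"):
            raise ValueError("units must be 'px' or 'um'")
        if self.valid is None:
            self.valid = np.ones(self.heights.shape, dtype=bool)

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.heights.shape[1:]

    def to_um(self) -> "SurfaceStack":
        """Return a copy with heights expressed in micrometres."""
        if self.units == "um":
            return replace(self, heights=self.heights.copy(), valid=self.valid.copy())
        return replace(
            self,
            heights=self.heights * self.axial_spacing_um,
            units="um",
            valid=self.valid.copy(),
        )

    def copy(self) -> "SurfaceStack":
        return replace(self, heights=self.heights.copy(), valid=self.valid.copy())


@dataclass
class ThicknessMap:
    """2D per-layer (or composite) thickness in µm with a validity mask."""

    values: np.ndarray      # (n_c, n_x) float, µm
    valid: np.ndarray       # (n_c, n_x) bool
    name: str = ""
    lateral_spacing_um: tuple[float, float] = (1.6, 1.6)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.valid.shape:
            raise ValueError("values and valid must have the same shape")


def layer_boundaries(layer: str) -> tuple[int, int]:
    """(upper, lower) boundary indices delimiting a single named layer."""
    if layer in COMPOSITE_SPANS:
        return COMPOSITE_SPANS[layer]
    k = LAYER_CLASS[layer]  # 1..10
    return k - 1, k
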