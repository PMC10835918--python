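"""Circular ROI masks centred on the optic nerve head, and regional means.

Regions (annuli on the isotropic lateral grid):
central r_onh < r <= r_mid; peripheral r_mid < r <= r_outer;
full = central + peripheral.  The ONH disc is excluded from all three.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .types import SurfaceStack, ThicknessMap

REGIONS = ("full", "central", "peripheral")


@dataclass
class ROIMask:
    mask: np.ndarray                      # bool, (n_c, n_x)
    region: str
    center_um: tuple[float, float]
    radii_um: tuple[float, float, float]  # (r_onh, r_mid, r_outer)


def detect_onh_center(
    stack: SurfaceStack,
    separation_frac: float = 0.5,
) -> tuple[float, float]:
    """Lateral centroid (c, x µm) of the region where inner boundaries converge.

    The pit is located where the ILM -> ONL-bottom separation falls below
    ``separation_frac`` of its median; falls back to the grid centre (with a
    warning) when no pit is found.
    """
    um = stack.to_um()
    sep = um.heights[6] - um.heights[0]  # inner-retina span
    threshold = separation_frac * np.median(sep)
    pit = sep < threshold
    dc, dx = um.lateral_spacing_um
    n_c, n_x = um.grid_shape
    if not pit.any():
        warnings.warn("no ONH pit found; using the geometric centre")
        return ((n_c - 1) * dc / 2.0, (n_x - 1) * dx / 2.0)
    cc, xx = np.nonzero(pit)
    return (float(cc.mean() * dc), float(xx.mean() * dx))


def make_masks(
    center_um: tuple[float, float],
    radii_um: tuple[float, float, float],
    grid_shape: tuple[int, int],
    spacing_um: tuple[float, float],
) -> dict[str, ROIMask]:
    """full / central / peripheral annulus masks (pixel-centre containment)."""
    r_onh, r_mid, r_outer = radii_um
    if not (0 <= r_onh < r_mid < r_outer):
        raise ValueError("require 0 <= r_onh < r_mid < r_outer")
    n_c, n_x = grid_shape
    cc = np.arange(n_c)[:, None] * spacing_um[0] - center_um[0]
    xx = np.arange(n_x)[None, :] * spacing_um[1] - center_um[1]
    r = np.hypot(cc, xx)
    central = (r > r_onh) & (r <= r_mid)
    peripheral = (r > r_mid) & (r <= r_outer)
    out = {
        "central": central,
        "peripheral": peripheral,
        "full": central | peripheral,
    }
    return {
        name: ROIMask(mask=m, region=name, center_um=center_um, radii_um=radii_um)
        for name, m in out.items()
    }


def mean_thickness(tmap: ThicknessMap, roi: ROIMask) -> tuple[float, int]:
    """Mean of valid thickness values inside the ROI; returns (µm, n_pixels)."""
    if tmap.values.shape != roi.mask.shape:
        raise ValueError("thickness map and mask must share a grid")
    sel = roi.mask & tmap.valid
    n = int(sel.sum())
    if n == 0:
        raise ValueError("no valid pixels inside the ROI")
    return float(tmap.values[sel].mean()), n


def regional_means(
    measures: dict[str, ThicknessMap],
    masks: dict[str, ROIMask],
) -> list[dict]:
    """Tidy rows of (measure, region, mean µm, n pixels)."""
    rows = []
    for name, tmap in measures.items():
        for region, roi in masks.items():
            mean, n = mean_thickness(tmap, roi)
            rows.append({"measure": name, "region": region,
                         "mean_um": mean, "n_pixels": n})
    return rows
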