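"""Paired B-scan / label augmentation: random affine + lateral flip.

Draws: axial and lateral translations up to 20 px, rotation magnitude up to
30 degrees, centred crop-and-zoom up to 25%, and a lateral flip with
probability 0.5.  There is never an axial flip.  The identical spatial
transform is applied to the image (linear interpolation) and to the labels
(nearest neighbour).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

MAX_TRANSLATE_PX = 20.0
MAX_ROTATE_DEG = 30.0
MAX_CROP_FRAC = 0.25
P_FLIP = 0.5


@dataclass(frozen=True)
class AffineParams:
    translate_z: float   # axial, px, in [-20, 20]
    translate_x: float   # lateral, px, in [-20, 20]
    angle_deg: float     # magnitude in [0, 30], signed
    crop_frac: float     # in [0, 0.25]; zoom factor = 1 / (1 - crop)
    flip_lateral: bool

    @property
    def is_identity(self) -> bool:
        return (self.translate_z == 0 and self.translate_x == 0
                and self.angle_deg == 0 and self.crop_frac == 0
                and not self.flip_lateral)


def draw_params(rng: np.random.Generator, scale: float = 1.0) -> AffineParams:
    """Draw transform parameters uniformly in the allowed ranges.

    ``scale`` shrinks the translation/rotation/crop magnitudes proportionally
    for reduced-size B-scans (the native ranges assume 400 x 1024 px images);
    the flip probability is unaffected.
    """
    t_max = MAX_TRANSLATE_PX * scale
    return AffineParams(
        translate_z=float(rng.uniform(-t_max, t_max)),
        translate_x=float(rng.uniform(-t_max, t_max)),
        angle_deg=float(rng.uniform(0.0, MAX_ROTATE_DEG * scale))
        * (1 if rng.random() < 0.5 else -1),
        crop_frac=float(rng.uniform(0.0, MAX_CROP_FRAC * scale)),
        flip_lateral=bool(rng.random() < P_FLIP),
    )


def apply_affine(
    bscan: np.ndarray,
    labels: np.ndarray | None,
    params: AffineParams,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Apply one transform to an aligned (z, x) image / label pair."""
    if params.is_identity:
        return bscan.copy(), None if labels is None else labels.copy()

    img = bscan[:, ::-1] if params.flip_lateral else bscan
    lab = None
    if labels is not None:
        lab = labels[:, ::-1] if params.flip_lateral else labels

    theta = np.deg2rad(params.angle_deg)
    scale = 1.0 / (1.0 - params.crop_frac)  # crop then zoom back up
    rot = np.array([[np.cos(theta), -np.sin(theta)],
                    [np.sin(theta), np.cos(theta)]])
    fwd = rot * scale
    inv = np.linalg.inv(fwd)
    center = (np.asarray(bscan.shape, dtype=float) - 1) / 2.0
    shift = np.array([params.translate_z, params.translate_x])
    offset = center - inv @ (center + shift)

    out_img = ndimage.affine_transform(
        np.asarray(img, dtype=np.float64), inv, offset=offset, order=1, mode="nearest",
    ).astype(bscan.dtype)
    out_lab = None
    if lab is not None:
        out_lab = ndimage.affine_transform(
            lab, inv, offset=offset, order=0, mode="nearest",
        )
    return out_img, out_lab


def augment(
    bscan: np.ndarray,
    labels: np.ndarray | None,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Randomly augment an aligned B-scan / label pair."""
    return apply_affine(bscan, labels, draw_params(rng))
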