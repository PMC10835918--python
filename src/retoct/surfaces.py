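"""Dense labels -> ordered boundary surfaces -> per-layer thickness maps.

Thickness follows the shortest-distance construction: boundary height maps are
resampled to an isotropic lateral grid, and for every point on the upper
boundary the Euclidean distance to the nearest point of the lower boundary
(k-nearest-neighbor, k = 1) is taken, in physical µm.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .types import (
    CLASS_NAMES,
    COMPOSITE_SPANS,
    LAYER_NAMES,
    LabelVolume,
    N_BOUNDARIES,
    SurfaceStack,
    ThicknessMap,
    layer_boundaries,
)


def _pava(y: np.ndarray) -> np.ndarray:
    """L2 isotonic (non-decreasing) projection via pool-adjacent-violators."""
    n = len(y)
    vals = y.astype(float).copy()
    weights = np.ones(n)
    # blocks as (value, weight) merged left-to-right
    out_v: list[float] = []
    out_w: list[float] = []
    for v, w in zip(vals, weights):
        out_v.append(v)
        out_w.append(w)
        while len(out_v) > 1 and out_v[-2] > out_v[-1]:
            v2, w2 = out_v.pop(), out_w.pop()
            v1, w1 = out_v.pop(), out_w.pop()
            out_v.append((v1 * w1 + v2 * w2) / (w1 + w2))
            out_w.append(w1 + w2)
    res = np.empty(n)
    i = 0
    for v, w in zip(out_v, out_w):
        res[i:i + int(w)] = v
        i += int(w)
    return res


def enforce_ordering(heights: np.ndarray) -> np.ndarray:
    """Project each (c, x) column of boundary heights to the ordered set."""
    out = heights.copy()
    viol = np.any(np.diff(heights, axis=0) < 0, axis=0)
    for c, x in zip(*np.nonzero(viol)):
        out[:, c, x] = _pava(heights[:, c, x])
    return out


def _inpaint(arr: np.ndarray, invalid: np.ndarray, size: int = 5, max_iter: int = 1000) -> np.ndarray:
    """Iterated median fill of invalid positions from a (size x size) window."""
    out = arr.copy()
    out[invalid] = np.nan
    half = size // 2
    n_c, n_x = out.shape
    for _ in range(max_iter):
        holes = np.argwhere(np.isnan(out))
        if holes.size == 0:
            break
        filled_any = False
        new = out.copy()
        for c, x in holes:
            win = out[max(0, c - half):c + half + 1, max(0, x - half):x + half + 1]
            if np.isfinite(win).any():
                new[c, x] = np.nanmedian(win)
                filled_any = True
        out = new
        if not filled_any:
            break
    return out


def labels_to_surfaces(labels: LabelVolume, strict: bool = True) -> SurfaceStack:
    """Boundary height maps (axial px) from a dense label volume.

    The transition depth of boundary k is the first voxel of its lower class
    (classes k+1 for k < 10; choroid for k = 10).  A-scans missing a class are
    flagged invalid and median-inpainted; ordering is enforced by isotonic
    projection.  With ``strict=True`` a retinal class entirely absent from the
    volume is an error; with ``strict=False`` (predicted labels) it is treated
    as invalid everywhere.
    """
    classes = labels.classes
    n_c, n_x, n_z = classes.shape

    if strict:
        for cls in range(1, 12):
            if not (classes == cls).any():
                raise ValueError(f"class {cls} ({CLASS_NAMES[cls]}) absent from the volume")

    heights = np.zeros((N_BOUNDARIES, n_c, n_x))
    valid = np.zeros((N_BOUNDARIES, n_c, n_x), dtype=bool)
    for k in range(N_BOUNDARIES):
        target = k + 1  # class whose first voxel marks the boundary
        ge = classes >= target
        present = (classes == target).any(axis=2)
        first = np.argmax(ge, axis=2).astype(float)
        first[~ge.any(axis=2)] = np.nan
        heights[k] = first
        valid[k] = present & np.isfinite(first)

    for k in range(N_BOUNDARIES):
        invalid = ~valid[k] | ~np.isfinite(heights[k])
        if invalid.any():
            heights[k] = _inpaint(heights[k], invalid)
    heights = np.nan_to_num(heights, nan=0.0)
    heights = enforce_ordering(heights)

    dc, dx, dz = labels.spacing_um
    return SurfaceStack(
        heights=heights,
        lateral_spacing_um=(dc, dx),
        axial_spacing_um=dz,
        units="px",
        valid=valid,
    )


def _linear_resample_axis(arr: np.ndarray, axis: int, spacing: float, target: float) -> np.ndarray:
    """Separable linear resampling (with edge extrapolation) along one axis."""
    n = arr.shape[axis]
    n_out = int(round(n * spacing / target))
    pos = np.arange(n_out) * target / spacing  # fractional source index
    lo = np.clip(np.floor(pos).astype(int), 0, n - 2)
    frac = pos - lo
    a = np.take(arr, lo, axis=axis)
    b = np.take(arr, lo + 1, axis=axis)
    shape = [1] * arr.ndim
    shape[axis] = n_out
    frac = frac.reshape(shape)
    return a * (1 - frac) + b * frac


def resample_isotropic(stack: SurfaceStack, target_um: float = 1.6) -> SurfaceStack:
    """Bilinearly upsample the surfaces onto an isotropic lateral grid.

    Heights are converted to µm; the output grid has
    ``round(n * spacing / target_um)`` samples per lateral axis (e.g. 400 px at
    4 µm -> 1000 samples at 1.6 µm).
    """
    if target_um <= 0:
        raise ValueError("target_um must be > 0")
    um = stack.to_um()
    dc, dx = um.lateral_spacing_um
    h = _linear_resample_axis(um.heights, 1, dc, target_um)
    h = _linear_resample_axis(h, 2, dx, target_um)
    v = _linear_resample_axis(um.valid.astype(float), 1, dc, target_um)
    v = _linear_resample_axis(v, 2, dx, target_um)
    return SurfaceStack(
        heights=h,
        lateral_spacing_um=(target_um, target_um),
        axial_spacing_um=um.axial_spacing_um,
        units="um",
        valid=v > 0.999,
    )


def _surface_points(heights: np.ndarray, spacing: tuple[float, float]) -> np.ndarray:
    n_c, n_x = heights.shape
    cc, xx = np.meshgrid(
        np.arange(n_c) * spacing[0], np.arange(n_x) * spacing[1], indexing="ij"
    )
    return np.column_stack([cc.ravel(), xx.ravel(), heights.ravel()])


def _windowed_nn_distance(
    upper: np.ndarray,
    lower: np.ndarray,
    spacing: tuple[float, float],
    window_um: float,
) -> np.ndarray:
    """Min distance from each upper point to lower points within a lateral window.

    Exact brute force over all lateral offsets inside the window, vectorized as
    shifted-array comparisons and pruned by ascending lateral distance.
    """
    sc, sx = spacing
    best = (lower - upper) ** 2  # zero-offset candidate
    mc = int(window_um // sc)
    mx = int(window_um // sx)
    n_c, n_x = upper.shape
    offsets = [
        (di, dj, (di * sc) ** 2 + (dj * sx) ** 2)
        for di in range(-min(mc, n_c - 1), min(mc, n_c - 1) + 1)
        for dj in range(-min(mx, n_x - 1), min(mx, n_x - 1) + 1)
        if (di, dj) != (0, 0) and (di * sc) ** 2 + (dj * sx) ** 2 <= window_um ** 2
    ]
    offsets.sort(key=lambda o: o[2])
    for di, dj, lat2 in offsets:
        if lat2 >= best.max():
            break
        # overlapping region of upper[i, j] vs lower[i + di, j + dj]
        u_i = slice(max(0, -di), min(n_c, n_c - di))
        u_j = slice(max(0, -dj), min(n_x, n_x - dj))
        l_i = slice(max(0, di), min(n_c, n_c + di))
        l_j = slice(max(0, dj), min(n_x, n_x + dj))
        cand = lat2 + (lower[l_i, l_j] - upper[u_i, u_j]) ** 2
        np.minimum(best[u_i, u_j], cand, out=best[u_i, u_j])
    return np.sqrt(best)


def thickness_map(
    upper: np.ndarray,
    lower: np.ndarray,
    lateral_spacing_um: tuple[float, float],
    valid: np.ndarray | None = None,
    symmetric: bool = False,
    window_um: float | None = 25.0,
    name: str = "",
) -> ThicknessMap:
    """Nearest-point (k = 1) distance from the upper to the lower boundary.

    Both boundaries are µm height maps on the same isotropic lateral grid.
    The search is restricted to a lateral window (default ±25 µm) — wide
    enough that it never binds on anatomical slopes while keeping the
    converging boundaries inside the ONH pit from short-circuiting distances
    measured near it; ``window_um=None`` searches globally (k-d tree).  With
    ``symmetric=True`` the upper->lower and lower->upper distances are
    averaged.
    """
    if upper.shape != lower.shape:
        raise ValueError("boundaries must share a grid")
    if valid is None:
        valid = np.ones(upper.shape, dtype=bool)
    if not valid.any():
        raise ValueError("empty valid region")
    upper = np.asarray(upper, float)
    lower = np.asarray(lower, float)

    if window_um is None:
        pts_up = _surface_points(upper, lateral_spacing_um)
        pts_lo = _surface_points(lower, lateral_spacing_um)
        d_ul, _ = cKDTree(pts_lo).query(pts_up, k=1)
        values = d_ul.reshape(upper.shape)
        if symmetric:
            d_lu, _ = cKDTree(pts_up).query(pts_lo, k=1)
            values = 0.5 * (values + d_lu.reshape(upper.shape))
    else:
        values = _windowed_nn_distance(upper, lower, lateral_spacing_um, window_um)
        if symmetric:
            values = 0.5 * (
                values
                + _windowed_nn_distance(lower, upper, lateral_spacing_um, window_um)
            )
    return ThicknessMap(
        values=values, valid=np.asarray(valid, bool), name=name,
        lateral_spacing_um=lateral_spacing_um,
    )


def thickness_between(
    stack: SurfaceStack,
    k_upper: int,
    k_lower: int,
    symmetric: bool = False,
    window_um: float | None = 25.0,
    name: str = "",
) -> ThicknessMap:
    """Thickness between two boundaries of one isotropic µm SurfaceStack."""
    if stack.units != "um":
        raise ValueError("stack must be in µm (resample_isotropic first)")
    valid = stack.valid[k_upper] & stack.valid[k_lower]
    return thickness_map(
        stack.heights[k_upper],
        stack.heights[k_lower],
        stack.lateral_spacing_um,
        valid=valid,
        symmetric=symmetric,
        window_um=window_um,
        name=name,
    )


def layer_thickness(stack: SurfaceStack, layer: str, symmetric: bool = False,
                    window_um: float | None = 25.0) -> ThicknessMap:
    """Thickness map of one named retinal layer."""
    k0, k1 = layer_boundaries(layer)
    return thickness_between(stack, k0, k1, symmetric=symmetric,
                             window_um=window_um, name=layer)


def composite_thickness(
    stack: SurfaceStack,
    layer_set: str | tuple[int, int],
    symmetric: bool = False,
    window_um: float | None = 25.0,
) -> ThicknessMap:
    """Thickness between the outermost bounding surfaces of a contiguous span.

    ``layer_set`` is 'total', 'inner', 'outer', or an explicit contiguous
    boundary index span ``(k_first, k_last)``.
    """
    if isinstance(layer_set, str):
        if layer_set not in COMPOSITE_SPANS:
            raise ValueError(f"unknown composite {layer_set!r}")
        k0, k1 = COMPOSITE_SPANS[layer_set]
        name = layer_set
    else:
        k0, k1 = layer_set
        if not (0 <= k0 < k1 < N_BOUNDARIES):
            raise ValueError("non-contiguous or out-of-range span")
        name = f"span:{k0}-{k1}"
    return thickness_between(stack, k0, k1, symmetric=symmetric,
                             window_um=window_um, name=name)


def sum_of_layers(stack: SurfaceStack, layers: tuple[str, ...], symmetric: bool = False) -> ThicknessMap:
    """Per-layer-sum cross-check variant of a composite thickness."""
    maps = [layer_thickness(stack, name, symmetric=symmetric) for name in layers]
    values = np.sum([m.values for m in maps], axis=0)
    valid = np.logical_and.reduce([m.valid for m in maps])
    return ThicknessMap(values=values, valid=valid, name="+".join(layers),
                        lateral_spacing_um=stack.lateral_spacing_um)


def all_measures(stack: SurfaceStack, symmetric: bool = False,
                 window_um: float | None = 25.0) -> dict[str, ThicknessMap]:
    """All 10 layer maps plus the total/inner/outer composites."""
    out = {name: layer_thickness(stack, name, symmetric=symmetric,
                                 window_um=window_um) for name in LAYER_NAMES}
    for comp in COMPOSITE_SPANS:
        out[comp] = composite_thickness(stack, comp, symmetric=symmetric,
                                        window_um=window_um)
    return out
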