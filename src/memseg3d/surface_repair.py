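"""Detection and repair of cavities in the upper embryo surface.

Photobleaching and low stain concentration leave patches of the embryo's
outer membrane unimaged.  Such a cavity opens a channel between a surface
cell and the background, and a watershed flood then leaks through it.  The
repair estimates a smooth upper surface of the whole embryo, finds columns
where the membrane signal is missing below that surface, and writes the
regressed surface voxels back into the binary membrane mask at exactly
those columns.

The smooth surface is obtained by morphological closing of the membrane
mask with a Euclidean ball large enough to bridge cavities, hole filling,
taking each (x, y) column's topmost solid voxel, and smoothing that height
field.  This is a deterministic stand-in for an iteratively evolved active
surface: the only property downstream code relies on is that the surface
does not dip into cavities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

__all__ = [
    "SurfaceMap",
    "VerticalDistance",
    "fit_embryo_surface",
    "vertical_distance_matrix",
    "cavity_mask",
    "repair_surface",
    "repair_membrane",
]


@dataclass
class SurfaceMap:
    """Upper-surface height field over (x, y).

    ``height[x, y]`` is the z of the smoothed upper embryo surface where
    ``valid``; ``cavity`` is filled in by :func:`cavity_mask`.
    """

    height: np.ndarray            # (X, Y) float
    valid: np.ndarray             # (X, Y) bool — embryo footprint
    cavity: np.ndarray | None = None
    n_slices: int = 0


@dataclass
class VerticalDistance:
    """Per-column vertical gap between the fitted surface and the membrane.

    ``distance[x, y]`` is the distance (slices) from the surface height down
    to the nearest membrane voxel within the search depth; 0 both when the
    membrane coincides with the surface and when none is found — the
    ``absence`` grid disambiguates the two.
    """

    distance: np.ndarray
    absence: np.ndarray
    search_depth: int


def _ball_closing(mask: np.ndarray, radius: float) -> np.ndarray:
    """Morphological closing with a Euclidean ball via two distance transforms.

    Padded by the ball radius so the erosion sees background beyond the
    grid; otherwise the closing leaks along the array border.
    """
    pad = int(np.ceil(radius)) + 2
    padded = np.pad(mask, pad)
    dilated = ndi.distance_transform_edt(~padded) <= radius
    closed = ndi.distance_transform_edt(dilated) > radius
    return closed[pad:-pad, pad:-pad, pad:-pad]


def fit_embryo_surface(
    mask: np.ndarray,
    closing_radius: float = 18.0,
    smooth_sigma: float = 3.0,
) -> SurfaceMap:
    """Fit the smooth upper surface of the embryo solid.

    ``closing_radius`` (voxels) must exceed roughly half the widest cavity
    for the closed solid to bridge it; ``smooth_sigma`` smooths the height
    field.  Columns outside the embryo footprint are invalid.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask has no true voxel")
    solid = _ball_closing(mask, closing_radius)
    solid |= mask  # closing guard: never lose actual signal columns
    solid = ndi.binary_fill_holes(solid)
    valid = solid.any(axis=2)
    nz = mask.shape[2]
    # topmost solid voxel per column
    top = (nz - 1) - np.argmax(solid[:, :, ::-1], axis=2)
    height = np.where(valid, top.astype(np.float64), 0.0)
    if smooth_sigma > 0:
        # extend heights outside the footprint with nearest valid value so
        # smoothing does not drag the rim toward 0
        idx = ndi.distance_transform_edt(~valid, return_distances=False, return_indices=True)
        filled = height[tuple(idx)]
        height = ndi.gaussian_filter(filled, sigma=smooth_sigma)
        # smoothing must not float above the closed solid: on the steep
        # lateral rim that would flag intact columns as cavities (over a
        # real cavity the closed solid is already bridged, so the clamp
        # does not undo the bridge)
        height = np.minimum(height, top + 1.0)
    height = np.clip(height, 0, nz - 1)
    return SurfaceMap(height=height, valid=valid, n_slices=nz)


def vertical_distance_matrix(
    surface: SurfaceMap, mask: np.ndarray, search_depth: int = 10
) -> VerticalDistance:
    """Distance from the fitted surface down to the nearest membrane voxel.

    Looks at z in [height - search_depth, height + 1] per valid column
    (one slice above tolerates rounding of the smoothed height).  Columns
    with no membrane voxel in that window get distance 0 and are flagged
    absent.
    """
    mask = np.asarray(mask, dtype=bool)
    nx, ny, nz = mask.shape
    h = np.rint(surface.height).astype(int)
    distance = np.zeros((nx, ny), dtype=np.float64)
    absence = np.zeros((nx, ny), dtype=bool)
    zs = np.arange(nz)
    for x in range(nx):
        for y in range(ny):
            if not surface.valid[x, y]:
                continue
            z0 = h[x, y]
            lo, hi = max(0, z0 - search_depth), min(nz - 1, z0 + 1)
            window = mask[x, y, lo:hi + 1]
            if not window.any():
                absence[x, y] = True
                continue
            zhit = zs[lo:hi + 1][window]
            distance[x, y] = float(np.min(np.abs(zhit - z0)))
    return VerticalDistance(distance, absence, search_depth)


def cavity_mask(
    vd: VerticalDistance,
    surface: SurfaceMap,
    smoothing_sigma: float = 1.0,
    transition_width: int = 2,
) -> np.ndarray:
    """Binary (x, y) mask of columns whose surface membrane needs repair.

    Cavity cores are valid columns with no membrane signal within the
    search window below the surface.  The smoothed distance grid is Otsu
    thresholded (over columns with a positive gap) to delimit the
    transition zone where the membrane has dropped far below the bridged
    surface; the core grows by up to ``transition_width`` columns into
    that zone.  The growth is deliberately bounded: large vertical gaps
    also occur all along the embryo's steep lateral rim, where the height
    field is unreliable and patching would only hurt.  Returns the empty
    mask when there is no core, and stores the result on ``surface``.
    """
    core = vd.absence & surface.valid
    if not core.any():
        surface.cavity = np.zeros_like(core)
        return surface.cavity
    sm = ndi.gaussian_filter(vd.distance, sigma=smoothing_sigma)
    gaps = sm[surface.valid & (vd.distance > 0)]
    cav = core.copy()
    if gaps.size >= 2 and np.ptp(gaps) > 0:
        thr = threshold_otsu(gaps)
        zone = surface.valid & (sm >= thr)
        grown = ndi.binary_dilation(core, iterations=transition_width)
        cav = core | (grown & zone)
    else:
        warnings.warn("degenerate distance grid; cavity limited to absent columns",
                      stacklevel=2)
    surface.cavity = cav
    return cav


def repair_surface(mask: np.ndarray, surface: SurfaceMap) -> np.ndarray:
    """Write the regressed surface voxel into every cavity column.

    For each (x, y) with a positive cavity mask the voxel at
    ``(x, y, height[x, y])`` is set; everything else is untouched.
    """
    if surface.cavity is None:
        raise ValueError("cavity mask not computed; call cavity_mask first")
    out = np.asarray(mask, dtype=bool).copy()
    nz = out.shape[2]
    h = np.rint(surface.height).astype(int)
    clamped = (h < 0) | (h > nz - 1)
    if (clamped & surface.cavity).any():
        warnings.warn("surface height clamped to stack bounds during repair", stacklevel=2)
    h = np.clip(h, 0, nz - 1)
    xs, ys = np.nonzero(surface.cavity)
    out[xs, ys, h[xs, ys]] = True
    return out


def repair_membrane(
    mask: np.ndarray,
    closing_radius: float = 18.0,
    surface_smooth_sigma: float = 3.0,
    search_depth: int = 10,
    smoothing_sigma: float = 1.0,
    repair_lower_surface: bool = False,
) -> np.ndarray:
    """Full cavity-repair pass: fit surface, locate cavities, patch the mask.

    A no-op (identical mask back) on an intact surface.  With
    ``repair_lower_surface`` the same procedure additionally runs on the
    z-flipped stack to patch the lower surface.
    """
    surface = fit_embryo_surface(mask, closing_radius, surface_smooth_sigma)
    vd = vertical_distance_matrix(surface, mask, search_depth)
    cavity_mask(vd, surface, smoothing_sigma)
    out = repair_surface(mask, surface)
    if repair_lower_surface:
        flipped = repair_membrane(
            out[:, :, ::-1], closing_radius, surface_smooth_sigma,
            search_depth, smoothing_sigma, repair_lower_surface=False,
        )
        out = flipped[:, :, ::-1]
    return out
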