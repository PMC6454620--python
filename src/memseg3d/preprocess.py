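"""Intensity normalization, Hessian plane enhancement, and binarization.

Confocal membrane stacks dim with slice depth (laser attenuation,
photobleaching).  The statistical normalization here builds a per-slice
intensity histogram matrix, extracts a threshold line across slices, and
rescales the deeper half of the stack so each deep slice matches the line
value of its mirror slice about the stack midplane.

Membrane sheets are plane-like: locally one large second derivative across
the sheet and two small ones within it.  The Hessian eigen-decomposition
captures this; the enhanced image is |lambda3| normalized to [0, 1], which
is then thresholded into the binary membrane mask consumed downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

from .stack_io import IntensityStack

__all__ = [
    "IntensityDistributionMatrix",
    "HessianEigensystem",
    "StructureTag",
    "gaussian_smooth",
    "build_intensity_matrix",
    "extract_threshold_line",
    "normalize_slices",
    "hessian_eigensystem",
    "enhance_membrane",
    "classify_structure",
    "binarize",
]


@dataclass
class IntensityDistributionMatrix:
    """Per-slice intensity histograms (rows = z slices, columns = bins)."""

    counts: np.ndarray            # raw counts, shape (Z, n_bins)
    smoothed: np.ndarray          # Gaussian-smoothed counts, same shape
    bin_edges: np.ndarray         # length n_bins + 1
    empty_slices: np.ndarray      # bool per slice: nothing above background
    threshold_line: np.ndarray | None = None   # per-slice intensity, set by extract

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class HessianEigensystem:
    """Per-voxel Hessian eigenvalues (and optionally eigenvectors).

    ``eigenvalues[..., k]`` is lambda_{k+1} with |l1| <= |l2| <= |l3|;
    ``eigenvectors[..., k]`` is the matching unit eigenvector when computed.
    """

    eigenvalues: np.ndarray                 # (X, Y, Z, 3), |.|-ascending
    eigenvectors: np.ndarray | None = None  # (X, Y, Z, 3, 3) or None
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)


class StructureTag(IntEnum):
    NONE = 0
    PLANE = 1
    STICK = 2
    BALL = 3


def gaussian_smooth(stack: IntensityStack, sigma: float | Sequence[float]) -> IntensityStack:
    """Linear Gaussian filtering; ``sigma`` in voxels, scalar or per-axis."""
    sig = np.broadcast_to(np.asarray(sigma, dtype=float), (3,))
    if np.any(sig < 0):
        raise ValueError(f"sigma must be non-negative, got {sigma}")
    out = ndi.gaussian_filter(stack.voxels.astype(np.float64), sigma=tuple(sig))
    return IntensityStack(out, stack.spacing)


def build_intensity_matrix(
    stack: IntensityStack,
    n_bins: int = 64,
    background_cutoff: float | None = None,
    smooth_sigma: tuple[float, float] = (1.0, 2.0),
) -> IntensityDistributionMatrix:
    """Embed each slice's foreground-intensity histogram as a matrix row.

    Voxels with intensity <= ``background_cutoff`` are ignored; the default
    cutoff is the Otsu threshold of the whole stack.  The matrix is
    2D-Gaussian smoothed (``smooth_sigma`` = (slices, bins)) before any
    threshold-line extraction.  A slice left empty after background
    exclusion yields a zero row and is flagged.
    """
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    v = stack.voxels
    if background_cutoff is None:
        background_cutoff = float(threshold_otsu(v))
    fg = v > background_cutoff
    if not fg.any():
        raise ValueError("no voxel above the background cutoff in the whole stack")
    lo, hi = float(v[fg].min()), float(v[fg].max())
    if hi <= lo:
        hi = lo + 1.0
    edges = np.linspace(lo, hi, n_bins + 1)
    nz = v.shape[2]
    counts = np.zeros((nz, n_bins), dtype=np.float64)
    empty = np.zeros(nz, dtype=bool)
    for z in range(nz):
        vals = v[:, :, z][fg[:, :, z]]
        if vals.size == 0:
            empty[z] = True
            continue
        counts[z], _ = np.histogram(vals, bins=edges)
    smoothed = ndi.gaussian_filter(counts, sigma=smooth_sigma)
    return IntensityDistributionMatrix(counts, smoothed, edges, empty)


def extract_threshold_line(
    matrix: IntensityDistributionMatrix, count_threshold: float
) -> np.ndarray:
    """Per-slice intensity where the smoothed histogram count crosses a level.

    For each slice, the line sits at the largest bin center whose smoothed
    count is >= ``count_threshold``; slices with no qualifying bin inherit
    the nearest qualifying slice's value.
    """
    if count_threshold <= 0:
        raise ValueError(f"count_threshold must be positive, got {count_threshold}")
    centers = matrix.bin_centers
    qualifies = matrix.smoothed >= count_threshold
    nz = qualifies.shape[0]
    line = np.full(nz, np.nan)
    for z in range(nz):
        idx = np.flatnonzero(qualifies[z])
        if idx.size:
            line[z] = centers[idx[-1]]
    valid = np.flatnonzero(~np.isnan(line))
    if valid.size == 0:
        raise ValueError("no slice has a bin reaching the count threshold")
    for z in np.flatnonzero(np.isnan(line)):
        line[z] = line[valid[np.argmin(np.abs(valid - z))]]
    matrix.threshold_line = line
    return line


def normalize_slices(
    stack: IntensityStack,
    line: np.ndarray,
    direction: str = "brighten_deep",
) -> IntensityStack:
    """Rescale the deeper half of the stack using mirror-slice line ratios.

    Slice ``z`` pairs with slice ``Z-1-z``; for ``z`` past the midplane the
    slice is multiplied by ``line[Z-1-z] / line[z]`` (default direction:
    deep, dim slices are brightened toward their shallow mirror).  The
    midline slice of an odd-depth stack is untouched.  ``direction =
    "dim_deep"`` applies the reciprocal factor instead.
    """
    v = stack.voxels.astype(np.float64).copy()
    nz = v.shape[2]
    line = np.asarray(line, dtype=float)
    if line.shape != (nz,):
        raise ValueError(f"line must have one entry per slice ({nz}), got {line.shape}")
    if direction not in ("brighten_deep", "dim_deep"):
        raise ValueError(f"unknown direction {direction!r}")
    for z in range((nz + 1) // 2, nz):
        if line[z] <= 0 or line[nz - 1 - z] <= 0:
            warnings.warn(f"non-positive line value at slice pair ({nz - 1 - z}, {z}); "
                          "factor clamped to 1", stacklevel=2)
            continue
        factor = line[nz - 1 - z] / line[z]
        if direction == "dim_deep":
            factor = 1.0 / factor
        v[:, :, z] *= factor
    return IntensityStack(v, stack.spacing)


def _abs_sort(eigvals: np.ndarray) -> np.ndarray:
    order = np.argsort(np.abs(eigvals), axis=-1, kind="stable")
    return np.take_along_axis(eigvals, order, axis=-1), order


def hessian_eigensystem(
    stack: IntensityStack,
    derivative_sigma: float = 1.0,
    compute_eigenvectors: bool = False,
) -> HessianEigensystem:
    """Per-voxel Hessian via Gaussian derivatives, eigenvalues |.|-sorted.

    Second derivatives are Gaussian-derivative estimates at scale
    ``derivative_sigma`` (voxels, on the near-isotropic working grid).
    Eigenvectors are only materialized on request; the membrane enhancement
    needs eigenvalues alone.
    """
    if derivative_sigma <= 0:
        raise ValueError(f"derivative_sigma must be positive, got {derivative_sigma}")
    v = stack.voxels.astype(np.float64)
    orders = {(0, 0): (2, 0, 0), (1, 1): (0, 2, 0), (2, 2): (0, 0, 2),
              (0, 1): (1, 1, 0), (0, 2): (1, 0, 1), (1, 2): (0, 1, 1)}
    h = {}
    for (i, j), order in orders.items():
        h[(i, j)] = ndi.gaussian_filter(v, sigma=derivative_sigma, order=order)
    H = np.empty(v.shape + (3, 3), dtype=np.float64)
    for i in range(3):
        for j in range(3):
            H[..., i, j] = h[(min(i, j), max(i, j))]
    if compute_eigenvectors:
        w, vec = np.linalg.eigh(H)
        w_sorted, order = _abs_sort(w)
        # reorder eigenvector columns to match |.|-ascending eigenvalues
        vec_sorted = np.take_along_axis(vec, order[..., None, :], axis=-1)
        return HessianEigensystem(w_sorted, vec_sorted, stack.spacing)
    w = np.linalg.eigvalsh(H)
    w_sorted, _ = _abs_sort(w)
    return HessianEigensystem(w_sorted, None, stack.spacing)


def enhance_membrane(eigs: HessianEigensystem) -> IntensityStack:
    """Enhanced membrane image: |lambda3| / max |lambda3|, in [0, 1].

    Plane-like voxels (one dominant curvature) light up; a degenerate
    all-zero Hessian field returns zeros with a warning.
    """
    lam3 = np.abs(eigs.eigenvalues[..., 2])
    m = lam3.max()
    if m == 0:
        warnings.warn("all Hessian eigenvalues are zero; enhancement is degenerate",
                      stacklevel=2)
        return IntensityStack(np.zeros_like(lam3), eigs.spacing)
    return IntensityStack(lam3 / m, eigs.spacing)


def classify_structure(
    eigs: HessianEigensystem, magnitude_threshold: float = 1.0
) -> np.ndarray:
    """Tag each voxel as plane / stick / ball / none by eigenvalue magnitudes.

    plane: |l1|, |l2| < thr <= |l3|; stick: |l1| < thr <= |l2|, |l3|;
    ball: thr <= |l1|, |l2|, |l3|; none otherwise.
    """
    if magnitude_threshold <= 0:
        raise ValueError(f"magnitude_threshold must be positive, got {magnitude_threshold}")
    a = np.abs(eigs.eigenvalues)
    big = a >= magnitude_threshold  # |.|-ascending, so big is monotone along last axis
    n_big = big.sum(axis=-1)
    tags = np.full(a.shape[:-1], StructureTag.NONE, dtype=np.uint8)
    tags[n_big == 1] = StructureTag.PLANE
    tags[n_big == 2] = StructureTag.STICK
    tags[n_big == 3] = StructureTag.BALL
    return tags


def binarize(enhanced: IntensityStack, threshold: float = 0.35) -> np.ndarray:
    """Threshold the enhanced [0, 1] image into a boolean membrane mask."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    v = enhanced.voxels
    if v.min() < 0 or v.max() > 1:
        raise ValueError("enhanced image must lie in [0, 1]")
    return v >= threshold
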