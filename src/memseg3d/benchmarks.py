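"""Standard phantom conditions and measurements for validating the pipeline.

These are the frozen study conditions the package is validated under: the
end-to-end recovery phantoms, the cavity-ablation fixture, the
interior/boundary comparison, the region-filter discrimination scenes, the
division-correction runs, and the normalization-symmetry measurement.
Tests and the reproduction script both build on them so the reported
numbers always refer to the same conditions.
"""

from __future__ import annotations

import numpy as np

from . import preprocess as pp
from . import region_filter as rf
from .pipeline import _default_count_threshold
from .stack_io import IntensityStack, LabelVolume
from .synthetic_embryo import Phantom, PhantomSpec

__all__ = [
    "standard_spec",
    "cavity_ablation_spec",
    "interior_boundary_spec",
    "discrimination_spec",
    "division_spec",
    "flooded_cells",
    "candidate_coefficients",
    "normalization_mirror_asymmetry",
]


def standard_spec(n_cells: int, seed: int) -> PhantomSpec:
    """End-to-end recovery condition: 96x96x64 grid, 1.5%/slice attenuation,
    six noise blobs, no cavity."""
    return PhantomSpec(n_cells=n_cells, seed=seed)


def cavity_ablation_spec(seed: int) -> PhantomSpec:
    """Surface-repair ablation condition: 8-cell stage with an apex cavity
    wide enough (radius 20) to fully open one surface cell."""
    return PhantomSpec(n_cells=8, cavity=(48.0, 48.0, 20.0), seed=seed)


def interior_boundary_spec(seed: int) -> PhantomSpec:
    """Interior-vs-boundary condition: 24-cell cavity phantom; only some
    Voronoi draws contain interior cells, so runs are screened for them."""
    return PhantomSpec(n_cells=24, cavity=(48.0, 48.0, 16.0), seed=seed)


def discrimination_spec(seed: int) -> PhantomSpec:
    """Region-filter discrimination scene: a flat, grid-filling embryo
    carrying three large detached surface sheets and five noise blobs
    inside cells."""
    return PhantomSpec(
        shape=(96, 96, 48),
        semi_axes=(44.0, 44.0, 21.0),
        n_cells=8,
        n_noise_blobs=5,
        noise_radius=(2.0, 2.5),
        noise_clearance=6.0,
        noise_location="inside",
        n_detached_patches=3,
        patch_radius=16.0,
        patch_gap=2.0,
        patch_offset=0.0,
        seed=seed,
    )


def division_spec(seed: int) -> PhantomSpec:
    """Division-correction condition: one dividing pair (60% interface
    hole) and one completed pair among 8 cells."""
    return PhantomSpec(
        shape=(64, 64, 48),
        semi_axes=(26.0, 26.0, 19.0),
        n_cells=8,
        n_noise_blobs=3,
        n_dividing_pairs=1,
        n_completed_pairs=1,
        seed=seed,
    )


def flooded_cells(truth: LabelVolume, seg: LabelVolume) -> list[int]:
    """Truth cells whose voxels are majority-owned by the background region
    (which is connected to the stack border) — the leak signature."""
    out = []
    for lab in truth.cell_labels():
        owners = np.bincount(seg.labels[truth.labels == lab].ravel())
        if owners.argmax() == 0:
            out.append(int(lab))
    return out


def candidate_coefficients(phantom: Phantom) -> list[tuple[str, float]]:
    """Polarization coefficients of the generator-labeled candidates.

    The scene's binary mask is the ground-truth membrane plus the noise
    blobs; each non-largest component is matched against the generator's
    blob / detached-patch masks and its influence-region polarization
    coefficient is computed against the accepted surface.
    """
    mask = phantom.membrane_mask | (phantom.noise_labels > 0)
    regions = rf.connected_components(mask, 26)
    phi_max = regions.region_mask(regions.phi_max)
    rows = []
    for rid in range(1, regions.n_regions + 1):
        if rid == regions.phi_max:
            continue
        m = regions.region_mask(rid)
        n_noise = int((m & (phantom.noise_labels > 0)).sum())
        n_patch = int((m & (phantom.patch_labels > 0)).sum())
        if n_noise > n_patch:
            kind = "noise"
        elif n_patch > 0:
            kind = "membrane"
        else:
            continue  # unlabeled debris: not scored
        coeff = rf.polarization_coefficient(rf.influence_region(phi_max, m))
        rows.append((kind, coeff))
    return rows


def normalization_mirror_asymmetry(
    membrane: IntensityStack, n_bins: int = 64
) -> tuple[float, float]:
    """(mean, max) relative mirror deviation of the threshold line after
    slice normalization, over bulk slice pairs.

    Bulk pairs are those where both slices hold at least 25% of the median
    per-slice foreground count; the line carried across near-empty cap
    slices is not a meaningful symmetry measurement.
    """
    sm = pp.gaussian_smooth(membrane, 1.0)
    mat = pp.build_intensity_matrix(sm, n_bins=n_bins)
    thr = _default_count_threshold(mat)
    line = pp.extract_threshold_line(mat, thr)
    norm = pp.normalize_slices(sm, line)
    mat2 = pp.build_intensity_matrix(norm, n_bins=n_bins)
    line2 = pp.extract_threshold_line(mat2, _default_count_threshold(mat2))
    counts = mat2.counts.sum(axis=1)
    bulk = counts >= 0.25 * np.median(counts[counts > 0])
    nz = len(line2)
    rel = [
        abs(line2[z] - line2[nz - 1 - z]) / max(line2[z], line2[nz - 1 - z])
        for z in range(nz // 2)
        if bulk[z] and bulk[nz - 1 - z]
    ]
    if not rel:
        raise ValueError("no bulk mirror pairs to measure")
    return float(np.mean(rel)), float(np.max(rel))
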