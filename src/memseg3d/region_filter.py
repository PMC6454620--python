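"""Screening of binary-membrane connected components into signal vs noise.

The binarized membrane image decomposes into connected components: one
large embryo-surface component plus smaller pieces that are either detached
membrane patches (keep) or noise spots (drop).  The two behave differently
when added to the accepted surface: the set of voxels whose
distance-to-surface changes (the "influence region" of the candidate) is
roughly a ball around an isolated noise spot, but strongly flattened or
elongated (polarized) for a patch that continues the surface.  The PCA
variance fractions of that influence region quantify this: the smallest
fraction gamma1/(gamma1+gamma2+gamma3) is near 1/3 for a ball and near 0
for a polarized region, so small values indicate membrane.  Both decision
directions are exposed; the default was fixed by phantom calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "RegionSet",
    "RegionDecision",
    "connected_components",
    "influence_region",
    "polarization_coefficient",
    "filter_regions",
]

_STRUCTURES = {
    6: ndi.generate_binary_structure(3, 1),
    18: ndi.generate_binary_structure(3, 2),
    26: ndi.generate_binary_structure(3, 3),
}


@dataclass
class RegionSet:
    """Connected components of a binary membrane mask.

    ``labeled`` assigns each true voxel a component id (1..n); ``sizes[i]``
    is the voxel count of component ``i+1``; ``phi_max`` is the id of the
    largest component (ties broken by lowest minimum linear index).
    """

    labeled: np.ndarray
    sizes: np.ndarray
    phi_max: int
    connectivity: int

    @property
    def n_regions(self) -> int:
        return len(self.sizes)

    def region_mask(self, region_id: int) -> np.ndarray:
        return self.labeled == region_id


@dataclass
class RegionDecision:
    region_id: int
    size: int
    coefficient: float
    accepted: bool
    reason: str


def connected_components(mask: np.ndarray, connectivity: int = 26) -> RegionSet:
    """Partition the true voxels into maximal connected components."""
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be 6, 18 or 26, got {connectivity}")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask has no true voxel")
    labeled, n = ndi.label(mask, structure=_STRUCTURES[connectivity])
    sizes = np.bincount(labeled.ravel())[1:]
    largest = sizes.max()
    tied = np.flatnonzero(sizes == largest) + 1
    if len(tied) == 1:
        phi_max = int(tied[0])
    else:
        flat = labeled.ravel()
        first_idx = {int(t): None for t in tied}
        for t in tied:
            first_idx[int(t)] = int(np.flatnonzero(flat == t)[0])
        phi_max = min(first_idx, key=first_idx.get)
    return RegionSet(labeled, sizes, phi_max, connectivity)


def _sq_edt(mask: np.ndarray) -> np.ndarray:
    """Exact integer squared Euclidean distance to the nearest true voxel."""
    if not mask.any():
        raise ValueError("distance to an empty set is undefined")
    idx = ndi.distance_transform_edt(~mask, return_distances=False, return_indices=True)
    coords = np.indices(mask.shape)
    return ((coords - idx) ** 2).sum(axis=0)


def influence_region(current: np.ndarray, candidate: np.ndarray) -> np.ndarray:
    """Voxels whose distance-to-set changes when ``candidate`` joins ``current``.

    Distances are exact (integer squared Euclidean), so the inequality test
    carries no floating-point ambiguity.  An empty candidate yields an
    empty region.
    """
    current = np.asarray(current, dtype=bool)
    candidate = np.asarray(candidate, dtype=bool)
    if (current & candidate).any():
        raise ValueError("candidate overlaps the current accepted set")
    if not candidate.any():
        return np.zeros_like(current)
    d_before = _sq_edt(current)
    d_after = _sq_edt(current | candidate)
    return d_before != d_after


def polarization_coefficient(region: np.ndarray) -> float:
    """Smallest PCA variance fraction of a voxel cloud, in [0, 1/3].

    Near 1/3 for an isotropic (ball-like) cloud, near 0 for a flat or
    degenerate one.  Fewer than 3 voxels (or a zero-variance cloud) count
    as fully degenerate and return 0.
    """
    coords = np.argwhere(np.asarray(region, dtype=bool))
    if len(coords) < 3:
        return 0.0
    cov = np.cov(coords.T.astype(np.float64))
    gamma = np.linalg.eigvalsh(cov)  # ascending
    total = gamma.sum()
    if total <= 0:
        return 0.0
    return float(gamma[0] / total)


def filter_regions(
    regions: RegionSet,
    accept_threshold: float = 0.1,
    rule_direction: Literal["smaller_is_membrane", "greater_is_membrane"] = "smaller_is_membrane",
    min_candidate_voxels: int = 10,
    return_decisions: bool = False,
):
    """Grow the accepted membrane set from the largest component outward.

    Candidates are visited in descending size (ties by lower region id,
    i.e. raster order of first voxel).  For each, the influence region
    against the current accepted union is computed and its polarization
    coefficient decides acceptance:

    * ``smaller_is_membrane`` (default, phantom-calibrated): coefficient
      <= ``accept_threshold`` accepts — polarized influence regions are
      membrane, ball-like ones are noise;
    * ``greater_is_membrane``: coefficient > ``accept_threshold`` accepts.

    Candidates below ``min_candidate_voxels`` are dropped outright.
    Returns the filtered boolean mask (and the per-candidate decision log
    when ``return_decisions``).
    """
    if rule_direction not in ("smaller_is_membrane", "greater_is_membrane"):
        raise ValueError(f"unknown rule_direction {rule_direction!r}")
    accepted = regions.region_mask(regions.phi_max)
    decisions: list[RegionDecision] = [
        RegionDecision(regions.phi_max, int(regions.sizes[regions.phi_max - 1]),
                       float("nan"), True, "phi_max")
    ]
    order = sorted(
        (rid for rid in range(1, regions.n_regions + 1) if rid != regions.phi_max),
        key=lambda rid: (-regions.sizes[rid - 1], rid),
    )
    for rid in order:
        size = int(regions.sizes[rid - 1])
        if size < min_candidate_voxels:
            decisions.append(RegionDecision(rid, size, float("nan"), False, "too_small"))
            continue
        cand = regions.region_mask(rid)
        coeff = polarization_coefficient(influence_region(accepted, cand))
        if rule_direction == "smaller_is_membrane":
            ok = coeff <= accept_threshold
        else:
            ok = coeff > accept_threshold
        if ok:
            accepted |= cand
        decisions.append(RegionDecision(rid, size, coeff, ok, "coefficient"))
    if return_decisions:
        return accepted, decisions
    return accepted
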