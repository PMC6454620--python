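"""Merging of daughter-cell pairs whose division has not completed.

A dividing cell carries two nuclei before the membrane between the
daughters has closed, so nucleus-seeded segmentation splits it in two.
The correction walks the lineage for daughter pairs (records at the same
time sharing a parent that existed earlier), inspects the mean membrane
intensity along the two regions' shared interface on a 0-255 scale, and
merges pairs whose interface is dark (mean strictly below the threshold,
40 by default) — a dark interface means the watershed drew the boundary
on a distance ridge inside a membrane hole, not on actual membrane.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi

from .stack_io import IntensityStack, LabelVolume, NucleusRecord

__all__ = [
    "DaughterPair",
    "MergeDecision",
    "find_daughter_pairs",
    "interface_voxels",
    "scale_to_255",
    "should_merge",
    "merge_cells",
    "correct_divisions",
]

_FACE6 = ndi.generate_binary_structure(3, 1)
_CUBE26 = ndi.generate_binary_structure(3, 3)


@dataclass(frozen=True)
class DaughterPair:
    parent_name: str
    label_a: int
    label_b: int
    time: int


@dataclass
class MergeDecision:
    pair: DaughterPair
    interface_size: int
    mean_intensity: float
    merged: bool


def find_daughter_pairs(
    records: Sequence[NucleusRecord], time: int
) -> list[DaughterPair]:
    """All unordered same-parent record pairs at ``time``.

    The parent must itself appear in the lineage at an earlier time point.
    More than two records sharing a parent is flagged and all pairs are
    emitted.
    """
    earlier_names = {r.name for r in records if r.time < time}
    groups: dict[str, list[NucleusRecord]] = {}
    for r in records:
        if r.time == time and r.parent_name and r.parent_name in earlier_names:
            groups.setdefault(r.parent_name, []).append(r)
    pairs = []
    for parent, members in sorted(groups.items()):
        if len(members) < 2:
            continue
        if len(members) > 2:
            warnings.warn(
                f"{len(members)} records share parent {parent!r} at t={time}; "
                "emitting all pairs", stacklevel=2,
            )
        members = sorted(members, key=lambda r: r.label)
        for a, b in combinations(members, 2):
            pairs.append(DaughterPair(parent, a.label, b.label, time))
    return pairs


def interface_voxels(
    labels: LabelVolume, a: int, b: int, exclude_junctions: bool = False
) -> np.ndarray:
    """Boolean mask of the face-adjacency interface between regions a and b.

    Voxels of ``a`` 6-adjacent to ``b`` plus the converse; empty when the
    regions do not touch.  With ``exclude_junctions`` the rim of the
    interface — voxels 26-adjacent to any third region or to background —
    is dropped, leaving the pair's private interface: membrane signal from
    walls shared with bystander cells would otherwise contaminate an
    intensity readout of this interface.  Falls back to the full interface
    when the rim is everything.
    """
    vol = labels.labels
    mask_a = vol == a
    mask_b = vol == b
    if not mask_a.any():
        raise ValueError(f"label {a} absent from the volume")
    if not mask_b.any():
        raise ValueError(f"label {b} absent from the volume")
    near_b = ndi.binary_dilation(mask_b, structure=_FACE6)
    near_a = ndi.binary_dilation(mask_a, structure=_FACE6)
    iface = (mask_a & near_b) | (mask_b & near_a)
    if exclude_junctions:
        others = ~(mask_a | mask_b)  # third cells and background
        pad = np.pad(others, 1, constant_values=True)  # grid border counts too
        rim = ndi.binary_dilation(pad, structure=_CUBE26)[1:-1, 1:-1, 1:-1]
        private = iface & ~rim
        if private.any():
            return private
        warnings.warn(
            f"interface of ({a}, {b}) has no junction-free interior; "
            "using the full interface", stacklevel=2,
        )
    return iface


def scale_to_255(stack: IntensityStack) -> IntensityStack:
    """Min-max rescale of the stack to the 0-255 intensity scale."""
    v = stack.voxels.astype(np.float64)
    lo, hi = v.min(), v.max()
    if hi <= lo:
        return IntensityStack(np.zeros_like(v), stack.spacing)
    return IntensityStack((v - lo) / (hi - lo) * 255.0, stack.spacing)


def should_merge(
    membrane: IntensityStack,
    interface: np.ndarray,
    intensity_threshold: float = 40.0,
) -> bool:
    """Merge iff the mean interface intensity is strictly below threshold.

    ``membrane`` must already be on the 0-255 scale (see
    :func:`scale_to_255`).  An interface hole drags the mean down; a
    closed membrane keeps it high.
    """
    interface = np.asarray(interface, dtype=bool)
    if not interface.any():
        raise ValueError("empty interface: no merge decision possible")
    return float(membrane.voxels[interface].mean()) < intensity_threshold


def merge_cells(
    labels: LabelVolume,
    pair: DaughterPair,
    records: Sequence[NucleusRecord],
) -> LabelVolume:
    """Relabel both daughter regions to one label.

    Uses the parent's lineage label when it exists and does not collide
    with another label present at the pair's time point; otherwise the
    smaller daughter label.  No voxel outside the two regions changes.
    """
    target = min(pair.label_a, pair.label_b)
    parent_recs = [
        r for r in records if r.name == pair.parent_name and r.time < pair.time
    ]
    if parent_recs:
        parent_label = max(parent_recs, key=lambda r: r.time).label
        in_use = {
            r.label for r in records
            if r.time == pair.time and r.label not in (pair.label_a, pair.label_b)
        }
        present = set(np.unique(labels.labels)) - {0, pair.label_a, pair.label_b}
        if parent_label not in in_use and parent_label not in present:
            target = parent_label
    out = labels.labels.copy()
    out[(out == pair.label_a) | (out == pair.label_b)] = target
    return LabelVolume(out, labels.spacing)


def correct_divisions(
    labels: LabelVolume,
    membrane: IntensityStack,
    records: Sequence[NucleusRecord],
    time: int,
    intensity_threshold: float = 40.0,
) -> tuple[LabelVolume, list[MergeDecision]]:
    """Full division-correction pass over one time point.

    ``membrane`` is min-max rescaled to 0-255 internally.  Pairs whose
    regions do not touch are skipped with a warning.  Returns the revised
    volume and the per-pair decision log.
    """
    scaled = scale_to_255(membrane)
    out = labels
    decisions = []
    for pair in find_daughter_pairs(records, time):
        present = np.unique(out.labels)
        if pair.label_a not in present or pair.label_b not in present:
            warnings.warn(f"pair {pair} has a missing region; skipped", stacklevel=2)
            continue
        iface = interface_voxels(out, pair.label_a, pair.label_b, exclude_junctions=True)
        n_iface = int(iface.sum())
        if n_iface == 0:
            warnings.warn(f"pair {pair} regions are not adjacent; skipped", stacklevel=2)
            continue
        mean_int = float(scaled.voxels[iface].mean())
        merged = mean_int < intensity_threshold
        if merged:
            out = merge_cells(out, pair, records)
        decisions.append(MergeDecision(pair, n_iface, mean_int, merged))
    return out, decisions
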