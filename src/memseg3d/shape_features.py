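"""Per-cell morphology, neighbor interfaces, and segmentation evaluation.

Features are computed from a label volume and its voxel spacing: volumes
by voxel counting, surface areas either by exposed-face counting (exact on
the voxel grid, overestimates smooth surfaces by a known ~1.5 factor) or
by a triangulated isosurface.  Neighbor interfaces are face-adjacency
counts; the per-time interface-ratio matrix of a focal cell normalizes
each column to sum to 1.  The multi-label Dice coefficient scores a
segmentation against ground truth over all cells at once:

    p = 2 * sum_i |T_i & S_i| / sum_i (|T_i| + |S_i|)

with truth/segmentation labels paired by maximal voxel overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.optimize import linear_sum_assignment
from skimage import measure

from .stack_io import LabelVolume, NucleusRecord

__all__ = [
    "CellFeatureRecord",
    "cell_volume",
    "cell_surface_area",
    "neighbor_face_counts",
    "interface_ratio_matrix",
    "classify_boundary_cells",
    "match_labels",
    "multilabel_dice",
    "feature_table",
]

_FACE26 = ndi.generate_binary_structure(3, 3)


@dataclass
class CellFeatureRecord:
    time: int
    name: str
    label: int
    volume: float               # µm³
    surface_area: float         # µm²
    neighbors: tuple[int, ...]
    is_boundary: bool


def _require_label(vol: np.ndarray, label: int) -> np.ndarray:
    mask = vol == label
    if not mask.any():
        raise ValueError(f"label {label} absent from the volume")
    return mask


def cell_volume(labels: LabelVolume, label: int, spacing: Sequence[float] | None = None) -> float:
    """Cell volume in µm³: voxel count times voxel volume."""
    spacing = labels.spacing if spacing is None else tuple(spacing)
    mask = _require_label(labels.labels, label)
    return float(mask.sum()) * spacing[0] * spacing[1] * spacing[2]


def cell_surface_area(
    labels: LabelVolume,
    label: int,
    spacing: Sequence[float] | None = None,
    method: str = "faces",
) -> float:
    """Cell surface area in µm².

    ``method="faces"`` counts voxel faces exposed to a different label and
    weights each by its physical face area — exact for blocky regions,
    about 1.5x the true area of a smooth surface.  ``method="isosurface"``
    measures a marching-cubes triangulation instead, close to the true
    area of smooth cells.
    """
    spacing = labels.spacing if spacing is None else tuple(spacing)
    mask = _require_label(labels.labels, label)
    if method == "faces":
        sx, sy, sz = spacing
        face_area = (sy * sz, sx * sz, sx * sy)
        total = 0.0
        for axis, area in enumerate(face_area):
            m = np.moveaxis(mask, axis, 0)
            diff = m[1:] != m[:-1]
            internal_exposed = (diff & (m[1:] | m[:-1])).sum()
            border_exposed = m[0].sum() + m[-1].sum()
            total += area * float(internal_exposed + border_exposed)
        return total
    if method == "isosurface":
        # light smoothing before triangulation suppresses the voxel
        # staircase that would otherwise bias the area upward ~10%
        padded = ndi.gaussian_filter(np.pad(mask.astype(np.float64), 2), 1.0)
        verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=spacing)
        return float(measure.mesh_surface_area(verts, faces))
    raise ValueError(f"unknown method {method!r}")


def neighbor_face_counts(labels: LabelVolume, label: int) -> dict[int, int]:
    """Face-adjacency counts between one cell and every touching label.

    Keys are neighbor labels (0 = background); values count the shared
    voxel faces, i.e. the discrete interface area in faces.
    """
    vol = labels.labels
    _require_label(vol, label)
    counts: dict[int, int] = {}
    for axis in range(3):
        a = np.moveaxis(vol, axis, 0)
        lo, hi = a[:-1], a[1:]
        sel = (lo == label) ^ (hi == label)
        other = np.where(lo == label, hi, lo)[sel]
        for lab, n in zip(*np.unique(other, return_counts=True)):
            counts[int(lab)] = counts.get(int(lab), 0) + int(n)
    return counts


def classify_boundary_cells(labels: LabelVolume) -> dict[int, bool]:
    """Per-label flag: does the cell touch background (26-adjacency)?

    The stack border counts as background, so a cell hitting the edge of
    the grid is a boundary cell.
    """
    vol = labels.labels
    bg = np.pad(vol, 1) == 0
    near_bg = ndi.binary_dilation(bg, structure=_FACE26)[1:-1, 1:-1, 1:-1]
    out = {}
    for lab in labels.cell_labels():
        out[int(lab)] = bool(near_bg[vol == lab].any())
    return out


def interface_ratio_matrix(
    volumes: Sequence[tuple[int, LabelVolume]],
    focal_name: str,
    records: Sequence[NucleusRecord],
    include_background: bool = False,
) -> pd.DataFrame:
    """Interface fractions of a focal cell with its neighbors over time.

    Rows are neighbor names (or ``"background"``), columns are time
    points; each column sums to 1.  Background contact is excluded (and
    the cell-cell ratios renormalized) unless ``include_background``.
    Time points where the focal cell is absent are omitted.
    """
    name_by_tl = {(r.time, r.label): r.name for r in records}
    label_by_tn = {(r.time, r.name): r.label for r in records}
    columns: dict[int, dict[str, float]] = {}
    for time, vol in volumes:
        focal_label = label_by_tn.get((time, focal_name))
        if focal_label is None or not (vol.labels == focal_label).any():
            continue
        counts = neighbor_face_counts(vol, focal_label)
        if not include_background:
            counts.pop(0, None)
        total = sum(counts.values())
        if total == 0:
            continue
        col = {}
        for lab, n in counts.items():
            key = "background" if lab == 0 else name_by_tl.get((time, lab), f"label_{lab}")
            col[key] = col.get(key, 0.0) + n / total
        columns[time] = col
    df = pd.DataFrame(columns).fillna(0.0)
    return df.sort_index(axis=1)


def match_labels(truth: LabelVolume, seg: LabelVolume) -> dict[int, int]:
    """Pair truth cells with segmentation cells by maximal voxel overlap.

    One-to-one assignment (Hungarian on the overlap matrix); truth cells
    with no overlapping segmentation cell stay unmatched.
    """
    if truth.shape != seg.shape:
        raise ValueError(f"shape mismatch: {truth.shape} vs {seg.shape}")
    t, s = truth.labels.ravel(), seg.labels.ravel()
    fg = (t > 0) & (s > 0)
    t_labels = truth.cell_labels()
    s_labels = seg.cell_labels()
    if len(t_labels) == 0 or len(s_labels) == 0:
        return {}
    t_idx = np.searchsorted(t_labels, t[fg])
    s_idx = np.searchsorted(s_labels, s[fg])
    overlap = np.zeros((len(t_labels), len(s_labels)), dtype=np.int64)
    np.add.at(overlap, (t_idx, s_idx), 1)
    rows, cols = linear_sum_assignment(overlap, maximize=True)
    return {
        int(t_labels[i]): int(s_labels[j])
        for i, j in zip(rows, cols)
        if overlap[i, j] > 0
    }


def multilabel_dice(truth: LabelVolume, seg: LabelVolume) -> float:
    """Multi-label Dice over all ground-truth cells, in [0, 1].

    Truth and segmentation labels are paired by maximal overlap; unmatched
    truth cells contribute only to the denominator.
    """
    matching = match_labels(truth, seg)
    t, s = truth.labels, seg.labels
    num = 0
    den = 0
    for lab in truth.cell_labels():
        t_mask = t == lab
        nt = int(t_mask.sum())
        m = matching.get(int(lab))
        if m is None:
            den += nt
            continue
        s_mask = s == m
        num += int((t_mask & s_mask).sum())
        den += nt + int(s_mask.sum())
    if den == 0:
        raise ValueError("no cells in the ground truth")
    return 2.0 * num / den


def per_cell_dice(truth: LabelVolume, seg: LabelVolume) -> dict[int, float]:
    """Dice of each truth cell against its overlap-matched segment."""
    matching = match_labels(truth, seg)
    out = {}
    for lab in truth.cell_labels():
        t_mask = truth.labels == lab
        m = matching.get(int(lab))
        if m is None:
            out[int(lab)] = 0.0
            continue
        s_mask = seg.labels == m
        out[int(lab)] = 2.0 * int((t_mask & s_mask).sum()) / (int(t_mask.sum()) + int(s_mask.sum()))
    return out


def feature_table(
    labels: LabelVolume,
    records: Sequence[NucleusRecord],
    time: int,
    spacing: Sequence[float] | None = None,
    area_method: str = "faces",
) -> pd.DataFrame:
    """One feature row per cell present in the volume at a time point."""
    spacing = labels.spacing if spacing is None else tuple(spacing)
    name_by_label = {r.label: r.name for r in records if r.time == time}
    boundary = classify_boundary_cells(labels)
    rows = []
    for lab in labels.cell_labels():
        lab = int(lab)
        nbrs = tuple(sorted(k for k in neighbor_face_counts(labels, lab) if k != 0))
        rows.append(
            {
                "time": time,
                "name": name_by_label.get(lab, f"label_{lab}"),
                "label": lab,
                "volume_um3": cell_volume(labels, lab, spacing),
                "surface_area_um2": cell_surface_area(labels, lab, spacing, area_method),
                "neighbors": ",".join(str(n) for n in nbrs),
                "is_boundary": boundary[lab],
            }
        )
    return pd.DataFrame(rows)
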