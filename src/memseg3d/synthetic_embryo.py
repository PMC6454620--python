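"""Ground-truthed synthetic embryo stacks for end-to-end validation.

The phantom emulates a fluorescent membrane stack of an early embryo:
a convex (ellipsoidal) embryo in a dark background, space-filling convex
cells (a Voronoi partition of seeded random centers) with thin bright
membrane walls, intensity attenuation with slice depth, additive noise
blobs, optional detached membrane patches, an optional cavity punched
into the upper embryo surface, and optional daughter-cell pairs whose
shared wall carries a membrane hole (division in progress).  Every
degradation is recorded as a ground-truth mask, and one nucleus is placed
strictly inside each cell, so the full pipeline can be scored against
known answers.

What it does not emulate: the confocal point-spread function, Poisson
shot noise (a Gaussian-blob noise model is the default; it gives the
region filter controllable, reproducible test cases), or cell-shape
irregularity beyond convex polyhedra.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi

from .division_correction import DaughterPair
from .stack_io import IntensityStack, LabelVolume, NucleusRecord

__all__ = ["PhantomSpec", "Phantom", "generate_phantom"]

_FACE6 = ndi.generate_binary_structure(3, 1)


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic embryo.

    Defaults describe the standard validation condition: a 96x96x64 grid,
    near-grid-filling ellipsoid, thin bright membranes, 1.5%-per-slice
    depth attenuation, and six noise blobs.
    """

    shape: tuple[int, int, int] = (96, 96, 64)
    semi_axes: tuple[float, float, float] = (40.0, 40.0, 26.0)
    n_cells: int = 16
    membrane_thickness: int = 2          # voxels across a cell-cell wall
    membrane_peak: float = 200.0         # arbitrary intensity units
    z_attenuation: float = 0.985         # per-slice multiplicative decay
    blur_sigma: float = 1.0              # imaging blur, voxels
    n_noise_blobs: int = 6
    noise_radius: tuple[float, float] = (3.0, 5.0)
    noise_intensity: float = 150.0
    noise_clearance: float = 6.0         # min gap between a blob and any membrane
    noise_location: str = "anywhere"     # "anywhere" | "inside" (cell interiors only)
    n_detached_patches: int = 0          # surface patches cut loose and sagged inward
    patch_radius: float = 6.0
    patch_gap: float = 2.5
    patch_offset: float = 3.0            # inward sag of a detached patch, voxels
    cavity: tuple[float, float, float] | None = None   # (cx, cy, radius) in (x, y)
    n_dividing_pairs: int = 0
    hole_fraction: float = 0.6           # interface fraction deleted for dividing pairs
    n_completed_pairs: int = 0
    background_noise: float = 2.0        # additive Gaussian sigma
    time: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("need at least one cell")
        if not 0 < self.z_attenuation <= 1:
            raise ValueError("z_attenuation must lie in (0, 1]")
        if not 0 <= self.hole_fraction <= 1:
            raise ValueError("hole_fraction must lie in [0, 1]")


@dataclass
class Phantom:
    """A generated phantom with all ground-truth artifacts."""

    spec: PhantomSpec
    membrane: IntensityStack
    truth: LabelVolume
    lineage: list[NucleusRecord]
    membrane_mask: np.ndarray            # bool, final (post-deletion) wall set
    boundary_set: np.ndarray             # bool, wall set before any deletion
    noise_labels: np.ndarray             # int, blob k has value k (0 = none)
    patch_labels: np.ndarray             # int, detached patch k has value k
    cavity_deleted: np.ndarray           # bool, voxels removed by the cavity
    hole_masks: dict[tuple[int, int], np.ndarray]
    dividing_pairs: list[DaughterPair]
    completed_pairs: list[DaughterPair]


def _sample_centers(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    a, b, c = spec.semi_axes
    cx, cy, cz = (n / 2.0 for n in spec.shape)
    vol = 4.0 / 3.0 * math.pi * a * b * c
    if vol < 30 * spec.n_cells:
        raise ValueError("ellipsoid too small for the requested cell count")
    d_min = 0.75 * (vol / spec.n_cells) ** (1.0 / 3.0)
    while d_min > 1.0:
        centers: list[np.ndarray] = []
        for _ in range(20000):
            p = rng.uniform(-1, 1, size=3)
            if (p ** 2).sum() > 0.85 ** 2:
                continue
            cand = np.array([cx + p[0] * a, cy + p[1] * b, cz + p[2] * c])
            if all(np.linalg.norm(cand - q) >= d_min for q in centers):
                centers.append(cand)
                if len(centers) == spec.n_cells:
                    return np.array(centers)
        d_min *= 0.8  # packing too tight for this draw; relax and retry
    raise ValueError("could not place cell centers inside the ellipsoid")


def _voronoi_truth(spec: PhantomSpec, centers: np.ndarray) -> np.ndarray:
    nx, ny, nz = spec.shape
    a, b, c = spec.semi_axes
    cx, cy, cz = nx / 2.0, ny / 2.0, nz / 2.0
    X, Y, Z = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    inside = ((X - cx) / a) ** 2 + ((Y - cy) / b) ** 2 + ((Z - cz) / c) ** 2 <= 1.0
    best_d = np.full(spec.shape, np.inf)
    labels = np.zeros(spec.shape, dtype=np.int32)
    for i, (px, py, pz) in enumerate(centers, start=1):
        d2 = (X - px) ** 2 + (Y - py) ** 2 + (Z - pz) ** 2
        closer = inside & (d2 < best_d)
        best_d[closer] = d2[closer]
        labels[closer] = i
    return labels


def _cell_boundary_set(truth: np.ndarray, thickness: int) -> np.ndarray:
    """Voxels adjacent to a label change, two layers thick across every wall.

    Cell-cell walls get one layer per cell; the embryo outline gets the
    cell-side layer plus one background-side layer, so the outer shell is
    as thick (and after blurring as bright) as interior walls.
    """
    padded = np.pad(truth, 1, constant_values=0)
    boundary = np.zeros(truth.shape, dtype=bool)
    core = padded[1:-1, 1:-1, 1:-1]
    for axis in range(3):
        for shift in (-1, 1):
            nb = np.roll(padded, shift, axis=axis)[1:-1, 1:-1, 1:-1]
            boundary |= nb != core
    outer = boundary & (truth == 0)  # background-side layer of the outline
    boundary &= truth > 0
    boundary |= outer & ndi.binary_dilation(truth > 0, structure=_FACE6)
    if thickness > 2:
        r = (thickness - 2) / 2.0
        boundary = ndi.distance_transform_edt(~boundary) <= r
    return boundary


def _adjacent_pairs(truth: np.ndarray) -> list[tuple[int, int, int]]:
    """(face_count, a, b) for every touching cell pair, largest first."""
    counts: dict[tuple[int, int], int] = {}
    for axis in range(3):
        m = np.moveaxis(truth, axis, 0)
        lo, hi = m[:-1], m[1:]
        sel = (lo != hi) & (lo > 0) & (hi > 0)
        if not sel.any():
            continue
        pairs = np.stack([lo[sel], hi[sel]], axis=1)
        pairs.sort(axis=1)
        uniq, n_faces = np.unique(pairs, axis=0, return_counts=True)
        for (a, b), n in zip(uniq, n_faces):
            counts[(int(a), int(b))] = counts.get((int(a), int(b)), 0) + int(n)
    out = [(n, a, b) for (a, b), n in counts.items()]
    out.sort(key=lambda t: (-t[0], t[1], t[2]))
    return out


def _pair_interface(membrane: np.ndarray, truth: np.ndarray, a: int, b: int) -> np.ndarray:
    near_a = ndi.binary_dilation(truth == a, structure=_FACE6)
    near_b = ndi.binary_dilation(truth == b, structure=_FACE6)
    return membrane & (((truth == a) & near_b) | ((truth == b) & near_a))


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Generate one phantom; bit-identical for identical specs."""
    rng = np.random.default_rng(spec.seed)
    nx, ny, nz = spec.shape
    centers = _sample_centers(spec, rng)
    truth = _voronoi_truth(spec, centers)
    boundary = _cell_boundary_set(truth, spec.membrane_thickness)
    membrane_mask = boundary.copy()
    adjacency = _adjacent_pairs(truth)

    # --- daughter pairs: dividing ones get an interface hole -------------
    need = spec.n_dividing_pairs + spec.n_completed_pairs
    used: set[int] = set()
    chosen: list[tuple[int, int]] = []
    for n_faces, a, b in adjacency:
        if len(chosen) == need:
            break
        if a in used or b in used or n_faces < 30:
            continue
        chosen.append((a, b))
        used.update((a, b))
    if len(chosen) < need:
        raise ValueError("not enough well-separated adjacent cell pairs for the "
                         "requested daughter pairs")
    dividing = chosen[: spec.n_dividing_pairs]
    completed = chosen[spec.n_dividing_pairs: need]
    hole_masks: dict[tuple[int, int], np.ndarray] = {}
    for a, b in dividing:
        iface = _pair_interface(membrane_mask, truth, a, b)
        coords = np.argwhere(iface)
        centroid = coords.mean(axis=0)
        d = np.linalg.norm(coords - centroid, axis=1)
        k = int(math.ceil(spec.hole_fraction * len(coords)))
        hole_idx = coords[np.argsort(d, kind="stable")[:k]]
        hole = np.zeros(spec.shape, dtype=bool)
        hole[tuple(hole_idx.T)] = True
        membrane_mask &= ~hole
        hole_masks[(a, b)] = hole

    # --- detached membrane patches (region-filter positives) -------------
    # A detached patch models a piece of outer surface that sagged inward:
    # the piece (plus a surrounding gap ring) is cut out of the shell and
    # re-inserted a few voxels toward the embryo center.  Its influence
    # region is then a thin slab hugging the surface — the polarized
    # signature the region filter keys on — whereas an isolated noise blob
    # influences a round neighborhood.
    patch_labels = np.zeros(spec.shape, dtype=np.int16)
    embryo_center = np.array([nx / 2.0, ny / 2.0, nz / 2.0])
    struct26 = ndi.generate_binary_structure(3, 3)
    for k in range(1, spec.n_detached_patches + 1):
        ext = membrane_mask & ndi.binary_dilation(truth == 0, structure=_FACE6)
        # sag the patch into open cell interior: keep clear of cell-cell walls
        interior_walls = membrane_mask & ~ext
        room = ndi.distance_transform_edt(~interior_walls)
        good = ext & (room >= spec.patch_radius + spec.patch_offset)
        cand = np.argwhere(good if good.any() else ext)
        placed = False
        for _ in range(200):
            center = cand[rng.integers(len(cand))]
            normal = embryo_center - center
            nrm = np.linalg.norm(normal)
            if nrm == 0:
                continue
            shift = np.rint(normal / nrm * spec.patch_offset).astype(int)
            coords = np.argwhere(membrane_mask)
            dd = np.linalg.norm(coords - center, axis=1)
            patch_sel = coords[dd <= spec.patch_radius]
            gap_sel = coords[(dd > spec.patch_radius) & (dd <= spec.patch_radius + spec.patch_gap)]
            if len(patch_sel) < 20:
                continue
            moved = patch_sel + shift
            if moved.min() < 0 or (moved >= np.array(spec.shape)).any():
                continue
            trial = membrane_mask.copy()
            trial[tuple(patch_sel.T)] = False
            trial[tuple(gap_sel.T)] = False
            moved_mask = np.zeros(spec.shape, dtype=bool)
            moved_mask[tuple(moved.T)] = True
            # sagged piece must stay a separate component
            if (moved_mask & ndi.binary_dilation(trial, structure=struct26)).any():
                continue
            if (moved_mask & (patch_labels > 0)).any():
                continue
            membrane_mask = trial | moved_mask
            patch_labels[moved_mask] = k
            placed = True
            break
        if not placed:
            raise ValueError("could not place a detached membrane patch")

    # --- surface cavity ---------------------------------------------------
    cavity_deleted = np.zeros(spec.shape, dtype=bool)
    if spec.cavity is not None:
        ccx, ccy, cr = spec.cavity
        X, Y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
        footprint = (X - ccx) ** 2 + (Y - ccy) ** 2 <= cr ** 2
        upper = np.zeros(spec.shape, dtype=bool)
        upper[:, :, int(nz / 2):] = True
        exterior_wall = membrane_mask & ndi.binary_dilation(truth == 0, structure=_FACE6)
        cavity_deleted = exterior_wall & upper & footprint[:, :, None]
        membrane_mask &= ~cavity_deleted

    # --- render intensities ----------------------------------------------
    img = np.zeros(spec.shape, dtype=np.float64)
    img[membrane_mask | (patch_labels > 0)] = spec.membrane_peak
    img = ndi.gaussian_filter(img, sigma=spec.blur_sigma)

    noise_labels = np.zeros(spec.shape, dtype=np.int16)
    if spec.n_noise_blobs > 0:
        signal = membrane_mask | (patch_labels > 0)
        dist_to_signal = ndi.distance_transform_edt(~signal)
        X, Y, Z = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
        for k in range(1, spec.n_noise_blobs + 1):
            r = rng.uniform(*spec.noise_radius)
            ok = (dist_to_signal > r + spec.noise_clearance) & (noise_labels == 0)
            if spec.noise_location == "inside":
                ok &= truth > 0
            ok[: 3], ok[-3:] = False, False
            ok[:, :3], ok[:, -3:] = False, False
            ok[:, :, :3], ok[:, :, -3:] = False, False
            cand = np.argwhere(ok)
            if len(cand) == 0:
                raise ValueError("no room left for a noise blob")
            bx, by, bz = cand[rng.integers(len(cand))]
            d2 = (X - bx) ** 2 + (Y - by) ** 2 + (Z - bz) ** 2
            img += spec.noise_intensity * np.exp(-d2 / (2 * (r / 1.5) ** 2))
            noise_labels[d2 <= r ** 2] = k

    z_factor = spec.z_attenuation ** np.arange(nz)
    img *= z_factor[None, None, :]
    if spec.background_noise > 0:
        img += np.abs(rng.normal(0.0, spec.background_noise, size=spec.shape))
    img = np.clip(img, 0, None)

    # --- nuclei + lineage -------------------------------------------------
    records: list[NucleusRecord] = []
    parent_of: dict[int, tuple[str, str]] = {}   # label -> (name, parent_name)
    for j, (a, b) in enumerate(dividing + completed, start=1):
        parent = f"P{j}"
        parent_of[a] = (f"{parent}d1", parent)
        parent_of[b] = (f"{parent}d2", parent)
        pa = 0.5 * (centers[a - 1] + centers[b - 1])
        records.append(NucleusRecord(spec.time - 1, parent, spec.n_cells + j,
                                     tuple(float(v) for v in pa), ""))
    for lab in range(1, spec.n_cells + 1):
        inner = ndi.distance_transform_edt(truth == lab)
        pos = np.unravel_index(np.argmax(inner), spec.shape)
        if truth[pos] != lab or inner[pos] <= 1.0:
            raise AssertionError(f"nucleus of cell {lab} is not strictly interior")
        name, parent = parent_of.get(lab, (f"C{lab:02d}", ""))
        records.append(NucleusRecord(spec.time, name, lab,
                                     tuple(float(v) for v in pos), parent))

    div_pairs = [DaughterPair(parent_of[a][1], a, b, spec.time) for a, b in dividing]
    comp_pairs = [DaughterPair(parent_of[a][1], a, b, spec.time) for a, b in completed]
    return Phantom(
        spec=spec,
        membrane=IntensityStack(img),
        truth=LabelVolume(truth),
        lineage=records,
        membrane_mask=membrane_mask,
        boundary_set=boundary,
        noise_labels=noise_labels,
        patch_labels=patch_labels,
        cavity_deleted=cavity_deleted,
        hole_masks=hole_masks,
        dividing_pairs=div_pairs,
        completed_pairs=comp_pairs,
    )
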