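"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by the most literal method available —
exhaustive search, direct set arithmetic, linear-scan flooding — and is
kept free of the package's own implementation choices.
"""

from __future__ import annotations

import numpy as np


def brute_sq_edt(mask: np.ndarray) -> np.ndarray:
    """Exact squared Euclidean distance to the nearest true voxel, O(n*m)."""
    mask = np.asarray(mask, dtype=bool)
    pts = np.argwhere(mask)
    if len(pts) == 0:
        raise ValueError("empty set")
    coords = np.argwhere(np.ones(mask.shape, dtype=bool))
    d2 = ((coords[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2).min(axis=1)
    return d2.reshape(mask.shape)


def brute_influence_region(current: np.ndarray, candidate: np.ndarray) -> np.ndarray:
    """Influence region by two exhaustive nearest-set computations."""
    if not np.asarray(candidate, dtype=bool).any():
        return np.zeros_like(np.asarray(current, dtype=bool))
    return brute_sq_edt(current) != brute_sq_edt(current | candidate)


def flood_watershed(terrain: np.ndarray, markers: np.ndarray) -> np.ndarray:
    """Priority-flood watershed by linear frontier scan (no heap).

    Semantics: voxels are claimed in ascending (terrain value, insertion
    age); seeds enter the frontier in ascending label order (raster order
    within a label); 6-connectivity.
    """
    terrain = np.asarray(terrain, dtype=float)
    out = np.asarray(markers).copy()
    frontier: list[tuple[float, int, tuple[int, int, int], int]] = []
    age = 0
    seeds = np.argwhere(out > 0)
    order = np.lexsort((np.arange(len(seeds)), out[tuple(seeds.T)]))
    for idx in order:
        p = tuple(seeds[idx])
        frontier.append((terrain[p], age, p, out[p]))
        age += 1
    shape = terrain.shape
    nbrs = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    while frontier:
        k = min(range(len(frontier)), key=lambda i: frontier[i][:2])
        _, _, (x, y, z), lab = frontier.pop(k)
        for dx, dy, dz in nbrs:
            p = (x + dx, y + dy, z + dz)
            if all(0 <= c < n for c, n in zip(p, shape)) and out[p] == 0:
                out[p] = lab
                frontier.append((terrain[p], age, p, lab))
                age += 1
    return out


def brute_otsu(values: np.ndarray) -> float:
    """Otsu threshold by exhaustive between-class-variance search.

    Scans midpoints between consecutive distinct values; returns the
    midpoint maximizing the between-class variance.
    """
    v = np.sort(np.asarray(values, dtype=float).ravel())
    uniq = np.unique(v)
    if len(uniq) < 2:
        raise ValueError("single-class data")
    best_t, best_var = None, -1.0
    for lo, hi in zip(uniq[:-1], uniq[1:]):
        t = 0.5 * (lo + hi)
        a, b = v[v <= t], v[v > t]
        var = len(a) * len(b) * (a.mean() - b.mean()) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return float(best_t)


def dice_by_sets(truth: np.ndarray, seg: np.ndarray, matching: dict[int, int]) -> float:
    """Multi-label Dice by direct per-cell set arithmetic."""
    num = den = 0
    for t_lab in np.unique(truth):
        if t_lab == 0:
            continue
        t_set = set(map(tuple, np.argwhere(truth == t_lab)))
        s_lab = matching.get(int(t_lab))
        s_set = (
            set(map(tuple, np.argwhere(seg == s_lab))) if s_lab is not None else set()
        )
        num += len(t_set & s_set)
        den += len(t_set) + len(s_set)
    return 2.0 * num / den
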