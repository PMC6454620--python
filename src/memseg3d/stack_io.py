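"""Stack and lineage I/O plus grid resampling.

Conventions used by every module in this package:

* voxel grids are indexed ``(x, y, z)`` with 0-based integer coordinates,
  ``z`` being the slice (depth) axis;
* all physical sizes are in micrometres;
* after resampling, every downstream operation works on the resampled
  ("working") grid, so seed positions and voxel grids always align.

Intensity stacks are stored on disk as multi-page grayscale TIFF (one page
per z slice, pages indexed ``(z, y, x)`` as written by common acquisition
software); label volumes as 16-bit integer TIFF; nucleus lineages as plain
CSV with a header.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from skimage.transform import resize

__all__ = [
    "IntensityStack",
    "LabelVolume",
    "NucleusRecord",
    "read_stack",
    "write_stack",
    "read_labels",
    "write_labels",
    "resample_stack",
    "read_lineage",
    "write_lineage",
    "records_at",
]

LINEAGE_COLUMNS = ["time", "name", "label", "x", "y", "z", "parent_name"]


@dataclass
class IntensityStack:
    """A 3D scalar voxel grid with per-axis physical spacing.

    Parameters
    ----------
    voxels
        Non-negative intensities, axis order ``(x, y, z)``.
    spacing
        Physical voxel size per axis in micrometres.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D grid, got ndim={self.voxels.ndim}")
        if min(self.voxels.shape) < 1:
            raise ValueError("all dimensions must be >= 1")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 strictly positive values, got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class LabelVolume:
    """Integer voxel grid; 0 is background, positive integers are cells."""

    labels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"expected a 3D grid, got ndim={self.labels.ndim}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError(f"labels must be integers, got dtype {self.labels.dtype}")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def cell_labels(self) -> np.ndarray:
        """Sorted positive labels present in the volume."""
        u = np.unique(self.labels)
        return u[u > 0]


@dataclass(frozen=True)
class NucleusRecord:
    """One nucleus at one time point of the lineage.

    ``position`` is in voxel coordinates of the working grid; ``parent_name``
    is the empty string for founder cells.
    """

    time: int
    name: str
    label: int
    position: tuple[float, float, float]
    parent_name: str = ""

    def __post_init__(self) -> None:
        if self.label <= 0:
            raise ValueError(f"nucleus label must be positive, got {self.label}")


def _to_xyz(pages: np.ndarray) -> np.ndarray:
    # TIFF pages come in as (z, y, x); package convention is (x, y, z)
    return np.ascontiguousarray(pages.transpose(2, 1, 0))


def _to_pages(voxels: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(voxels.transpose(2, 1, 0))


def read_stack(path: str | Path, spacing: Sequence[float] = (1.0, 1.0, 1.0)) -> IntensityStack:
    """Read a (multi-page) grayscale TIFF as an intensity stack."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    if pages.ndim != 3:
        raise ValueError(f"{path}: expected 3D content, got shape {pages.shape}")
    return IntensityStack(_to_xyz(pages).astype(np.float64), tuple(spacing))


def write_stack(stack: IntensityStack, path: str | Path) -> None:
    tifffile.imwrite(Path(path), _to_pages(stack.voxels.astype(np.float32)),
                     photometric="minisblack")


def read_labels(path: str | Path, spacing: Sequence[float] = (1.0, 1.0, 1.0)) -> LabelVolume:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    if pages.ndim != 3:
        raise ValueError(f"{path}: expected 3D content, got shape {pages.shape}")
    return LabelVolume(_to_xyz(pages).astype(np.int32), tuple(spacing))


def write_labels(volume: LabelVolume, path: str | Path) -> None:
    if volume.labels.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError("labels exceed the 16-bit TIFF range")
    tifffile.imwrite(Path(path), _to_pages(volume.labels.astype(np.uint16)),
                     photometric="minisblack")


def resample_stack(stack: IntensityStack, target_shape: Sequence[int]) -> IntensityStack:
    """Trilinear resampling onto ``target_shape``, preserving physical extent.

    Spacing is rescaled by old/new size per axis so that
    ``shape[i] * spacing[i]`` is unchanged.
    """
    target_shape = tuple(int(n) for n in target_shape)
    if len(target_shape) != 3 or any(n <= 0 for n in target_shape):
        raise ValueError(f"target shape must be 3 positive integers, got {target_shape}")
    if target_shape == stack.shape:
        return IntensityStack(stack.voxels.copy(), stack.spacing)
    out = resize(
        stack.voxels.astype(np.float64),
        target_shape,
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    new_spacing = tuple(
        s * old / new for s, old, new in zip(stack.spacing, stack.shape, target_shape)
    )
    return IntensityStack(out, new_spacing)


def read_lineage(
    path: str | Path,
    scale: Sequence[float] = (1.0, 1.0, 1.0),
    shape: Sequence[int] | None = None,
) -> list[NucleusRecord]:
    """Parse a lineage CSV into nucleus records.

    ``scale`` converts source-grid coordinates to the working grid
    (working = source * scale), e.g. ``(205/512, 285/712, 134/70)`` when
    positions were recorded on the acquisition grid.  When ``shape`` is
    given, out-of-bounds positions are rejected with the offending row
    identified.  Duplicate labels within a time point are rejected.
    """
    df = pd.read_csv(Path(path), dtype={"name": str, "parent_name": str}, keep_default_na=False)
    missing = [c for c in LINEAGE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"lineage file missing columns: {missing}")
    dup = df.duplicated(subset=["time", "label"], keep=False)
    if dup.any():
        rows = df.index[dup].tolist()
        raise ValueError(f"duplicate nucleus label within a time point at rows {rows}")
    sx, sy, sz = (float(s) for s in scale)
    records = []
    for idx, row in df.iterrows():
        pos = (float(row["x"]) * sx, float(row["y"]) * sy, float(row["z"]) * sz)
        if shape is not None and not all(0 <= p <= n - 1 for p, n in zip(pos, shape)):
            raise ValueError(
                f"row {idx} ({row['name']!r} at t={row['time']}): position {pos} "
                f"outside grid of shape {tuple(shape)}"
            )
        records.append(
            NucleusRecord(
                time=int(row["time"]),
                name=str(row["name"]),
                label=int(row["label"]),
                position=pos,
                parent_name=str(row["parent_name"]),
            )
        )
    return records


def write_lineage(records: Sequence[NucleusRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "time": r.time,
                "name": r.name,
                "label": r.label,
                "x": r.position[0],
                "y": r.position[1],
                "z": r.position[2],
                "parent_name": r.parent_name,
            }
            for r in records
        ],
        columns=LINEAGE_COLUMNS,
    )
    df.to_csv(Path(path), index=False)


def records_at(records: Sequence[NucleusRecord], time: int) -> list[NucleusRecord]:
    """Records of one time point, sorted by label."""
    return sorted((r for r in records if r.time == time), key=lambda r: r.label)
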