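"""End-to-end segmentation pipeline: stack in, labeled cells out.

Order of operations: Gaussian smoothing -> statistical slice normalization
-> Hessian plane enhancement -> binarization -> region filtering ->
surface cavity repair -> membrane-centered EDT terrain -> nucleus-seeded
watershed -> division correction.  Every stage's configuration and
decision log is kept on the result object.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np

from . import division_correction as dc
from . import preprocess as pp
from . import region_filter as rf
from . import surface_repair as sr
from . import watershed_seg as ws
from .stack_io import IntensityStack, LabelVolume, NucleusRecord, records_at

__all__ = ["PipelineConfig", "SegmentationResult", "segment"]


@dataclass
class PipelineConfig:
    """All tunable knobs of the pipeline, logged with every run."""

    # preprocessing
    sigma_smooth: float = 1.0
    n_bins: int = 64
    count_threshold: float | None = None     # None: 2% of median slice foreground
    normalize_direction: str = "brighten_deep"
    derivative_sigma: float = 1.0
    binarize_threshold: float = 0.35
    background_cutoff: float | None = None   # None: stack-wide Otsu
    # region filter
    connectivity: int = 26
    accept_threshold: float = 0.1
    rule_direction: str = "smaller_is_membrane"
    min_candidate_voxels: int = 10
    # surface repair
    enable_surface_repair: bool = True
    closing_radius: float = 18.0
    surface_smooth_sigma: float = 3.0
    search_depth: int = 10
    repair_lower_surface: bool = False
    # watershed
    seed_dilate_radius: float = 0.0
    # division correction
    enable_division_correction: bool = True
    division_threshold: float = 40.0


@dataclass
class SegmentationResult:
    """Labeled cells plus every intermediate product and decision log."""

    labels: LabelVolume
    config: PipelineConfig
    normalized: IntensityStack
    enhanced: IntensityStack
    binary_mask: np.ndarray
    filtered_mask: np.ndarray
    repaired_mask: np.ndarray
    terrain: np.ndarray
    threshold_line: np.ndarray
    region_decisions: list[rf.RegionDecision]
    merge_decisions: list[dc.MergeDecision]

    def config_dict(self) -> dict:
        return asdict(self.config)


def _default_count_threshold(matrix: pp.IntensityDistributionMatrix) -> float:
    """2% of the median per-slice foreground count.

    Keeps the threshold line on the bright shoulder of each slice's
    intensity distribution without riding single-bin outliers; the value
    scales with the histogram's bin count (computed for the default 64
    bins), so override ``count_threshold`` when changing ``n_bins``.
    """
    per_slice = matrix.counts.sum(axis=1)
    per_slice = per_slice[per_slice > 0]
    if per_slice.size == 0:
        raise ValueError("no slice has foreground voxels")
    return max(1.0, 0.02 * float(np.median(per_slice)))


def segment(
    membrane: IntensityStack,
    lineage: Sequence[NucleusRecord],
    time: int,
    config: PipelineConfig | None = None,
) -> SegmentationResult:
    """Segment one membrane stack at one lineage time point."""
    cfg = config or PipelineConfig()

    smoothed = pp.gaussian_smooth(membrane, cfg.sigma_smooth)
    matrix = pp.build_intensity_matrix(
        smoothed, n_bins=cfg.n_bins, background_cutoff=cfg.background_cutoff
    )
    count_thr = cfg.count_threshold
    if count_thr is None:
        count_thr = _default_count_threshold(matrix)
    line = pp.extract_threshold_line(matrix, count_thr)
    normalized = pp.normalize_slices(smoothed, line, direction=cfg.normalize_direction)

    eigs = pp.hessian_eigensystem(normalized, cfg.derivative_sigma)
    enhanced = pp.enhance_membrane(eigs)
    binary = pp.binarize(enhanced, cfg.binarize_threshold)

    regions = rf.connected_components(binary, cfg.connectivity)
    filtered, region_decisions = rf.filter_regions(
        regions,
        accept_threshold=cfg.accept_threshold,
        rule_direction=cfg.rule_direction,
        min_candidate_voxels=cfg.min_candidate_voxels,
        return_decisions=True,
    )

    if cfg.enable_surface_repair:
        repaired = sr.repair_membrane(
            filtered,
            closing_radius=cfg.closing_radius,
            surface_smooth_sigma=cfg.surface_smooth_sigma,
            search_depth=cfg.search_depth,
            repair_lower_surface=cfg.repair_lower_surface,
        )
    else:
        repaired = filtered

    seeds = ws.build_seeds(
        records_at(lineage, time), membrane.shape, dilate_radius=cfg.seed_dilate_radius
    )
    terrain = ws.membrane_centered_edt(repaired)
    labels = ws.seeded_watershed(terrain, seeds)

    merge_decisions: list[dc.MergeDecision] = []
    if cfg.enable_division_correction:
        labels, merge_decisions = dc.correct_divisions(
            labels, normalized, lineage, time, cfg.division_threshold
        )
    labels = LabelVolume(labels.labels, membrane.spacing)

    return SegmentationResult(
        labels=labels,
        config=cfg,
        normalized=normalized,
        enhanced=enhanced,
        binary_mask=binary,
        filtered_mask=filtered,
        repaired_mask=repaired,
        terrain=terrain,
        threshold_line=line,
        region_decisions=region_decisions,
        merge_decisions=merge_decisions,
    )
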