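"""End-to-end analysis: movie + post-hoc channels -> stratified statistics.

Stage order: segment -> kinetic quality filter -> rolling-ball background
subtraction -> channel alignment -> edge-ROI removal -> IR quantification
-> normalization -> grouping -> kinetics -> group statistics.  Quality- or
edge-failing ROIs are excluded from *all* downstream analysis (including IR
normalization), and that choice is recorded in the run metadata.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .background import rolling_ball_stack, rolling_ball_subtract
from .io import ChannelImage, TimeLapseStack
from .kinetics import GroupSummary, KineticRecords, compute_kinetics, summarize_groups
from .quantify import IrTable, build_ir_table
from .register import AlignmentTransform, apply_shift, estimate_shift, linearity_qc
from .segment import (
    QualityCriteria,
    build_candidate_mask,
    classify_roi_quality,
    remove_edge_rois,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable parameters of the full analysis pipeline."""

    # segmentation
    min_area_px: int = 4
    max_area_px: int = 400
    threshold_k: float = 5.0
    expected_sigma_px: float = 1.5
    # kinetic quality
    max_abs_baseline_slope: float = 0.002
    max_baseline_cv: float = 0.05
    min_unloading_extent: float = 0.05
    tail_window_frames: int = 10
    # background
    rolling_ball_radius: float = 12.0
    subtract_fm_background: bool = False
    # registration
    max_shift_px: int = 20
    min_correlation: float = 0.2
    # linearity QC
    qc_min_r: float = 0.5
    qc_slope_band: tuple[float, float] = (0.5, 1.5)
    # grouping / statistics
    group_channel: str | None = None
    alpha: float = 0.05


@dataclass
class PipelineResult:
    """Everything the pipeline produces, plus a metadata audit trail."""

    ir_table: IrTable
    kinetics: KineticRecords
    summary: GroupSummary
    rois: "np.ndarray | object"  # final RoiSet
    transforms: dict[str, AlignmentTransform]
    metadata: dict = field(default_factory=dict)


def run_pipeline(
    stack: TimeLapseStack,
    channels: dict[str, ChannelImage],
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full post-hoc correlation analysis.

    ``channels`` maps channel names to post-hoc immunofluorescence images
    (typically the marker under test first, a control marker second).
    Deterministic given identical inputs.
    """
    config = config or PipelineConfig()
    if not channels:
        raise ValueError("pipeline requires at least one post-hoc channel")
    meta: dict = {"config": dataclasses.asdict(config), "stages": {}}

    def _stage(name):
        meta["stages"][name] = "ok"

    try:
        if config.subtract_fm_background:
            stack = TimeLapseStack(
                rolling_ball_stack(stack.frames, config.rolling_ball_radius), stack.timing
            )
        _stage("fm_background")

        rois = build_candidate_mask(
            stack,
            min_area_px=config.min_area_px,
            max_area_px=config.max_area_px,
            threshold_k=config.threshold_k,
            tail_window_frames=config.tail_window_frames,
            expected_sigma_px=config.expected_sigma_px,
        )
        meta["n_candidate_rois"] = rois.n_rois
        _stage("segment")

        criteria = QualityCriteria(
            max_abs_baseline_slope=config.max_abs_baseline_slope,
            max_baseline_cv=config.max_baseline_cv,
            min_unloading_extent=config.min_unloading_extent,
            n_baseline_frames=stack.timing.n_baseline_frames,
            tail_window_frames=config.tail_window_frames,
        )
        verdict = classify_roi_quality(stack, rois, criteria)
        rois = rois.subset(verdict.passed)
        meta["n_quality_passed"] = rois.n_rois
        meta["quality_exclusion_policy"] = (
            "quality-failed ROIs are excluded from all downstream analysis, "
            "including IR normalization"
        )
        _stage("quality_filter")

        corrected: dict[str, ChannelImage] = {}
        for name, ch in channels.items():
            pix, _ = rolling_ball_subtract(ch.pixels, config.rolling_ball_radius)
            corrected[name] = ChannelImage(pix, channel_name=name, valid_mask=ch.valid_mask)
        _stage("rolling_ball")

        reference, _ = rolling_ball_subtract(
            stack.baseline_mean_image(), config.rolling_ball_radius
        )
        transforms: dict[str, AlignmentTransform] = {}
        aligned: dict[str, ChannelImage] = {}
        for name, ch in corrected.items():
            tr = estimate_shift(
                reference,
                ch.pixels,
                max_shift_px=config.max_shift_px,
                min_correlation=config.min_correlation,
                channel_name=name,
            )
            transforms[name] = tr
            aligned[name] = apply_shift(ch, tr)
        meta["shifts_px"] = {n: list(t.shift_px) for n, t in transforms.items()}
        meta["peak_correlations"] = {n: t.peak_correlation for n, t in transforms.items()}
        _stage("align")

        valid = np.logical_and.reduce([ch.valid_mask for ch in aligned.values()])
        n_before = rois.n_rois
        rois = remove_edge_rois(rois, valid)
        meta["n_edge_removed"] = n_before - rois.n_rois
        meta["n_final_rois"] = rois.n_rois
        _stage("edge_removal")

        ir_table = build_ir_table(rois, aligned, group_channel=config.group_channel)
        _stage("quantify")

        names = list(aligned)
        if len(names) >= 2 and rois.n_rois >= 3:
            qc = linearity_qc(
                ir_table.normalized(names[0]),
                ir_table.normalized(names[1]),
                min_r=config.qc_min_r,
                slope_band=config.qc_slope_band,
            )
            meta["linearity_qc"] = dataclasses.asdict(qc)
        _stage("linearity_qc")

        kinetics = compute_kinetics(stack, rois, config.tail_window_frames)
        _stage("kinetics")

        summary = summarize_groups(kinetics, ir_table.groups, alpha=config.alpha)
        meta["group_n"] = summary.group_n
        _stage("statistics")
    except Exception as exc:
        failed = [s for s in (
            "fm_background", "segment", "quality_filter", "rolling_ball", "align",
            "edge_removal", "quantify", "linearity_qc", "kinetics", "statistics",
        ) if s not in meta["stages"]]
        stage = failed[0] if failed else "unknown"
        raise type(exc)(f"[pipeline stage: {stage}] {exc}") from exc

    return PipelineResult(
        ir_table=ir_table,
        kinetics=kinetics,
        summary=summary,
        rois=rois,
        transforms=transforms,
        metadata=meta,
    )
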