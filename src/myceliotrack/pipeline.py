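"""End-to-end analysis of one position: registration → segmentation →
skeleton graphs → tracking → metrics tables.

Per-frame stages are independent and may run concurrently; results are
collected by frame index, so tables are identical for any parallelism degree.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import RunConfig
from .io_stack import ImageStack, background_correct, register_stack
from .metrics import DerivedSummary, derive_summary, hyphal_track_metrics, position_metrics
from .segmentation import BinaryMask, binarize, clean_mask
from .skeleton_graph import Skeleton, SkeletonGraph, build_graph, prune_skeleton, skeletonize
from .tracking import HyphaTrack, track_stack


@dataclass
class PositionResult:
    """Everything the pipeline produced for one position."""

    stack: ImageStack
    masks: list[BinaryMask]
    skeletons: list[Skeleton]
    graphs: list[SkeletonGraph]
    tracks: list[HyphaTrack]
    position_timeseries: pd.DataFrame
    track_summary: pd.DataFrame
    hypha_timeseries: pd.DataFrame
    summary: DerivedSummary
    config: RunConfig

    @property
    def position_id(self) -> str:
        return self.stack.position_id


def _process_frame(frame: np.ndarray, index: int, calibration: float,
                   config: RunConfig):
    corrected = background_correct(frame, config.background_blur_um, calibration)
    mask = binarize(
        corrected,
        calibration,
        method=config.binarization_method,
        window_um=config.binarization_window_um,
        k=config.binarization_k,
        abs_contrast=config.binarization_abs_contrast,
        invert=config.invert,
    )
    mask = clean_mask(
        mask, calibration,
        min_object_um2=config.cleaning_min_object_um2,
        max_hole_um2=config.cleaning_max_hole_um2,
        closing_um=config.cleaning_closing_um,
    )
    skeleton = skeletonize(mask)
    if config.skeleton_prune_um > 0:
        skeleton = prune_skeleton(skeleton, calibration, config.skeleton_prune_um)
    graph = build_graph(
        skeleton, calibration, frame_index=index,
        smoothing_iterations=config.smoothing_iterations,
    )
    return mask, skeleton, graph


def analyze_stack(
    stack: ImageStack,
    config: Optional[RunConfig] = None,
    jobs: Optional[int] = None,
) -> PositionResult:
    """Run the full pipeline on one calibrated stack."""
    config = config or RunConfig()
    jobs = jobs if jobs is not None else config.jobs

    if len(stack) >= 2:
        stack = register_stack(stack)
    if config.crop is not None:
        stack = stack.cropped(tuple(config.crop))

    cal = stack.calibration
    indices = range(len(stack))
    if jobs and jobs > 1:
        with ThreadPoolExecutor(max_workers=jobs) as pool:
            results = list(
                pool.map(
                    lambda i: _process_frame(stack.frames[i], i, cal, config),
                    indices,
                )
            )
    else:
        results = [_process_frame(stack.frames[i], i, cal, config) for i in indices]

    masks = [r[0] for r in results]
    skeletons = [r[1] for r in results]
    graphs = [r[2] for r in results]

    tracks = track_stack(
        graphs,
        junction_radius_um=config.junction_radius_um,
        tip_radius_um=config.tip_radius_um,
        shortcut_abs_um=config.shortcut_abs_um,
        shortcut_rel=config.shortcut_rel,
        min_track_points=config.min_track_points,
        min_track_length_um=config.min_track_length_um,
    )

    series = position_metrics(graphs, masks, stack)
    track_summary, hypha_timeseries = hyphal_track_metrics(tracks, stack.timestamps)
    summary = derive_summary(series, tracks)

    return PositionResult(
        stack=stack,
        masks=masks,
        skeletons=skeletons,
        graphs=graphs,
        tracks=tracks,
        position_timeseries=series,
        track_summary=track_summary,
        hypha_timeseries=hypha_timeseries,
        summary=summary,
        config=config,
    )
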