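"""End-to-end tracking: warm-up → per-frame subtract/segment/associate → bridge.

The model warms up on the first ``T`` frames (short videos are first padded
with cyclic duplicates so the warm-up never consumes original footage);
every subsequent frame is classified online, segmented, and associated
with the active tracks; finally the gap-bridging pass joins fragments.
Results are reported on original frame indices only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .background import BackgroundParams, init_model
from .io import FrameSequence, pad_short_video
from .segmentation import DetectionSet, SegmentationParams, segment_frame
from .tracking import Tracker, TrackerConfig, trajectories_to_table

__all__ = ["TrackingResult", "run_tracking"]


@dataclass
class TrackingResult:
    """Everything the pipeline produces for one video."""

    trajectories: pd.DataFrame  # tidy table: track_id, frame, x, y, flag
    detections: dict[int, DetectionSet]  # per original frame index
    masks: dict[int, np.ndarray] = field(default_factory=dict)
    first_tracked_frame: int = 0
    summary: dict = field(default_factory=dict)


def run_tracking(
    seq: FrameSequence,
    bg_params: BackgroundParams = BackgroundParams(),
    seg_params: SegmentationParams = SegmentationParams(),
    tracker_config: TrackerConfig = TrackerConfig(),
    keep_masks: bool = False,
) -> TrackingResult:
    """Track all larvae in a video.

    Videos shorter than the warm-up length ``T`` are padded in front with a
    full cyclic copy of themselves so that every original frame is tracked
    with a warmed-up model; for longer videos the first ``T`` frames serve
    as the warm-up sample and tracking output starts at frame ``T``.
    """
    T = bg_params.warmup_frames
    if seq.n_frames < T:
        seq = pad_short_video(seq, T + seq.n_frames)
    model = init_model(seq, bg_params)
    tracker = Tracker(tracker_config)
    detections: dict[int, DetectionSet] = {}
    masks: dict[int, np.ndarray] = {}
    first_tracked = None
    for padded_idx in range(T, seq.n_frames):
        original_idx = seq.original_index(padded_idx)
        if original_idx is None:  # still inside padding
            model.classify(seq.frames[padded_idx])
            continue
        mask = model.classify(seq.frames[padded_idx])
        dets = segment_frame(seq.frames[padded_idx], mask, seg_params, frame_index=original_idx)
        detections[original_idx] = dets
        if keep_masks:
            masks[original_idx] = mask
        tracker.step(original_idx, dets)
        if first_tracked is None:
            first_tracked = original_idx
    trajectories = tracker.finish()
    table = trajectories_to_table(trajectories)
    summary = {
        "n_tracks": len(trajectories),
        "n_bridged_gaps": int(sum(len(t.bridged_gaps) for t in trajectories)),
        "n_error_frames": int(sum(len(t.error_frames) for t in trajectories)),
        "n_frames_tracked": len(detections),
        "first_tracked_frame": first_tracked if first_tracked is not None else 0,
        "n_detections": int(sum(len(d) for d in detections.values())),
    }
    return TrackingResult(
        trajectories=table,
        detections=detections,
        masks=masks,
        first_tracked_frame=first_tracked if first_tracked is not None else 0,
        summary=summary,
    )
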