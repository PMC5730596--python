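"""Segmentation and tracking scores against ground truth.

Segmentation is scored at pixel level with Recall, Precision and their
harmonic mean (F-measure), plus the Similarity Index

    SI = F_measure − Num_miss / (2 · Num_GT),

which additionally penalises ground-truth objects that were missed or
occluded (an object counts as found when a predicted region centroid lies
within the match radius of it).

Tracking is scored with the CLEAR-MOT protocol:

    MOTP = Σ_{i,t} |D_{i,t} − GT_{i,t}|  /  Σ_t N_t          (mean match distance)
    MOTA = 1 − Σ_t (m_t + fp_t + mme_t) / Σ_t g_t            (can be negative)

where per frame t: ``m_t`` missed objects, ``fp_t`` false-positive
detections, ``mme_t`` identity mismatches and ``g_t`` ground-truth objects.
Correspondences persist from the previous frame while still within the
match radius; the remainder are matched by minimum-distance assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tracking import solve_assignment

__all__ = [
    "SegScores",
    "TrackScores",
    "seg_scores",
    "correspond",
    "motp",
    "mota",
    "count_identity_swaps",
    "max_gt_displacement",
    "evaluate_tracking",
    "evaluate_segmentation",
]


@dataclass
class SegScores:
    recall: float
    precision: float
    f_measure: float
    si: float
    num_miss: int
    num_gt: int


@dataclass
class TrackScores:
    motp: float | None
    mota: float
    misses: int
    false_positives: int
    mismatches: int
    id_swaps: int
    total_gt: int
    per_frame: pd.DataFrame | None = None


def seg_scores(
    gt_mask: np.ndarray,
    pred_mask: np.ndarray,
    gt_object_count: int,
    matched_object_count: int,
) -> SegScores:
    """Pixel Recall/Precision/F-measure and the object-aware Similarity Index."""
    gt = np.asarray(gt_mask, dtype=bool)
    pred = np.asarray(pred_mask, dtype=bool)
    if gt.shape != pred.shape:
        raise ValueError("ground-truth and predicted masks differ in shape")
    if gt_object_count < 1:
        raise ValueError("ground truth must contain at least one object")
    if not 0 <= matched_object_count <= gt_object_count:
        raise ValueError("matched_object_count must lie in [0, gt_object_count]")
    n_gt = int(gt.sum())
    if n_gt == 0:
        raise ValueError("empty ground-truth mask: recall undefined")
    n_pred = int(pred.sum())
    overlap = int((gt & pred).sum())
    recall = overlap / n_gt
    precision = overlap / n_pred if n_pred > 0 else 0.0
    f = 2 * recall * precision / (recall + precision) if recall + precision > 0 else 0.0
    num_miss = gt_object_count - matched_object_count
    si = f - num_miss / (2 * gt_object_count)
    return SegScores(recall, precision, f, si, num_miss, gt_object_count)


def _frame_positions(table: pd.DataFrame) -> dict[int, dict[int, tuple[float, float]]]:
    out: dict[int, dict[int, tuple[float, float]]] = {}
    for row in table.itertuples(index=False):
        out.setdefault(int(row.frame), {})[int(row.track_id)] = (float(row.x), float(row.y))
    return out


@dataclass
class Correspondence:
    """Per-frame CLEAR-MOT bookkeeping produced by :func:`correspond`."""

    frames: list[int] = field(default_factory=list)
    misses: list[int] = field(default_factory=list)
    false_positives: list[int] = field(default_factory=list)
    mismatches: list[int] = field(default_factory=list)
    n_gt: list[int] = field(default_factory=list)
    n_matches: list[int] = field(default_factory=list)
    match_distances: list[float] = field(default_factory=list)

    def per_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": self.frames,
                "misses": self.misses,
                "false_positives": self.false_positives,
                "mismatches": self.mismatches,
                "n_gt": self.n_gt,
                "n_matches": self.n_matches,
            }
        )


def correspond(
    gt_positions: dict[int, dict[int, tuple[float, float]]],
    det_positions: dict[int, dict[int, tuple[float, float]]],
    match_radius: float,
) -> Correspondence:
    """Establish GT↔detection correspondences frame by frame (CLEAR MOT).

    A correspondence made in an earlier frame persists while the pair stays
    within ``match_radius``; remaining objects are matched by
    minimum-distance assignment.  Unmatched GT objects count as misses,
    unmatched detections as false positives, and a GT object whose matched
    track identity differs from its previous one contributes a mismatch
    event in the frame where the change occurs.
    """
    if match_radius <= 0:
        raise ValueError("match_radius must be > 0")
    out = Correspondence()
    last_match: dict[int, int] = {}  # GT id → track id of its latest correspondence
    frames = sorted(set(gt_positions) | set(det_positions))
    for f in frames:
        gts = gt_positions.get(f, {})
        dets = det_positions.get(f, {})
        gt_ids = sorted(gts)
        det_ids = sorted(dets)
        det_index = {d: k for k, d in enumerate(det_ids)}
        matches: dict[int, int] = {}
        # 1. persistence: keep last frame's pairing when still close enough
        for g in gt_ids:
            t = last_match.get(g)
            if t is not None and t in dets and t not in matches.values():
                gx, gy = gts[g]
                dx, dy = dets[t]
                if np.hypot(gx - dx, gy - dy) <= match_radius:
                    matches[g] = t
        # 2. minimum-distance assignment for the remainder
        free_gt = [g for g in gt_ids if g not in matches]
        free_det = [d for d in det_ids if d not in matches.values()]
        if free_gt and free_det:
            G = np.array([gts[g] for g in free_gt])
            T = np.array([dets[d] for d in free_det])
            D = ((G[:, None, :] - T[None, :, :]) ** 2).sum(-1)
            D[D > match_radius**2] = np.inf
            for i, j in solve_assignment(D).pairs:
                matches[free_gt[i]] = free_det[j]
        mme = 0
        for g, t in matches.items():
            prev = last_match.get(g)
            if prev is not None and prev != t:
                mme += 1
            last_match[g] = t
            gx, gy = gts[g]
            dx, dy = dets[t]
            out.match_distances.append(float(np.hypot(gx - dx, gy - dy)))
        out.frames.append(f)
        out.n_gt.append(len(gt_ids))
        out.n_matches.append(len(matches))
        out.misses.append(len(gt_ids) - len(matches))
        out.false_positives.append(len(det_ids) - len(matches))
        out.mismatches.append(mme)
    return out


def motp(corr: Correspondence) -> float:
    """Mean Euclidean distance over all matched pairs (pixels)."""
    if not corr.match_distances:
        raise ValueError("MOTP undefined: no matches")
    return float(np.mean(corr.match_distances))


def mota(corr: Correspondence) -> float:
    """1 − (misses + false positives + mismatches) / total GT objects."""
    g = sum(corr.n_gt)
    if g < 1:
        raise ValueError("MOTA undefined: no ground-truth objects")
    errors = sum(corr.misses) + sum(corr.false_positives) + sum(corr.mismatches)
    return 1.0 - errors / g


def count_identity_swaps(corr: Correspondence) -> int:
    """Total identity mismatch events over the sequence (Σ_t mme_t)."""
    return int(sum(corr.mismatches))


def max_gt_displacement(gt: pd.DataFrame) -> float:
    """Largest consecutive-frame centroid displacement in a GT table (pixels).

    Scans every object's positions in frame order and takes the maximum
    Euclidean step between frames ``t`` and ``t+1``.  This is the empirical
    displacement bound that parameterises the association gate.
    """
    best = -1.0
    for _, track in gt.sort_values("frame").groupby("track_id"):
        frames = track["frame"].to_numpy()
        xy = track[["x", "y"]].to_numpy(float)
        consecutive = np.diff(frames) == 1
        if consecutive.any():
            steps = np.linalg.norm(np.diff(xy, axis=0), axis=1)[consecutive]
            best = max(best, float(steps.max()))
    if best < 0:
        raise ValueError("ground truth contains no consecutive-frame pairs")
    return best


def evaluate_tracking(
    gt: pd.DataFrame,
    pred: pd.DataFrame,
    match_radius: float,
    keep_per_frame: bool = False,
) -> TrackScores:
    """Score a predicted trajectory table against ground truth (CLEAR MOT)."""
    corr = correspond(_frame_positions(gt), _frame_positions(pred), match_radius)
    return TrackScores(
        motp=motp(corr) if corr.match_distances else None,
        mota=mota(corr),
        misses=int(sum(corr.misses)),
        false_positives=int(sum(corr.false_positives)),
        mismatches=int(sum(corr.mismatches)),
        id_swaps=count_identity_swaps(corr),
        total_gt=int(sum(corr.n_gt)),
        per_frame=corr.per_frame() if keep_per_frame else None,
    )


def evaluate_segmentation(
    gt_masks: list[np.ndarray],
    pred_masks: list[np.ndarray],
    gt_positions: dict[int, dict[int, tuple[float, float]]],
    detections: dict[int, np.ndarray],
    match_radius: float,
    per_video_counts: bool = False,
) -> SegScores:
    """Aggregate segmentation scores over a sequence.

    Pixel recall/precision pool over all frames; object miss counting is
    per frame by default (a GT object is found when any detection centroid
    of that frame lies within ``match_radius``), or pooled per video when
    ``per_video_counts`` is set.  Frames with an empty GT mask are skipped
    (nothing to recall).
    """
    if len(gt_masks) != len(pred_masks):
        raise ValueError("gt_masks and pred_masks differ in length")
    overlap = gt_total = pred_total = 0
    num_gt = num_miss = 0
    frame_penalties: list[float] = []
    for f, (gt_mask, pred_mask) in enumerate(zip(gt_masks, pred_masks)):
        gt_mask = np.asarray(gt_mask, bool)
        pred_mask = np.asarray(pred_mask, bool)
        if not gt_mask.any():
            continue
        overlap += int((gt_mask & pred_mask).sum())
        gt_total += int(gt_mask.sum())
        pred_total += int(pred_mask.sum())
        objs = gt_positions.get(f, {})
        cents = detections.get(f, np.empty((0, 2)))
        frame_gt = frame_miss = 0
        for gx, gy in objs.values():
            frame_gt += 1
            if len(cents) and (np.hypot(cents[:, 0] - gx, cents[:, 1] - gy) <= match_radius).any():
                continue
            frame_miss += 1
        num_gt += frame_gt
        num_miss += frame_miss
        if frame_gt > 0:
            frame_penalties.append(frame_miss / (2 * frame_gt))
    if gt_total == 0:
        raise ValueError("no non-empty ground-truth masks")
    recall = overlap / gt_total
    precision = overlap / pred_total if pred_total > 0 else 0.0
    f_measure = 2 * recall * precision / (recall + precision) if recall + precision > 0 else 0.0
    if num_gt == 0:
        raise ValueError("no ground-truth objects to count")
    # miss penalty: per-frame average by default, pooled per-video totals on request
    if per_video_counts:
        penalty = num_miss / (2 * num_gt)
    else:
        penalty = float(np.mean(frame_penalties)) if frame_penalties else 0.0
    si = f_measure - penalty
    return SegScores(recall, precision, f_measure, si, num_miss, num_gt)
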