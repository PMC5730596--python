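"""Frame-to-frame association and trajectory assembly.

Detections in consecutive frames are linked by minimum-cost bipartite
assignment (Hungarian/Munkres) on a cost matrix of *squared* centroid
distances, gated so that implausibly large jumps cost infinity and stay
unmatched.  Tracks that miss a detection become dormant fragments; after
the whole sequence is processed, a nearest-neighbour gap-bridging pass
joins each fragment start to the closest earlier-ending fragment when the
squared distance between the fragment endpoints is within
``bridge_ratio × gate`` (default 1.2× — a 20 % margin beyond unity for
rebound).  Gaps that are bridged are filled by linear interpolation and the
filled rows are flagged ``bridged``; fragment starts that could not be
bridged are flagged ``error``.

The association gate is taken from the maximum frame-to-frame displacement
observed in tracking ground truth when available (``max(dist_GT)``),
squared so both gates share squared-pixel units with the cost matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .io import empty_trajectories, validate_trajectories
from .segmentation import DetectionSet

__all__ = [
    "TrackerConfig",
    "AssignmentResult",
    "Trajectory",
    "Tracker",
    "compute_cost_matrix",
    "gate_matrix",
    "solve_assignment",
    "bridge_gaps",
    "trajectories_to_table",
]


@dataclass(frozen=True)
class TrackerConfig:
    """Association and bridging thresholds.

    max_displacement
        The per-frame displacement gate in *pixels* (``max(dist_GT)`` when
        derived from ground truth).  Association costs are squared
        distances, so the gate applied to the cost matrix is its square
        (``gate_is_squared=True``); set ``gate_is_squared=False`` to apply
        the pixel value directly to the squared costs (the literal-text
        reading, which mixes units).
    bridge_ratio
        Gap-bridging margin: fragments join when the squared distance
        between their endpoints is ≤ ``bridge_ratio × max_displacement²``.
    gate_slack_px
        Measurement allowance added to the displacement bound before it
        enters either gate.  Ground truth bounds the *true* per-frame
        displacement; a measured step adds two centroid localization
        errors; worse, a partially segmented body (e.g. inside an edge
        shadow, or mid-burst) biases the centroid by up to a quarter body
        length.  Without the allowance such frames break tracks and spawn
        duplicate fragments.  Set to 0 to use the raw ground-truth bound.
    """

    max_displacement: float = 10.0
    bridge_ratio: float = 1.2
    gate_is_squared: bool = True
    gate_slack_px: float = 3.0

    def __post_init__(self) -> None:
        if self.max_displacement <= 0:
            raise ValueError("max_displacement must be > 0")
        if self.bridge_ratio < 1.0:
            raise ValueError("bridge_ratio must be ≥ 1")
        if self.gate_slack_px < 0:
            raise ValueError("gate_slack_px must be ≥ 0")

    @property
    def effective_displacement(self) -> float:
        """Displacement bound including the measurement allowance (pixels)."""
        return self.max_displacement + self.gate_slack_px

    @property
    def dist_gate(self) -> float:
        """Gate applied to the squared-distance cost matrix."""
        if self.gate_is_squared:
            return self.effective_displacement**2
        return self.effective_displacement

    @property
    def bridge_gate(self) -> float:
        """Squared-distance condition for joining trajectory fragments."""
        return self.bridge_ratio * self.effective_displacement**2

    @classmethod
    def from_ground_truth(cls, gt: pd.DataFrame, bridge_ratio: float = 1.2, **kw) -> "TrackerConfig":
        from .evaluation import max_gt_displacement

        return cls(max_displacement=max_gt_displacement(gt), bridge_ratio=bridge_ratio, **kw)


@dataclass
class AssignmentResult:
    pairs: list[tuple[int, int]]
    unmatched_sources: list[int]
    unmatched_targets: list[int]
    total_cost: float


@dataclass
class Trajectory:
    """One object's time-indexed centroid sequence.

    ``points`` holds ``(frame, x, y)`` with strictly increasing frames over
    the observed detections; ``segments`` records the contiguous fragments
    that were concatenated, ``bridged_gaps`` the ``(end_frame,
    restart_frame)`` pairs joined by bridging, and ``error_frames`` the
    fragment-start frames whose gap failed the bridge distance condition.
    """

    track_id: int
    points: list[tuple[int, float, float]] = field(default_factory=list)
    segments: list[list[tuple[int, float, float]]] = field(default_factory=list)
    bridged_gaps: list[tuple[int, int]] = field(default_factory=list)
    error_frames: list[int] = field(default_factory=list)

    @property
    def start_frame(self) -> int:
        return self.points[0][0]

    @property
    def end_frame(self) -> int:
        return self.points[-1][0]

    @property
    def start_xy(self) -> tuple[float, float]:
        return self.points[0][1], self.points[0][2]

    @property
    def end_xy(self) -> tuple[float, float]:
        return self.points[-1][1], self.points[-1][2]


def compute_cost_matrix(sources, targets) -> np.ndarray:
    """Pairwise association costs: squared Euclidean centroid distances.

    The cost of linking source i to target j is ``(xj−xi)² + (yj−yi)²`` —
    the squared distance, with no square root.  Accepts
    :class:`~larvatrack.segmentation.DetectionSet` or ``(n, 2)`` arrays of
    (x, y) centroids; rectangular matrices (n ≠ m) are allowed.
    """
    src = sources.centroids() if isinstance(sources, DetectionSet) else np.atleast_2d(np.asarray(sources, float))
    tgt = targets.centroids() if isinstance(targets, DetectionSet) else np.atleast_2d(np.asarray(targets, float))
    if src.size == 0 or tgt.size == 0:
        return np.empty((src.shape[0] if src.size else 0, tgt.shape[0] if tgt.size else 0))
    return cdist(src, tgt, metric="sqeuclidean")


def gate_matrix(D: np.ndarray, config: TrackerConfig) -> np.ndarray:
    """Replace every cost above the distance gate with Inf."""
    D = np.array(D, dtype=float, copy=True)
    D[D > config.dist_gate] = np.inf
    return D


def solve_assignment(D: np.ndarray) -> AssignmentResult:
    """Minimum-cost unique assignment on a (possibly Inf-gated) cost matrix.

    Sources/targets that the optimum would force onto an Inf entry are left
    unmatched instead.  Returns at most ``min(n, m)`` pairs.
    """
    D = np.asarray(D, dtype=float)
    n, m = D.shape if D.ndim == 2 else (0, 0)
    if n == 0 or m == 0 or not np.isfinite(D).any():
        return AssignmentResult([], list(range(n)), list(range(m)), 0.0)
    finite = D[np.isfinite(D)]
    big = float(finite.max()) * min(n, m) + 1.0
    rows, cols = linear_sum_assignment(np.where(np.isfinite(D), D, big))
    pairs = [(int(i), int(j)) for i, j in zip(rows, cols) if np.isfinite(D[i, j])]
    matched_src = {i for i, _ in pairs}
    matched_tgt = {j for _, j in pairs}
    return AssignmentResult(
        pairs=pairs,
        unmatched_sources=[i for i in range(n) if i not in matched_src],
        unmatched_targets=[j for j in range(m) if j not in matched_tgt],
        total_cost=float(sum(D[i, j] for i, j in pairs)),
    )


class Tracker:
    """Online frame-to-frame tracker maintaining active and dormant tracks."""

    def __init__(self, config: TrackerConfig):
        self.config = config
        self.active: list[Trajectory] = []
        self.dormant: list[Trajectory] = []
        self._next_id = 1

    def _new_track(self, frame: int, x: float, y: float) -> Trajectory:
        t = Trajectory(track_id=self._next_id, points=[(frame, x, y)])
        self._next_id += 1
        return t

    def step(self, frame_index: int, detections: DetectionSet) -> None:
        """Associate this frame's detections with the active track ends.

        Matched tracks extend; unmatched detections found new tracks;
        unmatched tracks become dormant fragments (a gap opens, to be
        reconsidered by bridging once the whole sequence is processed).
        """
        centroids = detections.centroids()
        ends = np.array([t.end_xy for t in self.active]) if self.active else np.empty((0, 2))
        D = gate_matrix(compute_cost_matrix(ends, centroids), self.config)
        result = solve_assignment(D)

        claimed = np.array([centroids[j] for _, j in result.pairs]) if result.pairs else np.empty((0, 2))
        areas = [r.area for r in detections.regions] if detections.regions else []
        # a leftover detection within the gate of an already-claimed one is a
        # fragment of the same animal (its region split); fold it back into
        # the claimed detection by area-weighted averaging instead of letting
        # a half-body centroid found a duplicate track
        merged: dict[int, list[int]] = {}
        new_track_targets: list[int] = []
        for j in result.unmatched_targets:
            if len(claimed):
                x, y = centroids[j]
                d2 = (claimed[:, 0] - x) ** 2 + (claimed[:, 1] - y) ** 2
                k = int(np.argmin(d2))
                if d2[k] <= self.config.dist_gate:
                    merged.setdefault(k, []).append(j)
                    continue
            new_track_targets.append(j)

        still_active: list[Trajectory] = []
        for k, (i, j) in enumerate(result.pairs):
            parts = [j] + merged.get(k, [])
            w = np.array([max(areas[p], 1) for p in parts], dtype=float)
            xy = centroids[parts]
            x, y = (xy * w[:, None]).sum(axis=0) / w.sum()
            self.active[i].points.append((frame_index, float(x), float(y)))
            still_active.append(self.active[i])
        for i in result.unmatched_sources:
            self.dormant.append(self.active[i])
        for j in new_track_targets:
            x, y = centroids[j]
            still_active.append(self._new_track(frame_index, float(x), float(y)))
        self.active = still_active

    def fragments(self) -> list[Trajectory]:
        """All fragments (dormant + still active), each as a single segment."""
        frags = self.dormant + self.active
        for f in frags:
            f.segments = [list(f.points)]
        return sorted(frags, key=lambda t: (t.start_frame, t.track_id))

    def finish(self) -> list[Trajectory]:
        """Close the sequence: bridge gaps between fragments."""
        return bridge_gaps(self.fragments(), self.config)


def bridge_gaps(fragments: list[Trajectory], config: TrackerConfig) -> list[Trajectory]:
    """Join trajectory fragments across detection gaps (nearest neighbour).

    Fragments are visited in chronological order of their start frame.  For
    each one, the nearest earlier-ending open trajectory (squared distance
    between that trajectory's end and this fragment's start) is a bridge
    candidate; the gap is bridged iff the squared distance is within
    ``bridge_ratio × max_displacement²``.  Bridged fragments concatenate
    (recording the gap); a fragment with candidates but none within the
    condition starts a new trajectory and its start frame is recorded as an
    error.  Fragments with no earlier-ending candidate are genuine starts.
    """
    fragments = sorted(fragments, key=lambda t: (t.start_frame, t.track_id))
    finished: list[Trajectory] = []
    for frag in fragments:
        candidates = [t for t in finished if t.end_frame < frag.start_frame]
        if candidates:
            sx, sy = frag.start_xy
            d2 = [(t.end_xy[0] - sx) ** 2 + (t.end_xy[1] - sy) ** 2 for t in candidates]
            k = int(np.argmin(d2))
            if d2[k] <= config.bridge_gate:
                host = candidates[k]
                host.bridged_gaps.append((host.end_frame, frag.start_frame))
                host.points.extend(frag.points)
                host.segments.append(list(frag.points))
                host.error_frames.extend(frag.error_frames)
                continue
            frag.error_frames = sorted(set(frag.error_frames) | {frag.start_frame})
        finished.append(frag)
    return finished


def trajectories_to_table(trajectories: list[Trajectory]) -> pd.DataFrame:
    """Serialise trajectories to the tidy table schema.

    Observed detections are flagged ``observed``; bridged gaps are filled by
    linear interpolation between the fragment endpoints and flagged
    ``bridged``; the first observed frame after a failed bridge is flagged
    ``error``.
    """
    rows: list[tuple[int, int, float, float, str]] = []
    for traj in trajectories:
        errors = set(traj.error_frames)
        points = {f: (x, y) for f, x, y in traj.points}
        for f, x, y in traj.points:
            rows.append((traj.track_id, f, x, y, "error" if f in errors else "observed"))
        for end_f, restart_f in traj.bridged_gaps:
            x0, y0 = points[end_f]
            x1, y1 = points[restart_f]
            span = restart_f - end_f
            for f in range(end_f + 1, restart_f):
                u = (f - end_f) / span
                rows.append((traj.track_id, f, x0 + u * (x1 - x0), y0 + u * (y1 - y0), "bridged"))
    if not rows:
        return empty_trajectories()
    table = pd.DataFrame(rows, columns=["track_id", "frame", "x", "y", "flag"])
    return validate_trajectories(table)
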