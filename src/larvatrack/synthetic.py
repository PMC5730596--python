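"""Synthetic larvae videos with pixel-exact ground truth.

Renders grayscale well-plate scenes that reproduce the nuisance structure
of real larva microscopy — round or square wells with edge shadowing,
ink-label strokes on the dish, slowly drifting water particles, bright-
rimmed bubbles, low larva/background contrast and sensor noise — together
with exact per-frame larva masks and a trajectory ground-truth table, so
the tracking pipeline can be scored without any recorded data.

Larvae are oriented capsules (rectangle with semicircular caps) with a dark
core fading toward a semi-transparent periphery.  Locomotion follows a
two-state burst-and-rest Markov model: long quiescent periods with small
positional jitter, interrupted by brief fast swims along a persistent
heading — the bursty pattern that defeats frame-differencing detectors.
Resting larvae avoid each other (a configurable minimum separation), so
occlusions occur only in the dedicated scripted-crossing scene.

All randomness flows from a single seed; identical seeds give bit-identical
videos.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import FrameSequence, write_frames, write_masks, write_trajectories

__all__ = [
    "SceneConfig",
    "LarvaModel",
    "BurstMotion",
    "SceneSpec",
    "simulate_trajectories",
    "simulate_crossing",
    "render_video",
    "generate_scene",
    "suite_presets",
    "make_benchmark_suite",
]


@dataclass(frozen=True)
class SceneConfig:
    """Static scene geometry, artifacts and acquisition settings."""

    well_shape: str = "round"  # "round" or "square"
    well_radius: float = 50.0  # radius (round) or half-width (square), pixels
    image_size: int = 120
    background_level: int = 200  # water intensity inside the well
    shadow_strength: int = 0  # intensity drop of the well-edge shadow band
    n_labels: int = 0  # dark ink strokes drawn on the dish
    n_particles: int = 0  # small drifting dark dots
    n_bubbles: int = 0  # bright-rimmed discs
    noise_sigma: float = 2.0
    frame_rate: float = 15.0
    n_frames: int = 260
    seed: int = 0

    def __post_init__(self) -> None:
        if self.well_shape not in ("round", "square"):
            raise ValueError(f"well_shape must be 'round' or 'square', got {self.well_shape!r}")
        if min(self.n_labels, self.n_particles, self.n_bubbles) < 0 or self.noise_sigma < 0:
            raise ValueError("artifact counts and noise_sigma must be ≥ 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be ≥ 1")


@dataclass(frozen=True)
class LarvaModel:
    """Capsule-shaped larva body with a dark core and faded periphery."""

    body_length: float = 11.0
    body_width: float = 4.0
    core_intensity: int = 70
    periphery_contrast: float = 0.35  # fraction of core contrast kept at the body edge

    def __post_init__(self) -> None:
        if self.body_width > self.body_length:
            raise ValueError("body_width must not exceed body_length")
        if not 0.0 <= self.periphery_contrast <= 1.0:
            raise ValueError("periphery_contrast must be in [0,1]")


@dataclass(frozen=True)
class BurstMotion:
    """Two-state burst-and-rest locomotion parameters.

    Defaults give a long-run active fraction of ≈ burst_len /
    (burst_len + 1/p_burst) ≈ 0.074, matching the low activity proportion
    reported for resting larvae, with swim bursts of a few px/frame.
    """

    p_burst: float = 0.02  # per-frame probability of starting a burst while resting
    burst_len: int = 4  # frames per burst
    burst_speed: tuple[float, float] = (2.0, 4.0)  # px/frame, sampled uniformly
    rest_jitter: float = 0.05  # sub-pixel positional jitter σ at rest (micro-movements)
    heading_sigma: float = 0.4  # per-frame heading diffusion during bursts, radians
    # avoidance distance: ~1.5 body lengths, so two bodies never touch and
    # never fuse into one segmented region outside the scripted-occlusion scene
    min_separation: float = 16.0
    initial_burst: bool = True  # startle swim at recording start (post-handling escape)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_burst <= 1.0:
            raise ValueError("p_burst must be in [0,1]")
        if self.burst_len < 1:
            raise ValueError("burst_len must be ≥ 1")

    @property
    def active_fraction(self) -> float:
        """Expected long-run fraction of frames spent in bursts."""
        if self.p_burst == 0:
            return 0.0
        return self.burst_len / (self.burst_len + 1.0 / self.p_burst)


@dataclass(frozen=True)
class SceneSpec:
    """A named benchmark scene: geometry + motion + larvae."""

    name: str
    description: str
    scene: SceneConfig
    motion: BurstMotion = BurstMotion()
    larva: LarvaModel = LarvaModel()
    n_larvae: int = 1
    occlusion: bool = False  # scripted crossing instead of free motion


# ---------------------------------------------------------------------------
# locomotion


def _well_margin(scene: SceneConfig, larva: LarvaModel) -> float:
    return larva.body_length / 2.0 + 2.0


def _inside_well(x: float, y: float, scene: SceneConfig, margin: float) -> bool:
    cx = cy = scene.image_size / 2.0
    r = scene.well_radius - margin
    if scene.well_shape == "round":
        return (x - cx) ** 2 + (y - cy) ** 2 <= r * r
    return abs(x - cx) <= r and abs(y - cy) <= r


def _reflect_into_well(x: float, y: float, scene: SceneConfig, margin: float) -> tuple[float, float]:
    cx = cy = scene.image_size / 2.0
    r = scene.well_radius - margin
    if scene.well_shape == "square":
        x = cx + np.clip(x - cx, -r, r) * 2 - (x - cx) if abs(x - cx) > r else x
        y = cy + np.clip(y - cy, -r, r) * 2 - (y - cy) if abs(y - cy) > r else y
        x = float(np.clip(x, cx - r, cx + r))
        y = float(np.clip(y, cy - r, cy + r))
        return x, y
    dx, dy = x - cx, y - cy
    d = float(np.hypot(dx, dy))
    if d <= r:
        return x, y
    # fold the overshoot back inside along the radial direction
    d_new = max(2 * r - d, 0.0) if d < 2 * r else r * 0.5
    return cx + dx / d * d_new, cy + dy / d * d_new


def simulate_trajectories(
    n_larvae: int,
    motion: BurstMotion,
    scene: SceneConfig,
    larva: LarvaModel = LarvaModel(),
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate burst-and-rest larva trajectories confined to the well.

    Returns a trajectory-table DataFrame (``track_id, frame, x, y, flag``)
    with one row per larva per frame.  Larvae rest with small positional
    jitter, start bursts with probability ``p_burst`` per frame, swim at a
    per-burst speed along a diffusing heading, reflect off the well wall
    and steer apart below ``min_separation``.
    """
    if n_larvae < 0:
        raise ValueError("n_larvae must be ≥ 0")
    rng = np.random.default_rng(scene.seed) if rng is None else rng
    margin = _well_margin(scene, larva)
    usable = 2.0 * (scene.well_radius - margin)
    if usable <= 0 or (n_larvae > 1 and n_larvae * motion.min_separation**2 > usable**2 * 2):
        raise ValueError(
            f"well of radius {scene.well_radius} too small for {n_larvae} larvae "
            f"at min separation {motion.min_separation}"
        )
    if n_larvae == 0:
        return pd.DataFrame(columns=["track_id", "frame", "x", "y", "flag"])

    cx = cy = scene.image_size / 2.0
    pos = np.empty((n_larvae, 2))
    for i in range(n_larvae):  # rejection-sample separated start positions
        for _ in range(1000):
            p = rng.uniform(-(scene.well_radius - margin), scene.well_radius - margin, 2) + (cx, cy)
            if not _inside_well(p[0], p[1], scene, margin):
                continue
            if all(np.hypot(*(p - pos[j])) >= motion.min_separation for j in range(i)):
                pos[i] = p
                break
        else:
            raise ValueError("could not place larvae with the requested separation")

    heading = rng.uniform(0, 2 * np.pi, n_larvae)
    burst_left = np.zeros(n_larvae, dtype=int)
    speed = np.zeros(n_larvae)
    if motion.initial_burst and motion.burst_speed[1] > 0:
        # transfer into the well startles the larvae: all begin with an
        # escape dart of a body length or more, headed toward open water
        # (away from the nearest wall), which also keeps a just-started
        # recording from baking resting bodies into the first background
        # estimate
        speed[:] = rng.uniform(
            max(motion.burst_speed[0], 2.5), max(motion.burst_speed[1], 3.0), n_larvae
        )
        # the dart must clear at least two body lengths, or the body's own
        # extent re-covers the drop-in pixels before the water is ever seen
        dart_frames = np.ceil(2.2 * larva.body_length / speed).astype(int)
        burst_left[:] = np.maximum(motion.burst_len, dart_frames)
        to_center = np.arctan2(cy - pos[:, 1], cx - pos[:, 0])
        heading = to_center + rng.normal(0, 0.4, n_larvae)
    rows = []
    for f in range(scene.n_frames):
        for i in range(n_larvae):
            if burst_left[i] == 0 and rng.random() < motion.p_burst:
                burst_left[i] = motion.burst_len
                speed[i] = rng.uniform(*motion.burst_speed)
                heading[i] = rng.uniform(0, 2 * np.pi)
            if burst_left[i] > 0:
                heading[i] += rng.normal(0, motion.heading_sigma)
                step = speed[i] * np.array([np.cos(heading[i]), np.sin(heading[i])])
                burst_left[i] -= 1
            else:
                step = rng.normal(0, motion.rest_jitter, 2)
            new = pos[i] + step
            new = np.array(_reflect_into_well(new[0], new[1], scene, margin))
            # avoidance: larvae steer apart below min_separation, relaxing
            # half the violation per frame (a gentle push, never a jump)
            for j in range(n_larvae):
                if j == i:
                    continue
                sep = new - pos[j]
                d = float(np.hypot(*sep))
                if d < motion.min_separation:
                    u = sep / d if d > 1e-9 else rng.standard_normal(2)
                    u = u / max(float(np.hypot(*u)), 1e-9)
                    new = new + u * 0.5 * (motion.min_separation - d)
                    new = np.array(_reflect_into_well(new[0], new[1], scene, margin))
            pos[i] = new
            rows.append((i + 1, f, float(pos[i][0]), float(pos[i][1]), "observed"))
    return pd.DataFrame(rows, columns=["track_id", "frame", "x", "y", "flag"])


def simulate_crossing(
    scene: SceneConfig,
    larva: LarvaModel = LarvaModel(),
    cross_frame: int | None = None,
    speed: float = 3.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Two larvae on a scripted head-on crossing through the well centre.

    Both rest on opposite sides, swim toward each other, overlap at the
    centre around ``cross_frame`` (default: 75 % into the sequence, well
    clear of any model warm-up period) and continue to the far side — a
    deterministic occlusion event for testing that identities are never
    silently merged.
    """
    rng = np.random.default_rng(scene.seed) if rng is None else rng
    cx = cy = scene.image_size / 2.0
    margin = _well_margin(scene, larva)
    reach = scene.well_radius - margin - 1
    cross_frame = int(scene.n_frames * 0.75) if cross_frame is None else cross_frame
    travel_frames = int(np.ceil(reach / speed))
    start = cross_frame - travel_frames
    hop = 10.0  # initial startle swim away from the drop-in point, px
    rows = []
    for i, direction in enumerate((1.0, -1.0)):
        # startle hop at recording start, then rest until the approach
        x0 = cx - direction * (reach - hop)
        y0 = cy + direction * 3.0  # slight vertical offset so paths truly cross
        for f in range(scene.n_frames):
            if f < 4:
                x = x0 - direction * hop * (1.0 - f / 4.0)
                y = y0
            elif f < start:
                x, y = x0, y0
            elif f < cross_frame + travel_frames:
                prog = (f - start) * speed * direction
                x = x0 + prog
                y = y0 - direction * 6.0 * (f - start) / (2 * travel_frames)
            else:
                x = x0 + direction * 2 * (reach - hop)
                y = y0 - direction * 3.0
            jx, jy = rng.normal(0, 0.05, 2)
            x = float(np.clip(x + jx, cx - reach, cx + reach))
            y = float(np.clip(y + jy, cy - reach, cy + reach))
            rows.append((i + 1, f, x, y, "observed"))
    return pd.DataFrame(rows, columns=["track_id", "frame", "x", "y", "flag"])


# ---------------------------------------------------------------------------
# rendering


def _static_base(
    scene: SceneConfig,
    rng: np.random.Generator,
    keepout: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Render the static scene (well, shadow, labels, bubbles).

    Returns the float base image and a boolean mask of static-artifact
    pixels (shadow band, label strokes, bubble discs) for unambiguous
    false-positive attribution in tests.  Labels and bubbles are resampled
    (best effort) so they avoid the ``keepout`` region — the larvae's swim
    path — keeping artifact and organism pixels disjoint.
    """
    n = scene.image_size
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    cx = cy = n / 2.0
    base = np.full((n, n), float(scene.background_level))
    artifact = np.zeros((n, n), dtype=bool)

    if scene.well_shape == "round":
        dist = np.hypot(xx - cx, yy - cy)
        edge = dist - scene.well_radius
    else:
        dist = np.maximum(np.abs(xx - cx), np.abs(yy - cy))
        edge = dist - scene.well_radius
    base[edge > 0] = scene.background_level * 0.45  # dish material outside the well
    if scene.shadow_strength > 0:
        band = 6.0
        in_band = (edge <= 0) & (edge > -band)
        falloff = 1.0 + edge[in_band] / band  # 0 at inner edge of band → 1 at the rim
        base[in_band] -= scene.shadow_strength * falloff
        artifact |= in_band & (base < scene.background_level - 2)

    def clear_of_larvae(pix_y, pix_x):
        return keepout is None or not keepout[pix_y, pix_x].any()

    for _ in range(scene.n_labels):  # dark ink strokes on the dish
        for _attempt in range(50):
            ang = rng.uniform(0, 2 * np.pi)
            r0 = rng.uniform(0.35, 0.8) * scene.well_radius
            x0, y0 = cx + r0 * np.cos(ang), cy + r0 * np.sin(ang)
            ang2 = rng.uniform(0, np.pi)
            length = rng.uniform(8, 16)
            x1, y1 = x0 + length * np.cos(ang2), y0 + length * np.sin(ang2)
            t = np.linspace(0, 1, int(length * 3))
            px = np.clip(np.rint(x0 + t * (x1 - x0)), 0, n - 1).astype(int)
            py = np.clip(np.rint(y0 + t * (y1 - y0)), 0, n - 1).astype(int)
            rows = np.concatenate([np.clip(py + dy, 0, n - 1) for dy in (-1, 0)])
            cols = np.concatenate([px, px])
            if clear_of_larvae(rows, cols):
                break
        base[rows, cols] = 70.0
        artifact[rows, cols] = True

    for _ in range(scene.n_bubbles):  # bright-rimmed static bubbles
        for _attempt in range(50):
            ang = rng.uniform(0, 2 * np.pi)
            r0 = rng.uniform(0.2, 0.75) * scene.well_radius
            bx, by = cx + r0 * np.cos(ang), cy + r0 * np.sin(ang)
            br = rng.uniform(2.5, 4.5)
            d = np.hypot(xx - bx, yy - by)
            disc_y, disc_x = np.nonzero(d <= br)
            if clear_of_larvae(disc_y, disc_x):
                break
        rim = (d <= br) & (d > br - 1.5)
        interior = d <= br - 1.5
        base[rim] = np.minimum(base[rim] + 45.0, 255.0)
        base[interior] = np.minimum(base[interior] + 18.0, 255.0)
        artifact |= d <= br
    return base, artifact


def _draw_capsule(
    img: np.ndarray,
    x: float,
    y: float,
    heading: float,
    larva: LarvaModel,
    bg_reference: float,
) -> np.ndarray:
    """Draw one capsule larva into ``img`` (in place); returns its pixel mask."""
    n0, n1 = img.shape
    r = larva.body_width / 2.0
    h = max(larva.body_length / 2.0 - r, 0.0)
    ex, ey = np.cos(heading) * h, np.sin(heading) * h
    pad = int(np.ceil(h + r + 1))
    x_lo, x_hi = max(int(x) - pad, 0), min(int(x) + pad + 1, n1)
    y_lo, y_hi = max(int(y) - pad, 0), min(int(y) + pad + 1, n0)
    mask = np.zeros_like(img, dtype=bool)
    if x_lo >= x_hi or y_lo >= y_hi:
        return mask
    yy, xx = np.mgrid[y_lo:y_hi, x_lo:x_hi].astype(float)
    # distance from pixel centres to the capsule axis segment
    px, py = xx - x, yy - y
    if h > 0:
        t = np.clip((px * ex + py * ey) / (h * h), -1.0, 1.0)
    else:
        t = 0.0
    dx, dy = px - t * ex, py - t * ey
    d = np.hypot(dx, dy)
    body = d <= r
    if not body.any():
        return mask
    # dark core fading toward the transparent periphery
    depth = 1.0 - np.clip(d / r, 0.0, 1.0)
    fade = larva.periphery_contrast + (1.0 - larva.periphery_contrast) * depth
    patch = img[y_lo:y_hi, x_lo:x_hi]
    value = bg_reference + (larva.core_intensity - bg_reference) * fade
    patch[body] = np.minimum(patch[body], value[body])
    mask[y_lo:y_hi, x_lo:x_hi] = body
    return mask


def _headings_from_table(traj: pd.DataFrame) -> dict[int, np.ndarray]:
    """Per-track headings derived from frame-to-frame displacements.

    During rest (negligible displacement) the previous heading persists, so
    the body orientation does not flicker with sub-pixel jitter.
    """
    out = {}
    for tid, track in traj.sort_values("frame").groupby("track_id"):
        xy = track[["x", "y"]].to_numpy(float)
        steps = np.diff(xy, axis=0)
        headings = np.zeros(len(xy))
        current = 0.0
        for k, (dx, dy) in enumerate(steps):
            if np.hypot(dx, dy) > 0.8:
                current = float(np.arctan2(dy, dx))
            headings[k] = current
        if len(xy) > 1:
            headings[-1] = headings[-2]
        out[int(tid)] = headings
    return out


def render_video(
    traj: pd.DataFrame,
    scene: SceneConfig,
    larva: LarvaModel = LarvaModel(),
    rng: np.random.Generator | None = None,
) -> tuple[FrameSequence, list[np.ndarray], np.ndarray]:
    """Render a trajectory table into frames plus exact ground-truth masks.

    Returns ``(sequence, gt_masks, static_artifact_mask)``: the 8-bit
    grayscale video, one boolean larva mask per frame, and the static
    artifact support (shadow band, labels, bubbles) for FP attribution.
    """
    rng = np.random.default_rng(scene.seed) if rng is None else rng
    n = scene.image_size
    keepout = None
    if len(traj):
        # keep static artifacts off the larvae's entire swim path so that
        # artifact pixels and organism pixels stay disjoint
        keepout = np.zeros((n, n), dtype=bool)
        radius = int(np.ceil(larva.body_length / 2 + 2))
        for x, y in traj[["x", "y"]].to_numpy(float):
            ix, iy = int(round(x)), int(round(y))
            keepout[max(iy - radius, 0): iy + radius + 1,
                    max(ix - radius, 0): ix + radius + 1] = True
    base, artifact = _static_base(scene, rng, keepout)

    particles = rng.uniform(n * 0.25, n * 0.75, size=(scene.n_particles, 2))
    headings = _headings_from_table(traj) if len(traj) else {}
    by_frame = {f: g for f, g in traj.groupby("frame")} if len(traj) else {}

    frames = np.empty((scene.n_frames, n, n), dtype=np.uint8)
    gt_masks: list[np.ndarray] = []
    for f in range(scene.n_frames):
        img = base.copy()
        # drifting dark specks (single-pixel dots at this scene scale)
        particles += rng.normal(0, 0.15, particles.shape)
        for px, py in particles:
            ix, iy = int(round(px)), int(round(py))
            if 0 <= ix < n and 0 <= iy < n:
                img[iy, ix] = min(img[iy, ix], 120.0)
        mask = np.zeros((n, n), dtype=bool)
        if f in by_frame:
            for row in by_frame[f].sort_values("track_id").itertuples(index=False):
                hd = headings[int(row.track_id)]
                frame_pos = int(row.frame)
                mask |= _draw_capsule(
                    img, float(row.x), float(row.y), float(hd[frame_pos]),
                    larva, float(scene.background_level),
                )
        if scene.noise_sigma > 0:
            img = img + rng.normal(0, scene.noise_sigma, img.shape)
        frames[f] = np.clip(np.rint(img), 0, 255).astype(np.uint8)
        gt_masks.append(mask)
    return FrameSequence(frames, frame_rate=scene.frame_rate), gt_masks, artifact


def generate_scene(spec: SceneSpec, seed: int | None = None):
    """Simulate and render one benchmark scene entirely in memory.

    Returns a dict with the frame sequence, ground-truth trajectory table,
    per-frame larva masks, the static-artifact mask and the resolved spec.
    """
    scene = spec.scene if seed is None else replace(spec.scene, seed=seed)
    rng = np.random.default_rng(scene.seed)
    if spec.occlusion:
        traj = simulate_crossing(scene, spec.larva, rng=rng)
    else:
        traj = simulate_trajectories(spec.n_larvae, spec.motion, scene, spec.larva, rng=rng)
    seq, gt_masks, artifact = render_video(traj, scene, spec.larva, rng=rng)
    return {
        "spec": replace(spec, scene=scene),
        "sequence": seq,
        "ground_truth": traj,
        "gt_masks": gt_masks,
        "artifact_mask": artifact,
    }


def suite_presets(
    n_frames: int = 260, image_size: int = 120, base_seed: int = 0
) -> list[SceneSpec]:
    """The graded 10-scene benchmark: clearest background → most complex.

    Scene conditions step through the artifact taxonomy (edge shadow,
    particles, labels, bubbles), round and square wells, single and
    multiple larvae, low (14–15 fps) and high (117 fps) frame rates, one
    scripted-occlusion scene, and a final scene combining every artifact
    class.
    """

    def cfg(i, **kw):
        kw.setdefault("n_frames", n_frames)
        kw.setdefault("image_size", image_size)
        kw.setdefault("seed", base_seed * 1009 + i)
        return SceneConfig(**kw)

    # high-frame-rate capture of evoked escape responses: C-start bursts
    # reach tens of body lengths per second, so even at 117 fps the
    # per-frame displacement stays at a few pixels while bursts span more
    # frames; quiescent jitter is nearly frozen at this shutter speed
    fast = BurstMotion(
        p_burst=0.02, burst_len=10, burst_speed=(2.0, 4.0),
        rest_jitter=0.02, heading_sigma=0.3,
    )
    return [
        SceneSpec("seq01_clean_round", "clean round well, single larva",
                  cfg(1, frame_rate=15.0), n_larvae=1),
        SceneSpec("seq02_shadow", "round well with edge shadow, two larvae",
                  cfg(2, shadow_strength=60, frame_rate=14.0), n_larvae=2),
        SceneSpec("seq03_square_clean", "clean square well, two larvae",
                  cfg(3, well_shape="square", well_radius=45.0, frame_rate=15.0), n_larvae=2),
        SceneSpec("seq04_particles", "round well with drifting particles, two larvae",
                  cfg(4, n_particles=6, frame_rate=15.0), n_larvae=2),
        SceneSpec("seq05_square_particles", "square well with particles, single larva",
                  cfg(5, well_shape="square", well_radius=45.0, n_particles=6, frame_rate=14.0),
                  n_larvae=1),
        SceneSpec("seq06_shadow_single", "round well with edge shadow, single larva",
                  cfg(6, shadow_strength=60, frame_rate=15.0), n_larvae=1),
        SceneSpec("seq07_highfps", "high frame rate, clean round well, two larvae",
                  cfg(7, frame_rate=117.0), motion=fast, n_larvae=2),
        SceneSpec("seq08_bubbles_labels", "round well with particles, bubbles and labels",
                  cfg(8, n_particles=4, n_bubbles=3, n_labels=2, frame_rate=15.0), n_larvae=2),
        SceneSpec("seq09_occlusion", "square well with labels, scripted crossing occlusion",
                  cfg(9, well_shape="square", well_radius=45.0, n_labels=2, frame_rate=15.0),
                  n_larvae=2, occlusion=True),
        SceneSpec("seq10_complex", "most complex: shadow, particles, bubbles and labels, high fps",
                  cfg(10, shadow_strength=60, n_particles=6, n_bubbles=3, n_labels=2,
                      frame_rate=117.0),
                  motion=fast, n_larvae=3),
    ]


def make_benchmark_suite(
    out_dir: str | Path,
    seed: int = 0,
    presets: list[SceneSpec] | None = None,
) -> list[Path]:
    """Write the benchmark suite to disk: frames, GT masks, GT CSV, manifest.

    Each scene directory contains ``frames/`` (numbered PNGs), ``masks/``
    (binary PNGs), ``ground_truth.csv`` and ``manifest.yaml`` recording the
    full configuration and seed, so the data regenerate bit-identically.
    """
    out_dir = Path(out_dir)
    presets = suite_presets(base_seed=seed) if presets is None else presets
    written = []
    for spec in presets:
        data = generate_scene(spec)
        scene_dir = out_dir / spec.name
        write_frames(data["sequence"], scene_dir / "frames")
        write_masks(data["gt_masks"], scene_dir / "masks")
        write_trajectories(data["ground_truth"], scene_dir / "ground_truth.csv")
        def plain(d):  # YAML-safe: tuples → lists
            return {k: list(v) if isinstance(v, tuple) else v for k, v in d.items()}

        manifest = {
            "name": spec.name,
            "description": spec.description,
            "seed": data["spec"].scene.seed,
            "n_larvae": spec.n_larvae,
            "occlusion": spec.occlusion,
            "scene": plain(asdict(data["spec"].scene)),
            "motion": plain(asdict(spec.motion)),
            "larva": plain(asdict(spec.larva)),
        }
        with open(scene_dir / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=False)
        written.append(scene_dir)
    return written
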