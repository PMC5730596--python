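"""Video/frame I/O, grayscale conversion, short-video padding and trajectory tables.

Frames are 8-bit grayscale rasters stacked into a :class:`FrameSequence`.
Trajectories travel as tidy :class:`pandas.DataFrame` tables with columns
``track_id, frame, x, y, flag`` — the same schema is used for tracking
ground truth.

Coordinate convention: ``x`` = column, ``y`` = row, origin at the top-left
corner, frame indices 0-based.  Centroids may be fractional pixels.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "FrameSequence",
    "TRAJECTORY_COLUMNS",
    "TRAJECTORY_FLAGS",
    "load_frames",
    "pad_short_video",
    "read_trajectories",
    "write_trajectories",
    "validate_trajectories",
    "write_masks",
    "load_masks",
]

TRAJECTORY_COLUMNS = ("track_id", "frame", "x", "y", "flag")
TRAJECTORY_FLAGS = frozenset({"observed", "bridged", "error"})

#: luma weights for color → grayscale conversion (ITU-R BT.601)
_LUMA = np.array([0.299, 0.587, 0.114])

_FRAME_EXTENSIONS = (".png", ".tif", ".tiff")


@dataclass
class FrameSequence:
    """An ordered stack of equally sized 8-bit grayscale frames.

    Parameters
    ----------
    frames
        ``(n_frames, height, width)`` uint8 array.
    frame_rate
        Acquisition rate in frames per second (metadata only).
    original_start
        Index into ``frames`` where the original clip begins.  Non-zero
        only after :func:`pad_short_video` prepended warm-up duplicates;
        downstream stages report results on original frame indices only.
    """

    frames: np.ndarray
    frame_rate: float = 15.0
    original_start: int = 0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be (n, h, w), got shape {self.frames.shape}"
            )
        if self.frames.dtype != np.uint8:
            if self.frames.min() < 0 or self.frames.max() > 255:
                raise ValueError("frame intensities must lie in [0, 255]")
            self.frames = self.frames.astype(np.uint8)

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def height(self) -> int:
        return int(self.frames.shape[1])

    @property
    def width(self) -> int:
        return int(self.frames.shape[2])

    def original_index(self, padded_index: int) -> int | None:
        """Map a (possibly padded) frame index back to the original clip.

        Returns ``None`` for warm-up padding frames that have no original
        counterpart in the reported index space.
        """
        if padded_index < self.original_start:
            return None
        return padded_index - self.original_start

    def __len__(self) -> int:
        return self.n_frames

    def __iter__(self):
        return iter(self.frames)


def to_grayscale(frame: np.ndarray) -> np.ndarray:
    """Convert an H×W or H×W×3(4) frame to 8-bit grayscale (BT.601 luma)."""
    frame = np.asarray(frame)
    if frame.ndim == 2:
        gray = frame.astype(np.float64)
    elif frame.ndim == 3 and frame.shape[2] in (3, 4):
        gray = frame[..., :3].astype(np.float64) @ _LUMA
    else:
        raise ValueError(f"cannot interpret frame of shape {frame.shape}")
    return np.clip(np.rint(gray), 0, 255).astype(np.uint8)


def _numeric_sort_key(path: Path):
    m = re.search(r"(\d+)", path.stem)
    return (int(m.group(1)) if m else 0, path.name)


def _load_frame_dir(directory: Path) -> list[np.ndarray]:
    files = sorted(
        (p for p in directory.iterdir() if p.suffix.lower() in _FRAME_EXTENSIONS),
        key=_numeric_sort_key,
    )
    if not files:
        raise FileNotFoundError(f"no frame images (*{'/'.join(_FRAME_EXTENSIONS)}) in {directory}")
    return [to_grayscale(iio.imread(f)) for f in files]


def load_frames(source: str | Path, frame_rate: float = 15.0) -> FrameSequence:
    """Read a video file or a directory of numbered frames as grayscale.

    Directories are read as PNG/TIFF frames sorted by the numeric part of
    their filename.  Video files are decoded through imageio when a suitable
    plugin is available.  Color inputs are converted to single-channel luma.

    Raises
    ------
    FileNotFoundError
        If ``source`` does not exist or contains no frames.
    ValueError
        If decoded frames do not all share one shape.
    """
    source = Path(source)
    if not source.exists():
        raise FileNotFoundError(f"input not found: {source}")
    if source.is_dir():
        raw = _load_frame_dir(source)
    else:
        try:
            raw = [to_grayscale(f) for f in iio.imiter(source)]
        except Exception as exc:  # decoder errors vary by plugin
            raise ValueError(f"cannot decode video {source}: {exc}") from exc
        if not raw:
            raise ValueError(f"no frames decoded from {source}")
    shapes = {f.shape for f in raw}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent frame shapes in {source}: {sorted(shapes)}")
    return FrameSequence(np.stack(raw), frame_rate=frame_rate)


def write_frames(seq: FrameSequence, directory: str | Path, prefix: str = "frame") -> None:
    """Write a sequence as zero-padded numbered PNG frames (inverse of load)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ndigits = max(4, len(str(seq.n_frames - 1)))
    for i, frame in enumerate(seq.frames):
        iio.imwrite(directory / f"{prefix}_{i:0{ndigits}d}.png", frame)


def pad_short_video(seq: FrameSequence, T: int) -> FrameSequence:
    """Prepend duplicated frames so the sequence covers a T-frame warm-up.

    Short clips cannot feed the background model its full warm-up sample, so
    the whole clip is repeated cyclically in front of itself until the total
    length reaches ``T``.  Cyclic repetition (rather than freezing frame 0)
    keeps warm-up motion statistics similar to the clip itself.  The returned
    sequence records where the original clip starts so downstream results are
    reported on original frame indices only.
    """
    if T < 1:
        raise ValueError(f"T must be ≥ 1, got {T}")
    if seq.n_frames == 0:
        raise ValueError("cannot pad an empty sequence")
    if seq.n_frames >= T:
        return seq
    deficit = T - seq.n_frames
    reps = -(-deficit // seq.n_frames)  # ceil
    pad = np.concatenate([seq.frames] * reps)[:deficit]
    return FrameSequence(
        np.concatenate([pad, seq.frames]),
        frame_rate=seq.frame_rate,
        original_start=seq.original_start + deficit,
    )


def validate_trajectories(table: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise a trajectory table (schema + invariants)."""
    missing = set(TRAJECTORY_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"trajectory table missing columns: {sorted(missing)}")
    table = table.loc[:, list(TRAJECTORY_COLUMNS)].copy()
    table["track_id"] = table["track_id"].astype(np.int64)
    table["frame"] = table["frame"].astype(np.int64)
    table["x"] = table["x"].astype(np.float64)
    table["y"] = table["y"].astype(np.float64)
    table["flag"] = table["flag"].astype(str)
    bad_flags = set(table["flag"].unique()) - TRAJECTORY_FLAGS
    if bad_flags:
        raise ValueError(f"unknown trajectory flags: {sorted(bad_flags)}")
    if table.duplicated(["track_id", "frame"]).any():
        raise ValueError("duplicate (track_id, frame) pairs in trajectory table")
    monotone = table.sort_values(["track_id", "frame"]).groupby("track_id")["frame"].is_monotonic_increasing
    # duplicates excluded above ⇒ monotonic increasing is strict
    if not monotone.all():
        raise ValueError("frame indices must increase within each track")
    return table.sort_values(["track_id", "frame"], ignore_index=True)


def empty_trajectories() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "track_id": pd.Series(dtype=np.int64),
            "frame": pd.Series(dtype=np.int64),
            "x": pd.Series(dtype=np.float64),
            "y": pd.Series(dtype=np.float64),
            "flag": pd.Series(dtype=str),
        }
    )


def write_trajectories(table: pd.DataFrame, path: str | Path) -> None:
    """Write a trajectory table to CSV (header ``track_id,frame,x,y,flag``)."""
    validate_trajectories(table).to_csv(path, index=False)


def read_trajectories(path: str | Path) -> pd.DataFrame:
    """Read a trajectory (or ground-truth) CSV written by :func:`write_trajectories`."""
    table = pd.read_csv(path, dtype={"flag": str})
    if "flag" not in table.columns:  # GT tables may omit the flag column
        table["flag"] = "observed"
    table["flag"] = table["flag"].fillna("observed")
    return validate_trajectories(table)


def write_masks(masks: Iterable[np.ndarray], directory: str | Path, prefix: str = "mask") -> None:
    """Write binary masks as PNG bitmaps (0 = background, 255 = foreground)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    masks = list(masks)
    ndigits = max(4, len(str(max(len(masks) - 1, 0))))
    for i, mask in enumerate(masks):
        iio.imwrite(
            directory / f"{prefix}_{i:0{ndigits}d}.png",
            np.where(np.asarray(mask, bool), 255, 0).astype(np.uint8),
        )


def load_masks(directory: str | Path) -> list[np.ndarray]:
    """Load per-frame binary masks written by :func:`write_masks`."""
    directory = Path(directory)
    files = sorted(
        (p for p in directory.iterdir() if p.suffix.lower() in _FRAME_EXTENSIONS),
        key=_numeric_sort_key,
    )
    if not files:
        raise FileNotFoundError(f"no mask images in {directory}")
    return [iio.imread(f) > 127 for f in files]
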