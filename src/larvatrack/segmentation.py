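"""Foreground mask → clean larva regions.

The raw foreground mask from background subtraction is speckled with
sensor-noise fragments and water-ripple blobs.  The cleanup pipeline is:
gate the grayscale frame by the mask, 3×3 median filter, grayscale erosion,
Otsu threshold over the masked histogram, connected components, and a
relative-size filter that drops regions smaller than 20 % of the mean
region area (ripples are typically well under a fifth of a larva).

Larvae are dark bodies on a bright microscopy background, so binarisation
keeps the *dark* side of the Otsu split; bright residues (bubble rims,
ghost regions left where a long-static larva departed) are discarded here
rather than burdening the tracker.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.measure import label as _sk_label
from skimage.measure import regionprops as _sk_regionprops

__all__ = [
    "Region",
    "DetectionSet",
    "SegmentationParams",
    "median_filter_3x3",
    "gray_erosion",
    "otsu_threshold",
    "connected_components",
    "size_filter",
    "segment_frame",
]


@dataclass
class Region:
    """One segmented connected component.

    ``centroid`` is the unweighted mean of member pixel coordinates as
    ``(x, y)`` = (column, row); ``bbox`` is inclusive ``(xmin, ymin, xmax,
    ymax)``; ``coords`` holds member pixels as ``(row, col)`` pairs.
    """

    label: int
    area: int
    centroid: tuple[float, float]
    bbox: tuple[int, int, int, int]
    coords: np.ndarray

    def __post_init__(self) -> None:
        if self.area < 1:
            raise ValueError("region area must be ≥ 1")


@dataclass
class DetectionSet:
    """All surviving regions of one frame."""

    frame_index: int
    regions: list[Region] = field(default_factory=list)

    def centroids(self) -> np.ndarray:
        """(n, 2) array of region centroids as (x, y); empty → (0, 2)."""
        if not self.regions:
            return np.empty((0, 2))
        return np.array([r.centroid for r in self.regions], dtype=float)

    def __len__(self) -> int:
        return len(self.regions)


@dataclass(frozen=True)
class SegmentationParams:
    size_fraction: float = 0.20  # regions below this fraction of mean area are dropped
    median_window: int = 3
    erosion_size: int = 3
    connectivity: int = 8
    erosion_first: bool = False  # order is median → erosion by default

    def __post_init__(self) -> None:
        if not 0.0 < self.size_fraction < 1.0:
            raise ValueError("size_fraction must be in (0,1)")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


def median_filter_3x3(image: np.ndarray, window: int = 3) -> np.ndarray:
    """Median filter with a square moving window, edge replication at borders."""
    return ndimage.median_filter(np.asarray(image), size=window, mode="nearest")


def gray_erosion(image: np.ndarray, size: int = 3) -> np.ndarray:
    """Grayscale erosion: per-pixel minimum over a square structuring element."""
    return ndimage.grey_erosion(np.asarray(image), size=(size, size), mode="nearest")


def otsu_threshold(image: np.ndarray) -> int:
    """Otsu's threshold over the 256-bin histogram of ``image``.

    Returns the threshold ``t`` maximising the between-class variance of the
    split into classes ``≤ t`` and ``> t``; ties resolve to the lowest
    threshold.  Implemented as the (vectorised) exhaustive search over all
    255 candidate splits.

    Raises
    ------
    ValueError
        If the input has fewer than 2 distinct intensity values (no split
        exists; callers treat such frames as empty).
    """
    values = np.asarray(image).ravel()
    if values.size == 0:
        raise ValueError("cannot threshold an empty image")
    hist = np.bincount(values.astype(np.uint8), minlength=256).astype(float)
    if np.count_nonzero(hist) < 2:
        raise ValueError("image has fewer than 2 distinct intensities")
    levels = np.arange(256, dtype=float)
    n = hist.sum()
    cum_n = np.cumsum(hist)
    cum_mu = np.cumsum(hist * levels)
    mu_total = cum_mu[-1] / n
    # between-class variance for every threshold t = 0..254
    w0 = cum_n[:-1] / n
    w1 = 1.0 - w0
    valid = (w0 > 0) & (w1 > 0)
    mu0 = np.where(valid, cum_mu[:-1] / np.where(cum_n[:-1] > 0, cum_n[:-1], 1.0), 0.0)
    mu1 = np.where(valid, (cum_mu[-1] - cum_mu[:-1]) / np.where(n - cum_n[:-1] > 0, n - cum_n[:-1], 1.0), 0.0)
    sigma_b = np.where(valid, w0 * w1 * (mu0 - mu1) ** 2, -np.inf)
    return int(np.argmax(sigma_b))  # argmax returns the lowest tied index


def connected_components(binary: np.ndarray, connectivity: int = 8) -> list[Region]:
    """Label foreground components of a binary raster.

    8-connectivity by default (diagonal neighbours join).  Each region gets
    its pixel count, unweighted centroid as (x, y) and inclusive bbox.
    """
    binary = np.asarray(binary, dtype=bool)
    if not binary.any():
        return []
    labels = _sk_label(binary, connectivity=2 if connectivity == 8 else 1)
    regions = []
    for prop in _sk_regionprops(labels):
        cy, cx = prop.centroid  # skimage returns (row, col)
        ymin, xmin, ymax, xmax = prop.bbox  # half-open in skimage
        regions.append(
            Region(
                label=int(prop.label),
                area=int(prop.area),
                centroid=(float(cx), float(cy)),
                bbox=(int(xmin), int(ymin), int(xmax - 1), int(ymax - 1)),
                coords=prop.coords,
            )
        )
    return regions


def size_filter(regions: list[Region], fraction: float = 0.20) -> list[Region]:
    """Drop regions smaller than ``fraction`` × the mean region area.

    The mean is taken over the regions of the current frame; with the
    default fraction of 0.20 this removes ripple/noise blobs that are well
    below typical larva size.  Empty input passes through empty.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0,1)")
    if not regions:
        return []
    mean_area = float(np.mean([r.area for r in regions]))
    return [r for r in regions if r.area >= fraction * mean_area]


def segment_frame(
    frame: np.ndarray,
    mask: np.ndarray,
    params: SegmentationParams = SegmentationParams(),
    frame_index: int = 0,
) -> DetectionSet:
    """Full segmentation stage: mask-gated grayscale → denoise → threshold → regions.

    Pixels outside the foreground mask are gated to white (larvae are dark),
    the gated image is median-filtered and eroded, Otsu's threshold is
    computed over the masked pixels only, and the dark side of the split is
    labelled and size-filtered.  Degenerate inputs (empty mask, constant
    masked intensities) yield an empty detection set.
    """
    frame = np.asarray(frame)
    mask = np.asarray(mask, dtype=bool)
    if frame.shape != mask.shape:
        raise ValueError(f"frame shape {frame.shape} != mask shape {mask.shape}")
    if not mask.any():
        return DetectionSet(frame_index=frame_index)
    gated = np.where(mask, frame, 255).astype(np.uint8)
    if params.erosion_first:
        filtered = median_filter_3x3(gray_erosion(gated, params.erosion_size), params.median_window)
    else:
        filtered = gray_erosion(median_filter_3x3(gated, params.median_window), params.erosion_size)
    try:
        thr = otsu_threshold(filtered[mask])
    except ValueError:
        return DetectionSet(frame_index=frame_index)
    binary = mask & (filtered <= thr)
    regions = connected_components(binary, params.connectivity)
    regions = size_filter(regions, params.size_fraction)
    return DetectionSet(frame_index=frame_index, regions=regions)
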