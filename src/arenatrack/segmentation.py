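"""Background modelling and size-gated foreground segmentation.

The detection pipeline is the classical one for fixed-camera arena video:
build a static background (per-pixel median over a frame sample, optionally
refreshed with an exponential update), take the absolute difference of each
frame against it, threshold the difference at a user-set fraction of full
scale, optionally mask out regions outside the arena, and extract connected
components whose pixel area falls inside a [min_area, max_area] gate.  Each
surviving component becomes a :class:`Cluster` carrying the shape features
the tracker keys identity on: centroid, area, and extent along the primary
axis.

Conventions (shared package-wide): intensities in [0, 1]; x = column,
y = row, origin top-left, 0-based; components use 8-connectivity so that
diagonally touching thin animals remain a single object; the threshold
comparison is strict (``difference > threshold``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from skimage import measure as _skmeasure

from .frames import Frame, FrameSequence

__all__ = [
    "BackgroundModel",
    "Mask",
    "SegmentationParams",
    "Cluster",
    "median_background",
    "sample_frames",
    "update_background",
    "subtract",
    "apply_mask",
    "binarize",
    "label_clusters",
    "measure_cluster",
]


@dataclass
class BackgroundModel:
    """Static-scene estimate: per-pixel intensities plus the update weight."""

    pixels: np.ndarray
    update_weight: float = 0.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("background must be a 2-D grid")
        if not 0.0 <= self.update_weight <= 1.0:
            raise ValueError("update_weight must lie in [0, 1]")


@dataclass
class Mask:
    """Region-of-interest mask: positive pixels are kept, zeros removed."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be a 2-D grid")
        if (self.pixels < 0).any():
            raise ValueError("mask values must be non-negative")

    @property
    def keep(self) -> np.ndarray:
        return self.pixels > 0


@dataclass(frozen=True)
class SegmentationParams:
    """Threshold and cluster-size gate.

    threshold
        Fraction of full scale (0–1) a pixel's background difference must
        strictly exceed to count as foreground.  Low-contrast recordings
        call for small values (below 0.1 in typical arena footage).
    min_area, max_area
        Inclusive pixel-count gate for connected components.
    """

    threshold: float
    min_area: int
    max_area: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must lie in [0, 1]")
        if not 0 < self.min_area <= self.max_area:
            raise ValueError("need 0 < min_area <= max_area")


@dataclass(frozen=True)
class Cluster:
    """One detected connected foreground component."""

    frame: int
    label: int
    x: float
    y: float
    area: int
    length: float
    orientation: float
    bbox: tuple[int, int, int, int]  # (x0, y0, x1, y1), half-open
    time_s: float = 0.0


def _as_pixel_stack(frames: Iterable[Frame | np.ndarray]) -> np.ndarray:
    arrays = [f.pixels if isinstance(f, Frame) else np.asarray(f, dtype=np.float64)
              for f in frames]
    if not arrays:
        raise ValueError("median_background needs at least one frame")
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise ValueError(f"frames have mismatched shapes: {sorted(shapes)}")
    return np.stack(arrays)


def median_background(frames: Iterable[Frame | np.ndarray]) -> BackgroundModel:
    """Per-pixel median over a frame sample.

    For an even sample count the median is the mean of the two central
    order statistics.  Animals moving through a pixel in fewer than half
    of the sampled frames leave no trace in the result.
    """
    stack = _as_pixel_stack(frames)
    return BackgroundModel(np.median(stack, axis=0))


def sample_frames(frames: FrameSequence | Sequence[Frame],
                  max_samples: int = 101) -> list[Frame]:
    """Every k-th frame with k chosen so at most ``max_samples`` are taken.

    An odd sample count is preferred (drops the last sample if needed) so
    the per-pixel median is a single order statistic.
    """
    n = len(frames)
    if n == 0:
        raise ValueError("empty frame sequence")
    stride = -(-n // max_samples)  # ceil
    idx = list(range(0, n, stride))
    if len(idx) % 2 == 0 and len(idx) > 1:
        idx = idx[:-1]
    return [frames[i] for i in idx]


def update_background(model: BackgroundModel, frame: Frame | np.ndarray,
                      weight: float) -> BackgroundModel:
    """Exponential background refresh: ``(1-w)*old + w*frame``."""
    pix = frame.pixels if isinstance(frame, Frame) else np.asarray(frame, dtype=np.float64)
    if pix.shape != model.pixels.shape:
        raise ValueError("frame/background shape mismatch")
    if not 0.0 <= weight <= 1.0:
        raise ValueError("weight must lie in [0, 1]")
    return BackgroundModel((1.0 - weight) * model.pixels + weight * pix, weight)


def subtract(frame: Frame | np.ndarray, model: BackgroundModel) -> np.ndarray:
    """Absolute per-pixel difference |frame - background|.

    The absolute value makes one code path serve both recording polarities
    (dark animals on a light background and bright animals on a dark one).
    """
    pix = frame.pixels if isinstance(frame, Frame) else np.asarray(frame, dtype=np.float64)
    if pix.shape != model.pixels.shape:
        raise ValueError("frame/background shape mismatch")
    return np.abs(pix - model.pixels)


def apply_mask(image: np.ndarray, mask: Mask | np.ndarray) -> np.ndarray:
    keep = mask.keep if isinstance(mask, Mask) else np.asarray(mask) > 0
    if keep.shape != image.shape:
        raise ValueError("image/mask shape mismatch")
    return np.where(keep, image, 0.0)


def binarize(diff: np.ndarray, threshold: float) -> np.ndarray:
    """Foreground pixels are those strictly above the threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    return np.asarray(diff) > threshold


def measure_cluster(pixel_set) -> tuple[float, float, int, float, float,
                                        tuple[int, int, int, int]]:
    """Shape features of a set of foreground pixels.

    ``pixel_set`` is an (N, 2) array of (row, col) pixel coordinates (or
    anything convertible to one).  Returns ``(x, y, area, length,
    orientation, bbox)`` where the centroid is the mean of pixel centres,
    area is the pixel count, orientation is the principal axis of the
    second-moment matrix of pixel coordinates (radians in [0, pi), measured
    from the +x/column axis), and length is the peak-to-peak extent of
    pixel centres projected on that axis plus one — so a single pixel has
    length 1 and a horizontal 1x5 bar has length 5.
    """
    coords = np.atleast_2d(np.asarray(sorted(map(tuple, pixel_set))
                                      if not isinstance(pixel_set, np.ndarray)
                                      else pixel_set, dtype=np.float64))
    if coords.size == 0:
        raise ValueError("empty pixel set")
    rows, cols = coords[:, 0], coords[:, 1]
    y, x = float(rows.mean()), float(cols.mean())
    area = int(len(coords))
    dx, dy = cols - x, rows - y
    # second moments in (x, y) order
    sxx, syy, sxy = float(np.mean(dx * dx)), float(np.mean(dy * dy)), float(np.mean(dx * dy))
    if area == 1 or (sxx == 0.0 and syy == 0.0 and sxy == 0.0):
        orientation = 0.0
    else:
        cov = np.array([[sxx, sxy], [sxy, syy]])
        eigvals, eigvecs = np.linalg.eigh(cov)
        vx, vy = eigvecs[:, int(np.argmax(eigvals))]
        orientation = float(np.arctan2(vy, vx)) % np.pi
    proj = dx * np.cos(orientation) + dy * np.sin(orientation)
    length = float(np.ptp(proj)) + 1.0
    bbox = (int(cols.min()), int(rows.min()), int(cols.max()) + 1, int(rows.max()) + 1)
    return x, y, area, length, orientation, bbox


def label_clusters(binary: np.ndarray, params: SegmentationParams,
                   frame_index: int = 0, time_s: float = 0.0) -> list[Cluster]:
    """Connected components (8-connectivity) passing the area gate.

    Labels are assigned in order of each component's first pixel in raster
    scan (top-most row, then left-most column), starting at 1.
    """
    labelled, n = _skmeasure.label(np.asarray(binary, dtype=bool),
                                   connectivity=2, return_num=True)
    clusters: list[Cluster] = []
    if n == 0:
        return clusters
    regions = _skmeasure.regionprops(labelled)
    # skimage numbers components by raster order of their first pixel, which
    # is the ordering we promise; sort defensively by (top row, left col of
    # the first raster pixel) anyway.
    def first_pixel_key(region):
        r0 = int(region.coords[:, 0].min())
        c0 = int(region.coords[region.coords[:, 0] == r0, 1].min())
        return (r0, c0)

    out_label = 0
    for region in sorted(regions, key=first_pixel_key):
        if not params.min_area <= region.area <= params.max_area:
            continue
        out_label += 1
        x, y, area, length, orientation, bbox = measure_cluster(region.coords)
        clusters.append(Cluster(frame=frame_index, label=out_label, x=x, y=y,
                                area=area, length=length, orientation=orientation,
                                bbox=bbox, time_s=time_s))
    return clusters
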