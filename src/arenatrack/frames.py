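"""Grayscale frame containers.

Intensities are floats in [0, 1] regardless of the source bit depth; the
coordinate convention across the whole package is x = column, y = row,
origin at the top-left pixel centre, 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterator, Sequence

import numpy as np

__all__ = ["Frame", "FrameSequence", "ArrayFrameSequence", "LazyFrameSequence"]


@dataclass
class Frame:
    """A single grayscale frame with its index and acquisition time."""

    pixels: np.ndarray
    index: int = 0
    time_s: float = 0.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("frame pixels must be a 2-D grid")
        lo, hi = float(self.pixels.min(initial=0.0)), float(self.pixels.max(initial=0.0))
        if lo < -1e-9 or hi > 1 + 1e-9:
            raise ValueError(f"frame intensities must lie in [0, 1]; got [{lo}, {hi}]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


class FrameSequence(Sequence[Frame]):
    """Abstract ordered sequence of equally shaped frames."""

    shape: tuple[int, int]
    fps: float

    def __len__(self) -> int:  # pragma: no cover - abstract
        raise NotImplementedError

    def __getitem__(self, i: int) -> Frame:  # pragma: no cover - abstract
        raise NotImplementedError

    def __iter__(self) -> Iterator[Frame]:
        for i in range(len(self)):
            yield self[i]


class ArrayFrameSequence(FrameSequence):
    """Frames held in memory as a list of arrays."""

    def __init__(self, arrays: Sequence[np.ndarray], fps: float = 30.0):
        if len(arrays) == 0:
            raise ValueError("empty frame sequence")
        if fps <= 0:
            raise ValueError("fps must be positive")
        shapes = {a.shape for a in arrays}
        if len(shapes) != 1:
            raise ValueError(f"inconsistent frame shapes: {sorted(shapes)}")
        self._arrays = [np.asarray(a, dtype=np.float64) for a in arrays]
        self.shape = self._arrays[0].shape
        self.fps = float(fps)

    def __len__(self) -> int:
        return len(self._arrays)

    def __getitem__(self, i: int) -> Frame:
        arr = self._arrays[i]  # IndexError propagates
        return Frame(arr, index=i if i >= 0 else len(self) + i,
                     time_s=(i % len(self)) / self.fps)


class LazyFrameSequence(FrameSequence):
    """Frames rendered on demand by a deterministic ``render(i) -> ndarray``.

    Random access must be reproducible: the renderer may not keep mutable
    state between calls.  Used by the synthetic generator so that long
    high-resolution videos never need to be held in memory at once.
    """

    def __init__(self, render: Callable[[int], np.ndarray], n_frames: int,
                 shape: tuple[int, int], fps: float = 30.0):
        if n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        self._render = render
        self._n = int(n_frames)
        self.shape = shape
        self.fps = float(fps)

    def __len__(self) -> int:
        return self._n

    def __getitem__(self, i: int) -> Frame:
        if i < 0:
            i += self._n
        if not 0 <= i < self._n:
            raise IndexError(i)
        return Frame(self._render(i), index=i, time_s=i / self.fps)
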