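"""Synthetic arena video with exact ground truth.

Generates grayscale image sequences of elliptical animal blobs doing a
persistent random walk inside a rectangular arena, with optional scheduled
collisions, in either of the two recording regimes seen in small-animal
arena rigs: dark animals on a light background (ambient illumination) and
bright animals on a dark background (infrared darkfield).  Every frame
comes with a per-animal ground-truth record (true centre, rendered pixel
area, primary-axis length, merged flag), which makes the generator an
oracle for the segmentation and tracking stages.

Determinism: a single integer seed fixes everything.  Trajectories use one
seeded generator; per-frame pixel noise uses a generator keyed on
``(seed, frame)`` so frames can be re-rendered lazily in any order and
still be bit-identical.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .frames import LazyFrameSequence
from .segmentation import measure_cluster

__all__ = [
    "ArenaSpec",
    "AnimalSpec",
    "CollisionEvent",
    "GroundTruthRecord",
    "make_arena",
    "write_ground_truth",
    "read_ground_truth",
    "ground_truth_frame",
]

_GT_COLUMNS = ["frame", "animal_id", "x", "y", "area", "length", "visible", "merged"]


@dataclass(frozen=True)
class ArenaSpec:
    """Arena geometry, recording polarity, background level and pixel noise."""

    width: int
    height: int
    polarity: str = "bright_on_dark"
    background_level: float = 0.1
    noise_sigma: float = 0.01
    fps: float = 30.0

    def __post_init__(self) -> None:
        if self.width < 32 or self.height < 32:
            raise ValueError("arena must be at least 32x32 pixels")
        if self.polarity not in ("dark_on_light", "bright_on_dark"):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        if not 0.0 <= self.background_level <= 1.0:
            raise ValueError("background_level must lie in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.fps <= 0:
            raise ValueError("fps must be positive")


@dataclass(frozen=True)
class AnimalSpec:
    """One animal: nominal blob size/shape, contrast against background,
    and random-walk kinematics (speed in px/frame, heading persistence in
    [0, 1] where 1 means the heading never changes)."""

    animal_id: int
    target_area: int = 60
    axis_ratio: float = 3.0
    contrast: float = 0.5
    speed: float = 2.0
    heading_persistence: float = 0.8

    def __post_init__(self) -> None:
        if self.target_area < 4:
            raise ValueError("target_area must be >= 4 pixels")
        if self.axis_ratio < 1:
            raise ValueError("axis_ratio must be >= 1")
        if not 0.0 < self.contrast <= 1.0:
            raise ValueError("contrast must lie in (0, 1]")
        if self.speed < 0:
            raise ValueError("speed must be non-negative")
        if not 0.0 <= self.heading_persistence <= 1.0:
            raise ValueError("heading_persistence must lie in [0, 1]")

    @property
    def semi_axes(self) -> tuple[float, float]:
        """(major, minor) semi-axes of the ellipse with the target area."""
        b = np.sqrt(self.target_area / (np.pi * self.axis_ratio))
        return self.axis_ratio * b, b


@dataclass(frozen=True)
class CollisionEvent:
    """Scheduled occlusion: the two animals are steered so their blobs
    overlap mid-window and have separated again by ``frame_end``."""

    animal_a: int
    animal_b: int
    frame_start: int
    frame_end: int

    def __post_init__(self) -> None:
        if self.frame_start >= self.frame_end:
            raise ValueError("frame_start must precede frame_end")
        if self.animal_a == self.animal_b:
            raise ValueError("collision needs two distinct animals")


@dataclass(frozen=True)
class GroundTruthRecord:
    frame: int
    animal_id: int
    x: float
    y: float
    area: int
    length: float
    visible: bool
    merged: bool


def _ellipse_mask(cx: float, cy: float, a: float, b: float, theta: float,
                  width: int, height: int) -> np.ndarray:
    """(N, 2) array of (row, col) pixel centres inside the rotated ellipse."""
    r = int(np.ceil(a)) + 1
    x0, x1 = max(0, int(np.floor(cx)) - r), min(width - 1, int(np.ceil(cx)) + r)
    y0, y1 = max(0, int(np.floor(cy)) - r), min(height - 1, int(np.ceil(cy)) + r)
    xs, ys = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
    dx, dy = xs - cx, ys - cy
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return np.column_stack([ys[inside], xs[inside]])


def _simulate_paths(spec: ArenaSpec, animals: Sequence[AnimalSpec], n_frames: int,
                    collisions: Sequence[CollisionEvent], rng: np.random.Generator,
                    initial_positions):
    n = len(animals)
    major = np.array([a.semi_axes[0] for a in animals])
    margin = major + 1.0
    if np.any(2 * margin >= min(spec.width, spec.height) - 2):
        raise ValueError("animal blob too large for the arena")

    sep = major[:, None] + major[None, :] + 2.0  # centre distance for disjoint blobs

    index_of = {a.animal_id: i for i, a in enumerate(animals)}
    if len(index_of) != n:
        raise ValueError("duplicate animal ids")
    for ev in collisions:
        if ev.animal_a not in index_of or ev.animal_b not in index_of:
            raise ValueError("collision references unknown animal id")
        if ev.frame_end >= n_frames:
            raise ValueError("collision extends past the last frame")

    colliding_at_start = {frozenset((index_of[ev.animal_a], index_of[ev.animal_b]))
                          for ev in collisions if ev.frame_start == 0}

    pos = np.empty((n, 2))  # (x, y)
    if initial_positions is not None:
        if len(initial_positions) != n:
            raise ValueError("initial_positions must match the animal list")
        pos[:] = np.asarray(initial_positions, dtype=float)
        for i in range(n):
            if not (margin[i] <= pos[i, 0] <= spec.width - 1 - margin[i]
                    and margin[i] <= pos[i, 1] <= spec.height - 1 - margin[i]):
                raise ValueError(f"animal {animals[i].animal_id} starts outside the arena")
        for i in range(n):
            for j in range(i + 1, n):
                if (np.hypot(*(pos[i] - pos[j])) < sep[i, j]
                        and frozenset((i, j)) not in colliding_at_start):
                    raise ValueError(
                        f"animals {animals[i].animal_id} and {animals[j].animal_id} "
                        "overlap initially without a scheduled collision")
    else:
        for i in range(n):
            for _ in range(10_000):
                cand = rng.uniform([margin[i], margin[i]],
                                   [spec.width - 1 - margin[i], spec.height - 1 - margin[i]])
                if all(np.hypot(*(cand - pos[j])) >= sep[i, j] for j in range(i)):
                    pos[i] = cand
                    break
            else:
                raise ValueError("could not place animals without overlap; arena too crowded")

    heading = rng.uniform(0.0, 2 * np.pi, size=n)
    speeds = np.array([a.speed for a in animals])
    persist = np.array([a.heading_persistence for a in animals])

    # collision bookkeeping: per frame, which pair is being steered
    steer: dict[int, list[tuple[int, int, CollisionEvent]]] = {}
    for ev in collisions:
        # positions at frame_start are the anchors; steering moves the pair
        # from frame_start+1 onward
        for f in range(ev.frame_start + 1, ev.frame_end + 1):
            steer.setdefault(f, []).append((index_of[ev.animal_a], index_of[ev.animal_b], ev))

    anchors: dict[tuple[int, int, int], tuple[np.ndarray, np.ndarray]] = {}
    recovering: set[frozenset] = set(colliding_at_start)

    positions = np.empty((n_frames, n, 2))
    headings = np.empty((n_frames, n))
    positions[0] = pos
    headings[0] = heading

    for f in range(1, n_frames):
        steered: set[int] = set()
        exempt_pairs: set[frozenset] = set(recovering)
        new_pos = positions[f - 1].copy()
        # draw perturbations for every animal every frame: keeps the random
        # stream independent of the collision schedule
        turn = rng.normal(0.0, np.pi / 2, size=n) * (1.0 - persist)

        for ia, ib, ev in steer.get(f, []):
            key = (ev.frame_start, ia, ib)
            if key not in anchors:
                anchors[key] = (positions[ev.frame_start, ia].copy(),
                                positions[ev.frame_start, ib].copy())
            pa0, pb0 = anchors[key]
            s = (f - ev.frame_start) / (ev.frame_end - ev.frame_start)
            # linear swap: both reach the shared midpoint at s = 1/2, then
            # continue to the partner's start position (overlap then separate)
            new_pos[ia] = (1 - s) * pa0 + s * pb0
            new_pos[ib] = (1 - s) * pb0 + s * pa0
            steered.update((ia, ib))
            exempt_pairs.add(frozenset((ia, ib)))
            if f == ev.frame_end:
                for i, tgt, src in ((ia, pb0, pa0), (ib, pa0, pb0)):
                    d = tgt - src
                    if np.hypot(*d) > 0:
                        heading[i] = np.arctan2(d[1], d[0])
                recovering.add(frozenset((ia, ib)))

        for i in range(n):
            if i in steered:
                continue
            heading[i] = heading[i] + turn[i]
            cand = positions[f - 1, i] + speeds[i] * np.array([np.cos(heading[i]),
                                                               np.sin(heading[i])])
            # reflect at the walls (blob kept fully inside)
            for ax, hi in ((0, spec.width - 1), (1, spec.height - 1)):
                lo_b, hi_b = margin[i], hi - margin[i]
                if cand[ax] < lo_b:
                    cand[ax] = 2 * lo_b - cand[ax]
                    heading[i] = np.pi - heading[i] if ax == 0 else -heading[i]
                elif cand[ax] > hi_b:
                    cand[ax] = 2 * hi_b - cand[ax]
                    heading[i] = np.pi - heading[i] if ax == 0 else -heading[i]
                cand[ax] = np.clip(cand[ax], lo_b, hi_b)

            def clear(p):
                for j in range(n):
                    if j == i or frozenset((i, j)) in exempt_pairs:
                        continue
                    other = new_pos[j] if (j < i or j in steered) else positions[f - 1, j]
                    if np.hypot(*(p - other)) < sep[i, j]:
                        return False
                return True

            if clear(cand):
                new_pos[i] = cand
            else:
                back = positions[f - 1, i] - speeds[i] * np.array([np.cos(heading[i]),
                                                                   np.sin(heading[i])])
                back[0] = np.clip(back[0], margin[i], spec.width - 1 - margin[i])
                back[1] = np.clip(back[1], margin[i], spec.height - 1 - margin[i])
                if clear(back):
                    new_pos[i] = back
                    heading[i] = heading[i] + np.pi
                else:
                    new_pos[i] = positions[f - 1, i]  # stand still this frame

        # a recovering (post-collision) pair stops being exempt once separated
        for pair in list(recovering):
            i, j = tuple(pair)
            if np.hypot(*(new_pos[i] - new_pos[j])) >= sep[i, j]:
                recovering.discard(pair)

        positions[f] = new_pos
        headings[f] = heading

    return positions, headings


def make_arena(spec: ArenaSpec, animals: Sequence[AnimalSpec], n_frames: int,
               collisions: Sequence[CollisionEvent] = (), seed: int = 0,
               initial_positions=None):
    """Simulate an arena video.

    Returns ``(frames, records)`` where ``frames`` is a lazily rendered
    :class:`~arenatrack.frames.LazyFrameSequence` and ``records`` is one
    :class:`GroundTruthRecord` per (frame, animal): true sub-pixel centre,
    rendered pixel area and primary-axis length of the animal's own blob,
    and a ``merged`` flag set whenever its blob shares pixels with another
    animal's.

    The same ``seed`` gives bit-identical frames and records.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    traj_rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([int(seed), 1])))
    positions, headings = _simulate_paths(spec, animals, n_frames, collisions,
                                          traj_rng, initial_positions)
    n = len(animals)
    semi = [a.semi_axes for a in animals]

    def masks_for(f: int) -> list[np.ndarray]:
        return [_ellipse_mask(positions[f, i, 0], positions[f, i, 1],
                              semi[i][0], semi[i][1], headings[f, i],
                              spec.width, spec.height) for i in range(n)]

    # two blobs count as merged when their pixel sets touch under
    # 8-connectivity: that is exactly when a connected-components
    # segmenter sees a single object
    offsets = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)]

    records: list[GroundTruthRecord] = []
    for f in range(n_frames):
        masks = masks_for(f)
        keys = [set(map(tuple, m)) for m in masks]
        dilated = [{(r + dr, c + dc) for r, c in k for dr, dc in offsets} for k in keys]
        for i, a in enumerate(animals):
            merged = any(dilated[i] & keys[j] for j in range(n) if j != i)
            if len(masks[i]):
                _, _, area, length, _, _ = measure_cluster(masks[i])
            else:  # degenerate: blob entirely off-grid (cannot happen with margins)
                area, length = 0, 0.0
            records.append(GroundTruthRecord(
                frame=f, animal_id=a.animal_id,
                x=float(positions[f, i, 0]), y=float(positions[f, i, 1]),
                area=area, length=float(length), visible=True, merged=merged))

    base_seed = int(seed)

    def render(f: int) -> np.ndarray:
        # render canonically with bright blobs, complementing afterwards
        # for dark_on_light: mirroring polarity and background level then
        # gives bit-identical complements (the noise draw is shared)
        bright = spec.polarity == "bright_on_dark"
        bg = spec.background_level if bright else 1.0 - spec.background_level
        img = np.full((spec.height, spec.width), bg, dtype=np.float64)
        for i, a in enumerate(animals):
            m = _ellipse_mask(positions[f, i, 0], positions[f, i, 1],
                              semi[i][0], semi[i][1], headings[f, i],
                              spec.width, spec.height)
            if len(m):
                img[m[:, 0], m[:, 1]] = bg + a.contrast
        if spec.noise_sigma > 0:
            nrng = np.random.Generator(np.random.PCG64(
                np.random.SeedSequence([base_seed, 2, f])))
            img = img + nrng.normal(0.0, spec.noise_sigma, size=img.shape)
        img = np.clip(img, 0.0, 1.0)
        return img if bright else 1.0 - img

    frames = LazyFrameSequence(render, n_frames, (spec.height, spec.width), fps=spec.fps)
    return frames, records


def ground_truth_frame(records: Sequence[GroundTruthRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records], columns=_GT_COLUMNS)


def write_ground_truth(records: Sequence[GroundTruthRecord]) -> str:
    """Serialise records as CSV text (header + one row per record)."""
    if not records:
        raise ValueError("no records to write")
    return ground_truth_frame(records).to_csv(index=False, lineterminator="\n")


def read_ground_truth(source) -> list[GroundTruthRecord]:
    """Parse CSV text (or a path / file object) back into records."""
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    df = pd.read_csv(source, float_precision="round_trip")
    missing = set(_GT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"ground-truth CSV missing columns: {sorted(missing)}")
    return [GroundTruthRecord(frame=int(r.frame), animal_id=int(r.animal_id),
                              x=float(r.x), y=float(r.y), area=int(r.area),
                              length=float(r.length), visible=bool(r.visible),
                              merged=bool(r.merged))
            for r in df.itertuples(index=False)]
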