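"""Frame, table and config I/O, overlay rendering, and the end-to-end
pipeline behind the command-line interface.

Frames are read from a directory of numbered PNG/TIFF images (name order)
or, where an imageio video backend is available, from a video container.
Intensities are normalised to [0, 1] from the source bit depth and colour
is converted to grayscale (luma weights).  Lossless round-tripping uses
16-bit PNG or float32 TIFF.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml
from PIL import Image, ImageDraw

from .frames import ArrayFrameSequence, Frame, FrameSequence
from .metrics import Trajectory, epoch_stats
from .segmentation import Mask, SegmentationParams, median_background, sample_frames, subtract
from .stimulus import frame_states, parse_state_log
from .tracking import TrackerParams, track_animals

__all__ = [
    "PipelineConfig",
    "read_frames",
    "write_frames",
    "read_mask",
    "write_tracks_csv",
    "read_tracks_csv",
    "render_overlay",
    "estimate_threshold",
    "run_pipeline",
    "load_config",
]

_TRACK_COLUMNS = ["frame", "time_s", "track_id", "x", "y", "area", "length",
                  "merged", "status"]
_IMAGE_EXTS = {".png", ".tif", ".tiff"}


def _to_unit_gray(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 3:  # colour -> luma
        arr = arr[..., :3] @ np.array([0.299, 0.587, 0.114])
    arr = np.asarray(arr, dtype=np.float64)
    if np.issubdtype(np.asarray(arr).dtype, np.floating) and arr.max(initial=0) <= 1.0:
        return np.clip(arr, 0.0, 1.0)
    # integer images: scale by dtype range inferred from values
    scale = 65535.0 if arr.max(initial=0) > 255 else 255.0
    return np.clip(arr / scale, 0.0, 1.0)


def read_frames(path, fps: float = 30.0) -> FrameSequence:
    """Load a frame sequence from an image directory or a video file.

    Directory input: every PNG/TIFF in lexicographic name order (use
    zero-padded numbering).  Video input needs an imageio video backend;
    a clear error is raised when none is installed.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(str(p))
    if p.is_dir():
        files = sorted(f for f in p.iterdir() if f.suffix.lower() in _IMAGE_EXTS)
        if not files:
            raise ValueError(f"no PNG/TIFF images in {p}")
        arrays = []
        for f in files:
            raw = iio.imread(f)
            if f.suffix.lower() in (".tif", ".tiff") and np.issubdtype(raw.dtype, np.floating):
                arrays.append(np.clip(np.asarray(raw, dtype=np.float64), 0.0, 1.0))
            else:
                arrays.append(_to_unit_gray(raw))
        shapes = {a.shape for a in arrays}
        if len(shapes) != 1:
            raise ValueError(f"images in {p} have mixed sizes: {sorted(shapes)}")
        return ArrayFrameSequence(arrays, fps=fps)
    try:
        raw_frames = list(iio.imiter(p))
    except Exception as exc:
        raise ValueError(
            f"cannot read {p} as video (no imageio video backend available?); "
            "extract frames to a PNG/TIFF directory instead") from exc
    if not raw_frames:
        raise ValueError(f"no frames decoded from {p}")
    return ArrayFrameSequence([_to_unit_gray(a) for a in raw_frames], fps=fps)


def write_frames(frames: FrameSequence | Sequence[Frame], directory,
                 fmt: str = "png", bit_depth: int = 16) -> list[Path]:
    """Write frames as zero-padded numbered images.

    ``png`` writes 8- or 16-bit integers (lossless at that quantisation);
    ``tiff`` writes float32, exact for round-tripping.
    """
    out = Path(directory)
    out.mkdir(parents=True, exist_ok=True)
    width = max(4, len(str(len(frames) - 1)))
    paths = []
    for i, frame in enumerate(frames):
        pix = frame.pixels
        name = out / f"frame_{i:0{width}d}.{fmt}"
        if fmt == "png":
            if bit_depth == 16:
                iio.imwrite(name, np.round(pix * 65535).astype(np.uint16))
            else:
                iio.imwrite(name, np.round(pix * 255).astype(np.uint8))
        elif fmt in ("tif", "tiff"):
            iio.imwrite(name, pix.astype(np.float32))
        else:
            raise ValueError(f"unsupported frame format {fmt!r}")
        paths.append(name)
    return paths


def read_mask(path) -> Mask:
    """Load a region-of-interest mask image (positive = keep)."""
    return Mask(_to_unit_gray(iio.imread(path)))


def write_tracks_csv(track_table: pd.DataFrame, path) -> None:
    missing = set(_TRACK_COLUMNS) - set(track_table.columns)
    if missing:
        raise ValueError(f"track table missing columns: {sorted(missing)}")
    track_table[_TRACK_COLUMNS].to_csv(path, index=False, lineterminator="\n")


def read_tracks_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(_TRACK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"track CSV missing columns: {sorted(missing)}")
    return df


_PALETTE = [(230, 60, 60), (60, 160, 230), (70, 200, 110), (240, 180, 40),
            (180, 90, 220), (240, 120, 40), (100, 220, 220), (230, 100, 170)]
_STATE_ON = (255, 40, 40)
_STATE_OFF = (90, 90, 90)


def render_overlay(frames: FrameSequence | Sequence[Frame], track_table: pd.DataFrame,
                   states: Optional[Sequence[int]] = None,
                   trail: int = 50) -> list[np.ndarray]:
    """Annotate frames with track centroids, ids and trailing paths.

    When per-frame stimulus ``states`` are given the trail is coloured by
    the state in force at each sample (red while the light is on, grey
    otherwise), the convention used for stimulus-coded track figures.
    Returns a list of RGB uint8 arrays.
    """
    by_track = {tid: sub.sort_values("frame") for tid, sub in track_table.groupby("track_id")} \
        if len(track_table) else {}
    state_of_frame = (lambda f: int(states[f]) if states is not None and f < len(states) else None)
    out = []
    for frame in frames:
        img = Image.fromarray(np.round(frame.pixels * 255).astype(np.uint8)).convert("RGB")
        draw = ImageDraw.Draw(img)
        for tid, sub in by_track.items():
            past = sub[sub["frame"] <= frame.index].tail(trail)
            if len(past) == 0:
                continue
            xs, ys, fs = past["x"].to_numpy(), past["y"].to_numpy(), past["frame"].to_numpy()
            colour = _PALETTE[int(tid) % len(_PALETTE)]
            for k in range(1, len(xs)):
                st = state_of_frame(int(fs[k]))
                seg_colour = colour if st is None else (_STATE_ON if st else _STATE_OFF)
                draw.line([(xs[k - 1], ys[k - 1]), (xs[k], ys[k])], fill=seg_colour, width=1)
            if int(fs[-1]) == frame.index:
                x, y = float(xs[-1]), float(ys[-1])
                draw.ellipse([x - 2, y - 2, x + 2, y + 2], outline=colour)
                draw.text((x + 4, y - 10), str(int(tid)), fill=colour)
        out.append(np.asarray(img))
    return out


def estimate_threshold(frames: FrameSequence, background, cap: float = 0.1,
                       max_samples: int = 11) -> float:
    """Otsu split of the background-difference histogram, clamped to ``cap``.

    The fallback used when a config leaves the threshold unset; low caps
    suit the low-contrast regime typical of arena recordings.
    """
    from skimage.filters import threshold_otsu

    diffs = [subtract(f, background) for f in sample_frames(frames, max_samples)]
    values = np.concatenate([d.ravel() for d in diffs])
    try:
        t = float(threshold_otsu(values))
    except ValueError:  # constant image
        t = cap
    return min(max(t, 1e-6), cap)


@dataclass
class PipelineConfig:
    """Flat configuration for :func:`run_pipeline`; mirrors the YAML keys."""

    input: str
    output_dir: str
    mask: Optional[str] = None
    stimulus_log: Optional[str] = None
    fps: float = 30.0
    threshold: Optional[float] = None      # None -> estimated and logged
    min_area: int = 10
    max_area: int = 1_000_000
    max_move: float = 10.0
    min_active: int = 3
    max_inactive: int = 5
    feature_weight_area: float = 1.0
    feature_weight_length: float = 1.0
    distance_weight: float = 1.0
    merge_area: Optional[int] = None
    background_samples: int = 101
    overlay: bool = False
    seed: int = 0

    def tracker_params(self) -> TrackerParams:
        return TrackerParams(max_move=self.max_move, min_active=self.min_active,
                             max_inactive=self.max_inactive,
                             feature_weight_area=self.feature_weight_area,
                             feature_weight_length=self.feature_weight_length,
                             distance_weight=self.distance_weight,
                             merge_area=self.merge_area)


def load_config(path) -> PipelineConfig:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full offline pipeline described by ``config``.

    Stages: read frames → median background → (threshold estimate if
    unset) → segment → track → optional stimulus alignment and epoch
    stats → write outputs.  Outputs: ``tracks.csv``, ``run_log.json``,
    optionally ``epoch_stats.csv`` and ``overlay/``.  Any stage error
    aborts with a stage-named message and removes partial outputs.
    Returns a summary dict (paths, counts, parameters used).
    """
    out_dir = Path(config.output_dir)
    created = not out_dir.exists()
    out_dir.mkdir(parents=True, exist_ok=True)
    stage = "read"
    written: list[Path] = []
    try:
        in_path = Path(config.input)
        if not in_path.exists():
            raise FileNotFoundError(f"input path does not exist: {in_path}")
        frames = read_frames(in_path, fps=config.fps)
        mask = read_mask(config.mask) if config.mask else None

        stage = "background"
        bg = median_background(sample_frames(frames, config.background_samples))

        stage = "threshold"
        if config.threshold is None:
            threshold = estimate_threshold(frames, bg)
            threshold_provenance = "estimated"
        else:
            threshold, threshold_provenance = float(config.threshold), "user"
        seg = SegmentationParams(threshold=threshold, min_area=config.min_area,
                                 max_area=config.max_area)
        trk = config.tracker_params()

        stage = "track"
        assignments: list = []
        table = track_animals(frames, seg, trk, mask=mask, background=bg,
                              collect_assignments=assignments)
        tracks_path = out_dir / "tracks.csv"
        write_tracks_csv(table, tracks_path)
        written.append(tracks_path)

        stage = "stimulus"
        epoch_path = None
        states = None
        if config.stimulus_log:
            records = parse_state_log(config.stimulus_log)
            frame_times = [f.time_s for f in frames]
            states = frame_states(frame_times, records)
            steps = [(r.host_time_s, r.value) for r in records]
            stats = [epoch_stats(Trajectory.from_table(table, tid), steps)
                     for tid in sorted(table["track_id"].unique())] if len(table) else []
            epoch_path = out_dir / "epoch_stats.csv"
            pd.concat(stats, ignore_index=True).to_csv(epoch_path, index=False,
                                                       lineterminator="\n") \
                if stats else pd.DataFrame(columns=["track_id", "epoch_index", "state",
                                                    "t_start", "t_end", "displacement",
                                                    "mean_velocity"]
                                           ).to_csv(epoch_path, index=False,
                                                    lineterminator="\n")
            written.append(epoch_path)

        stage = "overlay"
        overlay_dir = None
        if config.overlay:
            overlay_dir = out_dir / "overlay"
            overlay_dir.mkdir(exist_ok=True)
            annotated = render_overlay(frames, table, states)
            width = max(4, len(str(len(annotated) - 1)))
            for i, arr in enumerate(annotated):
                iio.imwrite(overlay_dir / f"overlay_{i:0{width}d}.png", arr)
            written.append(overlay_dir)

        stage = "log"
        per_frame = [
            {"frame": i, "clusters": len(a.matches) + len(a.merges) + len(a.births)
                          + len(a.dropped),
             "matched": len(a.matches), "merged": len(a.merges),
             "births": len(a.births), "dropped": len(a.dropped),
             "misses": len(a.misses)}
            for i, a in enumerate(assignments)]
        run_log = {
            "parameters": {
                "threshold": {"value": threshold, "provenance": threshold_provenance},
                "min_area": config.min_area, "max_area": config.max_area,
                "max_move": config.max_move, "min_active": config.min_active,
                "max_inactive": config.max_inactive, "merge_area": config.merge_area,
                "background_samples": config.background_samples,
                "fps": config.fps, "seed": config.seed,
            },
            "counts": {
                "frames": len(frames),
                "tracks_emitted": int(table["track_id"].nunique()) if len(table) else 0,
                "tracks_born": int(sum(len(a.births) for a in assignments)),
                "tracks_archived_or_discarded": int(sum(len(a.discarded_tracks)
                                                        for a in assignments)),
                "clusters_found": int(sum(p["clusters"] for p in per_frame)),
                "clusters_dropped": int(sum(p["dropped"] for p in per_frame)),
            },
            "per_frame": per_frame,
        }
        log_path = out_dir / "run_log.json"
        log_path.write_text(json.dumps(run_log, indent=2) + "\n", encoding="utf-8")
        written.append(log_path)
        return {"tracks_csv": tracks_path, "epoch_stats_csv": epoch_path,
                "overlay_dir": overlay_dir, "run_log": log_path,
                "n_tracks": run_log["counts"]["tracks_emitted"],
                "threshold": threshold}
    except Exception as exc:
        for p in written:
            if p.is_dir():
                shutil.rmtree(p, ignore_errors=True)
            else:
                p.unlink(missing_ok=True)
        if created and out_dir.exists() and not any(out_dir.iterdir()):
            out_dir.rmdir()
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
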