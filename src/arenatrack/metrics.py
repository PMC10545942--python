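"""Stimulus-epoch trajectory statistics and tracking-quality scores.

Per light epoch (maximal constant-state interval of the stimulus record)
this module computes each animal's total path displacement and mean crawl
velocity, compares off vs on epochs with a paired Wilcoxon signed-rank
test, and scores a tracker's output against synthetic ground truth with an
identity-preservation percentage.

Displacement is path length (the sum of Euclidean step lengths between
consecutive samples), not net start-to-end distance, and positions are
used raw (no smoothing).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "Trajectory",
    "EpochStats",
    "PairedTestResult",
    "path_displacement",
    "mean_velocity",
    "segment_epochs",
    "epoch_stats",
    "paired_wilcoxon",
    "identity_preservation",
]


@dataclass
class Trajectory:
    """One track's positions over time; ``states`` is the per-sample
    stimulus value (0 = off) and may be omitted."""

    track_id: int
    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    states: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        if not (len(self.times) == len(self.x) == len(self.y)):
            raise ValueError("times/x/y lengths differ")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("sample times must be strictly increasing")

    @classmethod
    def from_table(cls, table: pd.DataFrame, track_id: int) -> "Trajectory":
        sub = table[table["track_id"] == track_id].sort_values("time_s")
        states = sub["state"].to_numpy() if "state" in sub.columns else None
        return cls(track_id, sub["time_s"].to_numpy(), sub["x"].to_numpy(),
                   sub["y"].to_numpy(), states)


@dataclass(frozen=True)
class EpochStats:
    epoch_index: int
    state: str                  # "on" / "off"
    t_start: float
    t_end: float
    displacement: float         # px (path length)
    mean_velocity: float        # px/s


@dataclass(frozen=True)
class PairedTestResult:
    n_pairs: int
    statistic: float            # W: rank sum of positive differences
    p_value: float


def _window(traj: Trajectory, t0: float, t1: float) -> np.ndarray:
    if t0 >= t1:
        raise ValueError("need t0 < t1")
    sel = (traj.times >= t0) & (traj.times <= t1)
    if sel.sum() < 2:
        raise ValueError(f"fewer than 2 samples in [{t0}, {t1}]")
    return sel


def path_displacement(traj: Trajectory, t0: float, t1: float) -> float:
    """Total path length (px) over samples with time in [t0, t1]."""
    sel = _window(traj, t0, t1)
    dx, dy = np.diff(traj.x[sel]), np.diff(traj.y[sel])
    return float(np.hypot(dx, dy).sum())


def mean_velocity(traj: Trajectory, t0: float, t1: float) -> float:
    """Path displacement divided by the window duration, px/s."""
    return path_displacement(traj, t0, t1) / (t1 - t0)


def _state_steps(timeline_or_records) -> tuple[np.ndarray, np.ndarray]:
    """(times, values) of the stimulus step function, any supported input."""
    obj = timeline_or_records
    if hasattr(obj, "events"):                      # StimulusTimeline
        pts = list(obj.events)
    elif len(obj) and hasattr(obj[0], "host_time_s"):  # LogRecords
        pts = [(r.host_time_s, r.value) for r in obj]
    else:
        pts = [(float(t), v) for t, v in obj]
    if not pts:
        raise ValueError("empty stimulus record")
    t = np.array([p[0] for p in pts], dtype=np.float64)
    v = np.array([p[1] for p in pts])
    return t, v


def segment_epochs(traj: Trajectory, timeline_or_records) -> list[tuple[int, float, float]]:
    """Maximal constant-state intervals intersected with the trajectory span.

    Returns ``[(state_value, t_start, t_end), ...]`` tiling
    ``[traj.times[0], traj.times[-1]]`` exactly, in time order.
    """
    t, v = _state_steps(timeline_or_records)
    span0, span1 = float(traj.times[0]), float(traj.times[-1])
    if t[0] > span0:
        raise ValueError("stimulus record starts after the trajectory")
    # collapse consecutive equal states into change points
    keep = np.concatenate([[True], np.asarray(v[1:]) != np.asarray(v[:-1])])
    ct, cv = t[keep], v[keep]
    bounds = np.concatenate([ct, [np.inf]])
    out: list[tuple[int, float, float]] = []
    for i in range(len(ct)):
        a, b = max(float(bounds[i]), span0), min(float(bounds[i + 1]), span1)
        if a < b:
            out.append((int(cv[i]), a, b))
    return out


def epoch_stats(traj: Trajectory, timeline_or_records) -> pd.DataFrame:
    """Displacement and mean velocity of one track per stimulus epoch."""
    rows = []
    for k, (state, a, b) in enumerate(segment_epochs(traj, timeline_or_records)):
        sel = (traj.times >= a) & (traj.times <= b)
        if sel.sum() < 2:
            disp, vel = 0.0, 0.0
        else:
            disp = path_displacement(traj, a, b)
            vel = disp / (b - a)
        rows.append((traj.track_id, k, "on" if state else "off", a, b, disp, vel))
    return pd.DataFrame(rows, columns=["track_id", "epoch_index", "state",
                                       "t_start", "t_end", "displacement",
                                       "mean_velocity"])


def paired_wilcoxon(values_off: Sequence[float],
                    values_on: Sequence[float]) -> PairedTestResult:
    """Two-sided paired Wilcoxon signed-rank test.

    Differences are ``on - off``; zero differences are dropped; tied
    absolute differences receive mid-ranks.  W is the rank sum over
    positive differences.  The p-value is exact (full enumeration of the
    2^n sign patterns, honouring the observed tie structure) for n <= 12
    pairs and uses the tie-corrected normal approximation (no continuity
    correction) above.  With every difference zero the test carries no
    information and p = 1 by convention.
    """
    off = np.asarray(values_off, dtype=np.float64)
    on = np.asarray(values_on, dtype=np.float64)
    if off.shape != on.shape or off.ndim != 1 or len(off) < 1:
        raise ValueError("need two equal-length 1-D samples with n >= 1")
    d = on - off
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return PairedTestResult(0, 0.0, 1.0)
    ranks = _midranks(np.abs(d))
    w = float(ranks[d > 0].sum())
    s = float(ranks.sum())            # distribution of W is symmetric about s/2
    dev = abs(w - s / 2)
    if n <= 12:
        count = 0
        for signs in itertools.product((0, 1), repeat=n):
            wp = float(sum(r for r, sg in zip(ranks, signs) if sg))
            if abs(wp - s / 2) >= dev - 1e-12:
                count += 1
        p = count / 2 ** n
    else:
        mu = n * (n + 1) / 4
        counts = pd.Series(np.abs(d)).value_counts().to_numpy()
        sigma2 = n * (n + 1) * (2 * n + 1) / 24 - float(((counts ** 3 - counts).sum())) / 48
        z = (w - mu) / math.sqrt(sigma2)
        p = 2 * (1 - norm.cdf(abs(z)))
    return PairedTestResult(n, w, min(1.0, float(p)))


def _midranks(values: np.ndarray) -> np.ndarray:
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values))
    sorted_v = values[order]
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_v[j + 1] == sorted_v[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def identity_preservation(track_table: pd.DataFrame, ground_truth,
                          max_move: float) -> float:
    """Percentage of ground-truth detections claimed by the right track.

    Tracks are mapped to animals once, by minimum-distance matching on the
    first frame both tables share.  A visible, non-merged ground-truth
    record counts as correct when the nearest emitted track position on
    its frame lies within ``max_move`` px and belongs to the mapped track.
    Returns 0.0 when there are no tracks.
    """
    from scipy.optimize import linear_sum_assignment

    gt = ground_truth if isinstance(ground_truth, pd.DataFrame) else \
        pd.DataFrame([r.__dict__ for r in ground_truth])
    if len(track_table) == 0:
        return 0.0
    common = sorted(set(track_table["frame"]) & set(gt["frame"]))
    if not common:
        raise ValueError("track table and ground truth share no frames")
    f0 = common[0]
    tt0 = track_table[track_table["frame"] == f0]
    gt0 = gt[gt["frame"] == f0]
    tids = tt0["track_id"].to_numpy()
    aids = gt0["animal_id"].to_numpy()
    dist = np.hypot(tt0["x"].to_numpy()[:, None] - gt0["x"].to_numpy()[None, :],
                    tt0["y"].to_numpy()[:, None] - gt0["y"].to_numpy()[None, :])
    ri, ci = linear_sum_assignment(dist)
    animal_of_track = {int(tids[i]): int(aids[j]) for i, j in zip(ri, ci)}

    scored = gt[gt["visible"] & ~gt["merged"]]
    total = len(scored)
    if total == 0:
        raise ValueError("no visible, non-merged ground-truth records to score")
    by_frame = {f: sub for f, sub in track_table.groupby("frame")}
    correct = 0
    for rec in scored.itertuples(index=False):
        sub = by_frame.get(rec.frame)
        if sub is None or len(sub) == 0:
            continue
        d = np.hypot(sub["x"].to_numpy() - rec.x, sub["y"].to_numpy() - rec.y)
        k = int(np.argmin(d))
        if d[k] <= max_move:
            tid = int(sub["track_id"].to_numpy()[k])
            if animal_of_track.get(tid) == rec.animal_id:
                correct += 1
    return 100.0 * correct / total
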