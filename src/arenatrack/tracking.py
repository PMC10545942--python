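"""Identity-preserving multi-object tracking.

Per-frame clusters are associated to persistent tracks by a gated,
globally optimal minimum-cost matching.  The cost of pairing a track with
a cluster combines three normalised terms: distance from the track's
predicted position (constant-velocity, one-step memory), relative area
deviation from the track's temporal mean area, and relative length
deviation from its temporal mean primary-axis length.  The time-averaged
area/length features are what lets a track reclaim the right animal after
an occlusion: while two or more tracks share a merged blob their feature
means are frozen, so the collision blob never corrupts them, and on
separation the frozen means decide which track takes which cluster.

Track lifecycle mirrors the classic active/inactive scheme: a new cluster
starts a provisional track, which becomes active after ``min_active``
consecutive matched frames (never-activated provisionals are discarded as
noise); a track missing for more than ``max_inactive`` frames is archived.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .frames import FrameSequence
from .segmentation import (Cluster, Mask, SegmentationParams, binarize,
                           apply_mask, label_clusters, median_background,
                           sample_frames, subtract)

__all__ = [
    "TrackerParams",
    "Track",
    "Assignment",
    "assignment_cost",
    "step",
    "resolve_split",
    "track_animals",
    "tracks_to_table",
]

_INFEASIBLE = math.inf
_BIG = 1e9          # sentinel for infeasible pairs inside the LSA matrix
_TIE_EPS = 1e-12    # index-ordered tie-break among equal-cost matchings

PROVISIONAL, ACTIVE, INACTIVE, ARCHIVED = "provisional", "active", "inactive", "archived"


@dataclass(frozen=True)
class TrackerParams:
    """Gate and lifecycle settings.

    max_move       : maximum plausible displacement, px/frame; the matching
                     gate scales with the number of frames a track has been
                     unobserved.
    min_active     : consecutive matched frames before a provisional track
                     is emitted as a real animal.
    max_inactive   : frames a track may go unmatched before it is archived.
    merge_area     : optional pixel area above which an unmatched cluster is
                     treated as a merged (multi-animal) blob.
    weights        : relative influence of the distance / area / length
                     terms in the assignment cost.
    """

    max_move: float
    min_active: int = 1
    max_inactive: int = 0
    feature_weight_area: float = 1.0
    feature_weight_length: float = 1.0
    distance_weight: float = 1.0
    merge_area: Optional[int] = None

    def __post_init__(self) -> None:
        if self.max_move <= 0:
            raise ValueError("max_move must be positive")
        if self.min_active < 1:
            raise ValueError("min_active must be >= 1")
        if self.max_inactive < 0:
            raise ValueError("max_inactive must be >= 0")
        w = (self.feature_weight_area, self.feature_weight_length, self.distance_weight)
        if any(x < 0 for x in w) or all(x == 0 for x in w):
            raise ValueError("weights must be non-negative and not all zero")


@dataclass
class Observation:
    frame: int
    time_s: float
    x: float
    y: float
    area: int
    length: float
    merged: bool = False


class Track:
    """One persistent animal identity."""

    def __init__(self, track_id: int, cluster: Cluster, params: TrackerParams):
        self.track_id = track_id
        self.status = ACTIVE if params.min_active <= 1 else PROVISIONAL
        self.history: list[Observation] = []
        self.mean_area: float = 0.0
        self.mean_length: float = 0.0
        self._n_feature_obs = 0
        self.active_count = 0
        self.inactive_count = 0
        self.merged = False
        self.ever_active = self.status == ACTIVE
        self._observe(cluster, merged=False)
        self.active_count = 1

    # -- state ------------------------------------------------------------
    @property
    def last(self) -> Observation:
        return self.history[-1]

    def predicted_position(self, frame: int) -> tuple[float, float]:
        """Constant-velocity prediction with one-step memory.

        Uses the last observed displacement (falls back to the last
        position for single-observation tracks); the gate, not the
        prediction, grows with the unobserved gap.  While the track is
        attached to a merged blob the prediction is the blob's last
        centroid: extrapolating across the pre-merge/merge position jump
        would shoot past the blob.
        """
        if self.merged:
            return self.last.x, self.last.y
        if len(self.history) >= 2:
            a, b = self.history[-2], self.history[-1]
            return b.x + (b.x - a.x), b.y + (b.y - a.y)
        return self.last.x, self.last.y

    def _observe(self, cluster: Cluster, merged: bool) -> None:
        self.history.append(Observation(cluster.frame, cluster.time_s, cluster.x,
                                        cluster.y, cluster.area, cluster.length,
                                        merged=merged))
        if not merged:
            n = self._n_feature_obs
            self.mean_area = (n * self.mean_area + cluster.area) / (n + 1)
            self.mean_length = (n * self.mean_length + cluster.length) / (n + 1)
            self._n_feature_obs = n + 1

    # -- transitions ------------------------------------------------------
    def mark_matched(self, cluster: Cluster, params: TrackerParams) -> None:
        self._observe(cluster, merged=False)
        self.merged = False
        self.inactive_count = 0
        self.active_count += 1
        if self.status == PROVISIONAL and self.active_count >= params.min_active:
            self.status = ACTIVE
        elif self.status == INACTIVE:
            self.status = ACTIVE
        self.ever_active = self.ever_active or self.status == ACTIVE

    def mark_merged(self, cluster: Cluster) -> None:
        self._observe(cluster, merged=True)
        self.merged = True
        self.inactive_count = 0

    def mark_missed(self, params: TrackerParams) -> None:
        self.inactive_count += 1
        if self.status in (ACTIVE, PROVISIONAL):
            self.status = INACTIVE
        if self.inactive_count > params.max_inactive:
            self.status = ARCHIVED


@dataclass
class Assignment:
    """Bookkeeping of one tracking step; clusters are conserved:
    every input cluster label appears in exactly one of matches' targets,
    merges' keys, births, or dropped."""

    matches: set = field(default_factory=set)          # (track_id, cluster_label)
    merges: dict = field(default_factory=dict)         # cluster_label -> {track_id}
    births: list = field(default_factory=list)         # cluster labels
    misses: list = field(default_factory=list)         # track ids
    dropped: list = field(default_factory=list)        # cluster labels
    discarded_tracks: list = field(default_factory=list)  # provisional ids removed


def assignment_cost(track: Track, cluster: Cluster,
                    params: TrackerParams) -> float:
    """Gated matching cost; ``math.inf`` when the move gate fails.

    The gate allows ``max_move`` pixels for every frame since the track
    was last observed; for a track attached to a merged blob it widens by
    half the blob's length, since the animal may emerge anywhere along
    the blob when the occlusion ends.  The cost is
    ``dw * d/max_move + wa * |area - mean_area|/mean_area
    + wl * |length - mean_length|/mean_length``
    with the *frozen* means while the track is merged.
    """
    if not track.history:
        raise ValueError("track has no observations")
    px, py = track.predicted_position(cluster.frame)
    d = math.hypot(cluster.x - px, cluster.y - py)
    gap = max(1, cluster.frame - track.last.frame)
    gate = params.max_move * gap + (track.last.length / 2 if track.merged else 0.0)
    if d > gate:
        return _INFEASIBLE
    cost = params.distance_weight * d / params.max_move
    if track.mean_area > 0:
        cost += params.feature_weight_area * abs(cluster.area - track.mean_area) / track.mean_area
    if track.mean_length > 0:
        cost += (params.feature_weight_length
                 * abs(cluster.length - track.mean_length) / track.mean_length)
    return cost


def _min_cost_matching(tracks: Sequence[Track], clusters: Sequence[Cluster],
                       params: TrackerParams):
    """Maximum-cardinality minimum-cost matching over feasible pairs.

    Returns (pairs, cost_matrix) with pairs as a list of (ti, cj) index
    tuples.  Ties between equal-cost optima are broken toward lower track
    ids then lower cluster labels via an index epsilon.
    """
    nt, nc = len(tracks), len(clusters)
    if nt == 0 or nc == 0:
        return [], np.zeros((nt, nc))
    cost = np.empty((nt, nc))
    for i, t in enumerate(tracks):
        for j, c in enumerate(clusters):
            cij = assignment_cost(t, c, params)
            cost[i, j] = _BIG if math.isinf(cij) else cij
    # tie-break toward pairing low track ids with low cluster labels: a
    # linear index term sums to a constant over permutations, so use a
    # product term (rearrangement inequality: -i*j is minimised by the
    # index-sorted pairing) plus a sum term for partial matchings
    i_idx, j_idx = np.arange(nt)[:, None], np.arange(nc)[None, :]
    tie = 0.1 * _TIE_EPS * (i_idx + j_idx) - _TIE_EPS * (i_idx * j_idx)
    rows, cols = linear_sum_assignment(cost + tie)
    pairs = [(int(i), int(j)) for i, j in zip(rows, cols) if cost[i, j] < _BIG]
    return pairs, cost


def step(tracks: list[Track], clusters: Sequence[Cluster],
         params: TrackerParams) -> tuple[list[Track], Assignment]:
    """Advance the tracker by one frame.

    ``tracks`` is mutated in place (matched/merged/missed transitions,
    provisional discards, new births) and returned together with the
    frame's :class:`Assignment`.
    """
    frames = {c.frame for c in clusters}
    if len(frames) > 1:
        raise ValueError(f"clusters from mixed frames: {sorted(frames)}")

    live = [t for t in tracks if t.status != ARCHIVED]
    live.sort(key=lambda t: t.track_id)
    order = sorted(range(len(clusters)), key=lambda j: clusters[j].label)
    cl = [clusters[j] for j in order]

    pairs, _ = _min_cost_matching(live, cl, params)
    match_of_cluster = {j: i for i, j in pairs}
    matched_tracks = {i for i, _ in pairs}

    # feasibility of unmatched tracks, for merge attribution
    unmatched = [i for i in range(len(live)) if i not in matched_tracks]
    feas: dict[int, list[int]] = {}
    for i in unmatched:
        feas[i] = [j for j in range(len(cl))
                   if not math.isinf(assignment_cost(live[i], cl[j], params))]

    assignment = Assignment()
    merged_tracks: set[int] = set()
    consumed_clusters: set[int] = set()

    def feasible_for_merge(i: int, j: int) -> bool:
        # attaching to an oversized blob: the animal may sit anywhere
        # inside it, so relax the gate by half the blob length
        t, c = live[i], cl[j]
        px, py = t.predicted_position(c.frame)
        gap = max(1, c.frame - t.last.frame)
        return math.hypot(c.x - px, c.y - py) <= params.max_move * gap + c.length / 2

    for j, c in enumerate(cl):
        oversized = params.merge_area is not None and c.area > params.merge_area
        uniq = [i for i in unmatched if feas.get(i) == [j]]
        group = [i for i in ([match_of_cluster[j]] if j in match_of_cluster else [])]
        group += [i for i in unmatched if feasible_for_merge(i, j)] if oversized else uniq
        group = sorted(set(group) - merged_tracks)
        if (oversized and group) or len(group) >= 2:
            assignment.merges[c.label] = {live[i].track_id for i in group}
            for i in group:
                live[i].mark_merged(c)
                merged_tracks.add(i)
            consumed_clusters.add(j)
        elif oversized and not group:
            assignment.dropped.append(c.label)
            consumed_clusters.add(j)

    for i, j in pairs:
        if j in consumed_clusters or i in merged_tracks:
            continue
        live[i].mark_matched(cl[j], params)
        assignment.matches.add((live[i].track_id, cl[j].label))
        consumed_clusters.add(j)
        matched_tracks.add(i)

    # births
    next_id = max((t.track_id for t in tracks), default=-1) + 1
    for j, c in enumerate(cl):
        if j in consumed_clusters:
            continue
        tracks.append(Track(next_id, c, params))
        assignment.births.append(c.label)
        next_id += 1

    # misses
    for i, t in enumerate(live):
        if i in matched_tracks or i in merged_tracks:
            continue
        if t.status == PROVISIONAL:
            # the consecutive-match requirement is broken: discard as noise
            tracks.remove(t)
            assignment.discarded_tracks.append(t.track_id)
        else:
            t.mark_missed(params)
            assignment.misses.append(t.track_id)
    return tracks, assignment


def resolve_split(merged_tracks: Sequence[Track], new_clusters: Sequence[Cluster],
                  params: TrackerParams) -> dict[int, int]:
    """Re-identify animals after an occlusion ends.

    Matches the tracks attached to a merged blob against the clusters that
    appear when it separates, by minimum total assignment cost using the
    means frozen at merge time.  Matched tracks resume normal updating
    (merged flag cleared); unmatched tracks stay merged.  Returns
    ``{track_id: cluster_label}``.
    """
    if len(merged_tracks) < 2:
        raise ValueError("a split involves at least two merged tracks")
    tr = sorted(merged_tracks, key=lambda t: t.track_id)
    cl = sorted(new_clusters, key=lambda c: c.label)
    pairs, _ = _min_cost_matching(tr, cl, params)
    out: dict[int, int] = {}
    for i, j in pairs:
        tr[i].mark_matched(cl[j], params)
        out[tr[i].track_id] = cl[j].label
    return out


def tracks_to_table(tracks: Iterable[Track], only_ever_active: bool = True) -> pd.DataFrame:
    """Flatten tracks into the canonical long table, sorted by (frame, track_id)."""
    rows = []
    for t in tracks:
        if only_ever_active and not t.ever_active:
            continue
        for ob in t.history:
            rows.append((ob.frame, ob.time_s, t.track_id, ob.x, ob.y,
                         ob.area, ob.length, ob.merged, t.status))
    df = pd.DataFrame(rows, columns=["frame", "time_s", "track_id", "x", "y",
                                     "area", "length", "merged", "status"])
    return df.sort_values(["frame", "track_id"], kind="stable").reset_index(drop=True)


def track_animals(frames: FrameSequence | Sequence, seg_params: SegmentationParams,
                  tracker_params: TrackerParams, mask: Optional[Mask] = None,
                  background: Optional[np.ndarray] = None,
                  background_samples: int = 101,
                  collect_assignments: Optional[list] = None) -> pd.DataFrame:
    """Run the full offline pipeline on a frame sequence.

    Stages: median background (from an at-most-``background_samples``
    frame subsample) → absolute difference → optional mask → threshold →
    8-connected size-gated clusters → per-frame tracking step.  Returns
    the long track table of every track that ever reached active status,
    including its provisional prefix.  Pass a list as
    ``collect_assignments`` to receive the per-frame :class:`Assignment`
    bookkeeping (used for conservation checks and run logs).
    """
    if len(frames) == 0:
        raise ValueError("no frames")
    if background is None:
        bg = median_background(sample_frames(frames, background_samples))
    else:
        from .segmentation import BackgroundModel
        bg = background if hasattr(background, "pixels") else BackgroundModel(background)
    tracks: list[Track] = []
    for frame in frames:
        diff = subtract(frame, bg)
        if mask is not None:
            diff = apply_mask(diff, mask)
        binary = binarize(diff, seg_params.threshold)
        clusters = label_clusters(binary, seg_params, frame.index, frame.time_s)
        tracks, assignment = step(tracks, clusters, tracker_params)
        if collect_assignments is not None:
            collect_assignments.append(assignment)
    return tracks_to_table(tracks)
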