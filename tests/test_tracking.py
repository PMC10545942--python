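"""Assignment cost, optimal matching, lifecycle, and merge/split identity."""

import math

import numpy as np
import pytest

from arenatrack import (Cluster, SegmentationParams, TrackerParams,
                        assignment_cost, identity_preservation, make_arena,
                        resolve_split, step, track_animals)
from arenatrack.tracking import Track, _min_cost_matching, tracks_to_table
from arenatrack.synthetic import ground_truth_frame

from conftest import make_animals
from helpers import brute_min_cost_matching

PARAMS = TrackerParams(max_move=10.0, min_active=1, max_inactive=3)


def make_cluster(frame, x, y, area=60, length=15.0, label=1):
    return Cluster(frame=frame, label=label, x=x, y=y, area=area, length=length,
                   orientation=0.0, bbox=(int(x) - 4, int(y) - 4, int(x) + 4, int(y) + 4),
                   time_s=frame / 30.0)


def make_track(track_id, x, y, area=60, length=15.0, frame=0,
               params=PARAMS) -> Track:
    return Track(track_id, make_cluster(frame, x, y, area, length), params)


class TestAssignmentCost:
    def test_perfect_match_costs_zero(self):
        t = make_track(0, 50.0, 50.0, area=60, length=15.0)
        c = make_cluster(1, 50.0, 50.0, area=60, length=15.0)
        assert assignment_cost(t, c, PARAMS) == 0.0

    def test_move_gate_infeasible(self):
        t = make_track(0, 50.0, 50.0)
        c = make_cluster(1, 50.0 + 2 * PARAMS.max_move, 50.0)
        assert math.isinf(assignment_cost(t, c, PARAMS))

    def test_gate_scales_with_gap(self):
        t = make_track(0, 50.0, 50.0)
        c = make_cluster(3, 50.0 + 2 * PARAMS.max_move, 50.0)  # 3-frame gap
        assert math.isfinite(assignment_cost(t, c, PARAMS))

    def test_cost_formula_with_default_weights(self):
        # d = max_move/2, area off by 50%, length equal -> 0.5 + 0.5 + 0 = 1.0
        t = make_track(0, 50.0, 50.0, area=60, length=15.0)
        c = make_cluster(1, 50.0 + PARAMS.max_move / 2, 50.0, area=90, length=15.0)
        assert assignment_cost(t, c, PARAMS) == pytest.approx(1.0)

    def test_constant_velocity_prediction(self):
        t = make_track(0, 50.0, 50.0)
        t.mark_matched(make_cluster(1, 54.0, 50.0), PARAMS)
        c = make_cluster(2, 58.0, 50.0)  # exactly at extrapolated position
        assert assignment_cost(t, c, PARAMS) == pytest.approx(0.0)


class TestStep:
    def test_simple_match_resets_inactive_count(self):
        t = make_track(0, 50.0, 50.0)
        t.inactive_count = 1
        tracks, a = step([t], [make_cluster(1, 52.0, 50.0)], PARAMS)
        assert a.matches == {(0, 1)}
        assert t.inactive_count == 0

    def test_far_cluster_births_new_track_and_marks_miss(self):
        t = make_track(0, 50.0, 50.0)
        far = make_cluster(1, 90.0, 90.0)
        tracks, a = step([t], [far], PARAMS)
        assert a.births == [1] and a.misses == [0]
        assert t.inactive_count == 1
        assert len(tracks) == 2

    def test_mixed_frame_clusters_rejected(self):
        t = make_track(0, 50.0, 50.0)
        with pytest.raises(ValueError, match="mixed frames"):
            step([t], [make_cluster(1, 50, 50, label=1), make_cluster(2, 60, 60, label=2)],
                 PARAMS)

    def test_three_by_three_matches_brute_force(self, rng):
        for _ in range(50):
            tracks = [make_track(i, *rng.uniform(20, 80, 2),
                                 area=int(rng.integers(40, 120)),
                                 length=float(rng.uniform(8, 25))) for i in range(3)]
            clusters = [make_cluster(1, *rng.uniform(20, 80, 2),
                                     area=int(rng.integers(40, 120)),
                                     length=float(rng.uniform(8, 25)), label=j + 1)
                        for j in range(3)]
            params = TrackerParams(max_move=40.0, min_active=1, max_inactive=3)
            cost = np.array([[assignment_cost(t, c, params) for c in clusters]
                             for t in tracks])
            got_pairs, got_cost = _min_cost_matching(tracks, clusters, params)
            _, want_cost = brute_min_cost_matching(cost)
            total = sum(cost[i, j] for i, j in got_pairs)
            assert total == pytest.approx(want_cost, abs=1e-9)

    def test_determinism_of_tie_break(self):
        # two identical tracks, two identical clusters: lowest id wins lowest label
        tracks = [make_track(0, 50.0, 50.0), make_track(1, 50.0, 50.0)]
        clusters = [make_cluster(1, 51.0, 50.0, label=1), make_cluster(1, 51.0, 50.0, label=2)]
        pairs, _ = _min_cost_matching(tracks, clusters, TrackerParams(max_move=10))
        assert pairs == [(0, 0), (1, 1)]


class TestLifecycle:
    def test_survives_exactly_max_inactive_frames(self):
        params = TrackerParams(max_move=10, min_active=1, max_inactive=3)
        t = make_track(0, 50.0, 50.0, params=params)
        tracks = [t]
        for f in range(1, 4):  # 3 == max_inactive missed frames
            tracks, _ = step(tracks, [], params)
        assert t.status != "archived"
        assert t.inactive_count == 3
        # the boundary + 1 frame archives it
        tracks, _ = step(tracks, [], params)
        assert t.status == "archived"

    def test_rematch_on_final_allowed_frame_rescues_track(self):
        params = TrackerParams(max_move=10, min_active=1, max_inactive=2)
        t = make_track(0, 50.0, 50.0, params=params)
        tracks = [t]
        for _ in range(2):
            tracks, _ = step(tracks, [], params)
        tracks, a = step(tracks, [make_cluster(3, 50.0, 50.0)], params)
        assert a.matches == {(0, 1)}
        assert t.status == "active" and t.inactive_count == 0

    def test_min_active_boundary_provisional_to_active(self):
        params = TrackerParams(max_move=10, min_active=3, max_inactive=3)
        tracks, a = step([], [make_cluster(0, 50.0, 50.0)], params)
        (t,) = tracks
        assert t.status == "provisional" and a.births == [1]
        tracks, _ = step(tracks, [make_cluster(1, 51.0, 50.0)], params)
        assert t.status == "provisional"  # 2 consecutive < min_active
        tracks, _ = step(tracks, [make_cluster(2, 52.0, 50.0)], params)
        assert t.status == "active"       # exactly min_active consecutive

    def test_interrupted_provisional_is_discarded(self):
        params = TrackerParams(max_move=10, min_active=3, max_inactive=3)
        tracks, _ = step([], [make_cluster(0, 50.0, 50.0)], params)
        tracks, a = step(tracks, [], params)
        assert tracks == [] and a.discarded_tracks == [0]

    def test_never_activated_tracks_absent_from_table(self):
        params = TrackerParams(max_move=10, min_active=5, max_inactive=3)
        tracks, _ = step([], [make_cluster(0, 50.0, 50.0)], params)
        assert tracks_to_table(tracks).empty
        # provisional history is emitted retroactively once activated
        for f in range(1, 5):
            tracks, _ = step(tracks, [make_cluster(f, 50.0 + f, 50.0)], params)
        table = tracks_to_table(tracks)
        assert list(table["frame"]) == [0, 1, 2, 3, 4]


class TestMergeSplit:
    params = TrackerParams(max_move=10, min_active=1, max_inactive=10, merge_area=150)

    def _merged_pair(self):
        a = make_track(0, 50.0, 50.0, area=60, length=12.0, params=self.params)
        b = make_track(1, 60.0, 50.0, area=120, length=20.0, params=self.params)
        blob = make_cluster(1, 55.0, 50.0, area=180, length=28.0)
        tracks, asg = step([a, b], [blob], self.params)
        return a, b, asg

    def test_oversized_cluster_merges_both_tracks(self):
        a, b, asg = self._merged_pair()
        assert asg.merges == {1: {0, 1}}
        assert a.merged and b.merged
        assert a.mean_area == 60 and b.mean_area == 120  # frozen, not 180

    def test_split_assigns_by_frozen_features(self):
        a, b, _ = self._merged_pair()
        # equal distances from the blob, features must decide
        c_small = make_cluster(2, 55.0, 45.0, area=58, length=12.5, label=1)
        c_big = make_cluster(2, 55.0, 55.0, area=125, length=21.0, label=2)
        out = resolve_split([a, b], [c_small, c_big], self.params)
        assert out == {0: 1, 1: 2}
        assert not a.merged and not b.merged

    def test_split_by_distance_when_features_tie(self):
        p = self.params
        a = make_track(0, 40.0, 50.0, area=60, length=12.0, params=p)
        b = make_track(1, 60.0, 50.0, area=60, length=12.0, params=p)
        blob = make_cluster(1, 50.0, 50.0, area=180, length=28.0)
        step([a, b], [blob], p)
        near_a = make_cluster(2, 45.0, 50.0, area=60, length=12.0, label=1)
        near_b = make_cluster(2, 55.0, 50.0, area=60, length=12.0, label=2)
        # predicted positions equal (blob centroid): pure distance cannot
        # separate, but identical costs tie-break by id/label order
        out = resolve_split([a, b], [near_a, near_b], p)
        assert out == {0: 1, 1: 2}

    def test_three_way_split_matches_permutation_oracle(self, rng):
        for _ in range(30):
            p = TrackerParams(max_move=60, min_active=1, max_inactive=10, merge_area=150)
            tracks = []
            for i in range(3):
                t = make_track(i, *rng.uniform(40, 60, 2),
                               area=int(rng.integers(40, 140)),
                               length=float(rng.uniform(8, 28)), params=p)
                t.merged = True
                tracks.append(t)
            clusters = [make_cluster(1, *rng.uniform(30, 70, 2),
                                     area=int(rng.integers(40, 140)),
                                     length=float(rng.uniform(8, 28)), label=j + 1)
                        for j in range(3)]
            cost = np.array([[assignment_cost(t, c, p) for c in clusters]
                             for t in tracks])
            out = resolve_split(tracks, clusters, p)
            got = sum(cost[tid, lab - 1] for tid, lab in out.items())
            _, want = brute_min_cost_matching(cost)
            assert got == pytest.approx(want, abs=1e-9)

    def test_two_unmatched_tracks_sharing_unique_target_merge(self):
        p = TrackerParams(max_move=10, min_active=1, max_inactive=5)  # no merge_area
        a = make_track(0, 50.0, 50.0, area=60, params=p)
        b = make_track(1, 56.0, 50.0, area=60, params=p)
        blob = make_cluster(1, 53.0, 50.0, area=130, length=26.0)
        _, asg = step([a, b], [blob], p)
        assert asg.merges == {1: {0, 1}}


class TestConservation:
    def test_every_cluster_accounted_for(self, rng):
        params = TrackerParams(max_move=15, min_active=2, max_inactive=2, merge_area=200)
        tracks = []
        for frame in range(30):
            n = int(rng.integers(0, 6))
            clusters = [make_cluster(frame, *rng.uniform(10, 90, 2),
                                     area=int(rng.integers(30, 260)), label=j + 1)
                        for j in range(n)]
            tracks, a = step(tracks, clusters, params)
            accounted = ({lab for _, lab in a.matches} | set(a.merges)
                         | set(a.births) | set(a.dropped))
            assert accounted == {c.label for c in clusters}
            assert len(a.matches) + len(a.merges) + len(a.births) + len(a.dropped) \
                == len(clusters)


class TestEndToEnd:
    def test_empty_video_empty_table(self, quiet_arena):
        frames, _ = make_arena(quiet_arena, [], 10, seed=0)
        table = track_animals(frames, SegmentationParams(0.08, 20, 200),
                              TrackerParams(max_move=8, min_active=2, max_inactive=3))
        assert table.empty

    def test_disjoint_animals_perfect_identity(self, small_arena):
        frames, records = make_arena(small_arena, make_animals(4, speed=2.0), 120, seed=33)
        table = track_animals(frames, SegmentationParams(0.08, 25, 200),
                              TrackerParams(max_move=8, min_active=3, max_inactive=5))
        assert table["track_id"].nunique() == 4
        gt = ground_truth_frame(records)
        assert identity_preservation(table, gt, 8.0) == 100.0

    def test_deterministic_track_table(self, small_arena):
        frames, _ = make_arena(small_arena, make_animals(3), 60, seed=44)
        seg = SegmentationParams(0.08, 25, 200)
        trk = TrackerParams(max_move=8, min_active=3, max_inactive=5)
        t1 = track_animals(frames, seg, trk)
        t2 = track_animals(frames, seg, trk)
        assert t1.equals(t2)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            TrackerParams(max_move=0)
        with pytest.raises(ValueError):
            TrackerParams(max_move=5, min_active=0)
        with pytest.raises(ValueError):
            TrackerParams(max_move=5, feature_weight_area=0,
                          feature_weight_length=0, distance_weight=0)
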