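"""Association and bridging: brute-force assignment oracle, gating, gaps."""

import itertools

import numpy as np
import pytest

from larvatrack.segmentation import DetectionSet, Region
from larvatrack.tracking import (
    Tracker,
    TrackerConfig,
    Trajectory,
    bridge_gaps,
    compute_cost_matrix,
    gate_matrix,
    solve_assignment,
    trajectories_to_table,
)


def brute_force_min_cost(D):
    """Exhaustive minimum total cost over all maximal feasible assignments.

    Enumerates every injective assignment of min(n, m) rows/columns, skipping
    Inf entries (a pair on an Inf entry is simply left out).
    """
    D = np.asarray(D, float)
    n, m = D.shape
    transposed = n > m
    if transposed:
        D = D.T
        n, m = m, n
    best = np.inf
    best_pairs = 0
    for cols in itertools.permutations(range(m), n):
        cost, pairs = 0.0, 0
        for i, j in enumerate(cols):
            if np.isfinite(D[i, j]):
                cost += D[i, j]
                pairs += 1
        if pairs > best_pairs or (pairs == best_pairs and cost < best):
            best, best_pairs = cost, pairs
    return best if best_pairs else 0.0, best_pairs


def _detections(points, frame=0):
    regions = [
        Region(label=k + 1, area=10, centroid=(float(x), float(y)),
               bbox=(int(x), int(y), int(x) + 1, int(y) + 1),
               coords=np.zeros((10, 2), int))
        for k, (x, y) in enumerate(points)
    ]
    return DetectionSet(frame_index=frame, regions=regions)


class TestCostMatrix:
    def test_three_four_five_triangle_gives_squared_distance(self):
        D = compute_cost_matrix([(0.0, 0.0)], [(3.0, 4.0)])
        assert D.shape == (1, 1)
        assert D[0, 0] == pytest.approx(25.0)

    def test_identical_point_sets_have_zero_diagonal(self, rng):
        pts = rng.uniform(0, 50, (6, 2))
        D = compute_cost_matrix(pts, pts)
        np.testing.assert_allclose(np.diag(D), 0, atol=1e-12)

    def test_matches_direct_re_evaluation(self, rng):
        src, tgt = rng.uniform(0, 100, (5, 2)), rng.uniform(0, 100, (7, 2))
        D = compute_cost_matrix(src, tgt)
        for i in range(5):
            for j in range(7):
                expect = (tgt[j, 0] - src[i, 0]) ** 2 + (tgt[j, 1] - src[i, 1]) ** 2
                assert D[i, j] == pytest.approx(expect)

    def test_empty_sets_give_empty_matrix(self):
        assert compute_cost_matrix(_detections([]), _detections([])).size == 0


class TestGateMatrix:
    config = TrackerConfig(max_displacement=np.sqrt(50), gate_slack_px=0.0)

    def test_entries_beyond_gate_become_inf(self):
        D = gate_matrix(np.array([[4.0, 100.0]]), self.config)
        assert D[0, 0] == 4.0 and np.isinf(D[0, 1])

    def test_infinite_gate_leaves_matrix_unchanged(self, rng):
        D0 = rng.uniform(0, 1e6, (4, 4))
        cfg = TrackerConfig(max_displacement=1e9, gate_slack_px=0.0)
        np.testing.assert_array_equal(gate_matrix(D0, cfg), D0)

    def test_all_entries_beyond_gate_yield_no_pairs(self):
        D = gate_matrix(np.full((3, 3), 1e9), self.config)
        assert solve_assignment(D).pairs == []


class TestSolveAssignment:
    def test_two_by_two_example(self):
        res = solve_assignment(np.array([[1.0, 2.0], [2.0, 1.0]]))
        assert sorted(res.pairs) == [(0, 0), (1, 1)]
        assert res.total_cost == pytest.approx(2.0)

    def test_zero_diagonal_gives_identity_assignment(self):
        D = np.full((4, 4), 1e6)
        np.fill_diagonal(D, 0.0)
        res = solve_assignment(D)
        assert sorted(res.pairs) == [(i, i) for i in range(4)]

    @pytest.mark.parametrize("shape", [(6, 6), (4, 6), (6, 3), (7, 7), (2, 7)])
    def test_matches_brute_force_on_random_matrices(self, rng, shape):
        for _ in range(20):
            D = rng.uniform(0, 100, shape)
            if rng.random() < 0.5:  # gate a random subset
                D[rng.random(shape) < 0.3] = np.inf
            res = solve_assignment(D)
            expect_cost, expect_pairs = brute_force_min_cost(D)
            assert len(res.pairs) == expect_pairs
            assert res.total_cost == pytest.approx(expect_cost)

    def test_assignment_uniqueness(self, rng):
        D = rng.uniform(0, 10, (5, 8))
        res = solve_assignment(D)
        sources = [i for i, _ in res.pairs]
        targets = [j for _, j in res.pairs]
        assert len(set(sources)) == len(sources)
        assert len(set(targets)) == len(targets)

    def test_gating_monotonicity(self, rng):
        """Shrinking the gate never increases the number of matched pairs."""
        D0 = rng.uniform(0, 100, (6, 6))
        gates = [120.0, 80.0, 40.0, 10.0, 1.0]
        counts = []
        for g in gates:
            D = D0.copy()
            D[D > g] = np.inf
            counts.append(len(solve_assignment(D).pairs))
        assert counts == sorted(counts, reverse=True)


class TestTrackerStep:
    config = TrackerConfig(max_displacement=5.0, gate_slack_px=0.0)

    def _tracker_with_tracks(self, points):
        tracker = Tracker(self.config)
        tracker.step(0, _detections(points))
        return tracker

    def test_two_tracks_extended_by_nearby_detections(self):
        tracker = self._tracker_with_tracks([(0, 0), (50, 50)])
        tracker.step(1, _detections([(1, 1), (51, 50)]))
        assert len(tracker.active) == 2
        assert not tracker.dormant
        assert [len(t.points) for t in tracker.active] == [2, 2]

    def test_occluded_track_goes_dormant(self):
        tracker = self._tracker_with_tracks([(0, 0), (50, 50)])
        tracker.step(1, _detections([(1, 1)]))
        assert len(tracker.active) == 1
        assert len(tracker.dormant) == 1

    def test_far_detection_founds_new_track(self):
        tracker = self._tracker_with_tracks([(0, 0)])
        tracker.step(1, _detections([(1, 0), (30, 30)]))
        assert len(tracker.active) == 2
        ids = {t.track_id for t in tracker.active}
        assert len(ids) == 2

    def test_split_fragment_near_claimed_detection_is_folded_in(self):
        """A second piece within the gate refines the track's centroid
        (area-weighted) instead of founding a duplicate track."""
        tracker = self._tracker_with_tracks([(10, 10)])
        tracker.step(1, _detections([(9, 10), (13, 10)]))
        assert len(tracker.active) == 1
        f, x, y = tracker.active[0].points[-1]
        assert x == pytest.approx(11.0)  # equal areas → midpoint
        assert y == pytest.approx(10.0)


class TestBridgeGaps:
    config = TrackerConfig(max_displacement=10.0, gate_slack_px=0.0)  # bridge gate 120

    def _frag(self, tid, points):
        t = Trajectory(track_id=tid, points=points)
        t.segments = [list(points)]
        return t

    def test_nearby_fragments_merge_and_record_gap(self):
        a = self._frag(1, [(40, 10.0, 10.0), (50, 10.0, 10.0)])
        b = self._frag(2, [(53, 11.0, 10.0), (60, 12.0, 10.0)])
        out = bridge_gaps([a, b], self.config)
        assert len(out) == 1
        assert out[0].bridged_gaps == [(50, 53)]
        assert out[0].error_frames == []

    def test_distant_fragment_records_error_instead(self):
        a = self._frag(1, [(40, 10.0, 10.0), (50, 10.0, 10.0)])
        b = self._frag(2, [(53, 60.0, 10.0), (60, 61.0, 10.0)])
        out = bridge_gaps([a, b], self.config)  # squared distance 2500 > 120
        assert len(out) == 2
        assert out[1].error_frames == [53]

    def test_first_fragment_of_a_scene_is_not_an_error(self):
        a = self._frag(1, [(0, 5.0, 5.0)])
        out = bridge_gaps([a], self.config)
        assert out[0].error_frames == []

    def test_chain_of_three_fragments_becomes_one_trajectory(self):
        frags = [
            self._frag(1, [(0, 10.0, 10.0), (10, 12.0, 10.0)]),
            self._frag(2, [(14, 13.0, 11.0), (20, 15.0, 12.0)]),
            self._frag(3, [(25, 16.0, 12.0), (30, 18.0, 13.0)]),
        ]
        out = bridge_gaps(frags, self.config)
        assert len(out) == 1
        assert out[0].bridged_gaps == [(10, 14), (20, 25)]
        frames = [f for f, _, _ in out[0].points]
        assert frames == sorted(frames)


class TestTrajectoryTable:
    def test_bridged_gap_rows_are_interpolated(self):
        t = Trajectory(track_id=1, points=[(0, 0.0, 0.0), (1, 1.0, 0.0), (5, 5.0, 0.0), (6, 6.0, 0.0)])
        t.bridged_gaps = [(1, 5)]
        table = trajectories_to_table([t])
        bridged = table[table.flag == "bridged"]
        assert list(bridged.frame) == [2, 3, 4]
        np.testing.assert_allclose(bridged.x, [2.0, 3.0, 4.0])

    def test_error_frame_flagged_on_its_row(self):
        t = Trajectory(track_id=2, points=[(3, 1.0, 2.0), (4, 1.5, 2.0)], error_frames=[3])
        table = trajectories_to_table([t])
        assert table.loc[table.frame == 3, "flag"].item() == "error"

    def test_empty_input_gives_empty_table(self):
        table = trajectories_to_table([])
        assert len(table) == 0
        assert list(table.columns) == ["track_id", "frame", "x", "y", "flag"]
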