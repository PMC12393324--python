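"""Keypoint-distance cost, optimal assignment, and the two-stage tracker."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from courtrack.evaluation import tracking_errors
from courtrack.kd_tracker import (Detection, Track, TrackerParams,
                                  associate_frame, build_cost_matrix,
                                  keypoint_distance, solve_assignment,
                                  track_session)
from courtrack.synthetic_arena import render_detections
from tests.conftest import ZERO_NOISE


def brute_force_kd(a, b):
    """Independent per-keypoint loop implementation of the KD cost."""
    total = 0.0
    for pa, pb in zip(a, b):
        total += ((pa[0] - pb[0]) ** 2 + (pa[1] - pb[1]) ** 2) ** 0.5
    return total / len(a)


def brute_force_assignment(cost):
    """Exhaustive minimum over all one-to-one pairings of a square matrix."""
    n = cost.shape[0]
    best = np.inf
    for perm in itertools.permutations(range(n)):
        total = sum(cost[i, perm[i]] for i in range(n))
        best = min(best, total)
    return best


def make_detection(keypoints, frame=0, confidence=0.9, sex="male"):
    kp = np.asarray(keypoints, dtype=float)
    return Detection(frame=frame,
                     box=(kp[:, 0].min() - 1, kp[:, 1].min() - 1,
                          kp[:, 0].max() + 1, kp[:, 1].max() + 1),
                     keypoints=kp, confidence=confidence, sex_label=sex)


def make_track(keypoints, track_id=0, frame=-1, **kw):
    return Track(track_id=track_id,
                 last_keypoints=np.asarray(keypoints, dtype=float),
                 last_frame=frame, **kw)


KP = np.array([[1.0, 0.0], [0.0, 0.0], [-1.0, 0.0]])


class TestKeypointDistance:
    def test_identical_sets_give_zero(self):
        assert keypoint_distance(KP, KP) == 0.0

    def test_uniform_3_4_displacement_gives_five(self):
        assert keypoint_distance(KP, KP + [3.0, 4.0]) == pytest.approx(5.0)

    def test_mean_of_unequal_displacements(self):
        a = np.array([[0.0, 0.0], [1.0, 0.0]])
        b = a + np.array([[0.0, 1.0], [0.0, 3.0]])
        assert keypoint_distance(a, b) == pytest.approx(2.0)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(1000):
            a = rng.normal(size=(3, 2)) * 10
            b = rng.normal(size=(3, 2)) * 10
            assert keypoint_distance(a, b) == pytest.approx(
                brute_force_kd(a, b), rel=1e-12)

    def test_mismatched_keypoint_count_rejected(self):
        with pytest.raises(ValueError):
            keypoint_distance(KP, KP[:2])

    @given(a=arrays(float, (3, 2), elements=st.floats(-50, 50)),
           b=arrays(float, (3, 2), elements=st.floats(-50, 50)),
           c=arrays(float, (3, 2), elements=st.floats(-50, 50)))
    def test_metric_properties(self, a, b, c):
        dab = keypoint_distance(a, b)
        assert dab >= 0
        assert dab == pytest.approx(keypoint_distance(b, a), abs=1e-9)
        assert keypoint_distance(a, a) == 0.0
        assert dab <= (keypoint_distance(a, c)
                       + keypoint_distance(c, b) + 1e-9)


class TestCostMatrixAndAssignment:
    def test_empty_track_list_gives_zero_rows(self):
        m = build_cost_matrix([], [make_detection(KP)])
        assert m.shape == (0, 1)

    def test_perfect_match_gives_zero_cost(self):
        m = build_cost_matrix([make_track(KP)], [make_detection(KP)])
        assert m.shape == (1, 1) and m[0, 0] == 0.0

    def test_matrix_elements_match_pairwise_kd(self, rng):
        tracks = [make_track(rng.normal(size=(3, 2)), track_id=i)
                  for i in range(2)]
        dets = [make_detection(rng.normal(size=(3, 2))) for _ in range(3)]
        m = build_cost_matrix(tracks, dets)
        for i in range(2):
            for j in range(3):
                assert m[i, j] == pytest.approx(keypoint_distance(
                    tracks[i].last_keypoints, dets[j].keypoints))

    def test_single_pair_within_gate(self):
        assert solve_assignment(np.array([[1.0]]), gate=10) == {(0, 0)}

    def test_unique_optimum(self):
        assert solve_assignment(np.array([[1.0, 2.0], [2.0, 1.0]]),
                                gate=10) == {(0, 0), (1, 1)}

    def test_gate_prunes_costly_pair(self):
        assert solve_assignment(np.array([[1.0]]), gate=0.5) == set()

    def test_empty_matrix(self):
        assert solve_assignment(np.empty((0, 3))) == set()

    def test_nonfinite_cost_rejected(self):
        with pytest.raises(ValueError):
            solve_assignment(np.array([[np.inf]]))

    def test_matches_exhaustive_permutation_minimum(self, rng):
        """Optimal-assignment total equals the brute-force permutation
        minimum on 500 random matrices up to 6x6."""
        for trial in range(500):
            n = 1 + trial % 6
            cost = rng.uniform(0, 10, size=(n, n))
            pairs = solve_assignment(cost, gate=np.inf)
            total = sum(cost[i, j] for i, j in pairs)
            assert len(pairs) == n
            assert total == pytest.approx(brute_force_assignment(cost))

    def test_gating_agrees_with_infinite_cost_variant(self, rng):
        """When the gate exceeds every matched cost, post-assignment pruning
        and gate-aware solving coincide."""
        for _ in range(50):
            n = 4
            cost = rng.uniform(0, 5, size=(n, n))
            pairs = solve_assignment(cost, gate=10.0)
            assert pairs == solve_assignment(cost, gate=np.inf)


class TestAssociateFrame:
    def test_close_confident_detection_matches_stage1(self):
        tracks = [make_track(KP)]
        det = make_detection(KP + [0.5, 0.0], confidence=0.5)
        _, outcomes, _ = associate_frame(tracks, [det], TrackerParams())
        assert outcomes == ["stage1"]
        assert tracks[0].frames_since_match == 0

    def test_confidence_below_stage1_floor_ignored(self):
        tracks = [make_track(KP)]
        det = make_detection(KP, confidence=0.05)
        _, outcomes, _ = associate_frame(tracks, [det],
                                         TrackerParams(n_flies=1))
        assert outcomes == ["unmatched"]
        assert tracks[0].state == "lost"

    def test_mid_confidence_beyond_stage1_gate_unmatched(self):
        """A detection with confidence 0.2 at a distance between the two
        gates fails stage 1 and is excluded from stage 2 by its higher
        confidence bar."""
        params = TrackerParams(dist_stage1_mm=2.0, dist_stage2_mm=6.0,
                               n_flies=1)
        tracks = [make_track(KP)]
        det = make_detection(KP + [4.0, 0.0], confidence=0.2)
        _, outcomes, _ = associate_frame(tracks, [det], params)
        assert outcomes == ["unmatched"]

    def test_high_confidence_beyond_stage1_gate_relinks_stage2(self):
        params = TrackerParams(dist_stage1_mm=2.0, dist_stage2_mm=6.0)
        tracks = [make_track(KP)]
        det = make_detection(KP + [4.0, 0.0], confidence=0.9)
        _, outcomes, _ = associate_frame(tracks, [det], params)
        assert outcomes == ["stage2"]

    def test_mixed_frames_rejected(self):
        dets = [make_detection(KP, frame=0), make_detection(KP, frame=1)]
        with pytest.raises(ValueError):
            associate_frame([], dets, TrackerParams())

    def test_track_cap_prevents_extra_tracks(self):
        params = TrackerParams(n_flies=1)
        tracks, outcomes, _ = associate_frame(
            [], [make_detection(KP), make_detection(KP + [5, 5])], params)
        assert sorted(outcomes) == ["new", "unmatched"]
        assert len(tracks) == 1

    def test_one_to_one_consumption(self, rng):
        """No detection feeds two tracks and no track consumes two
        detections, in any frame."""
        tracks = [make_track(rng.normal(size=(3, 2)), track_id=i)
                  for i in range(4)]
        dets = [make_detection(t.last_keypoints + rng.normal(0, 0.2, (3, 2)),
                               confidence=float(rng.uniform(0.2, 1)))
                for t in tracks for _ in range(2)]
        _, outcomes, _ = associate_frame(tracks, dets,
                                         TrackerParams(n_flies=4))
        matched_frames = [t.last_frame for t in tracks if t.last_frame == 0]
        n_matched_dets = sum(o in ("stage1", "stage2") for o in outcomes)
        assert n_matched_dets == len(matched_frames)
        assert n_matched_dets <= 4


class TestTrackSession:
    def test_empty_stream_gives_empty_table(self):
        out = track_session(pd.DataFrame(columns=["frame"]))
        assert len(out) == 0

    def test_unsorted_frames_rejected(self):
        df = pd.DataFrame({"frame": [1, 0]})
        with pytest.raises(ValueError):
            track_session(df)

    def test_single_fly_gap_relinked_to_same_track(self):
        dets = {}
        for f in range(10):
            if f == 5:
                continue  # one dropped frame mid-stream
            dets[f] = [make_detection(KP + [0.1 * f, 0.0], frame=f)]
        out = track_session(dets, TrackerParams(n_flies=1), n_frames=10)
        matched = out[out["matched"]]
        assert matched["track_id"].nunique() == 1

    def test_noiseless_session_recovers_identities(self, short_session):
        """On perfect detections the tracker reproduces ground-truth
        identities with zero swaps and zero fragmentations."""
        traj, _ = short_session
        dets = render_detections(traj, ZERO_NOISE)
        out = track_session(dets, TrackerParams(n_flies=3))
        assert out["track_id"].nunique() == 3
        err = tracking_errors(out, traj)
        assert err.id_switches == 0
        assert err.fragmentations == 0
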