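"""Courtship predicates, bout segmentation, indices, and exclusion rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from courtrack import ethogram
from courtrack.ethogram import (count_switches, courtship_index,
                                extract_bouts, facing_angle, is_courting,
                                is_encounter, pause_after_stimulus,
                                preference_index, switching_probability,
                                wing_song_mask)


def bouts_from(spans, fps=30.0):
    rows = [(s, e, t, (e - s) / fps) for s, e, t in spans]
    return pd.DataFrame(rows, columns=["start_frame", "end_frame",
                                       "target_id", "duration_s"])


class TestFacingAngle:
    @pytest.mark.parametrize("female,heading,expected", [
        ((1.0, 0.0), 0.0, 0.0),      # dead ahead
        ((-1.0, 0.0), 0.0, 180.0),   # directly behind
        ((1.0, 1.0), 0.0, 45.0),     # diagonal
    ])
    def test_reference_angles(self, female, heading, expected):
        assert facing_angle((0, 0), heading, female) == pytest.approx(expected)

    def test_coincident_positions_give_nan(self):
        assert np.isnan(facing_angle((1, 1), 0.0, (1, 1)))

    @given(heading=st.floats(0, 360),
           fx=st.floats(-10, 10), fy=st.floats(-10, 10))
    def test_range_and_heading_symmetry(self, heading, fx, fy):
        if fx == 0 and fy == 0:
            return
        a = facing_angle((0, 0), heading, (fx, fy))
        assert 0.0 <= a <= 180.0
        assert facing_angle((0, 0), heading + 360, (fx, fy)) == \
            pytest.approx(a, abs=1e-6)


class TestPredicates:
    @pytest.mark.parametrize("dist,ang,expected", [
        (4.0, 10.0, True),
        (5.1, 0.0, False),
        (4.0, 31.0, False),   # outside the 60-degree full cone
    ])
    def test_courtship_predicate(self, dist, ang, expected):
        fem = (dist * np.cos(np.radians(ang)), dist * np.sin(np.radians(ang)))
        assert bool(is_courting((0, 0), 0.0, fem)) is expected

    @pytest.mark.parametrize("dist,ang,expected", [
        (1.5, 10.0, True),
        (2.5, 0.0, False),
        (1.5, 40.0, False),
    ])
    def test_encounter_predicate(self, dist, ang, expected):
        fem = (dist * np.cos(np.radians(ang)), dist * np.sin(np.radians(ang)))
        assert bool(is_encounter((0, 0), 0.0, fem)) is expected


class TestExtractBouts:
    def test_all_false_gives_empty_table(self):
        out = extract_bouts(np.zeros(50, bool), np.full(50, -1), fps=30)
        assert len(out) == 0

    def test_single_run_duration(self):
        courting = np.zeros(120, bool)
        courting[10:100] = True
        targets = np.where(courting, 1, -1)
        out = extract_bouts(courting, targets, fps=30)
        assert len(out) == 1
        assert out.iloc[0]["duration_s"] == pytest.approx(3.0)

    def test_no_gap_merging(self):
        courting = np.array([True] * 10 + [False] + [True] * 10)
        targets = np.where(courting, 1, -1)
        out = extract_bouts(courting, targets, fps=30, min_bout_frames=1)
        assert len(out) == 2

    def test_short_runs_dropped(self):
        courting = np.array([True] * 2 + [False] * 3 + [True] * 10)
        targets = np.where(courting, 1, -1)
        out = extract_bouts(courting, targets, fps=30, min_bout_frames=5)
        assert len(out) == 1 and out.iloc[0]["start_frame"] == 5

    def test_target_change_splits_bout(self):
        courting = np.ones(20, bool)
        targets = np.array([1] * 10 + [2] * 10)
        out = extract_bouts(courting, targets, fps=30)
        assert list(out["target_id"]) == [1, 2]

    def test_durations_conserve_courting_time(self, rng):
        courting = rng.uniform(size=200) < 0.5
        targets = np.where(courting, rng.integers(1, 3, 200), -1)
        out = extract_bouts(courting, targets, fps=30)
        assert out["duration_s"].sum() * 30 == pytest.approx(courting.sum())


class TestCourtshipIndex:
    def test_plain_fraction(self):
        bouts = bouts_from([(0, 9000, 1)])  # 300 s of 600 s
        res = courtship_index(bouts, assay_frames=18000, fps=30)
        assert res.courtship_index_pct == pytest.approx(50.0)
        assert not res.excluded

    def test_copulation_truncates_denominator(self):
        # 200 s courting before copulation at 400 s of a 600 s assay
        bouts = bouts_from([(0, 6000, 1)])
        res = courtship_index(bouts, 18000, 30, copulation_frame=12000)
        assert res.courtship_index_pct == pytest.approx(50.0)
        assert not res.excluded

    def test_early_copulation_excludes_assay(self):
        bouts = bouts_from([(0, 600, 1)])
        res = courtship_index(bouts, 18000, 30, copulation_frame=900)  # 30 s
        assert res.excluded
        assert np.isnan(res.courtship_index_pct)

    def test_exclusion_boundary_exactly_ten_percent(self):
        bouts = bouts_from([(0, 600, 1)])
        at = courtship_index(bouts, 18000, 30, copulation_frame=1800)
        above = courtship_index(bouts, 18000, 30, copulation_frame=1801)
        assert at.excluded and not above.excluded


class TestPreferenceIndex:
    def test_equal_times_give_zero(self):
        a = bouts_from([(0, 3000, 1)])
        b = bouts_from([(4000, 7000, 2)])
        res = preference_index(a, b, assay_frames=18000, fps=30)
        assert res.preference_index == pytest.approx(0.0)

    def test_exclusive_courtship_gives_plus_one(self):
        a = bouts_from([(0, 4000, 1)])
        b = bouts_from([])
        res = preference_index(a, b, 18000, 30)
        assert res.preference_index == pytest.approx(1.0)

    def test_two_to_one_split(self):
        a = bouts_from([(0, 2700, 1)])      # 90 s
        b = bouts_from([(3000, 3900, 2)])   # 30 s
        res = preference_index(a, b, 18000, 30)
        assert res.preference_index == pytest.approx(0.5)

    def test_no_courtship_undefined_and_excluded(self):
        res = preference_index(bouts_from([]), bouts_from([]), 18000, 30)
        assert np.isnan(res.preference_index)
        assert res.excluded

    def test_exclusion_boundary_exactly_twenty_percent(self):
        # 20% of a 600 s assay = 120 s of courtship
        a = bouts_from([(0, 1800, 1)])
        b = bouts_from([(2000, 3800, 2)])
        at = preference_index(a, b, 18000, 30)
        assert not at.excluded
        b_short = bouts_from([(2000, 3799, 2)])
        below = preference_index(a, b_short, 18000, 30)
        assert below.excluded

    @given(ta=st.integers(0, 5000), tb=st.integers(0, 5000))
    def test_antisymmetry_exact(self, ta, tb):
        if ta + tb == 0:
            return
        a = bouts_from([(0, ta, 1)]) if ta else bouts_from([])
        b = bouts_from([(6000, 6000 + tb, 2)]) if tb else bouts_from([])
        ab = preference_index(a, b, 18000, 30).preference_index
        ba = preference_index(b, a, 18000, 30).preference_index
        assert ab == -ba


class TestSwitchesAndPauses:
    @pytest.mark.parametrize("targets,expected", [
        ([1, 1, 1], 0), ([1, 2, 1], 2), ([], 0), ([1, 2, 2, 1], 2),
    ])
    def test_switch_counts(self, targets, expected):
        spans = [(100 * i, 100 * i + 50, t) for i, t in enumerate(targets)]
        assert count_switches(bouts_from(spans)) == expected

    def test_pause_measured_to_resumption(self):
        bouts = bouts_from([(0, 1000, 1), (1129, 2000, 1)])
        # onset at 1000, resumes at 1129 -> 129 frames = 4.3 s
        assert pause_after_stimulus(bouts, 1000, window_frames=900,
                                    fps=30) == pytest.approx(4.3)

    def test_courting_through_stimulus_gives_zero(self):
        bouts = bouts_from([(0, 2000, 1)])
        assert pause_after_stimulus(bouts, 1000, 900, 30) == 0.0

    def test_no_resumption_censored_at_window(self):
        bouts = bouts_from([(0, 1000, 1)])
        assert pause_after_stimulus(bouts, 1000, 900, 30) == \
            pytest.approx(30.0)

    def test_not_courting_before_onset_gives_nan(self):
        bouts = bouts_from([(2000, 3000, 1)])
        assert np.isnan(pause_after_stimulus(bouts, 1000, 900, 30))

    def test_switching_probability_extremes(self):
        bouts = bouts_from([(0, 100, 1), (200, 300, 2),
                            (400, 500, 1), (600, 700, 2)])
        assert switching_probability(bouts, [150, 350, 550], 900) == 1.0
        same = bouts_from([(0, 100, 1), (200, 300, 1)])
        assert switching_probability(same, [150], 900) == 0.0

    def test_switching_probability_empty_denominator(self):
        bouts = bouts_from([(0, 100, 1)])
        assert np.isnan(switching_probability(bouts, [5000], 900))


class TestWingSongMask:
    def test_folded_wings_silent(self):
        assert not wing_song_mask(0.0, 0.0, threshold_deg=30)

    def test_one_extended_wing_sings(self):
        assert wing_song_mask(45.0, 0.0, threshold_deg=30)

    def test_threshold_inclusive(self):
        assert wing_song_mask(30.0, 0.0, threshold_deg=30)

    def test_vectorized(self):
        out = wing_song_mask(np.array([0.0, 45.0]), np.array([0.0, 0.0]), 30)
        assert list(out) == [False, True]


class TestScoreTrajectoryConservation:
    def test_per_target_times_sum_to_total(self, short_session):
        traj, _ = short_session
        flags = ethogram.score_trajectory(traj)
        bouts = extract_bouts(flags["courting"].to_numpy(),
                              flags["target_id"].to_numpy(), fps=30)
        total = bouts["duration_s"].sum()
        per_target = sum(bouts[bouts["target_id"] == t]["duration_s"].sum()
                         for t in bouts["target_id"].unique())
        assert per_target == pytest.approx(total)
        # CI from bouts equals CI from raw flags at min_bout_frames=1
        assert bouts["duration_s"].sum() * 30 == pytest.approx(
            flags["courting"].sum())
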