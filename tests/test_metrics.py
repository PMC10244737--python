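"""Dispersion, extremeness, auto/partner distance, and signal-area clouds."""

import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dispersim.game_model import PadPoint
from dispersim.metrics import (
    CloudSummary,
    auto_distance,
    descriptive_counts,
    extremeness_index,
    mean_distance_from_center,
    mean_pairwise_distance,
    mode_brightness,
    partner_distance,
    quintile_areas,
    quintile_bounds,
    rolling_dispersion,
    signal_area,
    success_index,
    success_index_from_counts,
    turn_series,
)
from dispersim.progression import is_established

from conftest import make_log

unit = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)


class TestSuccessIndex:
    def test_formula_extremes(self):
        assert success_index_from_counts([12] * 30) == 1.0
        assert success_index_from_counts([0] * 30) == 0.0

    def test_formula_on_partial_counts(self):
        assert success_index_from_counts([0, 0, 4, 4]) == pytest.approx(8 / 48)

    def test_all_failures_scores_zero(self):
        log = make_log([(r % 4, (0.5, 0.5), False) for r in range(12)])
        assert success_index(log) == 0.0

    def test_agrees_with_independent_mastery_replay(self, sim_logs_outer):
        """Replay the establishment/unlocking rules directly from outcomes
        and recompute the index, independently of the tracker."""
        log = sim_logs_outer[0]
        history = {}
        active = list(range(4))
        s_sum = 0
        for t in log:
            history.setdefault(t.referent_id, []).append(t.correct)
            established = {
                r
                for r in active
                if sum(history.get(r, [])[-4:]) >= 3
                and len(history.get(r, [])[-4:]) >= 3
            }
            if len(established) == len(active) and len(active) < 12:
                active = list(range(len(active) + 4))
            s_sum += len(established)
        assert success_index(log) == pytest.approx(s_sum / (12 * len(log)))


class TestDispersionMeasures:
    def test_corner_to_corner_distance(self):
        d = mean_pairwise_distance([PadPoint(0, 0), PadPoint(1, 1)])
        assert round(d, 2) == 1.41

    def test_identical_points_have_zero_distance(self):
        assert mean_pairwise_distance([(0.3, 0.3), (0.3, 0.3)]) == 0.0

    def test_four_corners_mean_pairwise(self):
        corners = [PadPoint(0, 0), PadPoint(0, 1), PadPoint(1, 0), PadPoint(1, 1)]
        # 4 side pairs at distance 1, 2 diagonals at sqrt(2)
        expected = (4 * 1 + 2 * math.sqrt(2)) / 6
        assert mean_pairwise_distance(corners) == pytest.approx(expected)

    def test_pairwise_needs_two_points(self):
        with pytest.raises(ValueError):
            mean_pairwise_distance([PadPoint(0.5, 0.5)])

    @pytest.mark.parametrize(
        "points, expected",
        [
            ([(0.5, 0.5)], 0.0),
            ([(0, 0), (0, 1), (1, 0), (1, 1)], math.sqrt(0.5)),
            ([(1.0, 0.5), (0.5, 1.0)], 0.5),
        ],
    )
    def test_mean_distance_from_center(self, points, expected):
        assert mean_distance_from_center(points) == pytest.approx(expected)

    def test_mode_brightness(self):
        one = [[(1.0, 0.0, 0.0)], [(0.2, 0.0, 0.0), (0.4, 0.0, 0.0)]]
        assert mode_brightness([one[0]]) == 1.0
        assert mode_brightness([one[1]]) == pytest.approx(0.3)
        assert mode_brightness(
            [[(0.2, 0.1, 0.0)], [(0.8, 0.0, 0.3)]]
        ) == pytest.approx(0.5)


class TestExtremeness:
    @pytest.mark.parametrize(
        "xy, expected",
        [
            ((1.0, 1.0), 1.0),  # corner
            ((0.5, 0.5), 1.0),  # center
            ((0.75, 0.75), 0.0),  # halfway from center to corner
            ((0.0, 0.0), 1.0),
        ],
    )
    def test_landmarks(self, xy, expected):
        assert extremeness_index(PadPoint(*xy)) == pytest.approx(expected)

    @given(x=unit, y=unit)
    @settings(max_examples=80, deadline=None)
    def test_bounded_on_whole_pad(self, x, y):
        v = extremeness_index(PadPoint(x, y))
        assert 0.0 <= v <= 1.0 + 1e-12


class TestSequentialDistances:
    def test_auto_distance_examples(self):
        log = make_log(
            [
                (0, (0.2, 0.2), True),   # player 0, first occurrence
                (0, (0.0, 0.0), True),   # player 1, first occurrence
                (0, (0.5, 0.6), True),   # player 0 again: vs (0.2, 0.2)
                (0, (0.6, 0.8), False),  # player 1 again: vs (0.0, 0.0)
            ]
        )
        assert auto_distance(log, log.trials[0]) is None
        assert auto_distance(log, log.trials[1]) is None
        assert auto_distance(log, log.trials[2]) == pytest.approx(0.5)
        assert auto_distance(log, log.trials[3]) == pytest.approx(1.0)

    def test_partner_distance_examples(self):
        log = make_log(
            [
                (0, (0.0, 0.0), True),   # player 0 sends referent 0
                (1, (0.2, 0.2), True),   # player 1: nobody else sent ref 1
                (5, (0.3, 0.3), True),
                (0, (0.6, 0.8), True),   # player 1 vs player 0's (0,0): 3-4-5
            ]
        )
        assert partner_distance(log, log.trials[1]) is None
        assert partner_distance(log, log.trials[3]) == pytest.approx(1.0)

    def test_exact_repeat_scores_zero(self):
        log = make_log([(0, (0.4, 0.4), True), (1, (0.9, 0.9), True),
                        (0, (0.4, 0.4), True)])
        assert auto_distance(log, log.trials[2]) == 0.0

    def test_symmetric_under_player_relabeling(self, toy_log):
        """Swapping who is player 0 and player 1 leaves both distance
        sequences unchanged: the measures only depend on same/other player."""
        from dispersim.game_model import GameLog, Trial

        swapped = GameLog(
            pair_id=toy_log.pair_id,
            condition=toy_log.condition,
            trials=[
                Trial(
                    turn=t.turn,
                    sender_id=1 - t.sender_id,
                    referent_id=t.referent_id,
                    signal=t.signal,
                    guess_id=t.guess_id,
                    correct=t.correct,
                )
                for t in toy_log
            ],
        )
        for orig_t, swap_t in zip(toy_log, swapped):
            assert auto_distance(toy_log, orig_t) == auto_distance(swapped, swap_t)
            assert partner_distance(toy_log, orig_t) == partner_distance(
                swapped, swap_t
            )


class TestRollingDispersion:
    def test_needs_two_successful_referents(self):
        log = make_log([(0, (0.1, 0.1), True), (1, (0.9, 0.9), False)])
        assert rolling_dispersion(log, 2) is None

    def test_two_and_three_referent_values(self):
        log = make_log(
            [
                (0, (0.0, 0.0), True),
                (1, (1.0, 1.0), True),
                (2, (0.5, 0.5), True),
            ]
        )
        assert rolling_dispersion(log, 2) == pytest.approx(math.sqrt(2))
        expected = (math.sqrt(2) + math.sqrt(0.5) + math.sqrt(0.5)) / 3
        assert rolling_dispersion(log, 3) == pytest.approx(expected)

    def test_uses_most_recent_success_per_referent(self):
        log = make_log(
            [
                (0, (0.0, 0.0), True),
                (1, (1.0, 1.0), True),
                (0, (1.0, 0.0), True),  # supersedes (0, 0)
            ]
        )
        assert rolling_dispersion(log, 3) == pytest.approx(1.0)

    def test_final_turn_matches_mean_pairwise_of_final_set(self, sim_logs_outer):
        log = sim_logs_outer[1]
        latest = {}
        for t in log:
            if t.correct:
                latest[t.referent_id] = t.first_point
        expected = mean_pairwise_distance(list(latest.values()))
        assert rolling_dispersion(log, log.trials[-1].turn) == pytest.approx(expected)


def rotate(points, theta, origin=(0.0, 0.0)):
    c, s = math.cos(theta), math.sin(theta)
    ox, oy = origin
    return [
        (ox + c * (x - ox) - s * (y - oy), oy + s * (x - ox) + c * (y - oy))
        for x, y in points
    ]


class TestSignalArea:
    def test_degenerate_clouds_have_zero_area(self):
        assert signal_area([(0.3, 0.3)] * 5) == 0.0
        collinear = [(0.1 * i, 0.2 * i) for i in range(6)]
        assert signal_area(collinear) == pytest.approx(0.0, abs=1e-12)

    def test_axis_aligned_rectangle(self):
        w, h = 0.6, 0.2
        cloud = [(0, 0), (w, 0), (0, h), (w, h)]
        assert signal_area(cloud) == pytest.approx(math.pi * w * h / 4)

    def test_rotation_and_translation_invariance(self):
        rng = np.random.default_rng(42)
        cloud = rng.random((30, 2)) * 0.3
        base = signal_area(cloud)
        for theta in (0.3, 1.2, 2.5):
            moved = rotate([tuple(p) for p in cloud], theta)
            shifted = [(x + 0.1, y + 0.2) for x, y in moved]
            assert signal_area(shifted) == pytest.approx(base, abs=1e-9)

    def test_single_far_outlier_is_discarded(self):
        rng = np.random.default_rng(7)
        tight = np.clip(rng.normal(0.5, 0.01, size=(40, 2)), 0, 1)
        with_outlier = np.vstack([tight, [[0.95, 0.95]]])
        # a lone distant point is dropped by the 2-SD rule, so the area
        # stays on the scale of the tight cluster, not of the full spread
        assert signal_area(with_outlier) < 0.01
        assert signal_area(with_outlier) == pytest.approx(
            signal_area(tight), rel=0.5
        )

    def test_empty_cloud_rejected(self):
        with pytest.raises(ValueError):
            signal_area([])


class TestQuintiles:
    @pytest.mark.parametrize(
        "n, sizes",
        [
            (10, (2, 2, 2, 2, 2)),
            (12, (3, 3, 2, 2, 2)),
            (11, (3, 2, 2, 2, 2)),
            (200, (40, 40, 40, 40, 40)),
        ],
    )
    def test_bounds_sizes(self, n, sizes):
        bounds = quintile_bounds(n)
        assert tuple(hi - lo for lo, hi in bounds) == sizes
        assert bounds[0][0] == 0 and bounds[-1][1] == n

    @given(n=st.integers(min_value=5, max_value=5000))
    @settings(max_examples=50, deadline=None)
    def test_bounds_partition_the_sequence(self, n):
        bounds = quintile_bounds(n)
        assert len(bounds) == 5
        widths = [hi - lo for lo, hi in bounds]
        assert sum(widths) == n
        assert max(widths) - min(widths) <= 1
        for (a, b), (c, d) in zip(bounds, bounds[1:]):
            assert b == c

    def test_referent_absent_from_quintile_emits_no_summary(self):
        moves = []
        for i in range(10):
            # referent 1 only appears (successfully) in the second half
            referent = 0 if i < 5 else 1
            moves.append((referent, (0.1 + 0.05 * i, 0.3), True))
        log = make_log(moves)
        summaries = quintile_areas(log)
        early = [c for c in summaries if c.quintile <= 2]
        assert all(c.referent_id == 0 for c in early)

    def test_failed_trials_excluded_from_clouds(self, toy_log):
        summaries = quintile_areas(toy_log)
        n_points = sum(c.n_points for c in summaries)
        assert n_points == sum(t.correct for t in toy_log)


class TestDescriptivesAndTurnSeries:
    def test_mean_word_length(self, toy_log):
        counts = descriptive_counts(toy_log)
        assert counts["mean_word_length"] == 1.0
        assert counts["final_established"] >= 0

    def test_turn_series_shape_and_missingness(self, toy_log):
        ts = turn_series(toy_log)
        assert len(ts) == len(toy_log)
        # each referent's first per-player occurrence has no auto-distance
        first_rows = ts.groupby(["referent_id", "sender_id"]).head(1)
        assert first_rows["auto_distance"].isna().all()

    def test_turns_since_new_referent_resets_at_unlock(self):
        # establish all four initial referents, triggering one unlock
        moves = [(r, (0.5, 0.5), True) for _ in range(3) for r in range(4)]
        moves += [(4, (0.2, 0.2), True), (5, (0.8, 0.8), True)]
        log = make_log(moves)
        ts = turn_series(log)
        assert ts["active_set_size"].iloc[-1] == 8
        unlock_turn = ts.loc[ts["active_set_size"].diff() > 0, "turn"].iloc[0]
        after = ts.loc[ts["turn"] == unlock_turn + 1, "turns_since_new_referent"]
        assert after.iloc[0] == 0
        assert ts["turns_since_new_referent"].iloc[0] == 0
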