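"""Behavioral segmentation, fear statistics, and pupil preprocessing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vrcfc import behavior
from vrcfc.behavior import (BACKTRACK, DISCARDED, FREEZE, RUN, TELEPORT,
                            discrimination_index, freeze_summary,
                            label_frames, percent_increase, pupil_preprocess,
                            segment_freezing, segment_running,
                            shock_aligned_velocity, split_traversals)
from vrcfc.simulate import generate_pupil

from oracles import freeze_epochs_bruteforce, run_epochs_bruteforce

RATE = 15.49


def _epochs(labeling, state):
    tab = labeling.epochs(state)
    return list(zip(tab.start_frame.tolist(), tab.end_frame.tolist()))


def _random_velocity(rng, n=300):
    """Velocity traces that exercise every threshold crossing."""
    levels = np.array([0.0, 0.0005, 0.001, 0.002, 0.5, 10.0, -0.0005, -3.0])
    v = rng.choice(levels, size=n)
    # stretch into short runs so min-length rules actually bind
    reps = rng.integers(1, 15, size=n)
    return np.repeat(v, reps)[:n]


class TestFreezingSegmentation:
    def test_twelve_subthreshold_frames_form_one_epoch(self):
        v = np.array([10.0] * 10 + [0.0] * 12 + [10.0] * 10)
        lab = segment_freezing(v, RATE)
        assert _epochs(lab, FREEZE) == [(10, 22)]

    def test_eleven_frames_are_discarded(self):
        v = np.array([10.0] * 10 + [0.0] * 11 + [10.0] * 10)
        lab = segment_freezing(v, RATE)
        assert _epochs(lab, FREEZE) == []
        assert np.all(lab.state[10:21] == DISCARDED)

    def test_all_running_has_no_freezes(self):
        lab = segment_freezing(np.full(100, 10.0), RATE)
        assert _epochs(lab, FREEZE) == []

    def test_frame_exactly_at_threshold_is_not_freezing(self):
        v = np.array([10.0] * 5 + [0.001] * 20 + [10.0] * 5)
        lab = segment_freezing(v, RATE)
        assert _epochs(lab, FREEZE) == []

    def test_matches_bruteforce_scanner(self, rng):
        for _ in range(100):
            v = _random_velocity(rng)
            lab = segment_freezing(v, RATE)
            assert _epochs(lab, FREEZE) == freeze_epochs_bruteforce(v)

    def test_empty_trace(self):
        lab = segment_freezing(np.array([]), RATE)
        assert len(lab.epoch_table) == 0

    def test_nonfinite_velocity_rejected(self):
        with pytest.raises(ValueError):
            segment_freezing(np.array([0.0, np.nan, 0.0]), RATE)


class TestRunningSegmentation:
    def test_alternating_single_frames_never_run(self):
        v = np.tile([10.0, 0.0], 20)
        lab = label_frames(v, RATE)
        assert _epochs(lab, RUN) == []

    def test_constant_running_is_one_epoch(self):
        lab = label_frames(np.full(50, 5.0), RATE)
        assert _epochs(lab, RUN) == [(0, 50)]

    def test_matches_bruteforce_scanner(self, rng):
        for _ in range(100):
            v = _random_velocity(rng)
            lab = segment_freezing(v, RATE)
            segment_running(v, lab)
            assert _epochs(lab, RUN) == run_epochs_bruteforce(v)


class TestBacktracking:
    def test_no_flags_for_forward_motion(self):
        flags = behavior.detect_backtracking(np.full(50, 5.0))
        assert not flags.any()

    def test_injected_bout_flagged(self, tuned_session):
        tl = tuned_session.timeline
        flags = behavior.detect_backtracking(tl.velocity_cm_s.to_numpy())
        truth_frames = tuned_session.truth.backtrack_frames
        if truth_frames.size:
            assert np.all(flags[truth_frames])

    def test_flags_never_overlap_freezes(self, tuned_session):
        lab = tuned_session.labeling
        flags = behavior.detect_backtracking(
            tuned_session.timeline.velocity_cm_s.to_numpy())
        assert not np.any(flags & (lab.state == FREEZE))

    def test_fraction_by_traversal_group(self):
        import pandas as pd
        laps = pd.DataFrame({"lap_id": [0, 1], "start_frame": [0, 10],
                             "end_frame": [10, 20]})
        flags = np.zeros(20, dtype=bool)
        flags[2:4] = True       # 2 of 10 frames in the first lap
        first, later = behavior.backtrack_fraction_by_traversal(flags, laps)
        assert first == pytest.approx(0.2)
        assert later == 0.0


def test_total_displacement_integrates_speed():
    v = np.array([10.0, -5.0, 0.0, 20.0])
    assert behavior.total_displacement(v, 10.0) == pytest.approx(3.5)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.sampled_from([0.0, 0.0005, 0.01, 5.0, -2.0]),
                min_size=1, max_size=200),
       st.integers(0, 2 ** 31 - 1))
def test_labeling_partitions_every_frame(levels, seed):
    """Every frame ends up in exactly one of the five states, and epochs
    respect their minimum lengths."""
    rng = np.random.default_rng(seed)
    v = np.repeat(levels, rng.integers(1, 14, size=len(levels)))
    teleport = rng.random(len(v)) < 0.05
    lab = label_frames(v, RATE, teleport=teleport)
    assert set(np.unique(lab.state)) <= {FREEZE, RUN, BACKTRACK,
                                         DISCARDED, TELEPORT}
    np.testing.assert_array_equal(lab.state == TELEPORT, teleport)
    tab = lab.epoch_table
    assert np.all(tab.end_frame > tab.start_frame)
    freezes = tab[tab.state == FREEZE]
    assert np.all(freezes.end_frame - freezes.start_frame >= 12)
    others = tab[tab.state != FREEZE]
    assert np.all(others.end_frame - others.start_frame >= 2)
    # epochs ordered, non-overlapping
    srt = tab.sort_values("start_frame")
    assert np.all(srt.start_frame.to_numpy()[1:] >= srt.end_frame.to_numpy()[:-1])


class TestFreezeSummary:
    def test_all_freezing_is_100_percent(self):
        lab = label_frames(np.zeros(40), RATE)
        assert freeze_summary(lab).pct_time_freezing == 100.0

    def test_reported_group_mean_increases(self):
        """Worked-example arithmetic from group-mean freeze lengths and
        freezing percentages."""
        assert round(percent_increase(21.1, 5.5)) == 284
        assert round(percent_increase(12.1, 4.2)) == 188
        assert percent_increase(77.8, 49.3) >= 57.0

    def test_matches_ground_truth_tiling(self, tuned_session):
        truth = tuned_session.truth
        freeze = sum(e - s for s, e in truth.true_freeze_epochs)
        total = freeze + sum(e - s for s, e in truth.true_run_epochs)
        summary = freeze_summary(tuned_session.labeling)
        assert summary.pct_time_freezing == pytest.approx(
            100.0 * freeze / total, abs=1.0)

    def test_detected_freezes_recover_truth(self, tuned_session):
        """Jaccard overlap of detected vs true freeze frames >= 0.95 at zero
        velocity noise."""
        lab = tuned_session.labeling
        detected = lab.state == FREEZE
        true = np.zeros_like(detected)
        for s, e in tuned_session.truth.true_freeze_epochs:
            true[s:e] = True
        jaccard = (detected & true).sum() / (detected | true).sum()
        assert jaccard >= 0.95

    def test_error_without_analyzable_frames(self):
        lab = label_frames(np.zeros(5), RATE)  # 5 frames: all discarded
        with pytest.raises(ValueError):
            freeze_summary(lab)


class TestDiscriminationIndex:
    @pytest.mark.parametrize("s,c,expected", [
        (30.0, 30.0, 0.0),
        (30.0, 0.0, 1.0),
        (47.8, 26.7, 0.2832),
    ])
    def test_values(self, s, c, expected):
        assert discrimination_index(s, c).di == pytest.approx(expected, abs=5e-5)

    def test_antisymmetric_and_bounded(self, rng):
        for _ in range(50):
            s, c = rng.uniform(0, 100, 2)
            if s + c == 0:
                continue
            di = discrimination_index(s, c).di
            assert -1.0 <= di <= 1.0
            assert di == pytest.approx(-discrimination_index(c, s).di)

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            discrimination_index(0.0, 0.0)


class TestShockAlignedVelocity:
    def test_constant_velocity_flat_zero_width(self):
        out = shock_aligned_velocity(np.full(500, 7.0), [100, 200, 300], RATE)
        assert np.allclose(out["mean"], 7.0)
        assert np.allclose(out["ci_high"] - out["ci_low"], 0.0)
        assert out["matrix"].shape[0] == 3

    def test_edge_onsets_dropped(self):
        out = shock_aligned_velocity(np.full(100, 1.0), [2, 50], RATE,
                                     pre_s=1.0, post_s=1.0)
        assert out["matrix"].shape[0] == 1

    def test_sprint_recovered_on_shock_day(self, shock_day_session):
        """Aligned mean velocity during the shock approaches the sprint
        factor times the pre-shock baseline."""
        tl = shock_day_session.timeline
        v = tl.velocity_cm_s.to_numpy()
        shock = tl.is_shock.to_numpy().astype(int)
        onsets = np.flatnonzero(np.diff(np.concatenate(([0], shock))) == 1)
        out = shock_aligned_velocity(v, onsets, RATE, pre_s=5.0, post_s=3.0)
        offsets = out["offsets_s"]
        in_shock = (offsets >= 0) & (offsets < 1.0)
        baseline_win = offsets < -2.0
        run_baseline = out["mean"][baseline_win]
        baseline = run_baseline[run_baseline > 1.0].mean()  # running frames only
        ratio = out["mean"][in_shock].mean() / baseline
        assert ratio > 2.5


class TestTraversals:
    def test_single_monotone_lap(self):
        pos = np.linspace(0, 199, 100)
        laps = split_traversals(pos, np.zeros(100, dtype=bool))
        assert len(laps) == 1
        assert (laps.start_frame[0], laps.end_frame[0]) == (0, 100)

    def test_lap_count_matches_teleports(self, tuned_session):
        tl = tuned_session.timeline
        tp = tl.is_teleport.to_numpy().astype(int)
        n_pauses = len(np.flatnonzero(np.diff(np.concatenate(([0], tp))) == 1))
        laps = tuned_session.laps
        assert len(laps) in (n_pauses, n_pauses + 1)

    def test_teleport_frames_belong_to_no_lap(self, tuned_session):
        tl = tuned_session.timeline
        tp = np.flatnonzero(tl.is_teleport.to_numpy())
        for row in tuned_session.laps.itertuples():
            assert not np.any((tp >= row.start_frame) & (tp < row.end_frame))


class TestPupilPreprocess:
    def test_no_blinks_equals_smoothed_input(self, tuned_session):
        raw, _ = generate_pupil(tuned_session.timeline, blink_rate_hz=0.0,
                                seed=3)
        from scipy.signal import savgol_filter
        out = pupil_preprocess(raw.area, raw.x_pos, raw.y_pos, raw.blink_area,
                               RATE)
        np.testing.assert_allclose(out["area"], savgol_filter(raw.area, 9, 3))

    def test_blink_frames_interpolated(self, tuned_session):
        raw, blink_frames = generate_pupil(tuned_session.timeline,
                                           blink_rate_hz=0.1, seed=3)
        out = pupil_preprocess(raw.area, raw.x_pos, raw.y_pos, raw.blink_area,
                               RATE)
        # the corrupted blink value (occluded pupil, area ~2) never survives
        assert np.all(out["area"].to_numpy()[blink_frames] > 10.0)

    def test_output_length_follows_target_rate(self, tuned_session):
        raw, _ = generate_pupil(tuned_session.timeline, seed=3)
        out = pupil_preprocess(raw.area, raw.x_pos, raw.y_pos, raw.blink_area,
                               RATE, target_rate=RATE / 2)
        assert len(out) == round(len(raw.area) / RATE * (RATE / 2))

    def test_all_blinked_rejected(self):
        n = 50
        with pytest.raises(ValueError):
            pupil_preprocess(np.ones(n), np.ones(n), np.ones(n), np.ones(n),
                             RATE, blink_mask=np.ones(n, dtype=bool))


def test_percent_increase_rejects_zero_reference():
    with pytest.raises(ValueError):
        percent_increase(1.0, 0.0)
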