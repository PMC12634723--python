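"""HSV conversion, colour thresholds, board observation and event machine."""

import colorsys

import numpy as np
import pytest

from mmdtkit import synth
from mmdtkit.vision import (
    PLACING,
    TURNING,
    BoardLayout,
    BoardState,
    advance_state,
    classify_hole_color,
    disc_timings,
    observe_board,
    rgb_to_hsv,
)


class TestRgbToHsv:
    @pytest.mark.parametrize("rgb,expected", [
        ((255, 0, 0), (0, 255, 255)),      # pure red
        ((255, 255, 255), (0, 0, 255)),    # achromatic white: hue defined 0
        ((0, 0, 0), (0, 0, 0)),
    ])
    def test_reference_pixels(self, rgb, expected):
        assert np.allclose(rgb_to_hsv(np.array(rgb, float)), expected)

    def test_matches_independent_reference_conversion(self):
        # colorsys is an independent straight-line implementation of the
        # standard formulas; rescale its output to the H/2, 255 S/V scale
        rng = np.random.default_rng(0)
        pixels = rng.integers(0, 256, size=(1000, 3))
        ours = rgb_to_hsv(pixels.astype(float))
        for (r, g, b), (h, s, v) in zip(pixels, ours):
            hr, sr, vr = colorsys.rgb_to_hsv(r / 255, g / 255, b / 255)
            ref = np.array([hr * 360 / 2, sr * 255, vr * 255])
            diff = np.abs(np.array([h, s, v]) - ref)
            diff[0] = min(diff[0], 180 - diff[0])  # hue wraps at 180
            assert np.all(diff <= 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            rgb_to_hsv(np.array([300.0, 0.0, 0.0]))


class TestClassifyHoleColor:
    @pytest.mark.parametrize("hsv,expected", [
        ((5, 200, 200), "red"),
        ((170, 150, 100), "red"),     # upper hue branch of red
        ((90, 10, 240), "white"),
        ((50, 128, 15), "black"),
        ((50, 60, 150), "unknown"),
    ])
    def test_threshold_ranges(self, hsv, expected):
        assert classify_hole_color(hsv) == expected

    def test_dark_red_pixels_classify_black(self):
        # the printed ranges overlap at low value; darkness takes precedence
        assert classify_hole_color((5, 200, 20)) == "black"


class TestObserveBoard:
    def test_empty_board_is_all_white(self, layout):
        img = np.full((480, 640, 3), 240, dtype=np.uint8)
        assert observe_board(img, layout) == ["white"] * 60

    def test_rendered_discs_detected_exactly(self, layout):
        sched = synth.SessionSchedule(
            phase=PLACING,
            disc_events=[(h, 0.1 * (i + 1)) for i, h in enumerate(range(0, 30, 2))],
            duration=4.0, seed=0)
        t, frame = list(synth.gen_board_frames(sched, layout, fps=1, seed=0))[-1]
        obs = observe_board(frame, layout)
        placed = set(range(0, 30, 2))
        for hole in layout.holes:
            assert obs[hole.id] == ("red" if hole.id in placed else "white")

    def test_gray_image_is_all_unknown(self, layout):
        img = np.full((480, 640, 3), 128, dtype=np.uint8)
        assert observe_board(img, layout) == ["unknown"] * 60

    def test_size_mismatch_rejected(self, layout):
        with pytest.raises(ValueError):
            observe_board(np.zeros((100, 100, 3), dtype=np.uint8), layout)


class TestAdvanceState:
    def test_placing_white_to_red_commits_after_debounce(self, layout):
        state = BoardState(layout, phase=PLACING, debounce=2)
        obs = ["white"] * 60
        obs[7] = "red"
        assert advance_state(state, obs, 1.0) == []       # first frame: pending
        events = advance_state(state, obs, 1.1)           # second frame: commit
        assert len(events) == 1
        ev = events[0]
        assert (ev.hole_id, ev.kind, ev.phase) == (7, "placed_correct", PLACING)
        assert ev.timestamp == 1.0                        # first-frame stamp
        assert state.placed == 1 and state.empty == 59

    def test_placing_black_means_upside_down(self, layout):
        state = BoardState(layout, phase=PLACING, debounce=1)
        obs = ["white"] * 60
        obs[3] = "black"
        (ev,) = advance_state(state, obs, 2.0)
        assert ev.kind == "placed_upside_down"

    def test_turning_transitions(self, layout):
        state = BoardState(layout, phase=TURNING, colors=["red"] * 60, debounce=1)
        obs = ["red"] * 60
        obs[0], obs[1] = "black", "white"
        events = advance_state(state, obs, 0.5)
        kinds = {ev.hole_id: ev.kind for ev in events}
        assert kinds == {0: "turned_correct", 1: "removed_incorrect"}

    def test_identical_observation_is_idempotent(self, layout):
        state = BoardState(layout, phase=PLACING)
        obs = ["white"] * 60
        for k in range(3):
            assert advance_state(state, obs, float(k)) == []
        assert state.events == []

    def test_unknown_never_triggers_events(self, layout):
        state = BoardState(layout, phase=PLACING, debounce=1)
        assert advance_state(state, ["unknown"] * 60, 0.0) == []
        assert state.colors == ["white"] * 60

    def test_count_conservation_under_random_observations(self, layout):
        rng = np.random.default_rng(4)
        state = BoardState(layout, phase=PLACING, debounce=2)
        for k in range(40):
            obs = list(rng.choice(["white", "red", "black", "unknown"], size=60))
            advance_state(state, obs, 0.1 * k)
            assert state.placed + state.empty == 60

    def test_flicker_shorter_than_debounce_ignored(self, layout):
        state = BoardState(layout, phase=PLACING, debounce=2)
        obs_red = ["white"] * 60
        obs_red[5] = "red"
        advance_state(state, obs_red, 0.0)
        advance_state(state, ["white"] * 60, 0.1)  # flicker back
        advance_state(state, ["white"] * 60, 0.2)
        assert state.events == []


class TestDiscTimings:
    def test_durations_relative_to_phase_start(self, layout):
        state = BoardState(layout, debounce=1)
        for hole, t in ((0, 2.0), (1, 3.2)):
            obs = ["white"] * 60
            obs[hole] = "red"
            advance_state(state, obs, t)
        durations, total = disc_timings(state.events, phase_start=0.9)
        assert durations == pytest.approx([1.1, 1.2])
        assert total == pytest.approx(2.3)

    def test_no_events(self):
        durations, total = disc_timings([], 0.0)
        assert durations == [] and total == 0.0

    def test_durations_sum_to_total(self, layout):
        sched = synth.SessionSchedule.generate(n_discs=15, seed=2, mean_gap=0.4)
        state = BoardState(layout)
        for t, frame in synth.gen_board_frames(sched, layout, seed=2):
            advance_state(state, observe_board(frame, layout), t)
        durations, total = disc_timings(state.events, 0.0)
        assert sum(durations) == pytest.approx(total)

    def test_unordered_events_rejected(self, layout):
        from mmdtkit.vision import DiscEvent
        events = [DiscEvent(0, 2.0, "placed_correct", PLACING),
                  DiscEvent(1, 1.0, "placed_correct", PLACING)]
        with pytest.raises(ValueError):
            disc_timings(events, 0.0)


class TestLayout:
    def test_default_grid_has_60_unique_in_bounds_centres(self, layout):
        assert layout.n_holes == 60
        assert len({(h.x, h.y) for h in layout.holes}) == 60

    def test_json_round_trip(self, tmp_path, layout):
        layout.to_json(tmp_path / "layout.json")
        back = BoardLayout.from_json(tmp_path / "layout.json")
        assert back.holes == layout.holes
        assert back.image_size == layout.image_size
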