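"""Simulator: layout generation, stepping, collision, visibility, sessions."""

import numpy as np
import pandas as pd
import pytest

from dodgegaze.constants import DEFAULT_SCREEN_MAP
from dodgegaze.environment import (
    DeadShipError, InvalidSpecError, Layout, ShipState, TrialSpec,
    check_collision, drift_push, enumerate_configurations, generate_layout,
    make_experiment_layouts, run_session, run_trial, step, visible_objects,
    DriftSection,
)
from dodgegaze.policies import constant_policy, null_policy


@pytest.mark.parametrize("length,difficulty,expected", [
    (9000, "easy", 12), (9000, "medium", 34), (9000, "hard", 68),
    (18000, "easy", 32), (18000, "medium", 84), (18000, "hard", 168),
])
def test_obstacle_counts_match_difficulty_table(length, difficulty, expected):
    lay = generate_layout(length, difficulty, seed=3)
    assert len(lay.obstacles) == expected


@pytest.mark.parametrize("difficulty,lo,hi", [("medium", 58, 62),
                                              ("hard", 116, 124)])
def test_midlength_obstacle_counts_in_range(difficulty, lo, hi):
    counts = {len(generate_layout(13500, difficulty, seed=s).obstacles)
              for s in range(5)}
    assert all(lo <= c <= hi for c in counts)


def test_unknown_length_difficulty_rejected():
    with pytest.raises(InvalidSpecError):
        generate_layout(9000, "impossible", seed=0)
    with pytest.raises(InvalidSpecError):
        generate_layout(7777, "easy", seed=0)
    with pytest.raises(InvalidSpecError):
        generate_layout(13500, "easy", seed=0)


def test_layout_generation_is_deterministic_and_in_bounds():
    a = generate_layout(9000, "medium", seed=11)
    b = generate_layout(9000, "medium", seed=11)
    assert a == b
    xs = np.array([o[0] for o in a.obstacles])
    ys = np.array([o[1] for o in a.obstacles])
    assert xs.min() >= 0 and xs.max() <= 720 - 36
    assert ys.min() >= 0 and ys.max() <= 9000 - 36
    spans = sorted(s.y_start for s in a.drift_sections)
    assert all(s2 - s1 >= 270 for s1, s2 in zip(spans, spans[1:]))
    assert all(s.span_px == 270 for s in a.drift_sections)


def test_layout_json_round_trip():
    lay = generate_layout(9000, "easy", seed=2)
    assert Layout.from_json(lay.to_json()) == lay


@pytest.mark.parametrize("experiment,expected", [(1, 36), (2, 30), (3, 36)])
def test_configuration_counts(experiment, expected):
    specs = enumerate_configurations(experiment)
    assert len(specs) == expected
    assert len(set(specs)) == expected


def test_experiment3_assignments_are_complementary():
    layouts = make_experiment_layouts(3, 0)
    specs = enumerate_configurations(3, layouts, 0)
    by_key = {}
    for s in specs:
        by_key.setdefault((s.layout_id, s.block), []).append(s)
    for (lay_id, block), pair in by_key.items():
        assert len(pair) == 2
        special = "off" if block == "normal" else block
        sets = [frozenset(i for i, t in enumerate(p.drift_type_per_section)
                          if t == special) for p in pair]
        assert sets[0].isdisjoint(sets[1])
        assert sets[0] | sets[1] == frozenset(range(8))
        assert all(len(s) == 4 for s in sets)


def test_step_free_fall_and_exact_key_step(empty_layout):
    spec = TrialSpec(empty_layout.id, 1, input_noise_sd=0)
    rng = np.random.default_rng(0)
    s0 = ShipState(x=342.0, y=600.0)
    s1 = step(s0, "none", spec, empty_layout, rng)
    assert (s1.x - s0.x, s1.y - s0.y) == (0.0, 6.0)
    s2 = step(s0, "right", spec, empty_layout, rng)
    assert s2.x - s0.x == 6.0
    s3 = step(s0, "left", spec, empty_layout, rng)
    assert s3.x - s0.x == -6.0


def test_step_noise_distribution_matches_normal(empty_layout):
    spec = TrialSpec(empty_layout.id, 1, input_noise_sd=6)
    rng = np.random.default_rng(42)
    s0 = ShipState(x=342.0, y=600.0)
    dx = np.array([step(s0, "right", spec, empty_layout, rng).x - s0.x
                   for _ in range(100_000)])
    assert dx.mean() == pytest.approx(6.0, abs=0.08)
    assert dx.std() == pytest.approx(6.0, abs=0.08)
    # negative tail draws are applied as-is
    assert (dx < 0).mean() == pytest.approx(0.1587, abs=0.01)


def test_drift_section_pushes_three_px():
    lay = Layout(id="d", length_px=9000, difficulty="easy", obstacles=(),
                 drift_sections=(DriftSection(y_start=1200, direction="right"),
                                 DriftSection(y_start=3000, direction="left")))
    spec = TrialSpec(lay.id, 1, drift_enabled=True)
    rng = np.random.default_rng(0)
    inside = ShipState(x=342.0, y=1194.0)        # falls to 1200, in section
    s = step(inside, "none", spec, lay, rng)
    assert s.x - inside.x == 3.0
    left = ShipState(x=342.0, y=2994.0)
    s = step(left, "none", spec, lay, rng)
    assert s.x - left.x == -3.0
    outside = ShipState(x=342.0, y=600.0)
    s = step(outside, "none", spec, lay, rng)
    assert s.x - outside.x == 0.0
    # disabled drift exerts nothing
    off = TrialSpec(lay.id, 1, drift_enabled=False)
    assert step(inside, "none", off, lay, rng).x == inside.x


def test_full_drift_traverse_accumulates_135_px():
    """Closed form: 270-px span at 6 px/frame = 45 frames x 3 px."""
    lay = Layout(id="d", length_px=9000, difficulty="easy", obstacles=(),
                 drift_sections=(DriftSection(y_start=1200, direction="right"),))
    spec = TrialSpec(lay.id, 1, drift_enabled=True)
    rng = np.random.default_rng(0)
    s = ShipState(x=342.0, y=0.0)
    while s.y < 2400:
        s = step(s, "none", spec, lay, rng)
    assert s.x - 342.0 == 135.0


def test_fake_and_off_sections_exert_no_force():
    lay = Layout(id="d", length_px=9000, difficulty="easy", obstacles=(),
                 drift_sections=(DriftSection(y_start=0, direction="right"),
                                 DriftSection(y_start=600, direction="right")))
    spec = TrialSpec(lay.id, 3, drift_enabled=True,
                     drift_type_per_section=("fake", "invisible"))
    assert drift_push(100.0, spec, lay) == 0.0       # fake: bar only
    assert drift_push(700.0, spec, lay) == 3.0       # invisible: force on


def test_stepping_dead_ship_raises(empty_layout):
    spec = TrialSpec(empty_layout.id, 1)
    dead = ShipState(x=0.0, y=0.0, alive=False)
    with pytest.raises(DeadShipError):
        step(dead, "none", spec, empty_layout, np.random.default_rng(0))


class TestCollision:
    def _lay(self, *obstacles):
        return Layout(id="c", length_px=9000, difficulty="easy",
                      obstacles=tuple(obstacles), drift_sections=())

    def test_disjoint_and_overlapping(self):
        lay = self._lay((200, 200))
        assert not check_collision(ShipState(x=100.0, y=100.0), lay)
        lay = self._lay((135, 135))
        assert check_collision(ShipState(x=100.0, y=100.0), lay)

    def test_walls(self):
        lay = self._lay()
        assert check_collision(ShipState(x=-1.0, y=100.0), lay)
        assert check_collision(ShipState(x=685.0, y=100.0), lay)
        assert not check_collision(ShipState(x=0.0, y=100.0), lay)
        assert not check_collision(ShipState(x=684.0, y=100.0), lay)

    def test_abutting_sprites_do_not_collide(self):
        lay = self._lay((136, 100))
        assert not check_collision(ShipState(x=100.0, y=100.0), lay)
        lay = self._lay((100, 136))
        assert not check_collision(ShipState(x=100.0, y=100.0), lay)

    def test_matches_rasterized_overlap_oracle(self):
        """Brute force: paint both half-open pixel boxes on a grid."""
        rng = np.random.default_rng(9)
        for _ in range(200):
            sx, sy = rng.integers(0, 650), rng.integers(0, 650)
            ox, oy = sx + rng.integers(-50, 50), sy + rng.integers(-50, 50)
            grid = np.zeros((760, 760), dtype=int)
            grid[sy:sy + 36, sx:sx + 36] += 1
            grid[max(oy, 0):oy + 36, max(ox, 0):ox + 36] += 1
            expected = bool((grid > 1).any()) or sx < 0 or sx + 36 > 720
            lay = self._lay((int(ox), int(oy)))
            got = check_collision(ShipState(x=float(sx), y=float(sy)), lay)
            assert got == expected


class TestVisibility:
    def test_object_below_within_visible_region(self):
        lay = Layout(id="v", length_px=9000, difficulty="easy",
                     obstacles=((342, 1000),), drift_sections=())
        state = ShipState(x=342.0, y=600.0)   # obstacle 400 px below ship
        scene = visible_objects(state, lay)
        assert scene.n_obstacles == 1
        sx, sy = scene.obstacles_screen[0]
        assert (sx, sy) == (954.0, 670.0)

    def test_object_below_occluder_not_counted(self):
        lay = Layout(id="v", length_px=9000, difficulty="easy",
                     obstacles=((342, 1500),), drift_sections=())
        state = ShipState(x=342.0, y=600.0)   # 900 px below: behind occluder
        assert visible_objects(state, lay).n_obstacles == 0

    def test_empty_layout(self, empty_layout):
        scene = visible_objects(ShipState(x=342.0, y=600.0), empty_layout)
        assert (scene.n_obstacles, scene.n_drift_sections) == (0, 0)
        assert scene.obstacles_screen == ()

    def test_onscreen_dwell_matches_closed_form(self):
        """A 36-px object crossing the 810-px window is on screen for
        (810 + 36)/6 − 1 = 140 frames (strict overlap at 6 px/frame),
        about 2.3–2.5 s at 60 FPS."""
        lay = Layout(id="v", length_px=18000, difficulty="easy",
                     obstacles=((342, 6000),), drift_sections=())
        visible = [visible_objects(ShipState(x=342.0, y=float(y)), lay).n_obstacles
                   for y in range(4002, 7002, 6)]
        assert sum(visible) == (810 + 36) // 6 - 1

    def test_invisible_drift_sections_still_counted(self):
        lay = Layout(id="v", length_px=9000, difficulty="easy", obstacles=(),
                     drift_sections=(DriftSection(y_start=700, direction="left"),))
        spec_inv = TrialSpec(lay.id, 3, drift_enabled=True,
                             drift_type_per_section=("invisible",))
        spec_off = TrialSpec(lay.id, 3, drift_enabled=True,
                             drift_type_per_section=("off",))
        state = ShipState(x=342.0, y=600.0)
        assert visible_objects(state, lay, spec=spec_inv).n_drift_sections == 1
        assert visible_objects(state, lay, spec=spec_off).n_drift_sections == 0


class TestTrialsAndSessions:
    def test_unobstructed_fall_completes_in_length_over_six_frames(
            self, empty_trial_log):
        assert empty_trial_log.outcome == "completed"
        assert empty_trial_log.n_control_frames == 9000 // 6
        frames = empty_trial_log.frames["frame"].to_numpy()
        assert np.array_equal(frames, np.arange(len(frames)))

    def test_wall_hugger_with_outward_drift_crashes(self):
        lay = Layout(id="w", length_px=9000, difficulty="easy", obstacles=(),
                     drift_sections=(DriftSection(y_start=300, direction="left"),))
        spec = TrialSpec(lay.id, 1, drift_enabled=True)
        log = run_trial(spec, lay, constant_policy("left"),
                        np.random.default_rng(0))
        assert log.outcome == "crashed"
        assert log.crash_frame is not None

    def test_trial_is_reproducible_from_seed(self, easy_layout):
        spec = TrialSpec(easy_layout.id, 1, input_noise_sd=6)
        logs = [run_trial(spec, easy_layout, constant_policy("right"),
                          np.random.default_rng(123)) for _ in range(2)]
        assert logs[0].outcome == logs[1].outcome
        pd.testing.assert_frame_equal(logs[0].frames, logs[1].frames)

    def test_session_completes_all_30_exp2_configurations(self):
        layouts = [Layout(id=f"e{i}", length_px=13500,
                          difficulty="medium" if i < 3 else "hard",
                          obstacles=(), drift_sections=())
                   for i in range(6)]
        specs = enumerate_configurations(2, layouts)
        logs = run_session(2, null_policy, np.random.default_rng(0),
                           layouts=layouts, specs=specs,
                           include_training=False)
        non_training = [l for l in logs if not l.spec.training]
        assert len(non_training) == 30
        assert all(l.outcome == "completed" for l in non_training)
        assert len({l.spec for l in non_training}) == 30

    def test_always_crashing_session_uses_three_attempts_each(self):
        # a wall of obstacles right below the control point kills every try
        wall = tuple((x, 300) for x in range(0, 720, 36))
        layouts = [Layout(id=f"c{i}", length_px=9000,
                          difficulty=["easy", "medium", "hard"][i % 3],
                          obstacles=wall, drift_sections=())
                   for i in range(6)]
        specs = enumerate_configurations(1, layouts)
        logs = run_session(1, null_policy, np.random.default_rng(1),
                           layouts=layouts, specs=specs,
                           include_training=False)
        assert len(logs) == 36 * 3
        assert all(l.outcome == "crashed" for l in logs)
        attempts = {}
        for l in logs:
            attempts[l.spec] = max(attempts.get(l.spec, 0), l.attempt_index)
        assert set(attempts.values()) == {3}

    def test_exp3_session_plays_normal_block_first(self):
        layouts = [Layout(id=f"x{i}", length_px=13500,
                          difficulty="medium" if i < 3 else "hard",
                          obstacles=(),
                          drift_sections=tuple(
                              DriftSection(y_start=400 + 1500 * k,
                                           direction="right" if k % 2
                                           else "left")
                              for k in range(8)))
                   for i in range(6)]
        specs = enumerate_configurations(3, layouts)
        logs = run_session(3, null_policy, np.random.default_rng(2),
                           layouts=layouts, specs=specs,
                           include_training=False, counterbalance=False)
        blocks = [l.spec.block for l in logs if not l.spec.training]
        first_normal = max(i for i, b in enumerate(blocks) if b == "normal")
        first_invisible = min(i for i, b in enumerate(blocks)
                              if b == "invisible")
        first_fake = min(i for i, b in enumerate(blocks) if b == "fake")
        assert first_normal < first_invisible < first_fake
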