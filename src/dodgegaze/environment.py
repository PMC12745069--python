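"""Frame-stepped simulator of the Dodge Asteroids environment.

A 36×36-px ship falls 6 px per frame through a 720-px-wide scrolling world
scattered with 36×36-px obstacles.  Key presses move the ship ±6 px
horizontally per frame; under *input noise* the keyed step is drawn from
``Normal(6, sd)``.  *Drift sections* are 270-px vertical spans that push the
ship 3 px per frame toward a fixed direction.  Three experiment designs are
enumerated: a 3 (noise sd 0/3/6) × 2 (drift on/off) design over six layouts
(36 configurations), a five-level noise design (30 configurations), and a
three-block drift-type design with complementary section assignments
(36 configurations).

All randomness flows through explicit ``numpy.random.Generator`` objects, so
every layout, trial and session is reproducible from its seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .constants import (
    DRIFT_BAR_OFFSET_PX,
    DRIFT_BAR_WIDTH_PX,
    DRIFT_PX_PER_FRAME,
    DRIFT_SPAN_PX,
    DEFAULT_SCREEN_MAP,
    ENV_WIDTH_PX,
    FALL_PX_PER_FRAME,
    KEY_STEP_PX,
    OBSTACLE_SIZE_PX,
    SHIP_SIZE_PX,
    ScreenMap,
    VALID_LENGTHS_PX,
)

__all__ = [
    "Layout",
    "DriftSection",
    "TrialSpec",
    "ShipState",
    "TrialLog",
    "InvalidSpecError",
    "DeadShipError",
    "AbortedTrialError",
    "OBSTACLE_COUNT_TABLE",
    "DRIFT_COUNT_TABLE",
    "generate_layout",
    "make_experiment_layouts",
    "enumerate_configurations",
    "step",
    "drift_push",
    "check_collision",
    "visible_objects",
    "run_trial",
    "run_session",
]


class InvalidSpecError(ValueError):
    """Unknown layout/difficulty combination or malformed trial spec."""


class DeadShipError(RuntimeError):
    """Attempted to step a ship that has already crashed."""


class AbortedTrialError(RuntimeError):
    """A policy raised during a trial; the trial is abandoned."""


# Obstacle counts by (length, difficulty).  Scalars are exact; 2-tuples are
# inclusive ranges sampled per layout.
OBSTACLE_COUNT_TABLE: dict[tuple[int, str], object] = {
    (9000, "easy"): 12,
    (9000, "medium"): 34,
    (9000, "hard"): 68,
    (18000, "easy"): 32,
    (18000, "medium"): 84,
    (18000, "hard"): 168,
    (13500, "medium"): (58, 62),
    (13500, "hard"): (116, 124),
}

# Default drift-section counts by (length, difficulty); 13,500-px layouts
# (experiments 2 and 3) use 8 fixed sections when drift is present.
DRIFT_COUNT_TABLE: dict[tuple[int, str], int] = {
    (9000, "easy"): 4,
    (9000, "medium"): 4,
    (9000, "hard"): 8,
    (18000, "easy"): 9,
    (18000, "medium"): 9,
    (18000, "hard"): 18,
    (13500, "medium"): 8,
    (13500, "hard"): 8,
}

NOISE_LEVELS = {1: (0, 3, 6), 2: (0, 3, 6, 9, 12), 3: (0,)}
BLOCKS = ("normal", "invisible", "fake")


@dataclass(frozen=True)
class DriftSection:
    y_start: int
    direction: str               # "left" | "right": direction of the push
    span_px: int = DRIFT_SPAN_PX
    bar_offset_px: int = DRIFT_BAR_OFFSET_PX
    bar_width_px: int = DRIFT_BAR_WIDTH_PX

    @property
    def y_end(self) -> int:
        return self.y_start + self.span_px


@dataclass(frozen=True)
class Layout:
    id: str
    length_px: int
    difficulty: str
    obstacles: tuple[tuple[int, int], ...]   # top-left corners
    drift_sections: tuple[DriftSection, ...]
    width_px: int = ENV_WIDTH_PX
    training: bool = False
    seed: Optional[int] = None

    def to_json(self) -> str:
        d = asdict(self)
        d["obstacles"] = [list(o) for o in self.obstacles]
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "Layout":
        d = json.loads(text)
        d["obstacles"] = tuple(tuple(o) for o in d["obstacles"])
        d["drift_sections"] = tuple(DriftSection(**s) for s in d["drift_sections"])
        return cls(**d)


@dataclass(frozen=True)
class TrialSpec:
    layout_id: str
    experiment: int
    input_noise_sd: float = 0.0
    drift_enabled: bool = False
    # experiment 3: section index -> "normal" | "invisible" | "fake" | "off"
    drift_type_per_section: Optional[tuple[str, ...]] = None
    block: str = "none"          # "normal" | "invisible" | "fake" | "none"
    training: bool = False
    # training trials switch their manipulation on only from this env y
    manipulation_from_y: float = 0.0

    def section_type(self, index: int) -> str:
        if not self.drift_enabled:
            return "off"
        if self.drift_type_per_section is None:
            return "normal"
        return self.drift_type_per_section[index]


@dataclass(frozen=True)
class ShipState:
    x: float
    y: float
    frame: int = 0
    alive: bool = True
    size_px: int = SHIP_SIZE_PX


@dataclass
class TrialLog:
    spec: TrialSpec
    layout_id: str
    frames: pd.DataFrame         # one row per frame, entry + control phase
    outcome: str                 # "completed" | "crashed"
    crash_frame: Optional[int]
    attempt_index: int = 1
    seed: Optional[int] = None

    @property
    def n_control_frames(self) -> int:
        return int((self.frames["phase"] == "control").sum())

    def control_frames(self) -> pd.DataFrame:
        df = self.frames[self.frames["phase"] == "control"].reset_index(drop=True)
        return df


# ---------------------------------------------------------------------------
# layout generation
# ---------------------------------------------------------------------------

def _obstacle_count(length_px: int, difficulty: str,
                    rng: np.random.Generator) -> int:
    key = (length_px, difficulty)
    if key not in OBSTACLE_COUNT_TABLE:
        raise InvalidSpecError(
            f"no obstacle-count entry for length={length_px}, "
            f"difficulty={difficulty!r}")
    entry = OBSTACLE_COUNT_TABLE[key]
    if isinstance(entry, tuple):
        lo, hi = entry
        return int(rng.integers(lo, hi + 1))
    return int(entry)


def _passable(obstacles: np.ndarray, width_px: int) -> bool:
    """True if every horizontal band has at least one ship-wide free column.

    Bands are delimited by obstacle y extents; within a band the set of
    blocking obstacles is constant, so it suffices to check that their
    blocked x-intervals do not cover all admissible ship x positions.
    """
    if len(obstacles) == 0:
        return True
    max_x = width_px - SHIP_SIZE_PX
    events = np.unique(np.concatenate([obstacles[:, 1],
                                       obstacles[:, 1] + OBSTACLE_SIZE_PX]))
    for y0, y1 in zip(events[:-1], events[1:]):
        mid = (y0 + y1) / 2
        active = obstacles[(obstacles[:, 1] < mid)
                           & (obstacles[:, 1] + OBSTACLE_SIZE_PX > mid)]
        if len(active) == 0:
            continue
        # ship box [x, x+36) overlaps obstacle [ox, ox+36) iff ox-35 <= x <= ox+35
        blocked = sorted((max(0, ox - SHIP_SIZE_PX + 1),
                          min(max_x, ox + OBSTACLE_SIZE_PX - 1))
                         for ox in active[:, 0])
        cursor = 0
        covered = True
        for lo, hi in blocked:
            if lo > cursor:
                covered = False
                break
            cursor = max(cursor, hi + 1)
        if covered and cursor <= max_x:
            covered = False
        if covered:
            return False
    return True


def _sample_drift_sections(n: int, length_px: int,
                           rng: np.random.Generator) -> tuple[DriftSection, ...]:
    """Place n non-overlapping 270-px sections uniformly in y (rejection)."""
    if n == 0:
        return ()
    if n * DRIFT_SPAN_PX > length_px:
        raise InvalidSpecError(
            f"cannot place {n} non-overlapping drift sections in "
            f"{length_px} px")
    for _ in range(10_000):
        starts = np.sort(rng.integers(0, length_px - DRIFT_SPAN_PX + 1, size=n))
        if np.all(np.diff(starts) >= DRIFT_SPAN_PX):
            dirs = rng.choice(["left", "right"], size=n)
            return tuple(DriftSection(int(s), str(d))
                         for s, d in zip(starts, dirs))
    # fall back to evenly spaced starts with random jitter-free directions
    gap = (length_px - n * DRIFT_SPAN_PX) // (n + 1)
    starts = [gap * (i + 1) + DRIFT_SPAN_PX * i for i in range(n)]
    dirs = rng.choice(["left", "right"], size=n)
    return tuple(DriftSection(int(s), str(d)) for s, d in zip(starts, dirs))


def generate_layout(length_px: int, difficulty: str,
                    n_drift_sections: Optional[int] = None,
                    seed: int = 0, *, layout_id: Optional[str] = None,
                    training: bool = False) -> Layout:
    """Generate a random layout with the difficulty table's obstacle count.

    Obstacle corners are sampled i.i.d. uniform over the admissible
    rectangle.  Layouts where some horizontal band is fully blocked (no
    ship-wide collision-free column) are rejected and resampled with an
    incremented seed so every layout is in principle completable.
    """
    if length_px not in VALID_LENGTHS_PX:
        raise InvalidSpecError(f"invalid layout length {length_px}")
    if (length_px, difficulty) not in OBSTACLE_COUNT_TABLE:
        raise InvalidSpecError(
            f"no difficulty entry for length={length_px}, "
            f"difficulty={difficulty!r}")
    if n_drift_sections is None:
        n_drift_sections = DRIFT_COUNT_TABLE[(length_px, difficulty)]
    attempt_seed = seed
    for _ in range(1000):
        rng = np.random.default_rng(attempt_seed)
        n_obs = _obstacle_count(length_px, difficulty, rng)
        xs = rng.integers(0, ENV_WIDTH_PX - OBSTACLE_SIZE_PX + 1, size=n_obs)
        ys = rng.integers(0, length_px - OBSTACLE_SIZE_PX + 1, size=n_obs)
        obstacles = np.column_stack([xs, ys])
        if _passable(obstacles, ENV_WIDTH_PX):
            sections = _sample_drift_sections(n_drift_sections, length_px, rng)
            return Layout(
                id=layout_id or f"L{length_px}-{difficulty}-s{seed}",
                length_px=length_px, difficulty=difficulty,
                obstacles=tuple((int(x), int(y)) for x, y in obstacles),
                drift_sections=sections, training=training, seed=seed)
        attempt_seed += 1
    raise RuntimeError("layout rejection sampling failed to terminate")


def make_experiment_layouts(experiment: int, seed: int = 0) -> list[Layout]:
    """The six layouts of an experiment, generated deterministically."""
    layouts: list[Layout] = []
    if experiment == 1:
        combos = [(9000, d) for d in ("easy", "medium", "hard")] + \
                 [(18000, d) for d in ("easy", "medium", "hard")]
    elif experiment in (2, 3):
        combos = [(13500, "medium")] * 3 + [(13500, "hard")] * 3
    else:
        raise InvalidSpecError(f"unknown experiment {experiment}")
    for i, (length, diff) in enumerate(combos):
        layouts.append(generate_layout(
            length, diff, seed=seed * 101 + i,
            layout_id=f"E{experiment}-{i}-{length}-{diff}"))
    return layouts


def enumerate_configurations(experiment: int,
                             layouts: Optional[Sequence[Layout]] = None,
                             seed: int = 0) -> list[TrialSpec]:
    """All trial configurations of an experiment design.

    Experiment 1: 6 layouts × noise sd {0,3,6} × drift on/off  → 36.
    Experiment 2: 6 layouts × noise sd {0,3,6,9,12}, no drift  → 30.
    Experiment 3: 6 layouts × 3 blocks × 2 complementary assignments of the
    block's special drift type to half of the 8 sections       → 36.
    """
    if layouts is None:
        layouts = make_experiment_layouts(experiment, seed)
    specs: list[TrialSpec] = []
    if experiment == 1:
        for lay in layouts:
            for sd in NOISE_LEVELS[1]:
                for drift in (False, True):
                    specs.append(TrialSpec(lay.id, 1, input_noise_sd=sd,
                                           drift_enabled=drift))
    elif experiment == 2:
        for lay in layouts:
            for sd in NOISE_LEVELS[2]:
                specs.append(TrialSpec(lay.id, 2, input_noise_sd=sd))
    elif experiment == 3:
        rng = np.random.default_rng(seed + 7919)
        for lay in layouts:
            n_sec = len(lay.drift_sections)
            special = rng.choice(n_sec, size=n_sec // 2, replace=False)
            mask = np.zeros(n_sec, dtype=bool)
            mask[special] = True
            for block in BLOCKS:
                # in the normal block the special half carries no drift
                special_type = "off" if block == "normal" else block
                for flip in (False, True):
                    types = tuple(special_type if (m ^ flip) else "normal"
                                  for m in mask)
                    specs.append(TrialSpec(lay.id, 3, drift_enabled=True,
                                           drift_type_per_section=types,
                                           block=block))
    else:
        raise InvalidSpecError(f"unknown experiment {experiment}")
    assert len(set(specs)) == len(specs)
    return specs


# ---------------------------------------------------------------------------
# stepping
# ---------------------------------------------------------------------------

def _obstacles_by_y(layout: Layout) -> tuple[np.ndarray, np.ndarray]:
    """Obstacle coordinates sorted by y for windowed range queries.

    Cached lazily on the (frozen) layout instance; the cache is an
    implementation detail invisible to equality, repr and serialization.
    """
    cached = layout.__dict__.get("_obs_index")
    if cached is not None:
        return cached
    if not layout.obstacles:
        out = (np.empty(0), np.empty(0))
    else:
        arr = np.asarray(layout.obstacles, dtype=float)
        order = np.argsort(arr[:, 1])
        out = (arr[order, 0].copy(), arr[order, 1].copy())
    object.__setattr__(layout, "_obs_index", out)
    return out


def obstacles_in_y_window(layout: Layout, y_lo: float, y_hi: float
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Obstacles whose top-left y lies in [y_lo, y_hi)."""
    xs, ys = _obstacles_by_y(layout)
    i = np.searchsorted(ys, y_lo, side="left")
    j = np.searchsorted(ys, y_hi, side="left")
    return xs[i:j], ys[i:j]

def drift_push(y: float, spec: TrialSpec, layout: Layout) -> float:
    """Signed lateral push (px) acting on a ship whose top edge is at y.

    The ship is inside a section while its top edge lies within
    [y_start, y_start + 270); a full uncontrolled traverse therefore spans
    exactly 270/6 = 45 frames and accumulates 135 px.  Only "normal" and
    "invisible" section types exert force; "fake" and "off" do not.
    """
    if not spec.drift_enabled or y < spec.manipulation_from_y:
        return 0.0
    for idx, sec in enumerate(layout.drift_sections):
        if sec.y_start <= y < sec.y_end:
            if spec.section_type(idx) in ("normal", "invisible"):
                return (DRIFT_PX_PER_FRAME if sec.direction == "right"
                        else -DRIFT_PX_PER_FRAME)
            return 0.0
    return 0.0


def step(state: ShipState, key: str, spec: TrialSpec, layout: Layout,
         rng: np.random.Generator) -> ShipState:
    """Advance the ship one frame.

    Vertical: always +6 px.  Horizontal: a keyed step of exactly ±6 px at
    zero noise, otherwise a signed draw from Normal(6, sd) applied in the
    keyed direction (negative tail draws move against it); plus ±3 px while
    inside an active drift section.  Walls are not clamped — collision is
    the caller's check.
    """
    if not state.alive:
        raise DeadShipError("cannot step a crashed ship")
    y_new = state.y + FALL_PX_PER_FRAME
    dx = 0.0
    if key in ("left", "right"):
        sd = spec.input_noise_sd if state.y >= spec.manipulation_from_y else 0.0
        mag = float(KEY_STEP_PX) if sd == 0 else float(rng.normal(KEY_STEP_PX, sd))
        dx += mag if key == "right" else -mag
    elif key != "none":
        raise InvalidSpecError(f"unknown key {key!r}")
    dx += drift_push(y_new, spec, layout)
    return ShipState(x=state.x + dx, y=y_new, frame=state.frame + 1)


def check_collision(state: ShipState, layout: Layout) -> bool:
    """True iff the ship overlaps an obstacle or touches a wall.

    Boxes are half-open pixel intervals [x, x+36), so sprites that merely
    abut do not collide.
    """
    if state.x < 0 or state.x + SHIP_SIZE_PX > layout.width_px:
        return True
    s = OBSTACLE_SIZE_PX
    xs, _ = obstacles_in_y_window(layout, state.y - s + 1e-9,
                                  state.y + SHIP_SIZE_PX)
    return bool(np.any((state.x < xs + s) & (xs < state.x + SHIP_SIZE_PX)))


@dataclass(frozen=True)
class VisibleScene:
    n_obstacles: int
    n_drift_sections: int
    obstacles_screen: tuple[tuple[float, float], ...]   # top-left, screen px


def visible_objects(state: ShipState, layout: Layout,
                    screen_map: ScreenMap = DEFAULT_SCREEN_MAP,
                    spec: Optional[TrialSpec] = None,
                    count_hidden_sections: bool = True) -> VisibleScene:
    """Objects whose box intersects the visible region (top 810 screen px).

    Drift sections are counted through their bar rectangle's y-span whether
    or not the bar is actually drawn (invisible sections still count; the
    covariate is defined by the environment, not the display).  Pass
    ``count_hidden_sections=False`` to count only sections whose bar is
    displayed (fake included, invisible excluded) instead.
    """
    vis_h = screen_map.visible_height
    # candidate window in env y (screen x is never the binding constraint
    # for a 720-px-wide world on a 1920-px screen)
    y_lo = state.y - screen_map.ship_screen_y - OBSTACLE_SIZE_PX
    y_hi = state.y + (vis_h - screen_map.ship_screen_y)
    xs, ys = obstacles_in_y_window(layout, y_lo, y_hi)
    obs_on = []
    for ox, oy in zip(xs, ys):
        sx, sy = screen_map.env_to_screen(ox, oy, state.x, state.y)
        if (sy + OBSTACLE_SIZE_PX > 0 and sy < vis_h
                and sx + OBSTACLE_SIZE_PX > 0 and sx < screen_map.screen_w):
            obs_on.append((float(sx), float(sy)))
    n_drift = 0
    for idx, sec in enumerate(layout.drift_sections):
        if spec is not None:
            kind = spec.section_type(idx)
            if kind == "off":
                continue
            if not count_hidden_sections and kind == "invisible":
                continue
        sy_top = screen_map.ship_screen_y + (sec.y_start - state.y)
        sy_bot = sy_top + sec.span_px
        if sy_bot > 0 and sy_top < vis_h:
            n_drift += 1
    return VisibleScene(len(obs_on), n_drift, tuple(obs_on))


# ---------------------------------------------------------------------------
# trials and sessions
# ---------------------------------------------------------------------------

ENTRY_START_Y = -float(DEFAULT_SCREEN_MAP.ship_screen_y)   # top of screen


def _scene_counts(state_y: float, layout: Layout, spec: Optional[TrialSpec],
                  screen_map: ScreenMap) -> tuple[int, int]:
    """On-screen object counts only (same counting rule as visible_objects,
    without materializing screen coordinates; x never binds for a 720-px
    world on a 1920-px screen)."""
    vis_h = screen_map.visible_height
    _, ys = _obstacles_by_y(layout)
    y_lo = state_y - screen_map.ship_screen_y - OBSTACLE_SIZE_PX
    y_hi = state_y + (vis_h - screen_map.ship_screen_y)
    n_obs = int(np.searchsorted(ys, y_hi, side="left")
                - np.searchsorted(ys, y_lo, side="right"))
    n_drift = 0
    for idx, sec in enumerate(layout.drift_sections):
        if spec is not None and spec.section_type(idx) == "off":
            continue
        sy_top = screen_map.ship_screen_y + (sec.y_start - state_y)
        if sy_top + sec.span_px > 0 and sy_top < vis_h:
            n_drift += 1
    return n_obs, n_drift

Policy = Callable[..., str]


def run_trial(spec: TrialSpec, layout: Layout, policy: Policy,
              rng: np.random.Generator,
              screen_map: ScreenMap = DEFAULT_SCREEN_MAP,
              attempt_index: int = 1, seed: Optional[int] = None) -> TrialLog:
    """Play one trial to completion or crash.

    The ship flies in from the top of the screen at 6 px/frame (entry
    phase, no control, no collision) and becomes controllable when it
    reaches the fixed screen position; from there the policy chooses a key
    each frame until the ship crosses the finish line or crashes.
    """
    reset = getattr(policy, "reset", None)
    if reset is not None:
        reset()
    start_x = float((layout.width_px - SHIP_SIZE_PX) // 2)
    rows: list[tuple] = []
    frame = 0
    # entry phase: screen top down to the control point (env y = 0)
    y = ENTRY_START_Y
    while y < 0:
        rows.append((frame, "entry", start_x, y, "none", 0.0, False, 0, 0))
        y += FALL_PX_PER_FRAME
        frame += 1
    state = ShipState(x=start_x, y=0.0, frame=frame)
    outcome, crash_frame = "completed", None
    while True:
        n_obs, n_drift = _scene_counts(state.y, layout, spec, screen_map)
        if check_collision(state, layout):
            rows.append((state.frame, "control", state.x, state.y, "none",
                         0.0, False, n_obs, n_drift))
            outcome, crash_frame = "crashed", state.frame
            break
        if state.y >= layout.length_px:
            break
        try:
            key = policy(state=state, scene=None, layout=layout,
                         spec=spec, rng=rng)
        except Exception as exc:       # noqa: BLE001 - report, do not mask
            raise AbortedTrialError(f"policy failed at frame {state.frame}") \
                from exc
        new_state = step(state, key, spec, layout, rng)
        drift_active = drift_push(new_state.y, spec, layout) != 0.0
        rows.append((state.frame, "control", state.x, state.y, key,
                     new_state.x - state.x, drift_active, n_obs, n_drift))
        state = new_state
    frames = pd.DataFrame(rows, columns=[
        "frame", "phase", "x", "y", "key", "dx", "drift_active",
        "n_obstacles_on_screen", "n_drift_sections_on_screen"])
    return TrialLog(spec=spec, layout_id=layout.id, frames=frames,
                    outcome=outcome, crash_frame=crash_frame,
                    attempt_index=attempt_index, seed=seed)


def make_training_spec(experiment: int, layout: Layout) -> TrialSpec:
    """Training configuration: easy 18,000-px layout, manipulation from
    halfway (noise sd 3 in experiments 1–2, drift in experiments 1 and 3)."""
    halfway = layout.length_px / 2
    if experiment == 1:
        return TrialSpec(layout.id, 1, input_noise_sd=3.0, drift_enabled=True,
                         training=True, manipulation_from_y=halfway)
    if experiment == 2:
        return TrialSpec(layout.id, 2, input_noise_sd=3.0,
                         training=True, manipulation_from_y=halfway)
    return TrialSpec(layout.id, 3, drift_enabled=True, training=True,
                     manipulation_from_y=halfway)


def run_session(experiment: int, policy: Policy, rng: np.random.Generator,
                layouts: Optional[Sequence[Layout]] = None,
                specs: Optional[Sequence[TrialSpec]] = None,
                layout_seed: int = 0, counterbalance: bool = False,
                include_training: bool = True,
                max_attempts: int = 3) -> list[TrialLog]:
    """Play a full session: randomized configuration order with requeueing.

    A completed configuration leaves the pool; a crashed one is mixed back
    in until it has crashed ``max_attempts`` times.  In experiment 3 the
    normal block always comes first and the invisible/fake order follows the
    counterbalance flag, with a normal-drift baseline configuration between
    blocks.
    """
    if layouts is None:
        layouts = make_experiment_layouts(experiment, layout_seed)
    if specs is None:
        specs = enumerate_configurations(experiment, layouts, layout_seed)
    lay_by_id = {l.id: l for l in layouts}
    logs: list[TrialLog] = []

    def play_pool(pool: list[TrialSpec]) -> None:
        attempts: dict[TrialSpec, int] = {s: 0 for s in pool}
        pool = list(pool)
        while pool:
            i = int(rng.integers(len(pool)))
            sp = pool[i]
            attempts[sp] += 1
            log = run_trial(sp, lay_by_id[sp.layout_id], policy, rng,
                            attempt_index=attempts[sp])
            logs.append(log)
            if log.outcome == "completed" or attempts[sp] >= max_attempts:
                pool.pop(i)

    def play_training() -> None:
        lay = generate_layout(18000, "easy",
                              seed=layout_seed * 9973 + 11,
                              layout_id=f"E{experiment}-training",
                              training=True)
        lay_by_id[lay.id] = lay
        sp = make_training_spec(experiment, lay)
        for attempt in range(1, max_attempts + 1):
            log = run_trial(sp, lay, policy, rng, attempt_index=attempt)
            logs.append(log)
            if log.outcome == "completed":
                break

    if include_training:
        play_training()
    if experiment in (1, 2):
        play_pool(list(specs))
    else:
        order = ["normal"] + (["fake", "invisible"] if counterbalance
                              else ["invisible", "fake"])
        for j, block in enumerate(order):
            if j > 0 and include_training:
                # baseline configuration with normal drift between blocks
                lay = layouts[0]
                base = TrialSpec(lay.id, 3, drift_enabled=True,
                                 training=True, block="normal")
                logs.append(run_trial(base, lay, policy, rng))
            play_pool([s for s in specs if s.block == block])
    return logs
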