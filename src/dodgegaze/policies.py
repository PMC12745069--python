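"""Scripted controllers that play trials.

These policies exist so that every downstream stage (gaze synthesis, event
detection, modeling) has trial streams to work on without human data.  They
are deliberately simple: the point is that completion probability responds
to input noise and drift, not that they resemble human play.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

from .constants import OBSTACLE_SIZE_PX, SHIP_SIZE_PX

__all__ = ["PolicyParams", "null_policy", "constant_policy",
           "GreedyGapPolicy", "get_policy"]


@dataclass(frozen=True)
class PolicyParams:
    lookahead_px: float = 400.0      # how far below the ship obstacles matter
    skill: float = 0.9               # per-frame probability of acting on plan
    reaction_lag_frames: int = 0
    edge_margin_px: float = 12.0     # aimed clearance from an obstacle edge

    def __post_init__(self):
        if not 0.0 <= self.skill <= 1.0:
            raise ValueError("skill must be in [0, 1]")
        if self.lookahead_px > 810:
            raise ValueError("lookahead exceeds the visible height")


def null_policy(**_kw) -> str:
    return "none"


def constant_policy(key: str):
    """Always press one key (e.g. a wall-hugger used to force crashes)."""
    def policy(**_kw) -> str:
        return key
    return policy


class GreedyGapPolicy:
    """Steer toward the widest collision-free horizontal gap ahead.

    Obstacles within ``lookahead_px`` below the ship block x-intervals; if
    the ship's current column is clear the policy rests, otherwise it moves
    toward the center of the widest free gap.  With probability
    ``1 - skill`` it emits "none" regardless (lapses), and the planned key
    stream can be delayed by a fixed reaction lag.
    """

    def __init__(self, params: PolicyParams = PolicyParams()):
        self.params = params
        self._queue: deque[str] = deque()

    def reset(self) -> None:
        self._queue.clear()

    @staticmethod
    def _gaps(blocked: list[tuple[float, float]], max_x: float
              ) -> list[tuple[float, float]]:
        merged: list[list[float]] = []
        for lo, hi in sorted(blocked):
            if merged and lo <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], hi)
            else:
                merged.append([lo, hi])
        gaps: list[tuple[float, float]] = []
        cursor = 0.0
        for lo, hi in merged:
            if lo > cursor:
                gaps.append((cursor, lo - 1))
            cursor = hi + 1
        if cursor <= max_x:
            gaps.append((cursor, float(max_x)))
        return gaps

    def _plan(self, state, layout) -> str:
        from .environment import obstacles_in_y_window
        look = self.params.lookahead_px
        max_x = layout.width_px - SHIP_SIZE_PX
        xs, ys = obstacles_in_y_window(layout,
                                       state.y - OBSTACLE_SIZE_PX + 1e-9,
                                       state.y + look + 1e-9)
        if len(xs) == 0:
            return "none"
        # plan against the nearest obstacle band only; farther bands become
        # nearest as the ship descends, so they are handled sequentially and
        # the ship never steers across a column it is about to fall into
        band_y = float(ys.min())
        band = xs[ys < band_y + 120.0]
        blocked = [(max(0.0, ox - SHIP_SIZE_PX + 1),
                    min(float(max_x), ox + OBSTACLE_SIZE_PX - 1))
                   for ox in band]
        gaps = self._gaps(blocked, float(max_x))
        if not gaps:
            return "none"
        in_blocked = any(lo <= state.x <= hi for lo, hi in blocked)
        widest = max(gaps, key=lambda g: (g[1] - g[0],
                                          -abs((g[0] + g[1]) / 2 - state.x)))
        target_gap = widest
        # crossing another blocked column to reach the widest gap is fatal
        # when the band is nearly upon the ship: settle for the nearest gap
        if in_blocked and band_y - state.y < 150.0:
            target_gap = min(gaps, key=lambda g: min(abs(g[0] - state.x),
                                                     abs(g[1] - state.x)))
        elif not in_blocked:
            # already in a gap: hold station at its center rather than
            # crossing to the widest one
            target_gap = min(gaps, key=lambda g: (not g[0] <= state.x <= g[1],
                                                  min(abs(g[0] - state.x),
                                                      abs(g[1] - state.x))))
        # aim for the nearest point comfortably inside the gap rather than
        # its center: minimal travel, like a human cutting the corner, at
        # the price that placement precision — and with it the input-noise
        # level — decides whether the pass succeeds
        lo, hi = target_gap
        margin = self.params.edge_margin_px
        if hi - lo <= 2 * margin:
            target = (lo + hi) / 2
        else:
            target = min(max(state.x, lo + margin), hi - margin)
        if abs(target - state.x) <= 6:
            return "none"
        return "right" if target > state.x else "left"

    def __call__(self, state=None, scene=None, layout=None, spec=None,
                 rng: np.random.Generator = None, **_kw) -> str:
        planned = self._plan(state, layout)
        if planned == "none" and spec is not None:
            # lean against an active drift push about half the time, which
            # cancels the push in expectation (6-px key vs 3-px drift)
            from .environment import drift_push
            push = drift_push(state.y + 6, spec, layout)
            if push != 0.0 and rng is not None and rng.random() < 0.5:
                planned = "left" if push > 0 else "right"
        if rng is not None and self.params.skill < 1.0 \
                and rng.random() > self.params.skill:
            planned = "none"
        if self.params.reaction_lag_frames > 0:
            self._queue.append(planned)
            if len(self._queue) <= self.params.reaction_lag_frames:
                return "none"
            return self._queue.popleft()
        return planned


def get_policy(name: str, params: PolicyParams | None = None):
    """Look a policy up by the name used in session configs."""
    if name == "null":
        return null_policy
    if name in ("left", "right"):
        return constant_policy(name)
    if name == "greedy_gap":
        return GreedyGapPolicy(params or PolicyParams())
    raise ValueError(f"unknown policy {name!r}")
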