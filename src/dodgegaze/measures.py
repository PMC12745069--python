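"""Per-fixation distance measures and per-trial covariates.

A fixation contributes one row with its distance to the ship center and to
the center of the closest on-screen obstacle (both in degrees of visual
angle, both taken at the fixation's onset frame) plus the visual-scene
covariates of that frame.  A trial contributes one row with its outcome,
manipulation levels, fixation count and the running count of consecutive
crash→completion pairs in the participant's prior history.

Fixations that begin during the automatic entry phase or after the crash
frame are excluded; training trials never enter the tables.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .constants import DEFAULT_SCREEN_MAP, OBSTACLE_SIZE_PX, ScreenMap
from .environment import ShipState, TrialLog, visible_objects
from .events import FixationEvent, assign_onset_frame, px_to_deg

__all__ = ["distance_to_ship", "distance_to_closest_obstacle",
           "consecutive_crash_completions", "build_tables", "JoinError"]


class JoinError(ValueError):
    """Inputs could not be aligned; offending ids are listed."""


def distance_to_ship(onset_x: float, onset_y: float,
                     screen_map: ScreenMap = DEFAULT_SCREEN_MAP) -> float:
    """Euclidean distance (degrees) from a fixation onset point to the
    on-screen ship center."""
    cx, cy = screen_map.ship_center
    return px_to_deg(float(np.hypot(onset_x - cx, onset_y - cy)))


def distance_to_closest_obstacle(onset_x: float, onset_y: float,
                                 obstacles_screen: Sequence[tuple[float, float]]
                                 ) -> float:
    """Distance (degrees) to the nearest on-screen obstacle center, or NaN
    when no obstacle is on screen (the row is then excluded from models of
    this measure)."""
    if len(obstacles_screen) == 0:
        return float("nan")
    h = OBSTACLE_SIZE_PX / 2
    dists = [np.hypot(onset_x - (ox + h), onset_y - (oy + h))
             for ox, oy in obstacles_screen]
    return px_to_deg(float(min(dists)))


def consecutive_crash_completions(prior_outcomes: Sequence[str]) -> int:
    """Count of (crash at i, completion at i+1) pairs in the strictly
    prior attempt history."""
    count = 0
    for a, b in zip(prior_outcomes[:-1], prior_outcomes[1:]):
        if a == "crashed" and b == "completed":
            count += 1
    return count


def _fixation_rows(participant: int, trial_idx: int, log: TrialLog,
                   fixations: Sequence[FixationEvent],
                   layouts_by_id: dict,
                   screen_map: ScreenMap) -> list[dict]:
    ctrl = log.control_frames()
    n_frames = len(ctrl)
    spec = log.spec
    layout = layouts_by_id[log.layout_id]
    rows = []
    for k, fix in enumerate(fixations):
        try:
            frame = assign_onset_frame(fix.onset_t, n_frames)
        except Exception:
            continue                      # outside the control phase
        if log.crash_frame is not None:
            crash_ctrl = log.crash_frame - (len(log.frames) - n_frames)
            if frame > crash_ctrl:
                continue
        frow = ctrl.iloc[frame]
        state = ShipState(x=float(frow["x"]), y=float(frow["y"]),
                          frame=int(frow["frame"]))
        scene = visible_objects(state, layout, screen_map, spec)
        rows.append(dict(
            participant=participant, trial=trial_idx, fixation=k,
            onset_t=fix.onset_t, onset_frame=frame,
            onset_x=fix.onset_x, onset_y=fix.onset_y,
            dist_to_ship_deg=distance_to_ship(fix.onset_x, fix.onset_y,
                                              screen_map),
            dist_to_closest_obstacle_deg=distance_to_closest_obstacle(
                fix.onset_x, fix.onset_y, scene.obstacles_screen),
            n_obstacles_on_screen=int(frow["n_obstacles_on_screen"]),
            n_drift_sections_on_screen=int(frow["n_drift_sections_on_screen"]),
            noise_level=spec.input_noise_sd,
            drift_enabled=spec.drift_enabled,
            block=spec.block,
            difficulty=layout.difficulty,
        ))
    return rows


def build_tables(sessions: dict[int, Sequence[TrialLog]],
                 events: dict[tuple[int, int], Sequence[FixationEvent]],
                 layouts: Sequence,
                 joc: Optional[dict[tuple[int, int], int]] = None,
                 screen_map: ScreenMap = DEFAULT_SCREEN_MAP
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the fixation and trial tables from sessions and detected
    events.

    ``sessions`` maps participant → ordered trial logs; ``events`` maps
    (participant, trial index) → that trial's detected fixations.  Training
    trials are dropped.  Unknown (participant, trial) keys in ``events``
    raise a JoinError listing the offenders.
    """
    layouts_by_id = {l.id: l for l in layouts}
    known = {(p, i) for p, logs in sessions.items() for i in range(len(logs))}
    orphans = sorted(set(events) - known)
    if orphans:
        raise JoinError(f"events reference unknown trials: {orphans[:10]}")
    fix_rows: list[dict] = []
    trial_rows: list[dict] = []
    for p, logs in sessions.items():
        outcome_history: list[str] = []
        for i, log in enumerate(logs):
            if log.spec.training or log.layout_id not in layouts_by_id:
                if not log.spec.training:
                    raise JoinError(f"unknown layout {log.layout_id}")
                outcome_history.append(log.outcome)
                continue
            fixations = list(events.get((p, i), ()))
            rows = _fixation_rows(p, i, log, fixations, layouts_by_id,
                                  screen_map)
            fix_rows.extend(rows)
            trial_rows.append(dict(
                participant=p, trial=i,
                completion=log.outcome == "completed",
                outcome=log.outcome,
                attempt_index=log.attempt_index,
                difficulty=layouts_by_id[log.layout_id].difficulty,
                noise_level=log.spec.input_noise_sd,
                drift_enabled=log.spec.drift_enabled,
                block=log.spec.block,
                n_fixations=len(rows),
                consecutive_crash_completions=consecutive_crash_completions(
                    outcome_history),
                joc=joc.get((p, i)) if joc else None,
            ))
            outcome_history.append(log.outcome)
    fix_df = pd.DataFrame(fix_rows)
    trial_df = pd.DataFrame(trial_rows)
    return fix_df, trial_df
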