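"""Synthetic binocular 2000-Hz gaze aligned to simulated trials.

Each trial's gaze is an alternating sequence of fixations and saccades.
A fixation's onset point lies at a distance from the on-screen ship center
drawn from a two-component (Close/Distant) mixture; the component means
shift linearly with the on-screen covariates of the onset frame (number of
obstacles, number of drift sections), with the trial's manipulation level
(noise sd or drift-type block), and with a per-participant random
intercept.  Within a fixation the fixated environment point scrolls with
the world (0.18 px per sample, far below the 1.25-px annotation bound) and
both eyes jitter around it; saccades are linear interpolations of at least
0.5° whose per-sample steps exceed the annotation bound, so with zero
jitter and no dropout the event detector recovers the generated fixations
exactly.

Judgments of control (JoC, 1–7) are generated from a continuous latent
Gaussian response and rounded/clipped, mirroring their treatment as a
Gaussian outcome in the models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .constants import (DEG_PER_PX, FPS, SAMPLE_RATE_HZ, SHIP_SCREEN_CENTER,
                        VISIBLE_HEIGHT_PX, SCREEN_W_PX)
from .environment import TrialLog, TrialSpec, run_session, make_experiment_layouts
from .policies import PolicyParams, get_policy

__all__ = ["ComponentEffects", "GazeParams", "JocParams", "SynthCohortSpec",
           "GazeStream", "Cohort", "synth_trial_gaze", "synth_joc",
           "make_cohort"]

SCROLL_PX_PER_SAMPLE = 6 * FPS / SAMPLE_RATE_HZ          # 0.18
_MIN_DIST_DEG = 0.2
# upper support of generated distances; well inside what the visible screen
# allows from the ship center, so component shifts are barely truncated
_MAX_DIST_DEG = 12.0


@dataclass(frozen=True)
class ComponentEffects:
    """Linear shifts of one mixture component's mean (transform scale)."""
    obstacles: float = 0.0           # per on-screen obstacle
    drift_sections: float = 0.0      # per on-screen drift section
    noise: dict = field(default_factory=dict)    # sd -> shift
    block: dict = field(default_factory=dict)    # block -> shift

    def __post_init__(self):
        # normalize noise keys to float so configs serialize canonically
        object.__setattr__(self, "noise",
                           {float(k): float(v) for k, v in self.noise.items()})

    def shift(self, n_obs: int, n_drift: int, noise_sd: float,
              block: str) -> float:
        return (self.obstacles * n_obs + self.drift_sections * n_drift
                + self.noise.get(noise_sd, 0.0) + self.block.get(block, 0.0))


def _default_close_effects() -> ComponentEffects:
    # cumulative level shifts; successive differences are −0.02 (weak vs
    # none) and −0.09 (strong vs weak), the printed Close-fixation pattern
    return ComponentEffects(obstacles=0.07,
                            noise={0: 0.0, 3: -0.02, 6: -0.11,
                                   9: -0.15, 12: -0.20},
                            block={"invisible": -0.03, "fake": -0.02})


def _default_distant_effects() -> ComponentEffects:
    return ComponentEffects(obstacles=0.05, drift_sections=0.15)


@dataclass(frozen=True)
class GazeParams:
    rate_hz: int = SAMPLE_RATE_HZ
    close_mean_deg: float = 3.0
    close_sd_deg: float = 1.0
    distant_mean_deg: float = 8.0
    distant_sd_deg: float = 1.2
    p_distant: float = 0.35
    fix_dur_mean_ms: float = 350.0
    fix_dur_sd_ms: float = 100.0
    fix_dur_min_ms: float = 60.0
    intra_fixation_jitter_px: float = 0.3        # per-sample step sd, < 1.25/3
    saccade_min_amp_deg: float = 0.5
    saccade_speed_px_per_sample: float = 3.0
    vergence_offset_px: float = 4.0
    dropout_rate: float = 0.05                   # single-eye loss per fixation
    participant_sd: float = 0.5                  # random-intercept sd (deg)
    close_transform: str = "identity"
    distant_transform: str = "identity"
    close_effects: ComponentEffects = field(default_factory=_default_close_effects)
    distant_effects: ComponentEffects = field(default_factory=_default_distant_effects)


@dataclass(frozen=True)
class JocParams:
    intercept: float = 3.2
    completion: float = 1.5
    difficulty: dict = field(default_factory=lambda: {
        "easy": 0.0, "medium": -0.2, "hard": -0.44})
    noise: dict = field(default_factory=lambda: {
        0: 0.0, 3: -0.1, 6: -0.34, 9: -0.6, 12: -0.9})
    drift_presence: float = -0.1
    block: dict = field(default_factory=lambda: {
        "invisible": -0.69, "fake": -0.03})
    n_fixations: float = 1.2e-3
    crash_completion: float = 0.03
    resid_sd: float = 0.8
    participant_sd: float = 0.4


@dataclass
class GazeStream:
    samples: pd.DataFrame        # t, lx, ly, rx, ry, vl, vr
    truth: pd.DataFrame          # generated fixation ground truth


# transform-scale helpers for generating distances that are linear after the
# experiment's response transform
_FWD = {"identity": lambda d: d, "sqrt": np.sqrt, "log": np.log,
        "reciprocal": lambda d: 1.0 / d}
_INV = {"identity": lambda v: v, "sqrt": lambda v: v ** 2,
        "log": np.exp, "reciprocal": lambda v: 1.0 / v}


def _draw_distance(cls: str, params: GazeParams, shift: float,
                   intercept: float, rng: np.random.Generator) -> float:
    if cls == "close":
        mean, sd, tr = (params.close_mean_deg, params.close_sd_deg,
                        params.close_transform)
    else:
        mean, sd, tr = (params.distant_mean_deg, params.distant_sd_deg,
                        params.distant_transform)
    # the component mean, all covariate shifts, the participant intercept
    # and the residual sd all live on the component's transform scale, so
    # the corresponding fitted model is linear in them by construction
    scale = 1.0 if tr == "identity" else abs(_FWD[tr](mean + 0.5) - _FWD[tr](mean)) / 0.5
    mu = float(_FWD[tr](mean)) + shift + intercept * scale
    lo, hi = _MIN_DIST_DEG, _MAX_DIST_DEG
    for _ in range(50):
        v = rng.normal(mu, sd * scale)
        with np.errstate(all="ignore"):
            d = float(_INV[tr](v)) if (tr not in ("log",) or v < 5) else np.inf
        if np.isfinite(d) and lo <= d <= hi:
            return d
    with np.errstate(all="ignore"):
        fallback = float(_INV[tr](mu))
    if not np.isfinite(fallback):
        fallback = mean
    return float(np.clip(fallback, lo, hi))


def synth_trial_gaze(trial_log: TrialLog, params: GazeParams,
                     participant_intercept: float,
                     rng: np.random.Generator) -> GazeStream:
    """Generate one trial's binocular stream plus its ground-truth table.

    Time zero is the first control frame; the stream spans the trial's
    control phase (up to crash or finish).
    """
    ctrl = trial_log.control_frames()
    n_frames = len(ctrl)
    n_total = int(n_frames / FPS * params.rate_hz)
    min_fix = int(params.fix_dur_min_ms / 1000 * params.rate_hz)
    empty = GazeStream(
        samples=pd.DataFrame(columns=["t", "lx", "ly", "rx", "ry", "vl", "vr"]),
        truth=pd.DataFrame(columns=[
            "fix_id", "onset_sample", "onset_t", "onset_frame", "x", "y",
            "cls", "distance_deg", "n_obstacles_on_screen",
            "n_drift_sections_on_screen"]))
    if n_total < min_fix:
        warnings.warn("trial shorter than one minimal fixation; empty stream",
                      stacklevel=2)
        return empty

    ship_cx, ship_cy = SHIP_SCREEN_CENTER
    n_obs_arr = ctrl["n_obstacles_on_screen"].to_numpy()
    n_drift_arr = ctrl["n_drift_sections_on_screen"].to_numpy()
    spec = trial_log.spec
    jitter = params.intra_fixation_jitter_px
    sacc_min_px = params.saccade_min_amp_deg / DEG_PER_PX

    cx = np.empty(n_total)
    cy = np.empty(n_total)
    vl = np.ones(n_total, dtype=bool)
    vr = np.ones(n_total, dtype=bool)
    truth_rows = []
    cursor = 0
    prev_end: Optional[np.ndarray] = None
    fix_id = 0
    while True:
        onset_frame = min(int(cursor / params.rate_hz * FPS), n_frames - 1)
        n_obs = int(n_obs_arr[onset_frame])
        n_drift = int(n_drift_arr[onset_frame])
        cls = "distant" if rng.random() < params.p_distant else "close"
        eff = params.distant_effects if cls == "distant" else params.close_effects
        shift = eff.shift(n_obs, n_drift, spec.input_noise_sd, spec.block)
        # onset point: distance from the ship center, direction biased
        # downward (where new objects appear); redraw the angle, not the
        # distance, when the point would leave the visible region
        d_deg = _draw_distance(cls, params, shift, participant_intercept, rng)
        d_px = d_deg / DEG_PER_PX
        for _ in range(60):
            ang = rng.normal(np.pi / 2, 0.9)
            q = np.array([ship_cx + d_px * np.cos(ang),
                          ship_cy + d_px * np.sin(ang)])
            in_bounds = (5 <= q[0] <= SCREEN_W_PX - 5
                         and 5 <= q[1] <= VISIBLE_HEIGHT_PX - 5)
            far_enough = prev_end is None or \
                np.hypot(*(q - prev_end)) >= sacc_min_px + 1
            if in_bounds and far_enough:
                break
        else:
            break  # no feasible placement; end the trial's gaze here
        # saccade from the previous fixation's end to the new onset
        if prev_end is not None:
            amp = float(np.hypot(*(q - prev_end)))
            n_steps = int(np.clip(round(amp / params.saccade_speed_px_per_sample),
                                  5, int(amp / 1.26)))
            n_interior = n_steps - 1
            if cursor + n_interior + min_fix > n_total:
                break
            frac = np.arange(1, n_steps) / n_steps
            sacc = prev_end + frac[:, None] * (q - prev_end)
            cx[cursor:cursor + n_interior] = sacc[:, 0]
            cy[cursor:cursor + n_interior] = sacc[:, 1]
            cursor += n_interior
        # fixation
        dur_ms = max(params.fix_dur_min_ms,
                     rng.normal(params.fix_dur_mean_ms, params.fix_dur_sd_ms))
        n_fix = int(dur_ms / 1000 * params.rate_hz)
        if cursor + n_fix > n_total:
            n_fix = n_total - cursor
            if n_fix < min_fix:
                break
        scroll = np.zeros((n_fix, 2))
        scroll[:, 1] = -SCROLL_PX_PER_SAMPLE
        steps = scroll.copy()
        if jitter > 0:
            j = rng.normal(0.0, jitter, size=(n_fix, 2))
            steps = scroll + j
            norms = np.hypot(steps[:, 0], steps[:, 1])
            too_big = norms > 1.2
            if np.any(too_big):
                steps[too_big] *= (1.2 / norms[too_big])[:, None]
        pos = q + np.vstack([np.zeros(2), np.cumsum(steps[:-1], axis=0)])
        cx[cursor:cursor + n_fix] = pos[:, 0]
        cy[cursor:cursor + n_fix] = pos[:, 1]
        if params.dropout_rate > 0 and rng.random() < params.dropout_rate:
            lost = vl if rng.random() < 0.5 else vr
            lost[cursor:cursor + n_fix] = False
        truth_rows.append((fix_id, cursor, cursor / params.rate_hz,
                           onset_frame, q[0], q[1], cls, d_deg,
                           n_obs, n_drift))
        fix_id += 1
        prev_end = pos[-1]
        cursor += n_fix
        if cursor >= n_total:
            break
    if not truth_rows:
        warnings.warn("no fixation fitted into the trial; empty stream",
                      stacklevel=2)
        return empty
    # tail: continue pursuing the last fixated point (extends the final
    # fixation without adding a new one)
    if cursor < n_total:
        k = n_total - cursor
        cx[cursor:] = prev_end[0]
        cy[cursor:] = prev_end[1] - SCROLL_PX_PER_SAMPLE * np.arange(1, k + 1)
        cursor = n_total

    t = np.arange(n_total) / params.rate_hz
    half = params.vergence_offset_px / 2
    samples = pd.DataFrame({
        "t": t, "lx": cx - half, "ly": cy, "rx": cx + half, "ry": cy,
        "vl": vl, "vr": vr})
    truth = pd.DataFrame(truth_rows, columns=[
        "fix_id", "onset_sample", "onset_t", "onset_frame", "x", "y", "cls",
        "distance_deg", "n_obstacles_on_screen", "n_drift_sections_on_screen"])
    return GazeStream(samples=samples, truth=truth)


def synth_joc(trial_rows: pd.DataFrame, params: JocParams,
              participant_intercept: float,
              rng: np.random.Generator) -> np.ndarray:
    """Latent-Gaussian 7-point judgments of control, one per trial row.

    Requires columns completion, difficulty, noise_level, drift_enabled,
    block, n_fixations, consecutive_crash_completions.
    """
    lat = (params.intercept
           + params.completion * trial_rows["completion"].to_numpy(float)
           + trial_rows["difficulty"].map(params.difficulty).fillna(0.0).to_numpy()
           + trial_rows["noise_level"].map(params.noise).fillna(0.0).to_numpy()
           + params.drift_presence * trial_rows["drift_enabled"].to_numpy(float)
           + trial_rows["block"].map(params.block).fillna(0.0).to_numpy()
           + params.n_fixations * trial_rows["n_fixations"].to_numpy(float)
           + params.crash_completion
           * trial_rows["consecutive_crash_completions"].to_numpy(float)
           + participant_intercept
           + rng.normal(0.0, params.resid_sd, size=len(trial_rows)))
    return np.clip(np.round(lat), 1, 7).astype(int)


@dataclass(frozen=True)
class SynthCohortSpec:
    n_participants: int
    experiment: int
    seed: int
    gaze_params: GazeParams = field(default_factory=GazeParams)
    joc_params: JocParams = field(default_factory=JocParams)
    policy: str = "greedy_gap"
    policy_params: PolicyParams = field(default_factory=PolicyParams)
    layout_seed: int = 0
    specs_subset: Optional[tuple[TrialSpec, ...]] = None
    include_training: bool = True

    def __post_init__(self):
        if self.n_participants < 2:
            raise ValueError("need at least 2 participants")


@dataclass
class Cohort:
    spec: SynthCohortSpec
    layouts: list
    sessions: dict                    # participant -> list[TrialLog]
    gaze: dict                        # (participant, trial_idx) -> GazeStream
    intercepts: pd.DataFrame          # participant random intercepts


def make_cohort(spec: SynthCohortSpec) -> Cohort:
    """Simulate a full cohort: sessions, gaze streams and intercepts.

    Everything derives from ``spec.seed``; identical specs give identical
    cohorts.  JoC responses are attached later (they need the measured
    per-trial fixation counts; see measures.build_tables).
    """
    master = np.random.default_rng(spec.seed)
    layouts = list(getattr(spec, "layouts", ()) or
                   make_experiment_layouts(spec.experiment, spec.layout_seed))
    sessions: dict[int, list[TrialLog]] = {}
    gaze: dict[tuple[int, int], GazeStream] = {}
    inter_rows = []
    for p in range(spec.n_participants):
        prng = np.random.default_rng(master.integers(2 ** 31))
        b_dist = float(prng.normal(0.0, spec.gaze_params.participant_sd))
        b_joc = float(prng.normal(0.0, spec.joc_params.participant_sd))
        policy = get_policy(spec.policy, spec.policy_params)
        logs = run_session(spec.experiment, policy, prng, layouts=layouts,
                           specs=spec.specs_subset,
                           layout_seed=spec.layout_seed,
                           counterbalance=bool(p % 2),
                           include_training=spec.include_training)
        sessions[p] = logs
        for i, log in enumerate(logs):
            if log.spec.training:
                continue
            gaze[(p, i)] = synth_trial_gaze(log, spec.gaze_params, b_dist, prng)
        inter_rows.append((p, b_dist, b_joc))
    intercepts = pd.DataFrame(inter_rows,
                              columns=["participant", "b_distance", "b_joc"])
    return Cohort(spec=spec, layouts=layouts, sessions=sessions, gaze=gaze,
                  intercepts=intercepts)
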