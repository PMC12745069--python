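"""Binocular preprocessing and eye-event detection.

Input is a 2000-Hz binocular sample stream (columns ``t, lx, ly, rx, ry,
vl, vr``).  The analyzed gaze position is the cyclopean point — the
midpoint of both eyes, falling back to the single valid eye when one
signal is lost.

Fixations are maximal runs in which every available eye travels at most
1.25 px (0.026°) between consecutive samples, for at least 25 consecutive
samples.  Candidate saccades are verified with a velocity-based detector:
per-eye, per-axis velocities from a 5-sample centered window, a
median-based threshold with multiplier λ = 6, a 4-sample minimum duration
and a 0.5° minimum amplitude, applied conjunctively.  Samples claimed by a
verified saccade are removed from fixation runs before the 25-sample rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import DEG_PER_PX, FPS, SAMPLE_DT_S

__all__ = [
    "SaccadeParams", "FixationEvent", "SaccadeEvent", "AlignmentError",
    "px_to_deg", "deg_to_px", "combine_eyes", "detect_fixations",
    "detect_saccades", "detect_events", "assign_onset_frame",
    "FIXATION_MAX_STEP_PX", "FIXATION_MIN_SAMPLES",
]

FIXATION_MAX_STEP_PX = 1.25
FIXATION_MIN_SAMPLES = 25


class AlignmentError(ValueError):
    """A fixation onset falls outside the trial's control phase."""


@dataclass(frozen=True)
class SaccadeParams:
    lam: float = 6.0                 # velocity-threshold multiplier
    min_samples: int = 4
    min_amp_deg: float = 0.5
    velocity_window_samples: int = 5  # centered difference window


@dataclass(frozen=True)
class FixationEvent:
    onset_index: int
    offset_index: int                # inclusive
    onset_t: float
    offset_t: float
    onset_x: float                   # cyclopean, screen px
    onset_y: float
    n_samples: int


@dataclass(frozen=True)
class SaccadeEvent:
    onset_index: int
    offset_index: int
    onset_t: float
    offset_t: float
    amplitude_deg: float


def px_to_deg(d_px):
    """Screen pixels → degrees of visual angle (1.25 px = 0.026°)."""
    d_px = np.asarray(d_px, dtype=float)
    if np.any(d_px < 0):
        raise ValueError("distance must be nonnegative")
    out = d_px * DEG_PER_PX
    return float(out) if out.ndim == 0 else out


def deg_to_px(d_deg):
    d_deg = np.asarray(d_deg, dtype=float)
    if np.any(d_deg < 0):
        raise ValueError("distance must be nonnegative")
    out = d_deg / DEG_PER_PX
    return float(out) if out.ndim == 0 else out


def combine_eyes(stream: pd.DataFrame) -> pd.DataFrame:
    """Cyclopean stream: midpoint of both eyes, single-eye fallback.

    Samples where both eyes are invalid are dropped.
    """
    if len(stream) == 0:
        return pd.DataFrame(columns=["t", "x", "y", "source"])
    vl = stream["vl"].to_numpy(dtype=bool)
    vr = stream["vr"].to_numpy(dtype=bool)
    keep = vl | vr
    lx, ly = stream["lx"].to_numpy(float), stream["ly"].to_numpy(float)
    rx, ry = stream["rx"].to_numpy(float), stream["ry"].to_numpy(float)
    x = np.where(vl & vr, (lx + rx) / 2, np.where(vl, lx, rx))
    y = np.where(vl & vr, (ly + ry) / 2, np.where(vl, ly, ry))
    source = np.where(vl & vr, "both", np.where(vl, "left_only", "right_only"))
    out = pd.DataFrame({"t": stream["t"].to_numpy(float)[keep],
                        "x": x[keep], "y": y[keep],
                        "source": source[keep]})
    return out.reset_index(drop=True)


def _cyclopean_xy(stream: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Cyclopean coordinates aligned 1:1 with the raw stream (NaN where
    both eyes are invalid)."""
    vl = stream["vl"].to_numpy(dtype=bool)
    vr = stream["vr"].to_numpy(dtype=bool)
    lx, ly = stream["lx"].to_numpy(float), stream["ly"].to_numpy(float)
    rx, ry = stream["rx"].to_numpy(float), stream["ry"].to_numpy(float)
    x = np.where(vl & vr, (lx + rx) / 2, np.where(vl, lx, np.where(vr, rx, np.nan)))
    y = np.where(vl & vr, (ly + ry) / 2, np.where(vl, ly, np.where(vr, ry, np.nan)))
    return x, y


def _step_ok(stream: pd.DataFrame,
             max_step_px: float = FIXATION_MAX_STEP_PX) -> np.ndarray:
    """Boolean per between-sample step: every available eye ≤ threshold.

    An eye is available for a step when it is valid at both endpoints;
    steps with no available eye break the run.
    """
    vl = stream["vl"].to_numpy(dtype=bool)
    vr = stream["vr"].to_numpy(dtype=bool)
    avail = []
    bad = []
    for v, xc, yc in ((vl, "lx", "ly"), (vr, "rx", "ry")):
        x = stream[xc].to_numpy(float)
        y = stream[yc].to_numpy(float)
        d = np.hypot(np.diff(x), np.diff(y))
        both = v[1:] & v[:-1]
        avail.append(both)
        bad.append(both & (d > max_step_px))
    return (avail[0] | avail[1]) & ~bad[0] & ~bad[1]


def detect_fixations(stream: pd.DataFrame,
                     min_samples: int = FIXATION_MIN_SAMPLES,
                     max_step_px: float = FIXATION_MAX_STEP_PX,
                     exclude: np.ndarray | None = None) -> list[FixationEvent]:
    """Maximal sub-threshold runs of at least ``min_samples`` samples.

    ``exclude`` optionally marks samples (e.g. verified saccade samples)
    that may not participate in any run.
    """
    n = len(stream)
    if n < min_samples:
        return []
    ok = _step_ok(stream, max_step_px)
    if exclude is not None:
        excl = np.asarray(exclude, dtype=bool)
        ok = ok & ~excl[1:] & ~excl[:-1]
    cx, cy = _cyclopean_xy(stream)
    fixations: list[FixationEvent] = []
    t = stream["t"].to_numpy(float)
    i = 0
    while i < n - 1:
        if not ok[i]:
            i += 1
            continue
        j = i
        while j < n - 1 and ok[j]:
            j += 1
        run_len = j - i + 1                # samples i..j inclusive
        if run_len >= min_samples:
            fixations.append(FixationEvent(
                onset_index=i, offset_index=j,
                onset_t=float(t[i]), offset_t=float(t[j]),
                onset_x=float(cx[i]), onset_y=float(cy[i]),
                n_samples=run_len))
        i = j + 1
    return fixations


def _eye_velocity(x: np.ndarray, y: np.ndarray, window: int,
                  dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-axis velocity from a centered moving window (5-sample default)."""
    n = len(x)
    vx = np.zeros(n)
    vy = np.zeros(n)
    if window == 5 and n >= 5:
        vx[2:-2] = (x[4:] + x[3:-1] - x[1:-3] - x[:-4]) / (6 * dt)
        vy[2:-2] = (y[4:] + y[3:-1] - y[1:-3] - y[:-4]) / (6 * dt)
    elif n >= 3:
        vx[1:-1] = (x[2:] - x[:-2]) / (2 * dt)
        vy[1:-1] = (y[2:] - y[:-2]) / (2 * dt)
    return vx, vy


def _median_sd(v: np.ndarray) -> float:
    """Median-based velocity scale, robust to the saccades themselves."""
    med = np.median(v)
    sd = np.sqrt(np.median(v ** 2) - med ** 2)
    return float(max(sd, 1e-9))


def detect_saccades(stream: pd.DataFrame,
                    params: SaccadeParams = SaccadeParams()
                    ) -> list[SaccadeEvent]:
    """Velocity-verified saccades: both eyes above the λ-threshold for at
    least 4 samples and total displacement of at least 0.5°."""
    n = len(stream)
    if n < params.velocity_window_samples:
        warnings.warn("stream shorter than velocity window; no saccades",
                      stacklevel=2)
        return []
    dt = SAMPLE_DT_S
    above = np.ones(n, dtype=bool)
    for xc, yc in (("lx", "ly"), ("rx", "ry")):
        x = stream[xc].to_numpy(float)
        y = stream[yc].to_numpy(float)
        vx, vy = _eye_velocity(x, y, params.velocity_window_samples, dt)
        # velocities are median-centered so that steady smooth-pursuit
        # scroll does not masquerade as saccadic motion
        vx = vx - np.median(vx)
        vy = vy - np.median(vy)
        eta_x = params.lam * _median_sd(vx)
        eta_y = params.lam * _median_sd(vy)
        crit = (vx / eta_x) ** 2 + (vy / eta_y) ** 2
        above &= crit > 1.0
    cx, cy = _cyclopean_xy(stream)
    t = stream["t"].to_numpy(float)
    out: list[SaccadeEvent] = []
    i = 0
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j < n and above[j]:
            j += 1
        # samples i..j-1 above threshold
        if j - i >= params.min_samples:
            x0, y0 = cx[i], cy[i]
            x1, y1 = cx[j - 1], cy[j - 1]
            amp = px_to_deg(float(np.hypot(x1 - x0, y1 - y0)))
            if amp >= params.min_amp_deg:
                out.append(SaccadeEvent(
                    onset_index=i, offset_index=j - 1,
                    onset_t=float(t[i]), offset_t=float(t[j - 1]),
                    amplitude_deg=amp))
        i = j
    return out


def detect_events(stream: pd.DataFrame,
                  sacc_params: SaccadeParams = SaccadeParams(),
                  min_fix_samples: int = FIXATION_MIN_SAMPLES
                  ) -> tuple[list[FixationEvent], list[SaccadeEvent]]:
    """Full detection pass: verified saccades first, then fixation runs on
    the remaining samples (a sample can belong to at most one event)."""
    saccades = detect_saccades(stream, sacc_params) if len(stream) else []
    excl = np.zeros(len(stream), dtype=bool)
    for s in saccades:
        excl[s.onset_index:s.offset_index + 1] = True
    fixations = detect_fixations(stream, min_fix_samples, exclude=excl)
    return fixations, saccades


def assign_onset_frame(onset_t: float, n_control_frames: int) -> int:
    """Game frame (control phase, 60 FPS) in which a fixation began.

    ``onset_t`` is measured from the first control frame.
    """
    frame = int(np.floor(onset_t * FPS))
    if onset_t < 0 or frame >= n_control_frames:
        raise AlignmentError(
            f"onset t={onset_t:.4f}s outside trial of {n_control_frames} frames")
    return frame


def events_to_frame(fixations: list[FixationEvent],
                    saccades: list[SaccadeEvent]) -> pd.DataFrame:
    """Tabular events (type, onset/offset, onset location) for CSV export."""
    rows = []
    for f in fixations:
        rows.append(("fixation", f.onset_t, f.offset_t, f.onset_x, f.onset_y,
                     f.n_samples, np.nan))
    for s in saccades:
        rows.append(("saccade", s.onset_t, s.offset_t, np.nan, np.nan,
                     s.offset_index - s.onset_index + 1, s.amplitude_deg))
    df = pd.DataFrame(rows, columns=["type", "onset_t", "offset_t",
                                     "onset_x", "onset_y", "n_samples",
                                     "amplitude_deg"])
    return df.sort_values("onset_t").reset_index(drop=True)
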