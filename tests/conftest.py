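"""Shared fixtures: small layouts, trial logs, gaze streams."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from dodgegaze.environment import (Layout, TrialSpec, generate_layout,
                                   run_trial)
from dodgegaze.gaze import GazeParams, synth_trial_gaze
from dodgegaze.policies import null_policy


@pytest.fixture(scope="session")
def easy_layout():
    return generate_layout(9000, "easy", seed=1)


@pytest.fixture(scope="session")
def empty_layout():
    """Obstacle-free, drift-free short layout."""
    return Layout(id="empty", length_px=9000, difficulty="easy",
                  obstacles=(), drift_sections=())


@pytest.fixture(scope="session")
def empty_trial_log(empty_layout):
    spec = TrialSpec(empty_layout.id, 1)
    return run_trial(spec, empty_layout, null_policy,
                     np.random.default_rng(0))


@pytest.fixture(scope="session")
def noiseless_gaze(empty_trial_log):
    """Gaze with zero jitter and zero dropout: exactly recoverable."""
    params = dataclasses.replace(GazeParams(), intra_fixation_jitter_px=0.0,
                                 dropout_rate=0.0)
    return synth_trial_gaze(empty_trial_log, params, 0.0,
                            np.random.default_rng(5))


def make_stream(points, valid=None):
    """Binocular stream from a list of cyclopean (x, y) sample positions."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    v = np.ones((n, 2), dtype=bool) if valid is None else np.asarray(valid)
    return pd.DataFrame({
        "t": np.arange(n) / 2000.0,
        "lx": pts[:, 0] - 2.0, "ly": pts[:, 1],
        "rx": pts[:, 0] + 2.0, "ry": pts[:, 1],
        "vl": v[:, 0], "vr": v[:, 1]})
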