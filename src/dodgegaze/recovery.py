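"""Parameter-recovery scenarios: plant effects, run the pipeline, check signs.

A recovery replicate simulates two reduced cohorts of 25 participants —
one in the noise × drift design (experiment 1 style, two short layouts)
and one in the drift-type block design (experiment 3 style, two layouts,
one section assignment per block) — runs the full detection/classification/
measurement/modeling pipeline on them, and asks whether each planted
effect comes back with the planted sign and |z| ≥ 2:

* more on-screen obstacles → larger Close-fixation distance to the ship
* strong (sd 6) vs weak (sd 3) input noise → smaller Close distance
* more on-screen drift sections → larger Distant distance
* invisible drift block → lower judgments of control
* strong input noise → lower completion log-odds

The planted magnitudes are the generator defaults; only the cohort size is
reduced relative to a full session (a subset of layouts and one section
assignment per block) to keep a replicate tractable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .environment import (TrialSpec, enumerate_configurations,
                          generate_layout, make_experiment_layouts)
from .gaze import SynthCohortSpec, make_cohort
from .pipeline import analyze_cohort

__all__ = ["RecoveryCheck", "recovery_cohort_spec", "run_recovery_replicate",
           "recovery_report", "PLANTED_SIGNS"]

# claim name -> (scenario, model, coefficient, planted sign)
PLANTED_SIGNS = {
    "close_obstacles": ("exp1", "close_distance", "n_obstacles_on_screen", +1),
    "close_noise_strong": ("exp1", "close_distance",
                           "C(noise_level, SuccDiff())[6-3]", -1),
    "distant_drift_sections": ("exp3", "distant_distance",
                               "n_drift_sections_on_screen", +1),
    "joc_invisible": ("exp3", "joc",
                      "C(block, Treatment('normal'))[T.invisible]", -1),
    "completion_noise_strong": ("exp1", "completion",
                                "C(noise_level, Treatment(0.0))[T.6]", -1),
}


@dataclass
class RecoveryCheck:
    claim: str
    beta: float
    z: float
    planted_sign: int

    @property
    def recovered(self) -> bool:
        return np.sign(self.beta) == self.planted_sign and abs(self.z) >= 2.0


def recovery_cohort_spec(scenario: str, seed: int,
                         n_participants: int = 25) -> SynthCohortSpec:
    """Reduced cohort spec for one recovery scenario.

    ``exp1``: the three 9,000-px layouts (easy/medium/hard) × noise
    {0, 3, 6} × drift on/off = 18 configurations per session.  ``exp3``:
    two short (9,000-px) layouts carrying 8 drift sections each × 3 blocks
    × 2 complementary section assignments = 12 configurations per session.
    """
    if scenario == "exp1":
        layouts = make_experiment_layouts(1, 0)
        keep = {l.id for l in layouts[:3]}           # the short layouts
        specs = tuple(s for s in enumerate_configurations(1, layouts, 0)
                      if s.layout_id in keep)
        return SynthCohortSpec(n_participants=n_participants, experiment=1,
                               seed=seed, specs_subset=specs,
                               include_training=False)
    if scenario == "exp3":
        layouts = [generate_layout(9000, d, n_drift_sections=8,
                                   seed=17 + i, layout_id=f"R3-{d}")
                   for i, d in enumerate(("medium", "hard"))]
        mask_rng = np.random.default_rng(23)
        specs = []
        for lay in layouts:
            special = mask_rng.choice(8, size=4, replace=False)
            mask = np.zeros(8, dtype=bool)
            mask[special] = True
            for block in ("normal", "invisible", "fake"):
                special_type = "off" if block == "normal" else block
                for flip in (False, True):
                    types = tuple(special_type if (m ^ flip) else "normal"
                                  for m in mask)
                    specs.append(TrialSpec(lay.id, 3, drift_enabled=True,
                                           drift_type_per_section=types,
                                           block=block))
        return _cohort_with_layouts(3, seed, n_participants, layouts,
                                    tuple(specs))
    raise ValueError(f"unknown scenario {scenario!r}")


@dataclass(frozen=True)
class _CohortWithLayouts(SynthCohortSpec):
    """Cohort spec carrying its own (non-canonical, scaled-down) layouts."""
    layouts: tuple = ()


def _cohort_with_layouts(experiment, seed, n_participants, layouts, specs):
    return _CohortWithLayouts(n_participants=n_participants,
                              experiment=experiment, seed=seed,
                              specs_subset=specs, include_training=False,
                              layouts=tuple(layouts))


def run_recovery_replicate(seed: int,
                           n_participants: int = 25) -> list[RecoveryCheck]:
    """One replicate: simulate both scenarios, fit, check every claim."""
    results = {}
    for scenario in ("exp1", "exp3"):
        spec = recovery_cohort_spec(scenario, seed=seed * 2 + (scenario == "exp3"),
                                    n_participants=n_participants)
        cohort = make_cohort(spec)
        results[scenario] = analyze_cohort(cohort)
    checks = []
    for claim, (scenario, model, term, sign) in PLANTED_SIGNS.items():
        res = results[scenario]["models"].get(model)
        if res is None or term not in res.coef.index:
            checks.append(RecoveryCheck(claim, np.nan, 0.0, sign))
            continue
        row = res.coef.loc[term]
        checks.append(RecoveryCheck(claim, float(row["beta"]),
                                    float(row["z"]), sign))
    return checks


def recovery_report(n_replicates: int = 10, base_seed: int = 1,
                    n_participants: int = 25) -> pd.DataFrame:
    """Sign-recovery rates over seeded replicates."""
    rows = []
    for r in range(n_replicates):
        for c in run_recovery_replicate(base_seed + r, n_participants):
            rows.append((r, c.claim, c.beta, c.z, c.recovered))
    df = pd.DataFrame(rows, columns=["replicate", "claim", "beta", "z",
                                     "recovered"])
    return (df.groupby("claim")
              .agg(rate=("recovered", "mean"), mean_beta=("beta", "mean"),
                   mean_z=("z", "mean"))
              .reset_index())
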