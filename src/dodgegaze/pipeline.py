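"""Configuration, default model specs, and the end-to-end pipeline.

The pipeline runs simulate → synthesize gaze → detect events → classify
fixations → measure → fit → bootstrap on a synthetic cohort, writing each
stage's artifact (tables, split summary, coefficient tables) under the
output directory together with a manifest naming the config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .clustering import ClusterParams, apply_split, kquantiles_fit
from .events import SaccadeParams, detect_events
from .gaze import (Cohort, GazeParams, JocParams, SynthCohortSpec, make_cohort,
                   synth_joc)
from .measures import build_tables
from .policies import PolicyParams
from .stats import ModelResult, ModelSpec, fit_mixed, parametric_bootstrap

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ValidationReport", "validate_config",
           "default_model_specs", "analyze_cohort", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    experiment: int
    n_participants: int
    seed: Optional[int]
    policy: str = "greedy_gap"
    policy_params: PolicyParams = field(default_factory=PolicyParams)
    gaze_params: GazeParams = field(default_factory=GazeParams)
    joc_params: JocParams = field(default_factory=JocParams)
    cluster_params: ClusterParams = field(default_factory=ClusterParams)
    saccade_params: SaccadeParams = field(default_factory=SaccadeParams)
    bootstrap_reps: int = 0
    layout_seed: int = 0
    force_drift: Optional[bool] = None     # override drift for every trial
    max_configs: Optional[int] = None      # truncate the design (desk scale)
    out_dir: Optional[str] = None

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        d = yaml.safe_load(text)
        for key, klass in (("policy_params", PolicyParams),
                           ("gaze_params", GazeParams),
                           ("joc_params", JocParams),
                           ("cluster_params", ClusterParams),
                           ("saccade_params", SaccadeParams)):
            if key in d and isinstance(d[key], dict):
                sub = dict(d[key])
                if key == "gaze_params":
                    from .gaze import ComponentEffects
                    for ek in ("close_effects", "distant_effects"):
                        if ek in sub and isinstance(sub[ek], dict):
                            eff = dict(sub[ek])
                            eff["noise"] = {float(k): v for k, v in
                                            eff.get("noise", {}).items()}
                            sub[ek] = ComponentEffects(**eff)
                d[key] = klass(**sub)
        return cls(**d)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


@dataclass
class ValidationReport:
    failures: list[str]

    @property
    def valid(self) -> bool:
        return not self.failures

    def __str__(self):
        if self.valid:
            return "config valid"
        return "config invalid:\n" + "\n".join(f"  - {f}" for f in self.failures)


def validate_config(config: PipelineConfig) -> ValidationReport:
    """Schema and cross-field checks; failures go in the report, not raised."""
    fails: list[str] = []
    if config.experiment not in (1, 2, 3):
        fails.append(f"unknown experiment {config.experiment}")
    if config.seed is None:
        fails.append("seed is required")
    if config.n_participants < 2:
        fails.append("need at least 2 participants")
    if config.experiment == 2 and config.force_drift:
        fails.append("experiment 2 has no drift manipulation")
    if config.policy not in ("null", "left", "right", "greedy_gap"):
        fails.append(f"unknown policy {config.policy!r}")
    if not 0 <= config.gaze_params.p_distant <= 1:
        fails.append("p_distant must be a probability")
    if config.gaze_params.intra_fixation_jitter_px >= 1.25:
        fails.append("intra-fixation jitter at or above the 1.25-px bound")
    if config.bootstrap_reps < 0:
        fails.append("bootstrap_reps must be nonnegative")
    return ValidationReport(fails)


def default_model_specs(experiment: int) -> dict[str, ModelSpec]:
    """The four model families of one experiment.

    The random-structure ladder runs from a participant intercept to a
    participant slope on the main manipulation; fixed structures are never
    pruned.
    """
    noise_term = "C(noise_level, SuccDiff())"
    block_term = "C(block, Treatment('normal'))"
    if experiment in (1, 2):
        dist_terms = f"n_obstacles_on_screen + n_drift_sections_on_screen + {noise_term}" \
            if experiment == 1 else f"n_obstacles_on_screen + {noise_term}"
        joc_terms = (f"completion + C(difficulty) + {noise_term} + "
                     "n_fixations + consecutive_crash_completions")
        if experiment == 1:
            joc_terms += " + C(difficulty) : drift_enabled + drift_enabled"
        comp_terms = "C(difficulty) + C(noise_level, Treatment(0.0))"
        if experiment == 1:
            comp_terms += " + drift_enabled"
        ladder = ({"re_formula": "1"},)
    else:
        dist_terms = (f"n_obstacles_on_screen + n_drift_sections_on_screen + "
                      f"{block_term}")
        joc_terms = (f"completion + C(difficulty) + {block_term} + "
                     "n_fixations + consecutive_crash_completions")
        comp_terms = f"C(difficulty) + {block_term}"
        ladder = ({"re_formula": "1"},)
    return {
        "close_distance": ModelSpec(
            response="dist_to_ship_deg", formula=dist_terms,
            family="gaussian", random_candidates=ladder),
        "distant_distance": ModelSpec(
            response="dist_to_ship_deg", formula=dist_terms,
            family="gaussian", random_candidates=ladder),
        "joc": ModelSpec(
            response="joc", formula=joc_terms, family="gaussian",
            random_candidates=ladder),
        "completion": ModelSpec(
            response="completion", formula=comp_terms, family="bernoulli"),
    }


def attach_joc(cohort: Cohort, trial_df: pd.DataFrame) -> pd.DataFrame:
    """Generate the per-trial 7-point control judgments for a cohort.

    Needs the measured fixation counts, hence runs after build_tables.
    """
    rng = np.random.default_rng(cohort.spec.seed + 909_090_909)
    out = trial_df.copy()
    out["joc"] = 0
    for p in out["participant"].unique():
        mask = out["participant"] == p
        b = float(cohort.intercepts.loc[
            cohort.intercepts["participant"] == p, "b_joc"].iloc[0])
        out.loc[mask, "joc"] = synth_joc(out[mask], cohort.spec.joc_params,
                                         b, rng)
    return out


def analyze_cohort(cohort: Cohort,
                   cluster_params: ClusterParams = ClusterParams(),
                   saccade_params: SaccadeParams = SaccadeParams(),
                   model_specs: Optional[dict[str, ModelSpec]] = None,
                   bootstrap_reps: int = 0, bootstrap_seed: int = 0
                   ) -> dict:
    """Detect → classify → measure → fit on an in-memory cohort."""
    events = {}
    for key, stream in cohort.gaze.items():
        fixes, _ = detect_events(stream.samples, saccade_params)
        events[key] = fixes
    fix_df, trial_df = build_tables(cohort.sessions, events, cohort.layouts)
    trial_df = attach_joc(cohort, trial_df)
    split = kquantiles_fit(fix_df["dist_to_ship_deg"].to_numpy(),
                           cluster_params)
    fix_df, _ = apply_split(fix_df, split)
    # per-trial class counts for the proportion model
    counts = (fix_df.groupby(["participant", "trial"])["cls"]
              .apply(lambda s: (s == "distant").sum()).rename("n_distant"))
    trial_df = trial_df.merge(counts, on=["participant", "trial"], how="left")
    trial_df["n_distant"] = trial_df["n_distant"].fillna(0).astype(int)

    specs = model_specs or default_model_specs(cohort.spec.experiment)
    results: dict[str, ModelResult] = {}
    boots: dict[str, pd.DataFrame] = {}
    for name, spec in specs.items():
        if name == "close_distance":
            data = fix_df[fix_df["cls"] == "close"]
        elif name == "distant_distance":
            data = fix_df[fix_df["cls"] == "distant"]
        elif name in ("joc", "completion"):
            data = trial_df
        else:
            data = fix_df
        try:
            res = fit_mixed(data, spec)
        except Exception as exc:              # noqa: BLE001
            logger.warning("model %s failed: %s", name, exc)
            continue
        results[name] = res
        if bootstrap_reps > 0 and spec.family == "gaussian":
            boots[name] = parametric_bootstrap(res, bootstrap_reps,
                                               seed=bootstrap_seed)
    return {"fix_table": fix_df, "trial_table": trial_df, "split": split,
            "models": results, "bootstrap": boots, "events": events}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full pipeline from a config and write artifacts.

    Raises on invalid configs; each stage's output lands in
    ``config.out_dir`` (tables as CSV, split and manifest as JSON).
    """
    report = validate_config(config)
    if not report.valid:
        raise ValueError(str(report))
    specs_subset = None
    if config.force_drift is not None or config.max_configs is not None:
        from .environment import enumerate_configurations, make_experiment_layouts
        layouts = make_experiment_layouts(config.experiment, config.layout_seed)
        specs = enumerate_configurations(config.experiment, layouts,
                                         config.layout_seed)
        if config.force_drift is not None:
            specs = [dataclasses.replace(s, drift_enabled=config.force_drift)
                     for s in specs]
        if config.max_configs is not None:
            specs = specs[:config.max_configs]
        specs_subset = tuple(specs)
    cohort_spec = SynthCohortSpec(
        n_participants=config.n_participants, experiment=config.experiment,
        seed=config.seed, gaze_params=config.gaze_params,
        joc_params=config.joc_params, policy=config.policy,
        policy_params=config.policy_params, layout_seed=config.layout_seed,
        specs_subset=specs_subset)
    cohort = make_cohort(cohort_spec)
    result = analyze_cohort(cohort, config.cluster_params,
                            config.saccade_params,
                            bootstrap_reps=config.bootstrap_reps,
                            bootstrap_seed=config.seed or 0)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest = {"config_hash": config.config_hash,
                    "package_version": _pkg_version,
                    "experiment": config.experiment,
                    "seed": config.seed,
                    "stages": ["simulate", "synth-gaze", "detect", "classify",
                               "measure", "fit"]}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        (out / "config.yaml").write_text(config.to_yaml())
        result["fix_table"].to_csv(out / "fixations.csv", index=False)
        result["trial_table"].to_csv(out / "trials.csv", index=False)
        split = result["split"]
        (out / "split.json").write_text(json.dumps({
            "threshold_deg": split.threshold_deg,
            "objective": split.objective,
            "n_close": split.n_close, "n_distant": split.n_distant,
            "centers_deg": list(split.centers_deg)}, indent=1))
        for name, res in result["models"].items():
            res.coef.to_csv(out / f"model_{name}.csv")
        for name, ci in result["bootstrap"].items():
            ci.to_csv(out / f"bootstrap_{name}.csv")
        for lay in cohort.layouts:
            (out / f"layout_{lay.id}.json").write_text(lay.to_json())
    return result
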