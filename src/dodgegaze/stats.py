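"""Inference stage: transforms, contrasts, mixed models, bootstrap CIs.

Response transforms are chosen by Box–Cox profile likelihood and mapped to
the nearest named transform (λ≈1 identity, λ≈0.5 square root, λ≈0 log,
λ≈−1 reciprocal; reciprocal-of-log is available as an explicit override).
Gaussian responses are fitted with a linear mixed model by maximum
likelihood; the binary completion outcome uses a Bernoulli mixed model fit
by variational Bayes.  Fixed-effects structures are never pruned; only the
candidate random-effects structures compete, by BIC.  Hypothesis tests use
the |z| ≥ 2 criterion, and 95% highest-density confidence intervals come
from a parametric bootstrap (simulate from the fitted model, refit,
collect the coefficient draws).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import patsy
from scipy import stats as sps
from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning

logger = logging.getLogger(__name__)

__all__ = ["ModelSpec", "ModelResult", "TRANSFORMS", "apply_transform",
           "boxcox_select", "successive_difference_contrasts", "fit_mixed",
           "parametric_bootstrap", "proportion_distant_model", "hdi"]

TRANSFORMS = {
    "identity": lambda y: y,
    "log": np.log,
    "sqrt": np.sqrt,
    "reciprocal": lambda y: 1.0 / y,
    "reciprocal_of_log": lambda y: 1.0 / np.log(y),
}

_LAMBDA_MAP = [(1.0, "identity"), (0.5, "sqrt"), (0.0, "log"),
               (-1.0, "reciprocal")]


def _shift_nonpositive(y: np.ndarray) -> np.ndarray:
    """Replace nonpositive values by half the smallest positive value.

    Distances are nonnegative; exact zeros would break log/reciprocal
    transforms, so they are nudged up by the smallest half-step present in
    the data (logged, never silent).
    """
    y = np.asarray(y, dtype=float)
    if np.all(y > 0):
        return y
    pos = y[y > 0]
    if len(pos) == 0:
        raise ValueError("no positive values to anchor the shift")
    eps = 0.5 * pos.min()
    n_bad = int((y <= 0).sum())
    logger.info("shifted %d nonpositive values to %.3g before transform",
                n_bad, eps)
    out = y.copy()
    out[out <= 0] = eps
    return out


def apply_transform(y: np.ndarray, name: str) -> np.ndarray:
    if name not in TRANSFORMS:
        raise ValueError(f"unknown transform {name!r}")
    y = np.asarray(y, dtype=float)
    if name in ("log", "reciprocal", "reciprocal_of_log"):
        y = _shift_nonpositive(y)
    if name == "reciprocal_of_log":
        # log of values in (0, 1] is nonpositive; keep the argument > 1
        if np.any(y <= 1.0):
            y = y + 1.0 - y.min() + 1e-6
    return TRANSFORMS[name](y)


def boxcox_select(y: np.ndarray) -> tuple[str, float]:
    """Profile-likelihood Box–Cox λ, mapped to the nearest named transform.

    Returns (transform name, λ̂).
    """
    y = np.asarray(y, dtype=float)
    y = _shift_nonpositive(y)
    _, lmbda = sps.boxcox(y)
    name = min(_LAMBDA_MAP, key=lambda t: abs(t[0] - lmbda))[1]
    return name, float(lmbda)


def successive_difference_contrasts(levels: Sequence) -> pd.DataFrame:
    """Backward-difference coding: coefficient j estimates level_j −
    level_{j−1} for ordered levels.

    Columns sum to zero; for two levels the estimated contrast coincides
    with treatment coding's.
    """
    k = len(levels)
    if k < 2:
        raise ValueError("need at least two levels")
    mat = np.zeros((k, k - 1))
    for j in range(1, k):
        mat[:j, j - 1] = -(k - j) / k
        mat[j:, j - 1] = j / k
    cols = [f"{levels[j]}-{levels[j - 1]}" for j in range(1, k)]
    return pd.DataFrame(mat, index=list(levels), columns=cols)


class SuccDiff:
    """patsy contrast wrapper for successive-difference coding."""

    def code_with_intercept(self, levels):
        m = successive_difference_contrasts(levels)
        full = np.column_stack([np.ones(len(levels)), m.to_numpy()])
        return patsy.ContrastMatrix(full, ["[mean]"] + [f"[{c}]" for c in m.columns])

    def code_without_intercept(self, levels):
        m = successive_difference_contrasts(levels)
        return patsy.ContrastMatrix(m.to_numpy(), [f"[{c}]" for c in m.columns])


@dataclass(frozen=True)
class ModelSpec:
    response: str
    formula: str                     # patsy RHS, e.g. "n_obstacles_on_screen + C(noise_level, SuccDiff())"
    transform: str = "identity"
    family: str = "gaussian"         # "gaussian" | "bernoulli"
    group: str = "participant"
    # candidate random structures: list of dicts with optional keys
    # "re_formula" (random intercept/slopes) and "vc_formula"
    random_candidates: tuple = (({"re_formula": "1"}),)

    def __post_init__(self):
        if self.family not in ("gaussian", "bernoulli"):
            raise ValueError("family must be gaussian or bernoulli")
        if self.family == "bernoulli" and self.transform != "identity":
            raise ValueError("transforms apply to gaussian responses only")


@dataclass
class ModelResult:
    spec: ModelSpec
    coef: pd.DataFrame               # index term: beta, se, z, significant
    chosen_random: dict
    bic: float
    n_obs: int
    converged: bool
    fit: object = None               # underlying statsmodels results
    diagnostics: dict = field(default_factory=dict)

    def __repr__(self):
        return (f"ModelResult({self.spec.response}, n={self.n_obs}, "
                f"bic={self.bic:.1f}, converged={self.converged})\n"
                f"{self.coef.round(4)}")


def _design(df: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, np.ndarray, list[str]]:
    y = apply_transform(df[spec.response].to_numpy(float), spec.transform) \
        if spec.family == "gaussian" else df[spec.response].to_numpy(float)
    X = patsy.dmatrix(spec.formula, df, return_type="dataframe",
                      eval_env=patsy.EvalEnvironment([{"SuccDiff": SuccDiff}]))
    return y, X.to_numpy(), list(X.columns)


def _fit_gaussian_candidate(y, X, names, df, spec, cand):
    re_formula = cand.get("re_formula", "1")
    vc_formula = cand.get("vc_formula")
    groups = df[spec.group].to_numpy()
    exog_re = patsy.dmatrix(re_formula, df, return_type="dataframe")
    md = MixedLM(y, X, groups=groups, exog_re=exog_re.to_numpy())
    if vc_formula:
        md = MixedLM.from_formula(
            f"__y__ ~ {spec.formula}",
            data=df.assign(__y__=y), groups=df[spec.group],
            re_formula=re_formula, vc_formula=vc_formula)
        names = md.exog_names
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        res = None
        for method in (None, "lbfgs", "powell"):
            try:
                res = md.fit(reml=False) if method is None \
                    else md.fit(reml=False, method=method)
            except (np.linalg.LinAlgError, ValueError):
                continue
            if getattr(res, "converged", True) and \
                    np.all(np.isfinite(np.asarray(res.bse_fe))):
                break
    return res


def fit_mixed(df: pd.DataFrame, spec: ModelSpec) -> ModelResult:
    """ML fit with BIC selection over candidate random structures.

    Gaussian responses use a linear mixed model; the Bernoulli completion
    model uses a variational-Bayes logistic mixed model with a participant
    intercept (z = posterior mean / posterior sd).  Non-convergence is
    reported in the result, never silently swallowed.
    """
    df = df.reset_index(drop=True)
    if spec.family == "bernoulli":
        return _fit_bernoulli(df, spec)
    y, X, names = _design(df, spec)
    keep = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    df, y, X = df[keep].reset_index(drop=True), y[keep], X[keep]
    best, best_cand, best_bic = None, None, np.inf
    for cand in spec.random_candidates:
        res = _fit_gaussian_candidate(y, X, names, df, spec, cand)
        if res is None:
            continue
        k = len(res.params)
        bic = -2 * res.llf + k * np.log(len(y))
        if bic < best_bic:
            best, best_cand, best_bic = res, cand, bic
    if best is None:
        raise RuntimeError("no candidate random structure could be fitted")
    fe = best.fe_params
    se = best.bse_fe if hasattr(best, "bse_fe") else best.bse[:len(fe)]
    # models built from arrays carry auto-generated names; prefer patsy's
    fe_names = best.model.exog_names \
        if best.model.exog_names[:1] == ["Intercept"] else names
    coef = pd.DataFrame({
        "beta": np.asarray(fe), "se": np.asarray(se)},
        index=fe_names[:len(fe)])
    coef["z"] = coef["beta"] / coef["se"]
    coef["significant"] = coef["z"].abs() >= 2.0
    converged = bool(getattr(best, "converged", True))
    if not converged:
        logger.warning("mixed model for %s did not converge", spec.response)
    return ModelResult(spec=spec, coef=coef, chosen_random=best_cand,
                       bic=float(best_bic), n_obs=int(len(y)),
                       converged=converged, fit=best,
                       diagnostics={"scale": float(best.scale),
                                    "cov_re": np.asarray(best.cov_re).tolist()})


def _fit_bernoulli(df: pd.DataFrame, spec: ModelSpec) -> ModelResult:
    formula = f"{spec.response} ~ {spec.formula}"
    d = df.copy()
    d[spec.response] = d[spec.response].astype(float)
    vc = {"participant": f"0 + C({spec.group})"}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        md = BinomialBayesMixedGLM.from_formula(formula, vc, d)
        res = md.fit_vb()
    names = md.exog_names if hasattr(md, "exog_names") else \
        list(res.model.exog_names)
    coef = pd.DataFrame({"beta": res.fe_mean, "se": res.fe_sd}, index=names)
    coef["z"] = coef["beta"] / coef["se"]
    coef["significant"] = coef["z"].abs() >= 2.0
    return ModelResult(spec=spec, coef=coef,
                       chosen_random={"vc_formula": vc},
                       bic=float("nan"), n_obs=int(len(d)),
                       converged=True, fit=res,
                       diagnostics={"vcp_mean": res.vcp_mean.tolist()})


def hdi(draws: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``mass`` of the draws."""
    x = np.sort(np.asarray(draws, dtype=float))
    n = len(x)
    m = max(int(np.ceil(mass * n)), 2)
    widths = x[m - 1:] - x[:n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def _simulate_gaussian(res, rng: np.random.Generator) -> np.ndarray:
    """Draw a response vector from a fitted Gaussian mixed model."""
    model = res.model
    y_hat = model.exog @ res.fe_params
    scale = res.scale
    cov_re = np.atleast_2d(np.asarray(res.cov_re))
    y = y_hat + rng.normal(0.0, np.sqrt(scale), size=len(y_hat))
    for lab in model.group_labels:
        idx = model.row_indices[lab]
        if cov_re.size:
            b = rng.multivariate_normal(np.zeros(cov_re.shape[0]), cov_re)
            Z = model.exog_re[idx] if model.exog_re is not None else None
            if Z is not None:
                y[idx] += Z @ b
    if getattr(model, "exog_vc", None) is not None and len(res.vcomp):
        vc = model.exog_vc
        for jv, name in enumerate(vc.names):
            sd = np.sqrt(max(float(res.vcomp[jv]), 0.0))
            for ig, lab in enumerate(model.group_labels):
                mat = vc.mats[jv][ig]
                idx = model.row_indices[lab]
                u = rng.normal(0.0, sd, size=mat.shape[1])
                y[idx] += np.asarray(mat @ u).ravel()
    return y


def parametric_bootstrap(result: ModelResult, n_reps: int = 10_000,
                         seed: int = 0, ci_mass: float = 0.95,
                         progress: bool = False) -> pd.DataFrame:
    """Parametric-bootstrap highest-density CIs for every coefficient.

    Responses are simulated from the fitted model and refitted with the
    same design; coefficient draws form the intervals.  Refit failures are
    counted; more than 1% triggers a warning.
    """
    rng = np.random.default_rng(seed)
    res = result.fit
    if result.spec.family == "bernoulli":
        return _bootstrap_bernoulli(result, n_reps, rng, ci_mass)
    model = res.model
    draws = np.empty((n_reps, len(res.fe_params)))
    failures = 0
    start = res.params_object
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for r in range(n_reps):
            y_star = _simulate_gaussian(res, rng)
            try:
                md = MixedLM(y_star, model.exog, groups=model.groups,
                             exog_re=model.exog_re,
                             exog_vc=getattr(model, "exog_vc", None))
                rs = md.fit(reml=False, start_params=start)
                draws[r] = rs.fe_params
            except Exception:
                draws[r] = np.nan
                failures += 1
    if failures > 0.01 * n_reps:
        warnings.warn(f"{failures}/{n_reps} bootstrap refits failed",
                      stacklevel=2)
    rows = []
    names = result.coef.index
    for j, name in enumerate(names):
        d = draws[:, j]
        d = d[np.isfinite(d)]
        lo, hi = hdi(d, ci_mass)
        rows.append((name, float(result.coef["beta"].iloc[j]), lo, hi))
    out = pd.DataFrame(rows, columns=["term", "beta", "ci_low", "ci_high"])
    out["n_reps"] = n_reps
    out["failures"] = failures
    return out.set_index("term")


def _bootstrap_bernoulli(result: ModelResult, n_reps: int,
                         rng: np.random.Generator,
                         ci_mass: float) -> pd.DataFrame:
    res = result.fit
    model = res.model
    X = model.exog
    eta_fe = X @ res.fe_mean
    # posterior-mean random effects enter the simulated linear predictor
    vc_mean = res.vc_mean if hasattr(res, "vc_mean") else None
    eta_re = model.exog_vc @ vc_mean if vc_mean is not None else 0.0
    p = 1.0 / (1.0 + np.exp(-(eta_fe + np.asarray(eta_re).ravel())))
    draws = np.empty((n_reps, len(res.fe_mean)))
    failures = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for r in range(n_reps):
            y_star = (rng.random(len(p)) < p).astype(float)
            try:
                md = BinomialBayesMixedGLM(y_star, X, model.exog_vc,
                                           model.ident)
                rs = md.fit_vb()
                draws[r] = rs.fe_mean
            except Exception:
                draws[r] = np.nan
                failures += 1
    if failures > 0.01 * n_reps:
        warnings.warn(f"{failures}/{n_reps} bootstrap refits failed",
                      stacklevel=2)
    rows = []
    for j, name in enumerate(result.coef.index):
        d = draws[:, j]
        d = d[np.isfinite(d)]
        lo, hi = hdi(d, ci_mass)
        rows.append((name, float(result.coef["beta"].iloc[j]), lo, hi))
    out = pd.DataFrame(rows, columns=["term", "beta", "ci_low", "ci_high"])
    out["n_reps"] = n_reps
    out["failures"] = failures
    return out.set_index("term")


def proportion_distant_model(trial_df: pd.DataFrame,
                             formula: str = "C(difficulty) * drift_enabled",
                             random_candidates: tuple = ({"re_formula": "1"},)
                             ) -> ModelResult:
    """Mixed model for the per-trial proportion of Distant fixations.

    Trials with zero fixations are excluded (logged); the default fixed
    structure carries the difficulty × drift interaction.
    """
    d = trial_df.copy()
    if "n_distant" not in d or "n_fixations" not in d:
        raise ValueError("trial table needs n_distant and n_fixations")
    zero = d["n_fixations"] == 0
    if zero.any():
        logger.info("excluding %d zero-fixation trials", int(zero.sum()))
        d = d[~zero]
    d["prop_distant"] = d["n_distant"] / d["n_fixations"]
    if d["prop_distant"].nunique() <= 1:
        logger.warning("proportion of distant fixations has zero variance")
    spec = ModelSpec(response="prop_distant", formula=formula,
                     family="gaussian",
                     random_candidates=random_candidates)
    return fit_mixed(d, spec)
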