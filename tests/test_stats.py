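"""Transforms, contrasts, mixed models, bootstrap machinery."""

import numpy as np
import pandas as pd
import pytest

from dodgegaze.stats import (ModelSpec, apply_transform, boxcox_select,
                             fit_mixed, hdi, parametric_bootstrap,
                             proportion_distant_model,
                             successive_difference_contrasts)


class TestBoxCox:
    def test_lognormal_maps_to_log(self):
        rng = np.random.default_rng(0)
        name, lam = boxcox_select(np.exp(rng.normal(size=800)))
        assert name == "log" and abs(lam) < 0.15

    def test_shifted_normal_maps_to_identity(self):
        rng = np.random.default_rng(1)
        name, lam = boxcox_select(rng.normal(10, 1, size=800))
        assert name == "identity"

    def test_squared_magnitudes_map_to_sqrt(self):
        rng = np.random.default_rng(2)
        name, _ = boxcox_select(rng.normal(3, 0.5, size=800) ** 2)
        assert name == "sqrt"

    def test_reciprocal_case(self):
        rng = np.random.default_rng(3)
        name, lam = boxcox_select(1.0 / rng.normal(5, 0.5, size=800))
        assert name == "reciprocal"

    def test_idempotent_after_applying_chosen_transform(self):
        rng = np.random.default_rng(4)
        y = np.exp(rng.normal(size=800))
        name, _ = boxcox_select(y)
        name2, _ = boxcox_select(apply_transform(y, name) + 10)
        assert name2 == "identity"


class TestTransforms:
    def test_zero_values_shifted_before_log(self):
        y = np.array([0.0, 1.0, 2.0])
        out = apply_transform(y, "log")
        assert np.isfinite(out).all()
        assert out[0] == pytest.approx(np.log(0.5))

    def test_unknown_transform_rejected(self):
        with pytest.raises(ValueError):
            apply_transform(np.ones(3), "cube")

    def test_reciprocal_of_log_available(self):
        out = apply_transform(np.array([2.0, 3.0]), "reciprocal_of_log")
        assert np.isfinite(out).all()

    def test_bernoulli_forbids_transform(self):
        with pytest.raises(ValueError):
            ModelSpec(response="completion", formula="1",
                      family="bernoulli", transform="log")


class TestContrasts:
    def test_five_levels_give_four_zero_sum_columns(self):
        m = successive_difference_contrasts([0, 3, 6, 9, 12])
        assert m.shape == (5, 4)
        assert np.allclose(m.to_numpy().sum(axis=0), 0.0)

    def test_single_level_rejected(self):
        with pytest.raises(ValueError):
            successive_difference_contrasts(["only"])

    def test_each_column_estimates_successive_difference(self):
        # regression of cell means on the coding recovers level_i - level_{i-1}
        means = np.array([2.0, 5.0, 4.0])
        m = successive_difference_contrasts(list("abc")).to_numpy()
        X = np.column_stack([np.ones(3), m])
        beta = np.linalg.solve(X, means)
        assert beta[1] == pytest.approx(3.0)      # b - a
        assert beta[2] == pytest.approx(-1.0)     # c - b

    def test_two_levels_match_treatment_coding_estimate(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({
            "g": np.repeat(np.arange(8), 20),
            "level": rng.choice(["lo", "hi"], size=160),
        })
        df["y"] = (df["level"] == "hi") * 1.7 + rng.normal(0, 1, 160)
        df["participant"] = df["g"]
        sd = fit_mixed(df, ModelSpec(
            response="y", formula="C(level, SuccDiff())"))
        tr = fit_mixed(df, ModelSpec(
            response="y", formula="C(level, Treatment('hi'))"))
        # both estimate lo - hi up to naming; compare magnitudes
        assert abs(sd.coef["beta"].iloc[1]) == pytest.approx(
            abs(tr.coef["beta"].iloc[1]), rel=1e-6)


def _sim_lmm(rng, n_g=20, n_per=30, beta_x=0.5, sd_b=0.6, sd_e=1.0):
    g = np.repeat(np.arange(n_g), n_per)
    x = rng.normal(size=n_g * n_per)
    b = rng.normal(0, sd_b, size=n_g)[g]
    y = 1.0 + beta_x * x + b + rng.normal(0, sd_e, size=n_g * n_per)
    return pd.DataFrame({"participant": g, "x": x, "y": y})


class TestFitMixed:
    def test_recovers_planted_fixed_effect(self):
        df = _sim_lmm(np.random.default_rng(6))
        res = fit_mixed(df, ModelSpec(response="y", formula="x"))
        assert res.coef.loc["x", "beta"] == pytest.approx(0.5, abs=0.15)
        assert res.coef.loc["x", "significant"]
        assert res.converged and res.n_obs == 600

    def test_bic_prefers_simpler_structure_without_slope_variance(self):
        df = _sim_lmm(np.random.default_rng(7))
        res = fit_mixed(df, ModelSpec(
            response="y", formula="x",
            random_candidates=({"re_formula": "1"},
                               {"re_formula": "1 + x"})))
        assert res.chosen_random == {"re_formula": "1"}

    def test_bernoulli_family_recovers_sign(self):
        rng = np.random.default_rng(8)
        df = _sim_lmm(rng)
        p = 1 / (1 + np.exp(-(0.3 - 1.0 * df["x"])))
        df["completion"] = rng.random(len(df)) < p
        res = fit_mixed(df, ModelSpec(response="completion", formula="x",
                                      family="bernoulli"))
        assert res.coef.loc["x", "beta"] < 0
        assert abs(res.coef.loc["x", "z"]) >= 2


class TestBootstrap:
    def test_hdi_shortest_interval(self):
        draws = np.concatenate([np.zeros(98), [50.0, -50.0]])
        lo, hi = hdi(draws, 0.95)
        assert (lo, hi) == (0.0, 0.0)
        rng = np.random.default_rng(9)
        lo, hi = hdi(rng.normal(0, 1, 20000), 0.95)
        assert lo == pytest.approx(-1.96, abs=0.1)
        assert hi == pytest.approx(1.96, abs=0.1)

    def test_ci_brackets_point_estimate(self):
        df = _sim_lmm(np.random.default_rng(10), n_g=10, n_per=15)
        res = fit_mixed(df, ModelSpec(response="y", formula="x"))
        ci = parametric_bootstrap(res, n_reps=120, seed=1)
        for term in ci.index:
            assert ci.loc[term, "ci_low"] <= res.coef.loc[term, "beta"] \
                <= ci.loc[term, "ci_high"]
        assert (ci["failures"] == 0).all()

    def test_seeded_bootstrap_is_reproducible(self):
        df = _sim_lmm(np.random.default_rng(11), n_g=8, n_per=12)
        res = fit_mixed(df, ModelSpec(response="y", formula="x"))
        a = parametric_bootstrap(res, n_reps=60, seed=7)
        b = parametric_bootstrap(res, n_reps=60, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_rep_counts_agree_within_monte_carlo_error(self):
        df = _sim_lmm(np.random.default_rng(12), n_g=10, n_per=15)
        res = fit_mixed(df, ModelSpec(response="y", formula="x"))
        small = parametric_bootstrap(res, n_reps=150, seed=2)
        large = parametric_bootstrap(res, n_reps=600, seed=3)
        se = res.coef.loc["x", "se"]
        assert small.loc["x", "ci_low"] == pytest.approx(
            large.loc["x", "ci_low"], abs=0.5 * se)
        assert small.loc["x", "ci_high"] == pytest.approx(
            large.loc["x", "ci_high"], abs=0.5 * se)


class TestProportionDistant:
    def _trials(self, rng, interaction=0.0):
        rows = []
        for pid in range(20):
            b = rng.normal(0, 0.05)
            for _ in range(24):
                diff = rng.choice(["medium", "hard"])
                drift = rng.random() < 0.5
                mu = 0.4 + b + interaction * (diff == "hard") * drift
                n_fix = int(rng.integers(20, 60))
                n_distant = rng.binomial(n_fix, np.clip(mu, 0.01, 0.99))
                rows.append((pid, diff, drift, n_fix, n_distant))
        return pd.DataFrame(rows, columns=[
            "participant", "difficulty", "drift_enabled", "n_fixations",
            "n_distant"])

    def test_planted_negative_interaction_recovered(self):
        df = self._trials(np.random.default_rng(13), interaction=-0.12)
        res = proportion_distant_model(
            df, formula="C(difficulty, Treatment('medium')) * drift_enabled")
        term = [t for t in res.coef.index if "hard" in t and ":" in t]
        assert len(term) == 1
        assert res.coef.loc[term[0], "beta"] < 0
        assert abs(res.coef.loc[term[0], "z"]) >= 2

    def test_zero_fixation_trials_excluded_and_props_bounded(self):
        df = self._trials(np.random.default_rng(14))
        df.loc[:3, "n_fixations"] = 0
        df.loc[:3, "n_distant"] = 0
        res = proportion_distant_model(df)
        assert res.n_obs == len(df) - 4

    def test_all_distant_is_degenerate_but_handled(self):
        df = self._trials(np.random.default_rng(15))
        df["n_distant"] = df["n_fixations"]
        res = proportion_distant_model(df)
        assert res.coef["beta"].iloc[0] == pytest.approx(1.0, abs=1e-6)
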