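import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from statsmodels.stats.anova import AnovaRM

from dyadsynch.stats_models import (
    RegressionStageResult,
    fit_hierarchical_regression,
    fit_mixed_ancova,
    partial_eta_squared_ci,
    simple_slopes,
)

from _oracles import ols_by_hand


def _tidy(n_subjects, rng, cue_effect=0.0, gen_effect=0.0, trial_levels=3):
    rows = []
    for s in range(n_subjects):
        gen = "G2" if s % 2 == 0 else "G3"
        gcode = 1.0 if gen == "G2" else -1.0
        match = 0.5 if s % 3 == 0 else -0.5
        base = rng.normal(40, 8)
        for cue in ("Tx", "NT"):
            for tr in range(1, trial_levels + 1):
                rows.append({
                    "subject": f"s{s}", "generation": gen, "gender_match": match,
                    "cue": cue, "trial": tr,
                    "value": base + cue_effect * (cue == "Tx")
                    + gen_effect * gcode + rng.normal(0, 3),
                })
    return pd.DataFrame(rows)


class TestMixedAncova:
    def test_no_cue_difference_gives_zero_f(self, rng):
        df = _tidy(12, rng)
        wide = df.pivot_table(index="subject", columns=["cue", "trial"], values="value")
        # force Tx cells identical to NT cells per subject
        for tr in range(1, 4):
            wide[("Tx", tr)] = wide[("NT", tr)]
        tidy = wide.stack(["cue", "trial"], future_stack=True).rename("value").reset_index()
        meta = df.drop_duplicates("subject")[["subject", "generation", "gender_match"]]
        tidy = tidy.merge(meta, on="subject")
        out = fit_mixed_ancova(tidy)
        assert out.effects["cue"].F == pytest.approx(0.0, abs=1e-18)

    def test_within_effects_match_anova_rm_without_covariate(self, rng):
        df = _tidy(14, rng, cue_effect=2.0)
        single = df[df["generation"] == "G2"]
        out = fit_mixed_ancova(single, between=None, covariate=None)
        oracle = AnovaRM(single, "value", "subject", within=["cue", "trial"]).fit()
        tab = oracle.anova_table
        for mine, theirs in [("cue", "cue"), ("trial", "trial"),
                             ("cue x trial", "cue:trial")]:
            eff = out.effects[mine]
            assert eff.F == pytest.approx(tab.loc[theirs, "F Value"], rel=1e-10)
            assert eff.df_num == tab.loc[theirs, "Num DF"]
            assert eff.df_den == tab.loc[theirs, "Den DF"]

    def test_degrees_of_freedom_follow_split_plot_structure(self, rng):
        df = _tidy(20, rng, trial_levels=6)
        out = fit_mixed_ancova(df)
        # N=20, between parameters: intercept + generation + covariate
        assert (out.effects["cue"].df_num, out.effects["cue"].df_den) == (1, 17)
        assert (out.effects["trial"].df_num, out.effects["trial"].df_den) == (5, 85)
        assert out.effects["cue x trial"].df_den == 85
        assert out.effects["generation"].df_den == 17

    def test_between_effect_matches_subject_mean_glm_oracle(self, rng):
        df = _tidy(16, rng, gen_effect=3.0)
        out = fit_mixed_ancova(df)
        means = df.groupby("subject").agg(
            value=("value", "mean"), generation=("generation", "first"),
            gender_match=("gender_match", "first")).reset_index()
        X = np.column_stack([
            np.ones(len(means)),
            np.where(means["generation"] == "G2", 1.0, -1.0),
            means["gender_match"] - means["gender_match"].mean(),
        ])
        fit = sm.OLS(means["value"].to_numpy(), X).fit()
        assert out.effects["generation"].F == pytest.approx(fit.tvalues[1] ** 2, rel=1e-8)

    def test_adjusted_mean_difference_recovers_injected_cue_effect(self, rng):
        df = _tidy(40, rng, cue_effect=7.0, trial_levels=6)
        out = fit_mixed_ancova(df)
        diff = out.adjusted_difference
        assert diff.mean == pytest.approx(7.0, abs=1.5)
        assert diff.ci[0] < 7.0 < diff.ci[1]
        assert out.adjusted_means["Tx"].mean > out.adjusted_means["NT"].mean

    def test_dropped_subjects_are_reported(self, rng):
        df = _tidy(10, rng)
        df = df[~((df["subject"] == "s0") & (df["cue"] == "Tx") & (df["trial"] == 1))]
        out = fit_mixed_ancova(df)
        assert out.dropped_subjects == ["s0"]
        assert out.n_subjects == 9

    def test_partial_eta_ci_reproduces_published_pain_effect(self):
        # F(1, 62) = 18.14 corresponds to eta_p^2 = 0.23, 95% CI [0.07, 0.39]
        eta = 18.14 / (18.14 + 62)
        assert round(eta, 2) == 0.23
        lo, hi = partial_eta_squared_ci(18.14, 1, 62)
        assert round(lo, 2) == 0.07
        assert round(hi, 2) == 0.39


class TestHierarchicalRegression:
    def test_noise_free_outcome_recovers_slope_exactly(self, rng):
        x = rng.normal(size=30)
        df = pd.DataFrame({"y": 2.5 * x, "x": x})
        (stage,) = fit_hierarchical_regression(df, "y", [["x"]])
        assert stage.table.loc["x", "B"] == pytest.approx(2.5, abs=1e-10)
        assert stage.r2_adj == pytest.approx(1.0, abs=1e-10)

    def test_coefficients_match_normal_equations_oracle(self, rng):
        n = 40
        df = pd.DataFrame({
            "x1": rng.normal(size=n), "x2": rng.normal(size=n),
            "x3": rng.normal(size=n),
        })
        df["y"] = rng.normal(size=n)
        stages = fit_hierarchical_regression(df, "y", [["x1"], ["x2"], ["x3"]])
        for k, preds in enumerate([["x1"], ["x1", "x2"], ["x1", "x2", "x3"]]):
            X = np.column_stack([np.ones(n)] + [df[p] for p in preds])
            oracle = ols_by_hand(X, df["y"].to_numpy())
            mine = stages[k].table["B"].to_numpy()
            np.testing.assert_allclose(mine, oracle, atol=1e-10)

    def test_stages_are_nested_with_identical_sample(self, rng):
        n = 50
        df = pd.DataFrame({"x1": rng.normal(size=n), "x2": rng.normal(size=n)})
        df["y"] = df["x1"] + rng.normal(size=n)
        df.loc[3, "x2"] = np.nan  # must shrink every stage identically
        stages = fit_hierarchical_regression(df, "y", [["x1"], ["x2"]])
        assert stages[0].nobs == stages[1].nobs == n - 1
        assert stages[1].r2 >= stages[0].r2

    def test_standardised_beta_definition(self, rng):
        n = 60
        df = pd.DataFrame({"x": rng.normal(2, 5, size=n)})
        df["y"] = 3 * df["x"] + rng.normal(0, 4, size=n)
        (stage,) = fit_hierarchical_regression(df, "y", [["x"]])
        b = stage.table.loc["x", "B"]
        expected_beta = b * df["x"].std(ddof=1) / df["y"].std(ddof=1)
        assert stage.table.loc["x", "beta"] == pytest.approx(expected_beta, abs=1e-12)

    def test_collinear_predictors_rejected_with_diagnostics(self, rng):
        df = pd.DataFrame({"x1": rng.normal(size=30)})
        df["x2"] = 2 * df["x1"]
        df["y"] = rng.normal(size=30)
        with pytest.raises(ValueError, match="condition number"):
            fit_hierarchical_regression(df, "y", [["x1", "x2"]])


class TestSimpleSlopes:
    def _fit_interaction(self, rng, n=80, b_f=2.0, b_i=-1.5):
        df = pd.DataFrame({"x": rng.normal(size=n), "m": rng.normal(size=n)})
        df["x:m"] = df["x"] * df["m"]
        df["y"] = b_f * df["x"] + 0.5 * df["m"] + b_i * df["x:m"] + rng.normal(size=n)
        (stage,) = fit_hierarchical_regression(df, "y", [["x", "m", "x:m"]])
        return df, stage

    def test_slopes_reconstruct_linear_combination(self, rng):
        df, stage = self._fit_interaction(rng)
        res = simple_slopes(stage, "x", "m", [0.0, 1.0, -2.0])
        b_f = stage.table.loc["x", "B"]
        b_i = stage.table.loc["x:m", "B"]
        for (label, est, se, ci), lv in zip(res.slopes, [0.0, 1.0, -2.0]):
            assert est == pytest.approx(b_f + lv * b_i, abs=1e-12)
            assert ci[0] < est < ci[1]

    def test_published_conditional_effects_from_effect_coding(self):
        # synchrony main effect 3.62 and interaction -4.65 under G2=+1/G3=-1
        # coding imply conditional slopes -1.03 (G2) and 8.27 (G3)
        table = pd.DataFrame(
            {"B": [3.62, 2.18, -4.65], "SE": [1.61, 1.59, 1.61]},
            index=["synchrony", "generation", "synchrony:generation"],
        )
        cov = pd.DataFrame(np.diag([1.61**2, 1.59**2, 1.61**2]),
                           index=table.index, columns=table.index)
        stage = RegressionStageResult(
            stage=3, predictors=list(table.index), table=table, r2=0.2,
            r2_adj=0.15, F=8.32, f_p=0.005, df_model=3, df_resid=59, nobs=63,
            cov_params=cov,
        )
        res = simple_slopes(stage, "synchrony", "generation",
                            {"G2": 1.0, "G3": -1.0})
        slopes = dict((lab, est) for lab, est, _, _ in res.slopes)
        assert slopes["G2"] == pytest.approx(-1.03, abs=1e-12)
        assert slopes["G3"] == pytest.approx(8.27, abs=1e-12)

    def test_zero_interaction_gives_identical_slopes(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=50), "m": rng.normal(size=50)})
        df["x:m"] = 0.0
        df["y"] = 2 * df["x"] + rng.normal(size=50)
        df["x:m"] = df["x"] * df["m"]
        (stage,) = fit_hierarchical_regression(df, "y", [["x", "m", "x:m"]])
        stage.table.loc["x:m", "B"] = 0.0  # exact zero interaction
        res = simple_slopes(stage, "x", "m", [-1.0, 0.0, 1.0])
        ests = [est for _, est, _, _ in res.slopes]
        assert ests[0] == ests[1] == ests[2]

    def test_interval_matches_bootstrap_oracle(self, rng):
        df, stage = self._fit_interaction(rng, n=120)
        res = simple_slopes(stage, "x", "m", [1.0])
        _, est, se, ci = res.slopes[0]
        # percentile bootstrap of the conditional slope at m = 1
        boot = []
        data = df[["x", "m", "x:m", "y"]].to_numpy()
        for _ in range(10_000):
            idx = rng.integers(0, len(data), len(data))
            X = np.column_stack([np.ones(len(data)), data[idx, :3]])
            beta = np.linalg.lstsq(X, data[idx, 3], rcond=None)[0]
            boot.append(beta[1] + 1.0 * beta[3])
        lo, hi = np.percentile(boot, [2.5, 97.5])
        width = hi - lo
        assert ci[0] == pytest.approx(lo, abs=0.2 * width)
        assert ci[1] == pytest.approx(hi, abs=0.2 * width)

    def test_missing_moderator_rejected(self, rng):
        _, stage = self._fit_interaction(rng)
        with pytest.raises(ValueError):
            simple_slopes(stage, "x", "absent", [0.0])
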