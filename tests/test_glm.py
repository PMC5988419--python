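"""The adequacy logistic model: IRLS fit, tests, profile CIs, predictions."""

import numpy as np
import pandas as pd
import pytest

from trialpower.glm import AdequacyLogit, SeparationError, build_design
from trialpower.scenario import DISCIPLINES


@pytest.fixture(scope="module")
def simple_fit():
    rng = np.random.default_rng(7)
    n = 500
    x1 = rng.normal(size=n)
    x2 = rng.integers(0, 2, n).astype(float)
    eta = -0.5 + 0.8 * x1 - 0.6 * x2
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    X = np.column_stack([np.ones(n), x1, x2])
    return AdequacyLogit(X, y, ["intercept", "x1", "x2"]), X, y


class TestIrlsAgainstOracle:
    def test_coefficients_match_statsmodels(self, simple_fit):
        sm = pytest.importorskip("statsmodels.api")
        model, X, y = simple_fit
        res = model.fit()
        ref = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(res.params.to_numpy(), ref.params, atol=1e-6)
        np.testing.assert_allclose(res.bse.to_numpy(), ref.bse, rtol=1e-5)
        assert res.deviance == pytest.approx(ref.deviance, abs=1e-8)

    def test_intercept_only_balanced_response(self):
        y = np.array([0.0, 1.0] * 50)
        X = np.ones((100, 1))
        res = AdequacyLogit(X, y, ["intercept"]).fit()
        assert res.params.iloc[0] == pytest.approx(0.0, abs=1e-10)
        chi2, df, p = res.lr_test_vs_null()
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert df == 0

    def test_constant_response_raises(self):
        X = np.column_stack([np.ones(20), np.arange(20.0)])
        with pytest.raises(SeparationError):
            AdequacyLogit(X, np.ones(20), ["intercept", "x"]).fit()

    def test_complete_separation_detected(self):
        x = np.linspace(-2, 2, 40)
        y = (x > 0).astype(float)
        X = np.column_stack([np.ones(40), x])
        with pytest.raises(SeparationError):
            AdequacyLogit(X, y, ["intercept", "x"]).fit()


class TestDesign:
    def test_grouped_design_structure(self, planted_small):
        X, y, names, info = build_design(planted_small["analysis"])
        assert sum(t.startswith("combination=") for t in names) == 3
        assert sum(t.startswith("country_group=") for t in names) == 2
        assert sum(t.startswith("discipline=") for t in names) == 30
        assert "year" in names and "intercept" in names
        assert "combination=FF" not in names          # reference level
        assert "discipline=" + DISCIPLINES[0] not in names
        # year centered at first cohort year
        j = names.index("year")
        assert X[:, j].min() == 0.0

    def test_lr_df_36_in_grouped_mode(self, planted_fit):
        chi2, df, p = planted_fit.lr_test_vs_null()
        assert df == 36
        assert chi2 >= 0.0

    def test_empty_level_dropped_with_warning(self, toy_cohort):
        sub = toy_cohort[toy_cohort["combination"] != "FM"]
        X, y, names, info = build_design(sub)
        assert "combination=FM" not in names
        assert any("FM" in w for w in info["warnings"])


class TestFactorWald:
    def test_one_dummy_factor_chi2_equals_z_squared(self):
        rng = np.random.default_rng(1)
        n = 300
        x = rng.integers(0, 2, n).astype(float)
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.4 * x - 0.2)))).astype(float)
        X = np.column_stack([np.ones(n), x])
        r = AdequacyLogit(X, y, ["intercept", "combination=MM"]).fit()
        chi2, df, p = r.wald_test_factor("combination")
        assert df == 1
        assert chi2 == pytest.approx(float(r.wald_z["combination=MM"]) ** 2)
        assert r.last_factor_df_levels == 2

    def test_null_factor_pvalues_are_uniform(self):
        """With no true factor effect the Wald p-values are U(0,1)."""
        from scipy import stats as sps
        rng = np.random.default_rng(42)
        pvals = []
        for _ in range(200):
            n = 600
            lv = rng.integers(0, 4, n)
            y = (rng.random(n) < 0.3).astype(float)   # independent of factor
            X = np.column_stack([np.ones(n)] + [(lv == k).astype(float)
                                                for k in (1, 2, 3)])
            names = ["intercept"] + [f"combination=L{k}" for k in (1, 2, 3)]
            res = AdequacyLogit(X, y, names).fit()
            pvals.append(res.wald_test_factor("combination")[2])
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_planted_combination_factor_is_detected(self, planted_fit):
        chi2, df, p = planted_fit.wald_test_factor("combination")
        assert df == 3
        assert p < 0.005


class TestProfileCI:
    def test_close_to_wald_at_large_n(self, planted_fit):
        term = "combination=MF"
        plo, phi = planted_fit.profile_ci(term)
        wald = planted_fit.conf_int_wald().loc[term]
        assert plo == pytest.approx(wald["ci_low"], rel=0.02)
        assert phi == pytest.approx(wald["ci_high"], rel=0.02)

    def test_interval_contains_point_estimate(self, planted_fit):
        for term in ("combination=MM", "year"):
            lo, hi = planted_fit.profile_ci(term)
            assert lo < float(np.exp(planted_fit.params[term])) < hi


class TestPredictedProbabilities:
    def test_balanced_null_model_predicts_half(self):
        rng = np.random.default_rng(8)
        y = rng.integers(0, 2, 400).astype(bool)   # independent of covariates
        cov = pd.DataFrame({
            "combination": rng.choice(["FF", "MM"], 400),
            "year": rng.integers(1985, 2000, 400),
            "country_group": rng.choice(["Anglosphere", "Europe"], 400),
            "discipline": rng.choice(DISCIPLINES[:3], 400),
            "adequate_80": y,
        })
        res = AdequacyLogit.from_cohort(cov).fit()
        grid = res.predicted_probabilities([1990])
        assert grid["probability"].to_numpy() == pytest.approx(y.mean(), abs=0.15)

    def test_monotone_in_year_and_mf_above_ff(self, planted_fit):
        grid = planted_fit.predicted_probabilities(range(1980, 2016, 5))
        for (combo, grp), sub in grid.groupby(["combination", "country_group"]):
            assert sub.sort_values("year")["probability"].is_monotonic_increasing
        wide = grid.pivot_table(index=["year", "country_group"],
                                columns="combination", values="probability")
        assert (wide["MF"] > wide["FF"]).all()
        assert ((grid["ci_low"] >= 0) & (grid["ci_high"] <= 1)).all()


class TestSummary:
    def test_summary_and_table_are_consistent(self, planted_fit):
        txt = planted_fit.summary()
        assert "combination=MF" in txt
        tab = planted_fit.to_table(profile=False)
        mf = tab[(tab["variable"] == "combination") & (tab["level"] == "MF")]
        assert mf["odds_ratio"].iloc[0] == pytest.approx(
            float(np.exp(planted_fit.params["combination=MF"])))
        assert set(tab.columns) == {"variable", "level", "odds_ratio",
                                    "ci_low", "ci_high", "z_value", "p_value"}
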