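"""Corpus generator: determinism, planted-mode round trip, power inversion."""

import numpy as np
import pandas as pd
import pytest

import trialpower as tp
from trialpower.power import mc_power_oracle, power_binary
from trialpower.scenario import SyntheticScenario, solve_intercept
from trialpower.simulate import invert_power_for_n, linear_predictor, plant_adequacy


class TestScenarioValidation:
    def test_probability_vectors_must_normalize(self):
        with pytest.raises(ValueError):
            SyntheticScenario(measure_mix={"OR": 0.5, "SMD": 0.4})

    def test_planted_requires_coefficients(self):
        with pytest.raises(ValueError):
            SyntheticScenario(mode="planted")
        with pytest.raises(ValueError):
            SyntheticScenario(planted_coefficients={"year": 0.01})

    def test_paper_fit_scenario_coefficients(self):
        sc = tp.paper_fit_scenario()
        assert sc.n_trials == 31_873
        assert sc.year_range == (1975, 2017)
        assert sc.adequacy_cutoff == 0.8
        assert sc.planted_coefficients["combination=MF"] == pytest.approx(np.log(2.08))
        assert "combination=FF" not in sc.planted_coefficients  # reference = 0
        assert sum(sc.combination_probs.values()) == pytest.approx(1.0)

    def test_intercept_solves_marginal_rate(self):
        sc = tp.paper_fit_scenario()
        coeffs = dict(sc.planted_coefficients)
        coeffs.pop("intercept")
        b0 = solve_intercept(sc, coeffs, target_rate=0.13)
        assert b0 == pytest.approx(sc.planted_coefficients["intercept"], abs=1e-8)


class TestInversion:
    def test_smd_half_effect_needs_64_per_arm(self):
        assert invert_power_for_n("SMD", 0.5, None, 0.80) == 64

    def test_boundary_is_tight_for_or(self):
        n = invert_power_for_n("OR", np.log(2), 0.2, 0.90)
        assert power_binary("OR", np.log(2), 0.2, n, n) >= 0.90
        assert power_binary("OR", np.log(2), 0.2, n - 1, n - 1) < 0.90

    def test_mc_oracle_confirms_smd_boundary(self):
        lo, _ = mc_power_oracle("SMD", 0.5, None, 63, 63, reps=50_000, seed=2)
        hi, _ = mc_power_oracle("SMD", 0.5, None, 64, 64, reps=50_000, seed=2)
        assert lo < 0.80 + 0.006
        assert hi > 0.80 - 0.006

    def test_target_near_alpha_gives_floor_n(self):
        assert invert_power_for_n("SMD", 0.5, None, 0.0501) <= 4

    def test_null_effect_raises(self):
        with pytest.raises(ValueError):
            invert_power_for_n("OR", 0.0, 0.3, 0.8)

    def test_invalid_target_raises(self):
        with pytest.raises(ValueError):
            invert_power_for_n("OR", 0.5, 0.3, 0.04)


class TestPlantAdequacy:
    def _cov(self, n, combo="MM"):
        return pd.DataFrame({
            "combination": [combo] * n, "year": [1990] * n,
            "country_group": ["Europe"] * n, "discipline": ["Wounds"] * n,
        })

    def test_zero_predictor_gives_half(self):
        rng = np.random.default_rng(0)
        cov = self._cov(20_000)
        flags, target = plant_adequacy(cov, {}, 0.8, rng)
        assert flags.mean() == pytest.approx(0.5, abs=0.01)
        assert (target[flags] > 0.8).all()
        assert (target[~flags] < 0.8).all()

    def test_quarter_probability_binomial_check(self):
        rng = np.random.default_rng(1)
        coeffs = {"intercept": float(np.log(0.25 / 0.75))}
        flags, _ = plant_adequacy(self._cov(10_000), coeffs, 0.8, rng)
        se = np.sqrt(0.25 * 0.75 / 10_000)
        assert flags.mean() == pytest.approx(0.25, abs=2 * se + 1e-9)

    def test_extreme_negative_predictor_never_adequate(self):
        rng = np.random.default_rng(2)
        coeffs = {"intercept": -40.0}
        flags, _ = plant_adequacy(self._cov(5000), coeffs, 0.8, rng)
        assert not flags.any()

    def test_linear_predictor_term_lookup(self):
        eta = linear_predictor(["MF"], [1995], ["Europe"], ["Wounds"],
                               {"intercept": 0.1, "combination=MF": 0.7,
                                "year": 0.03, "country_group=Europe": -0.2,
                                "discipline=Wounds": -0.5}, 1975)
        assert eta[0] == pytest.approx(0.1 + 0.7 + 0.03 * 20 - 0.2 - 0.5)


class TestGeneration:
    def test_seeded_determinism(self):
        sc = tp.default_scenario(n_trials=300, seed=9)
        m1, t1 = tp.generate_corpus(sc)
        m2, t2 = tp.generate_corpus(sc)
        pd.testing.assert_frame_equal(t1, t2)
        pd.testing.assert_frame_equal(m1, m2)

    def test_different_seeds_differ(self):
        t1 = tp.generate_corpus(tp.default_scenario(n_trials=300, seed=1))[1]
        t2 = tp.generate_corpus(tp.default_scenario(n_trials=300, seed=2))[1]
        assert not t1.equals(t2)

    def test_combination_point_mass(self):
        sc = tp.default_scenario(n_trials=400, seed=3).replace(
            combination_probs={"FF": 0.0, "MM": 1.0, "FM": 0.0, "MF": 0.0,
                               "unknown": 0.0},
            name_missing_rate=0.0)
        _, trials = tp.generate_corpus(sc)
        asn = tp.assign_genders(trials, tp.NameTable.bundled())
        assert (asn["combination"] == "MM").all()

    def test_tau_zero_shares_effect_within_meta(self):
        sc = tp.default_scenario(n_trials=400, seed=4).replace(tau=0.0)
        _, _, truth = tp.generate_with_truth(sc)
        assert np.allclose(truth["true_effect"], truth["meta_true_effect"])

    def test_corpus_schema_and_invariants(self, planted_small):
        trials = planted_small["trials"]
        assert list(trials.columns) == [
            "trial_id", "meta_id", "year", "measure", "n1", "n2", "events1",
            "events2", "mean1", "sd1", "mean2", "sd2", "first_author_name",
            "last_author_name", "country", "discipline"]
        assert (trials["n1"] >= 2).all() and (trials["n2"] >= 2).all()
        binary = trials["measure"].isin(["OR", "RR", "RD"])
        assert (trials.loc[binary, "events1"] >= 0).all()
        assert (trials.loc[binary, "events1"] <= trials.loc[binary, "n1"]).all()
        assert (trials.loc[binary, "events2"] <= trials.loc[binary, "n2"]).all()
        assert trials.loc[binary, ["mean1", "sd1"]].isna().all().all()
        smd = ~binary
        assert (trials.loc[smd, "sd1"] > 0).all()
        assert trials.loc[smd, ["events1", "events2"]].isna().all().all()

    def test_planted_round_trip_reproduces_flags(self, planted_small):
        joined = planted_small["truth"].merge(
            planted_small["power_results"], on="trial_id")
        ok = np.isfinite(joined["power"])
        agreement = (joined.loc[ok, "adequate_80"]
                     == joined.loc[ok, "adequate"]).mean()
        assert agreement >= 0.99
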