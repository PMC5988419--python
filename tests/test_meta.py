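"""Pooling, significance screening and true-effect selection."""

import numpy as np
import pandas as pd
import pytest

from trialpower.meta import (assign_true_effects, dersimonian_laird,
                             is_significant, pool_fixed, summarize_metas,
                             trial_estimates, trial_true_effect)


class TestPoolFixed:
    def test_single_study_identity(self):
        assert pool_fixed([0.4], [0.1]) == pytest.approx((0.4, 0.1))

    def test_equal_weights_give_mean(self):
        pooled, se = pool_fixed([0.5, 1.0], [0.5, 0.5])
        assert pooled == pytest.approx(0.75)
        assert se == pytest.approx(0.5 / np.sqrt(2))

    def test_hand_computed_weights(self):
        pooled, se = pool_fixed([0.2, 0.8], [0.1, 0.3])
        assert pooled == pytest.approx(0.26, abs=1e-10)
        assert se == pytest.approx(0.0949, abs=1e-4)

    def test_pooled_within_range_and_se_below_min(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            est = rng.normal(size=5)
            ses = rng.uniform(0.05, 0.5, size=5)
            pooled, se = pool_fixed(est, ses)
            assert est.min() - 1e-12 <= pooled <= est.max() + 1e-12
            assert se <= ses.min()

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            pool_fixed([], [])


class TestDersimonianLaird:
    def test_homogeneous_gives_tau2_zero(self):
        pooled, se, tau2 = dersimonian_laird([0.3, 0.3, 0.3], [0.1, 0.2, 0.1])
        assert tau2 == 0.0
        assert pooled == pytest.approx(0.3)

    def test_truncation_reduces_to_fixed_effect(self):
        est, ses = [0.30, 0.32], [0.3, 0.3]   # Q < k-1
        assert dersimonian_laird(est, ses)[:2] == pytest.approx(pool_fixed(est, ses))

    def test_hand_evaluated_heterogeneous_case(self):
        # w=100 each, FE=0.5, Q=50, tau2=(50-1)/(200-100)=0.49
        pooled, se, tau2 = dersimonian_laird([0.0, 1.0], [0.1, 0.1])
        assert tau2 == pytest.approx(0.49)
        assert pooled == pytest.approx(0.5)
        assert se == pytest.approx(1 / np.sqrt(2 * 1 / (0.01 + 0.49)))

    def test_single_study_raises(self):
        with pytest.raises(ValueError):
            dersimonian_laird([0.1], [0.1])


class TestSignificance:
    def test_null_not_significant(self):
        assert not is_significant(0.0, 0.2)

    def test_boundary(self):
        assert is_significant(1.96001 * 0.1, 0.1)
        assert not is_significant(1.9599 * 0.1, 0.1)

    def test_hand_computed_z(self):
        assert is_significant(0.26, 0.0949)   # z ~ 2.74, p ~ 0.006


def _toy_trials():
    return pd.DataFrame({
        "trial_id": ["a", "a", "b", "c"],
        "meta_id": ["m1", "m2", "m1", "m3"],
        "measure": ["OR"] * 4,
        "n1": [100, 400, 100, 60], "n2": [100, 400, 100, 60],
        "events1": [20, 80, 25, 10], "events2": [40, 160, 45, 11],
        "mean1": np.nan, "sd1": np.nan, "mean2": np.nan, "sd2": np.nan,
    })


class TestTrialEstimates:
    def test_log_or_matches_hand_computation(self):
        est = trial_estimates(_toy_trials())
        row = est.iloc[0]
        assert row["estimate"] == pytest.approx(
            np.log((40 / 60) / (20 / 80)))
        assert row["se"] == pytest.approx(
            np.sqrt(1 / 20 + 1 / 80 + 1 / 40 + 1 / 60))

    def test_zero_cell_gets_continuity_correction(self):
        t = _toy_trials().iloc[[0]].assign(events1=0)
        est = trial_estimates(t)
        assert np.isfinite(est["estimate"]).all()
        assert np.isfinite(est["se"]).all()

    def test_smd_cohens_d(self):
        t = pd.DataFrame({
            "trial_id": ["s"], "meta_id": ["m"], "measure": ["SMD"],
            "n1": [50], "n2": [50], "events1": [np.nan], "events2": [np.nan],
            "mean1": [0.0], "sd1": [1.0], "mean2": [0.5], "sd2": [1.0],
        })
        est = trial_estimates(t)
        assert est["estimate"].iloc[0] == pytest.approx(0.5)
        assert est["se"].iloc[0] == pytest.approx(
            np.sqrt(100 / 2500 + 0.25 / 200))


class TestTrueEffectSelection:
    def test_single_membership_takes_that_pool(self):
        trials = _toy_trials()
        metas = summarize_metas(trials)
        memberships = trial_estimates(trials)
        out = assign_true_effects(memberships, metas)
        b = out[out["trial_id"] == "b"].iloc[0]
        assert b["source_meta"] == "m1"
        assert b["true_effect"] == pytest.approx(
            metas.set_index("meta_id").loc["m1", "pooled"])

    def test_max_weight_rule_prefers_dominant_membership(self):
        trials = _toy_trials()
        metas = summarize_metas(trials)
        memberships = trial_estimates(trials)
        # trial "a" sits in m1 (weight fraction ~1/2) and m2 (alone: 1.0)
        out = assign_true_effects(memberships, metas)
        assert out[out["trial_id"] == "a"].iloc[0]["source_meta"] == "m2"
        effect, src = trial_true_effect("a", memberships, metas)
        assert src == "m2"

    def test_trial_only_in_nonsignificant_meta_is_excluded(self):
        trials = _toy_trials()
        metas = summarize_metas(trials)
        assert not metas.set_index("meta_id").loc["m3", "significant"]
        out = assign_true_effects(trial_estimates(trials), metas)
        assert np.isnan(out[out["trial_id"] == "c"].iloc[0]["true_effect"])

    def test_first_rule(self):
        trials = _toy_trials()
        metas = summarize_metas(trials)
        out = assign_true_effects(trial_estimates(trials), metas, rule="first")
        assert out[out["trial_id"] == "a"].iloc[0]["source_meta"] == "m1"
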