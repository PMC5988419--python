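import numpy as np
import pandas as pd
import pytest

import trialpower as tp
from trialpower import cohort as cohort_mod
from trialpower import gender as gender_mod
from trialpower import meta as meta_mod
from trialpower import power as power_mod


def run_planted(scenario):
    """Full downstream pass over a planted corpus; returns all stage outputs."""
    metas, trials, truth = tp.generate_with_truth(scenario)
    meta_results = meta_mod.summarize_metas(trials)
    memberships = meta_mod.trial_estimates(trials)
    effects = meta_mod.assign_true_effects(memberships, meta_results)
    power_results = power_mod.compute_trial_power(trials, effects)
    assignments = gender_mod.assign_genders(trials, gender_mod.NameTable.bundled())
    analysis, unknown_kept, flow = cohort_mod.build_cohort(
        trials, power_results, assignments)
    return {
        "scenario": scenario, "metas": metas, "trials": trials, "truth": truth,
        "meta_results": meta_results, "power_results": power_results,
        "assignments": assignments, "analysis": analysis,
        "unknown_kept": unknown_kept, "flow": flow,
    }


@pytest.fixture(scope="session")
def planted_small():
    """A 3,000-trial planted corpus with the published coefficients."""
    return run_planted(tp.paper_fit_scenario(seed=11).replace(n_trials=3000))


@pytest.fixture(scope="session")
def planted_fit(planted_small):
    return tp.analyze_cohort(planted_small["analysis"])


@pytest.fixture(scope="session")
def toy_cohort():
    """Small hand-built cohort covering every factor with both outcomes."""
    rng = np.random.default_rng(5)
    n = 400
    from trialpower.scenario import DISCIPLINES
    combos = rng.choice(["FF", "MM", "FM", "MF"], size=n)
    groups = rng.choice(["Anglosphere", "Europe", "Non-western"], size=n)
    disc = rng.choice(DISCIPLINES[:4], size=n)
    year = rng.integers(1980, 2016, size=n)
    eta = -1.5 + 0.5 * (combos == "MF") + 0.02 * (year - 1980)
    adequate = rng.random(n) < 1 / (1 + np.exp(-eta))
    return pd.DataFrame({
        "trial_id": [f"T{i}" for i in range(n)],
        "combination": combos, "year": year,
        "period": [cohort_mod.period(int(y)) for y in year],
        "country": "United States", "country_group": groups,
        "discipline": disc, "adequate_80": adequate,
        "first_gender": [c[0] for c in combos],
        "last_gender": [c[1] for c in combos],
        "power": rng.random(n),
    })
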