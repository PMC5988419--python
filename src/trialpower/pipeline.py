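"""End-to-end pipeline: simulate -> pool -> power -> gender -> cohort -> model.

A :class:`RunConfig` drives one reproducible run; every intermediate table
is written as CSV under the output directory together with a manifest of
checksums, the seed and package versions.  All randomness flows from the
scenario seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, cohort as cohort_mod, gender as gender_mod
from . import meta as meta_mod, power as power_mod, simulate as sim_mod
from .glm import AdequacyLogit, SeparationError
from .scenario import SyntheticScenario, default_scenario

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "analyze_cohort"]


@dataclasses.dataclass
class RunConfig:
    scenario: SyntheticScenario | None = None
    cutoffs: tuple[float, ...] = (0.7, 0.8, 0.9)
    primary_cutoff: float = 0.8
    pooling_model: str = "dl"            # "dl" or "fixed"
    dedup_rule: str = "max_weight"       # or "first"
    country_mode: str = "grouped"
    out_dir: str | Path = "trialpower_run"
    profile_ci: bool = True
    log_level: str = "INFO"

    def __post_init__(self):
        if self.scenario is None:
            self.scenario = default_scenario()
        if not all(0.0 < c < 1.0 for c in self.cutoffs):
            raise ValueError("cutoffs must lie in (0, 1)")
        if self.primary_cutoff not in self.cutoffs:
            raise ValueError("primary_cutoff must be one of the cutoffs")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def analyze_cohort(cohort: pd.DataFrame, cutoff: float = 0.8,
                   country_mode: str = "grouped", profile: bool = True):
    """Fit the adequacy model on a cohort; returns the results object."""
    model = AdequacyLogit.from_cohort(cohort, country_mode=country_mode,
                                      cutoff=cutoff)
    return model.fit()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scenario = config.scenario
    stage = "simulate"
    try:
        metas_true, trials = sim_mod.generate_corpus(scenario)
        trials.to_csv(out / "trials.csv", index=False)
        metas_true.to_csv(out / "meta_analyses.csv", index=False)
        (out / "scenario.json").write_text(json.dumps(
            dataclasses.asdict(scenario), indent=2, default=str))

        stage = "pool"
        meta_results = meta_mod.summarize_metas(trials, model=config.pooling_model)
        meta_results.to_csv(out / "meta_results.csv", index=False)

        stage = "power"
        memberships = meta_mod.trial_estimates(trials)
        effects = meta_mod.assign_true_effects(memberships, meta_results,
                                               rule=config.dedup_rule)
        power_results = power_mod.compute_trial_power(
            trials, effects, cutoffs=config.cutoffs)
        power_results.to_csv(out / "power_results.csv", index=False)

        stage = "gender"
        assignments = gender_mod.assign_genders(trials, gender_mod.NameTable.bundled())
        assignments.to_csv(out / "gender_assignments.csv", index=False)

        stage = "cohort"
        analysis, unknown_kept, flow = cohort_mod.build_cohort(
            trials, power_results, assignments)
        analysis.to_csv(out / "cohort.csv", index=False)
        unknown_kept.to_csv(out / "cohort_with_unknown.csv", index=False)
        flow.to_csv(out / "flow.csv", index=False)

        stage = "report"
        _write_reports(out, analysis, unknown_kept, config.primary_cutoff)

        stage = "analyze"
        results = analyze_cohort(analysis, cutoff=config.primary_cutoff,
                                 country_mode="grouped")
        results.to_table(profile=config.profile_ci).to_csv(
            out / "table1.csv", index=False)
        chi2, df, p = results.lr_test_vs_null()
        wchi2, wdf, wp = results.wald_test_factor("combination")
        summary = {
            "n_obs": results.n_obs,
            "lr_chi2": chi2, "lr_df": df, "lr_p": p,
            "combination_wald_chi2": wchi2, "combination_wald_df": wdf,
            "combination_wald_df_levels": results.last_factor_df_levels,
            "combination_wald_p": wp,
            "converged": results.converged,
        }
        try:
            sens = analyze_cohort(analysis, cutoff=config.primary_cutoff,
                                  country_mode="individual")
            sens.to_table(profile=False).to_csv(out / "table2.csv", index=False)
            summary["sensitivity_lr_df"] = sens.lr_test_vs_null()[1]
        except (SeparationError, ValueError) as exc:
            log.warning("country sensitivity model skipped: %s", exc)
            summary["sensitivity_error"] = str(exc)
        (out / "model_summary.json").write_text(json.dumps(summary, indent=2))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "seed": scenario.seed,
        "n_trials": int(scenario.n_trials),
        "mode": scenario.mode,
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "files": {p.name: _sha256(p) for p in sorted(out.glob("*.csv"))},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _write_reports(out: Path, analysis: pd.DataFrame,
                   unknown_kept: pd.DataFrame, cutoff: float) -> None:
    """Per-figure proportion tables (adequacy and composition views)."""
    pt = cohort_mod.proportion_table
    pt(analysis, ["combination"], cutoff).to_csv(out / "fig1a.csv", index=False)
    pt(analysis, ["combination", "period"], cutoff).to_csv(
        out / "fig1a_periods.csv", index=False)
    pt(unknown_kept, ["combination"], cutoff).to_csv(out / "fig1c.csv", index=False)
    fig2 = pd.concat([
        pt(unknown_kept, ["first_gender"], cutoff).assign(position="first")
          .rename(columns={"first_gender": "gender"}),
        pt(unknown_kept, ["last_gender"], cutoff).assign(position="last")
          .rename(columns={"last_gender": "gender"}),
    ], ignore_index=True)
    fig2.to_csv(out / "fig2.csv", index=False)
    pt(analysis, ["combination", "country_group"], cutoff).to_csv(
        out / "fig4a.csv", index=False)
    pt(analysis, ["combination", "discipline"], cutoff).to_csv(
        out / "fig5.csv", index=False)
    pt(analysis, ["combination", "discipline"], cutoff,
       mode="composition").to_csv(out / "fig6.csv", index=False)
    pt(analysis, ["combination", "period"], cutoff,
       mode="composition").to_csv(out / "fig7.csv", index=False)
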