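"""Synthetic Cochrane-like corpus generator.

Produces meta-analyses of two-arm trials (binary or standardized-mean-
difference outcomes) with author names, countries, disciplines and years,
in two modes:

* **mechanistic** — arm sizes are drawn from a log-normal, outcomes from the
  trial's true effect; adequacy emerges from the data.
* **planted** — the user supplies the true log-odds of the adequacy
  logistic model.  Each trial's adequacy flag is a Bernoulli draw from that
  model and the trial's (equal) arm sizes are then chosen by *power
  inversion* so that the downstream pipeline — DerSimonian-Laird pooling,
  power at the pooled estimate and the observed control risk, strict
  classification at the cutoff — reproduces the flag.  Because the pooled
  estimate is itself a function of the generated data, the generator
  iterates a frozen-quantile fixed point: outcome draws use fixed uniform
  quantiles so that re-inverting sample sizes against the *realized* pooled
  estimate converges, followed by a final local adjustment of n.  Outcomes
  are always genuine binomial (or normal-theory) draws; only sample sizes
  are manipulated.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import meta as meta_mod
from . import power as power_mod
from .cohort import load_country_table
from .gender import NameTable
from .scenario import KNOWN_COMBINATIONS, SyntheticScenario, _year_probs

__all__ = [
    "generate_corpus",
    "generate_with_truth",
    "invert_power_for_n",
    "plant_adequacy",
    "linear_predictor",
]

N_CAP = 300_000
TRIAL_COLUMNS = ["trial_id", "meta_id", "year", "measure", "n1", "n2",
                 "events1", "events2", "mean1", "sd1", "mean2", "sd2",
                 "first_author_name", "last_author_name", "country",
                 "discipline"]


# ---------------------------------------------------------------- inversion

def _power_vec(measure: str, theta, p1, n, alpha):
    """Power at equal arm sizes n, tolerant of edge treated risks."""
    n = np.asarray(n, dtype=float)
    if measure == "SMD":
        return power_mod.power_smd(theta, n, n, alpha)
    p2 = power_mod.treated_risk(measure, theta, p1, strict=False)
    p2 = np.clip(p2, 1e-9, 1 - 1e-9)
    se = power_mod._binary_se(measure, p1, p2, n, n)
    z_crit = stats.norm.ppf(1 - alpha / 2)
    z = np.abs(theta) / se
    from scipy.special import ndtr
    return ndtr(z - z_crit) + ndtr(-z - z_crit)


def _invert_n_vec(measure: str, theta, p1, target, alpha=0.05, n_cap=N_CAP):
    """Smallest integer n (equal arms) with power >= target, per element.

    Monotone bisection; capped at ``n_cap`` when the target is unreachable.
    """
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    target = np.atleast_1d(np.asarray(target, dtype=float))
    p1 = np.atleast_1d(np.asarray(p1, dtype=float)) if p1 is not None else None
    size = np.broadcast_shapes(theta.shape, target.shape)
    lo = np.full(size, 1, dtype=np.int64)           # invariant: power(lo) < target
    hi = np.full(size, n_cap, dtype=np.int64)       # invariant: power(hi) >= target (or cap)
    top = _power_vec(measure, theta, p1, hi, alpha)
    reachable = top >= target
    while True:
        gap = hi - lo
        if int(gap.max()) <= 1:
            break
        mid = lo + gap // 2
        pw = _power_vec(measure, theta, p1, mid, alpha)
        ge = pw >= target
        lo = np.where(ge, lo, mid)
        hi = np.where(ge, mid, hi)
    out = np.where(reachable, hi, n_cap)
    return np.maximum(out, 2)


def invert_power_for_n(measure, true_effect, control_risk, target_power,
                       alpha=0.05):
    """Smallest per-arm n whose computed power reaches ``target_power``.

    Equal arms; ``true_effect`` on the pooling scale.  Raises for a null
    effect (no finite n) or a target outside (alpha, 1).
    """
    if not alpha < target_power < 1.0:
        raise ValueError("target_power must lie strictly between alpha and 1")
    if measure == "SMD":
        if true_effect == 0.0:
            raise ValueError("null effect: power never exceeds alpha")
    else:
        if true_effect == 0.0:
            raise ValueError("null effect: power never exceeds alpha")
    n = int(_invert_n_vec(measure, true_effect, control_risk, target_power,
                          alpha=alpha)[0])
    # local scan guards the integer boundary
    while n > 2 and float(_power_vec(measure, true_effect, control_risk,
                                     n - 1, alpha)) >= target_power:
        n -= 1
    return n


# ------------------------------------------------------------- planted draw

def linear_predictor(combination, year, country_group, discipline,
                     coefficients: dict[str, float], first_year: int):
    """Planted log-odds of adequacy for vectors of covariates."""
    eta = np.full(len(np.atleast_1d(year)), coefficients.get("intercept", 0.0))
    eta = eta + coefficients.get("year", 0.0) * (np.asarray(year) - first_year)
    for arr, prefix in ((combination, "combination"),
                        (country_group, "country_group"),
                        (discipline, "discipline")):
        s = pd.Series(np.asarray(arr, dtype=object))
        eta = eta + s.map(lambda v, p=prefix: coefficients.get(f"{p}={v}", 0.0)
                          ).to_numpy(dtype=float)
    return eta


def plant_adequacy(covariates: pd.DataFrame, planted_coefficients: dict,
                   cutoff: float, rng: np.random.Generator,
                   first_year: int | None = None):
    """Draw adequacy flags and target powers from the planted logistic model.

    ``covariates`` needs combination, year, country_group, discipline.
    Returns (adequate flags, target powers); targets are uniform in
    (cutoff, 0.99] for adequate trials and [0.06, cutoff) otherwise, so a
    subsequent power inversion places each trial on the correct side.
    """
    if first_year is None:
        first_year = int(covariates["year"].min())
    eta = linear_predictor(covariates["combination"], covariates["year"],
                           covariates["country_group"],
                           covariates["discipline"],
                           planted_coefficients, first_year)
    p = 1.0 / (1.0 + np.exp(-eta))
    adequate = rng.random(len(p)) < p
    u = rng.random(len(p))
    target = np.where(adequate,
                      cutoff + u * (0.99 - cutoff) + 1e-6,
                      0.06 + u * (cutoff - 0.06 - 1e-6))
    return adequate, target


# ------------------------------------------------------------------ helpers

def _draw_categorical(rng, probs: dict, size: int) -> np.ndarray:
    keys = np.array(list(probs.keys()), dtype=object)
    p = np.array(list(probs.values()), dtype=float)
    return rng.choice(keys, size=size, p=p / p.sum())


def _name_pools(table: NameTable):
    female, male, ambiguous = [], [], []
    for name, (p, _) in sorted(table._table.items()):
        if p > 0.5:
            female.append(name.title())
        elif p < 0.5:
            male.append(name.title())
        else:
            ambiguous.append(name.title())
    return np.array(female), np.array(male), np.array(ambiguous)


def _assemble_names(rng, latent_combo, unknown_mask, miss_rate, table):
    """Author names realizing the latent combination / unknown status."""
    n = len(latent_combo)
    female, male, ambiguous = _name_pools(table)
    first = np.empty(n, dtype=object)
    last = np.empty(n, dtype=object)
    g_first = np.array([c[0] for c in latent_combo])
    g_last = np.array([c[1] for c in latent_combo])
    for arr, g in ((first, g_first), (last, g_last)):
        fem = g == "F"
        arr[fem] = rng.choice(female, size=int(fem.sum()))
        arr[~fem] = rng.choice(male, size=int((~fem).sum()))
    # obscure authors of unknown trials: at least one of the two
    r1 = rng.random(n) < miss_rate
    r2 = rng.random(n) < miss_rate
    neither = unknown_mask & ~r1 & ~r2
    pick_first = rng.random(n) < 0.5
    r1 = r1 | (neither & pick_first)
    r2 = r2 | (neither & ~pick_first)
    how = rng.random(n)
    for arr, robs in ((first, unknown_mask & r1), (last, unknown_mask & r2)):
        idx = np.flatnonzero(robs)
        for i in idx:
            if how[i] < 0.8:
                arr[i] = ""                      # missing first name
            elif how[i] < 0.9 or len(ambiguous) == 0:
                arr[i] = f"Zz{i % 97:02d}"       # absent from the table
            else:
                arr[i] = rng.choice(ambiguous)   # exact 0.5 tie
    return first, last


def _binary_data(u1, u2, n, p1, p2):
    e1 = stats.binom.ppf(u1, n, p1).astype(np.int64)
    e2 = stats.binom.ppf(u2, n, p2).astype(np.int64)
    return e1, e2


def _smd_data(z1, z2, uv1, uv2, n, d):
    """Summary statistics of two normal arms (sigma=1, shift d)."""
    n = np.asarray(n, dtype=float)
    mean1 = z1 / np.sqrt(n)
    mean2 = d + z2 / np.sqrt(n)
    sd1 = np.sqrt(stats.chi2.ppf(uv1, n - 1) / (n - 1))
    sd2 = np.sqrt(stats.chi2.ppf(uv2, n - 1) / (n - 1))
    return mean1, sd1, mean2, sd2


# ------------------------------------------------------------ main generator

def generate_corpus(scenario: SyntheticScenario):
    """Generate (meta_analyses, trials) tables for a scenario."""
    metas, trials, _ = generate_with_truth(scenario)
    return metas, trials


def generate_with_truth(scenario: SyntheticScenario):
    """Generate the corpus plus the per-trial ground-truth table.

    Returns (meta_analyses, trials, truth); truth carries the latent
    combination, the planted adequacy flag and target power (planted mode),
    and the per-trial true effect.
    """
    if scenario.mode == "planted" and not scenario.planted_coefficients:
        raise ValueError("planted mode requires planted_coefficients")
    rng = np.random.default_rng(scenario.seed)
    n_tr = scenario.n_trials

    # --- partition into meta-analyses
    kmin, kmean = scenario.trials_per_meta
    sizes = []
    total = 0
    while total < n_tr:
        k = kmin + rng.poisson(max(kmean - kmin, 0.0))
        sizes.append(int(k))
        total += k
    sizes[-1] -= total - n_tr
    if sizes[-1] < 1:
        sizes.pop()
    sizes = np.array(sizes)
    n_tr = int(sizes.sum())
    n_meta = len(sizes)
    meta_idx = np.repeat(np.arange(n_meta), sizes)

    # --- per-meta measure and true pooled effect
    measure_meta = _draw_categorical(rng, scenario.measure_mix, n_meta)
    theta_meta = np.empty(n_meta)
    for m, (mu, sd) in scenario.true_effect_dist.items():
        mask = measure_meta == m
        theta_meta[mask] = rng.normal(mu, sd, size=int(mask.sum()))
    measure_trial = measure_meta[meta_idx]
    theta_trial = theta_meta[meta_idx] + rng.normal(0.0, scenario.tau, size=n_tr)

    # --- per-trial covariates
    years = np.arange(scenario.year_range[0], scenario.year_range[1] + 1)
    year = rng.choice(years, size=n_tr, p=_year_probs(scenario.year_range))
    country = _draw_categorical(rng, scenario.country_probs, n_tr)
    discipline = _draw_categorical(rng, scenario.discipline_probs, n_tr)
    latent_combo = _draw_categorical(rng, scenario.known_combination_probs(), n_tr)
    unknown = rng.random(n_tr) < scenario.combination_probs.get("unknown", 0.0)

    # --- control risks, truncated so trial-level treated risks stay valid
    a, b = scenario.baseline_risk_dist
    p1 = np.clip(rng.beta(a, b, size=n_tr), 0.05, 0.60)
    rr = measure_trial == "RR"
    p1[rr] = np.minimum(p1[rr], 0.90 / np.exp(theta_trial[rr]))
    rd = measure_trial == "RD"
    p1[rd] = np.minimum(p1[rd], 0.90 - theta_trial[rd])
    p1 = np.clip(p1, 0.02, 0.95)

    ctable = load_country_table()
    cgroup = np.array([ctable.get(c, "Non-western") for c in country], dtype=object)

    # --- frozen outcome quantiles
    u1, u2 = rng.random(n_tr), rng.random(n_tr)
    z1, z2 = rng.standard_normal(n_tr), rng.standard_normal(n_tr)
    uv1, uv2 = rng.random(n_tr), rng.random(n_tr)

    truth = pd.DataFrame({
        "latent_combination": latent_combo,
        "unknown": unknown,
        "true_effect": theta_trial,
        "meta_true_effect": theta_meta[meta_idx],
    })

    if scenario.mode == "planted":
        cov = pd.DataFrame({"combination": latent_combo, "year": year,
                            "country_group": cgroup, "discipline": discipline})
        adequate, target = plant_adequacy(
            cov, scenario.planted_coefficients, scenario.adequacy_cutoff, rng,
            first_year=int(scenario.year_range[0]))
        n_arm, e1, e2, m1, s1, m2, s2 = _planted_sizes(
            scenario, measure_trial, theta_trial, theta_meta, meta_idx, p1,
            target, adequate, u1, u2, z1, z2, uv1, uv2)
        n1 = n2 = n_arm
        truth["adequate"] = adequate
        truth["target_power"] = target
    else:
        logm, logs, floor = scenario.arm_size_dist
        n1 = np.maximum(np.round(rng.lognormal(logm, logs, n_tr)), floor).astype(np.int64)
        n2 = np.maximum(np.round(rng.lognormal(logm, logs, n_tr)), floor).astype(np.int64)
        binm = measure_trial != "SMD"
        e1 = np.full(n_tr, -1, dtype=np.int64)
        e2 = np.full(n_tr, -1, dtype=np.int64)
        m1 = np.full(n_tr, np.nan)
        s1 = np.full(n_tr, np.nan)
        m2 = np.full(n_tr, np.nan)
        s2 = np.full(n_tr, np.nan)
        for m in ("OR", "RR", "RD"):
            mask = measure_trial == m
            if mask.any():
                p2 = np.clip(power_mod.treated_risk(m, theta_trial[mask],
                                                    p1[mask], strict=False),
                             1e-6, 1 - 1e-6)
                e1[mask] = stats.binom.ppf(u1[mask], n1[mask], p1[mask]).astype(np.int64)
                e2[mask] = stats.binom.ppf(u2[mask], n2[mask], p2).astype(np.int64)
        smd = measure_trial == "SMD"
        if smd.any():
            m1[smd], s1[smd], m2[smd], s2[smd] = _smd_data(
                z1[smd], z2[smd], uv1[smd], uv2[smd], n1[smd], theta_trial[smd])
            # independent arm-2 size for SMD as well
            m2[smd] = theta_trial[smd] + z2[smd] / np.sqrt(n2[smd])

    first, last = _assemble_names(rng, latent_combo, unknown,
                                  scenario.name_missing_rate,
                                  NameTable.bundled())

    width = len(str(n_tr))
    trial_id = np.array([f"T{i:0{width}d}" for i in range(1, n_tr + 1)])
    meta_id = np.array([f"M{j:05d}" for j in meta_idx + 1])
    smd = measure_trial == "SMD"
    trials = pd.DataFrame({
        "trial_id": trial_id,
        "meta_id": meta_id,
        "year": year.astype(int),
        "measure": measure_trial,
        "n1": np.asarray(n1, dtype=np.int64),
        "n2": np.asarray(n2, dtype=np.int64),
        "events1": np.where(smd, np.nan, e1.astype(float)),
        "events2": np.where(smd, np.nan, e2.astype(float)),
        "mean1": m1, "sd1": s1, "mean2": m2, "sd2": s2,
        "first_author_name": first,
        "last_author_name": last,
        "country": country,
        "discipline": discipline,
    })[TRIAL_COLUMNS]
    metas = pd.DataFrame({
        "meta_id": np.array([f"M{j:05d}" for j in range(1, n_meta + 1)]),
        "measure": measure_meta,
        "k": sizes,
        "true_effect": theta_meta,
    })
    truth.insert(0, "trial_id", trial_id)
    return metas, trials, truth


def _pool_by_meta(est, se, meta_idx, n_meta):
    """Vectorised per-meta DerSimonian-Laird pool (fixed-effect for k=1)."""
    w = 1.0 / se**2
    s1 = np.bincount(meta_idx, weights=w, minlength=n_meta)
    swx = np.bincount(meta_idx, weights=w * est, minlength=n_meta)
    fe = swx / s1
    q = np.bincount(meta_idx, weights=w * (est - fe[meta_idx]) ** 2,
                    minlength=n_meta)
    k = np.bincount(meta_idx, minlength=n_meta)
    s2 = np.bincount(meta_idx, weights=w**2, minlength=n_meta)
    with np.errstate(invalid="ignore", divide="ignore"):
        tau2 = np.maximum(0.0, (q - (k - 1)) / (s1 - s2 / s1))
    tau2 = np.where(k >= 2, tau2, 0.0)
    wre = 1.0 / (se**2 + tau2[meta_idx])
    s1re = np.bincount(meta_idx, weights=wre, minlength=n_meta)
    pooled = np.bincount(meta_idx, weights=wre * est, minlength=n_meta) / s1re
    return pooled, 1.0 / np.sqrt(s1re)


def _planted_sizes(scenario, measure_trial, theta_trial, theta_meta, meta_idx,
                   p1_true, target, adequate, u1, u2, z1, z2, uv1, uv2,
                   n_fixed_point=4, n_adjust=3):
    """Equal arm sizes realizing the planted flags under downstream recomputation."""
    n_tr = len(measure_trial)
    n_meta = len(theta_meta)
    cutoff = scenario.adequacy_cutoff
    est = np.empty(n_tr)
    se = np.empty(n_tr)
    e1 = np.full(n_tr, -1, dtype=np.int64)
    e2 = np.full(n_tr, -1, dtype=np.int64)
    m1 = np.full(n_tr, np.nan)
    s1 = np.full(n_tr, np.nan)
    m2 = np.full(n_tr, np.nan)
    s2 = np.full(n_tr, np.nan)
    groups = {m: measure_trial == m for m in ("OR", "RR", "RD", "SMD")}
    groups = {m: g for m, g in groups.items() if g.any()}

    theta_use = theta_meta[meta_idx].copy()
    p1_use = p1_true.copy()
    n_arm = None

    def regen(n_arm, mask_all=None):
        """Deterministic outcome data at the current sizes (frozen quantiles)."""
        for m, g in groups.items():
            mask = g if mask_all is None else (g & mask_all)
            if not mask.any():
                continue
            if m == "SMD":
                m1[mask], s1[mask], m2[mask], s2[mask] = _smd_data(
                    z1[mask], z2[mask], uv1[mask], uv2[mask],
                    n_arm[mask], theta_trial[mask])
            else:
                p2 = np.clip(power_mod.treated_risk(m, theta_trial[mask],
                                                    p1_true[mask], strict=False),
                             1e-6, 1 - 1e-6)
                e1[mask], e2[mask] = _binary_data(u1[mask], u2[mask],
                                                  n_arm[mask], p1_true[mask], p2)

    def estimates(n_arm):
        frame = pd.DataFrame({
            "trial_id": np.arange(n_tr), "meta_id": meta_idx,
            "measure": measure_trial, "n1": n_arm, "n2": n_arm,
            "events1": e1.astype(float), "events2": e2.astype(float),
            "mean1": m1, "sd1": s1, "mean2": m2, "sd2": s2,
        })
        per = meta_mod.trial_estimates(frame)
        return per["estimate"].to_numpy(), per["se"].to_numpy()

    for _ in range(n_fixed_point):
        new_n = np.empty(n_tr, dtype=np.int64)
        for m, g in groups.items():
            new_n[g] = _invert_n_vec(m, theta_use[g],
                                     None if m == "SMD" else p1_use[g],
                                     target[g])
        n_arm = new_n
        regen(n_arm)
        est[:], se[:] = estimates(n_arm)
        pooled, _ = _pool_by_meta(est, se, meta_idx, n_meta)
        theta_use = pooled[meta_idx]
        bin_mask = measure_trial != "SMD"
        p1_use = p1_true.copy()
        p1_use[bin_mask] = power_mod.observed_control_risk(
            e1[bin_mask].astype(float), n_arm[bin_mask].astype(float))

    # final local adjustment: make downstream classification match the flag
    for _ in range(n_adjust):
        pw = np.empty(n_tr)
        for m, g in groups.items():
            pw[g] = _power_vec(m, theta_use[g],
                               None if m == "SMD" else p1_use[g], n_arm[g], 0.05)
        mismatch = (pw > cutoff) != adequate
        if not mismatch.any():
            break
        for m, g in groups.items():
            gm = g & mismatch
            if not gm.any():
                continue
            n_arm[gm] = _invert_n_vec(m, theta_use[gm],
                                      None if m == "SMD" else p1_use[gm],
                                      target[gm])
        regen(n_arm, mismatch)
        est[:], se[:] = estimates(n_arm)
        pooled, _ = _pool_by_meta(est, se, meta_idx, n_meta)
        theta_use = pooled[meta_idx]
        bin_mask = measure_trial != "SMD"
        p1_use[bin_mask] = power_mod.observed_control_risk(
            e1[bin_mask].astype(float), n_arm[bin_mask].astype(float))

    return n_arm, e1, e2, m1, s1, m2, s2
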