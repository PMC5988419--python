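"""Meta-analytic pooling and per-trial true-effect selection.

Trials are pooled per outcome (meta-analysis) by inverse variance, either
fixed-effect or DerSimonian-Laird random-effects.  Only meta-analyses with a
significant pooled estimate (two-sided p < 0.05) contribute a "true effect":
a non-significant pooled estimate is neither reliable nor known, so trials
appearing only in non-significant meta-analyses are excluded from the power
survey.  Effects are pooled on the log scale for OR and RR, and on the
identity scale for RD and SMD.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special

__all__ = [
    "pool_fixed",
    "dersimonian_laird",
    "is_significant",
    "trial_estimates",
    "summarize_metas",
    "trial_true_effect",
    "assign_true_effects",
]


def pool_fixed(estimates, ses):
    """Inverse-variance fixed-effect pool: returns (pooled, se)."""
    est = np.asarray(estimates, dtype=float)
    se = np.asarray(ses, dtype=float)
    if est.size == 0:
        raise ValueError("cannot pool an empty set of estimates")
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    w = 1.0 / se**2
    return float(np.sum(w * est) / np.sum(w)), float(1.0 / np.sqrt(np.sum(w)))


def dersimonian_laird(estimates, ses):
    """DerSimonian-Laird random-effects pool: returns (pooled, se, tau2).

    tau2 is the moment estimator max(0, (Q - (k-1)) / (S1 - S2/S1)) with
    S1 = sum(w), S2 = sum(w^2); when it truncates to zero the result equals
    the fixed-effect pool.
    """
    est = np.asarray(estimates, dtype=float)
    se = np.asarray(ses, dtype=float)
    if est.size < 2:
        raise ValueError("DerSimonian-Laird needs at least two studies")
    w = 1.0 / se**2
    fe = np.sum(w * est) / np.sum(w)
    q = float(np.sum(w * (est - fe) ** 2))
    s1 = float(np.sum(w))
    s2 = float(np.sum(w**2))
    tau2 = max(0.0, (q - (est.size - 1)) / (s1 - s2 / s1))
    w_re = 1.0 / (se**2 + tau2)
    pooled = float(np.sum(w_re * est) / np.sum(w_re))
    return pooled, float(1.0 / np.sqrt(np.sum(w_re))), tau2


def is_significant(pooled, se, alpha=0.05):
    """Two-sided z-test on the pooled estimate: p < alpha."""
    if se <= 0:
        raise ValueError("se must be positive")
    p = 2.0 * special.ndtr(-abs(pooled) / se)
    return bool(p < alpha)


def _haldane(e1, n1, e2, n2):
    """0.5 continuity correction applied to all cells when any cell is zero."""
    zero = (e1 == 0) | (e1 == n1) | (e2 == 0) | (e2 == n2)
    add = 0.5 * zero
    return e1 + add, n1 + 2 * add, e2 + add, n2 + 2 * add


def trial_estimates(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-trial effect estimates and SEs on the pooling scale.

    Input rows follow the corpus schema (measure, n1, n2, events or arm
    summaries).  log OR / log RR use a 0.5 correction on zero cells; the SMD
    is Cohen's d from the pooled SD with the usual large-sample SE.
    """
    measure = trials["measure"].to_numpy()
    n1 = trials["n1"].to_numpy(dtype=float)
    n2 = trials["n2"].to_numpy(dtype=float)
    est = np.full(len(trials), np.nan)
    se = np.full(len(trials), np.nan)

    binary = np.isin(measure, ("OR", "RR", "RD"))
    if binary.any():
        e1 = trials.loc[binary, "events1"].to_numpy(dtype=float)
        e2 = trials.loc[binary, "events2"].to_numpy(dtype=float)
        m1, m2 = n1[binary], n2[binary]
        a1, b1, a2, b2 = _haldane(e1, m1, e2, m2)
        p1, p2 = a1 / b1, a2 / b2
        mm = measure[binary]
        est_b = np.empty(binary.sum())
        se_b = np.empty(binary.sum())
        is_or = mm == "OR"
        est_b[is_or] = (np.log(p2 / (1 - p2)) - np.log(p1 / (1 - p1)))[is_or]
        se_b[is_or] = np.sqrt(
            1 / (b1 * p1 * (1 - p1)) + 1 / (b2 * p2 * (1 - p2))
        )[is_or]
        is_rr = mm == "RR"
        est_b[is_rr] = (np.log(p2) - np.log(p1))[is_rr]
        se_b[is_rr] = np.sqrt((1 - p1) / (b1 * p1) + (1 - p2) / (b2 * p2))[is_rr]
        is_rd = mm == "RD"
        est_b[is_rd] = (p2 - p1)[is_rd]
        se_b[is_rd] = np.sqrt(p1 * (1 - p1) / b1 + p2 * (1 - p2) / b2)[is_rd]
        est[binary] = est_b
        se[binary] = se_b

    smd = measure == "SMD"
    if smd.any():
        mean1 = trials.loc[smd, "mean1"].to_numpy(dtype=float)
        mean2 = trials.loc[smd, "mean2"].to_numpy(dtype=float)
        sd1 = trials.loc[smd, "sd1"].to_numpy(dtype=float)
        sd2 = trials.loc[smd, "sd2"].to_numpy(dtype=float)
        k1, k2 = n1[smd], n2[smd]
        sp = np.sqrt(((k1 - 1) * sd1**2 + (k2 - 1) * sd2**2) / (k1 + k2 - 2))
        d = (mean2 - mean1) / sp
        est[smd] = d
        se[smd] = np.sqrt((k1 + k2) / (k1 * k2) + d**2 / (2 * (k1 + k2)))

    return pd.DataFrame({
        "trial_id": trials["trial_id"].to_numpy(),
        "meta_id": trials["meta_id"].to_numpy(),
        "measure": measure,
        "estimate": est,
        "se": se,
    })


def summarize_metas(trials: pd.DataFrame, model: str = "dl", alpha: float = 0.05) -> pd.DataFrame:
    """Pool every meta-analysis in a trial table.

    Returns one row per meta_id: measure, k, pooled, se, tau2, p_value,
    significant.  ``model`` is "dl" (default) or "fixed"; single-study
    meta-analyses fall back to the fixed-effect identity.
    """
    if model not in ("dl", "fixed"):
        raise ValueError("model must be 'dl' or 'fixed'")
    per = trial_estimates(trials)
    rows = []
    for meta_id, grp in per.groupby("meta_id", sort=True):
        est, se = grp["estimate"].to_numpy(), grp["se"].to_numpy()
        if model == "dl" and len(grp) >= 2:
            pooled, pooled_se, tau2 = dersimonian_laird(est, se)
        else:
            pooled, pooled_se = pool_fixed(est, se)
            tau2 = 0.0
        p = 2.0 * special.ndtr(-abs(pooled) / pooled_se)
        rows.append({
            "meta_id": meta_id,
            "measure": grp["measure"].iloc[0],
            "k": len(grp),
            "pooled": pooled,
            "se": pooled_se,
            "tau2": tau2,
            "p_value": p,
            "significant": bool(p < alpha),
        })
    return pd.DataFrame(rows)


def trial_true_effect(trial_id, memberships: pd.DataFrame, metas: pd.DataFrame,
                      rule: str = "max_weight"):
    """True effect for one trial: pooled estimate of its chosen significant meta.

    A trial appearing in several significant meta-analyses is assigned to the
    one where its inverse-variance weight fraction is largest ("max_weight",
    ties to the smallest meta_id) or to its first occurrence ("first").
    Returns (effect, meta_id), or (nan, None) when the trial is only in
    non-significant meta-analyses.
    """
    table = assign_true_effects(memberships, metas, rule=rule)
    rows = table[table["trial_id"] == trial_id]
    if rows.empty:
        raise KeyError(f"unknown trial {trial_id!r}")
    row = rows.iloc[0]
    if pd.isna(row["true_effect"]):
        return float("nan"), None
    return float(row["true_effect"]), row["source_meta"]


def assign_true_effects(memberships: pd.DataFrame, metas: pd.DataFrame,
                        rule: str = "max_weight") -> pd.DataFrame:
    """Vectorised true-effect assignment for every trial in ``memberships``.

    ``memberships`` is the per-trial estimate table (trial_id, meta_id, se);
    ``metas`` the pooled table from :func:`summarize_metas`.  Only
    significant meta-analyses are eligible sources.
    """
    if rule not in ("max_weight", "first"):
        raise ValueError("rule must be 'max_weight' or 'first'")
    sig = metas[metas["significant"]][["meta_id", "pooled", "se"]].rename(
        columns={"pooled": "true_effect", "se": "pooled_se"})
    cand = memberships.merge(sig, on="meta_id", how="inner", suffixes=("", "_meta"))
    all_ids = memberships["trial_id"].drop_duplicates()
    if cand.empty:
        return pd.DataFrame({"trial_id": all_ids, "true_effect": np.nan,
                             "source_meta": None})
    if rule == "max_weight":
        w = 1.0 / cand["se"].to_numpy() ** 2
        total_w = cand.groupby("meta_id")["se"].transform(lambda s: np.sum(1.0 / s**2))
        cand = cand.assign(_frac=w / total_w.to_numpy())
        cand = cand.sort_values(["trial_id", "_frac", "meta_id"],
                                ascending=[True, False, True])
    picked = cand.drop_duplicates("trial_id")[["trial_id", "true_effect", "meta_id"]]
    picked = picked.rename(columns={"meta_id": "source_meta"})
    out = pd.DataFrame({"trial_id": all_ids}).merge(picked, on="trial_id", how="left")
    return out
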