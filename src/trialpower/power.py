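"""Post-hoc statistical power of individual two-arm trials.

The power of a trial is the probability that its two-sided test rejects the
null at level ``alpha`` when the true effect equals a specified value — here,
the pooled estimate of the meta-analysis the trial belongs to.  Binary
measures (odds ratio, risk ratio, risk difference) use the large-sample
normal approximation on the pooling scale; the standardized mean difference
uses the exact noncentral-t power of the two-sample t-test.

All functions accept scalars or numpy arrays and broadcast.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "power_binary",
    "power_smd",
    "classify_power",
    "observed_control_risk",
    "compute_trial_power",
    "mc_power_oracle",
    "DomainError",
]

BINARY_MEASURES = ("OR", "RR", "RD")
CUTOFFS = (0.7, 0.8, 0.9)


class DomainError(ValueError):
    """Raised when a derived treated-arm risk falls outside (0, 1)."""


def _ndtr(x):
    return special.ndtr(x)


def treated_risk(measure: str, true_effect, control_risk, strict: bool = True):
    """Derive the treated-arm event risk implied by the effect and control risk.

    OR and RR effects are on the log scale; RD on the identity scale.
    With ``strict`` the result must lie in (0, 1); otherwise out-of-range
    values are returned as-is (callers mask them).
    """
    p1 = np.asarray(control_risk, dtype=float)
    theta = np.asarray(true_effect, dtype=float)
    if measure == "OR":
        odds2 = np.exp(theta) * p1 / (1.0 - p1)
        p2 = odds2 / (1.0 + odds2)
    elif measure == "RR":
        p2 = np.exp(theta) * p1
    elif measure == "RD":
        p2 = p1 + theta
    else:
        raise ValueError(f"not a binary measure: {measure!r}")
    if strict and np.any((p2 <= 0.0) | (p2 >= 1.0)):
        raise DomainError(f"derived treated risk outside (0,1) for {measure}")
    return p2


def _binary_se(measure: str, p1, p2, n1, n2):
    q1, q2 = 1.0 - p1, 1.0 - p2
    if measure == "OR":
        var = 1.0 / (n1 * p1 * q1) + 1.0 / (n2 * p2 * q2)
    elif measure == "RR":
        var = q1 / (n1 * p1) + q2 / (n2 * p2)
    else:  # RD
        var = p1 * q1 / n1 + p2 * q2 / n2
    return np.sqrt(var)


def power_binary(measure, true_effect, control_risk, n1, n2, alpha=0.05):
    """Two-sided power for a binary-outcome trial under the normal approximation.

    ``true_effect`` is on the pooling scale (log OR, log RR, or RD).  The
    standard error is the usual large-sample variance evaluated at the
    alternative (control risk and the derived treated risk).

    power = Phi(|theta|/SE - z_{1-a/2}) + Phi(-|theta|/SE - z_{1-a/2})
    """
    p1 = np.asarray(control_risk, dtype=float)
    if np.any((p1 <= 0.0) | (p1 >= 1.0)):
        raise DomainError("control risk must lie strictly inside (0, 1)")
    theta = np.asarray(true_effect, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    p2 = treated_risk(measure, theta, p1)
    se = _binary_se(measure, p1, p2, n1, n2)
    z_crit = stats.norm.ppf(1.0 - alpha / 2.0)
    z_eff = np.abs(theta) / se
    out = _ndtr(z_eff - z_crit) + _ndtr(-z_eff - z_crit)
    return out if out.ndim else float(out)


def power_smd(d, n1, n2, alpha=0.05):
    """Power of the two-sided two-sample t-test for a standardized mean difference.

    Noncentrality lambda = d * sqrt(n1*n2/(n1+n2)), df = n1 + n2 - 2.
    """
    d = np.asarray(d, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    df = n1 + n2 - 2.0
    nc = np.abs(d) * np.sqrt(n1 * n2 / (n1 + n2))
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, df)
    with np.errstate(all="ignore"):
        out = stats.nct.sf(t_crit, df, nc) + stats.nct.cdf(-t_crit, df, nc)
    # scipy's noncentral t loses accuracy (NaN) at large df/noncentrality;
    # fall back to the asymptotic normal power there
    z_crit = stats.norm.ppf(1.0 - alpha / 2.0)
    approx = _ndtr(nc - z_crit) + _ndtr(-nc - z_crit)
    out = np.where(np.isfinite(out), out, approx)
    return out if np.ndim(out) else float(out)


def classify_power(power, cutoff):
    """Adequacy flag: strictly greater than the cutoff."""
    return np.asarray(power) > cutoff if np.ndim(power) else power > cutoff


def observed_control_risk(events1, n1):
    """Observed control-arm risk with a continuity correction at the boundary.

    When the control arm has 0 or n1 events the plug-in risk would give an
    infinite (or zero) variance, so it is replaced by (events1+0.5)/(n1+1).
    """
    e = np.asarray(events1, dtype=float)
    n = np.asarray(n1, dtype=float)
    p = e / n
    boundary = (e <= 0.0) | (e >= n)
    p = np.where(boundary, (e + 0.5) / (n + 1.0), p)
    return p if p.ndim else float(p)


def power_of_trials(trials: pd.DataFrame, effects: np.ndarray, alpha=0.05) -> np.ndarray:
    """Vectorised per-trial power given each trial's assigned true effect.

    ``trials`` uses the corpus schema (measure, n1, n2, events1); ``effects``
    is aligned with its rows and on each measure's pooling scale.  Rows with
    a NaN effect get NaN power.
    """
    power = np.full(len(trials), np.nan)
    measure = trials["measure"].to_numpy()
    n1 = trials["n1"].to_numpy(dtype=float)
    n2 = trials["n2"].to_numpy(dtype=float)
    for m in BINARY_MEASURES:
        mask = (measure == m) & np.isfinite(effects)
        if not mask.any():
            continue
        p1 = observed_control_risk(
            trials.loc[mask, "events1"].to_numpy(dtype=float), n1[mask]
        )
        p2 = treated_risk(m, effects[mask], p1, strict=False)
        valid = (p2 > 0.0) & (p2 < 1.0)
        se = np.where(valid, _binary_se(m, p1, np.clip(p2, 1e-12, 1 - 1e-12),
                                        n1[mask], n2[mask]), np.nan)
        z_crit = stats.norm.ppf(1.0 - alpha / 2.0)
        z_eff = np.abs(effects[mask]) / se
        power[mask] = np.where(valid, _ndtr(z_eff - z_crit) + _ndtr(-z_eff - z_crit), np.nan)
    mask = (measure == "SMD") & np.isfinite(effects)
    if mask.any():
        power[mask] = power_smd(effects[mask], n1[mask], n2[mask], alpha)
    return power


def compute_trial_power(trials: pd.DataFrame, true_effects: pd.DataFrame,
                        alpha=0.05, cutoffs=CUTOFFS) -> pd.DataFrame:
    """Per-trial power results against assigned meta-analytic true effects.

    ``true_effects`` has columns trial_id, true_effect, source_meta (NaN
    effect = trial excluded because it has no significant source).  Returns a
    frame with one row per trial: power, adequacy flags, provenance.
    """
    merged = trials.drop_duplicates("trial_id").merge(true_effects, on="trial_id", how="left")
    eff = merged["true_effect"].to_numpy(dtype=float)
    pw = power_of_trials(merged, eff, alpha=alpha)
    out = pd.DataFrame({
        "trial_id": merged["trial_id"],
        "measure": merged["measure"],
        "power": pw,
        "true_effect_used": eff,
        "source_meta": merged.get("source_meta"),
        "alpha": alpha,
    })
    for c in cutoffs:
        out[f"adequate_{int(round(c * 100))}"] = np.where(
            np.isfinite(pw), pw > c, False
        )
    return out


def mc_power_oracle(measure, true_effect, control_risk, n1, n2,
                    alpha=0.05, reps=100_000, seed=0):
    """Monte-Carlo power estimate by simulating trials and testing each.

    Independent of the analytic formulas: draws arm data at the true
    parameters and applies the standard two-sided Wald test (binary
    measures, 0.5 continuity correction on zero cells) or the pooled
    two-sample t-test (SMD).  Returns (power, binomial SE).
    """
    rng = np.random.default_rng(seed)
    z_crit = stats.norm.ppf(1.0 - alpha / 2.0)
    if measure in BINARY_MEASURES:
        p1 = float(control_risk)
        p2 = float(treated_risk(measure, true_effect, p1))
        x1 = rng.binomial(int(n1), p1, size=reps).astype(float)
        x2 = rng.binomial(int(n2), p2, size=reps).astype(float)
        zero = (x1 == 0) | (x1 == n1) | (x2 == 0) | (x2 == n2)
        a1, b1 = x1 + 0.5 * zero, n1 - x1 + 0.5 * zero
        a2, b2 = x2 + 0.5 * zero, n2 - x2 + 0.5 * zero
        m1, m2 = n1 + 1.0 * zero, n2 + 1.0 * zero
        if measure == "OR":
            est = np.log(a2 / b2) - np.log(a1 / b1)
            se = np.sqrt(1 / a1 + 1 / b1 + 1 / a2 + 1 / b2)
        elif measure == "RR":
            est = np.log(a2 / m2) - np.log(a1 / m1)
            se = np.sqrt(1 / a1 - 1 / m1 + 1 / a2 - 1 / m2)
        else:
            r1, r2 = a1 / m1, a2 / m2
            est = r2 - r1
            se = np.sqrt(r1 * (1 - r1) / m1 + r2 * (1 - r2) / m2)
        reject = np.abs(est / se) > z_crit
    elif measure == "SMD":
        d = float(true_effect)
        n1, n2 = int(n1), int(n2)
        m1 = rng.normal(0.0, 1.0 / np.sqrt(n1), size=reps)
        m2 = rng.normal(d, 1.0 / np.sqrt(n2), size=reps)
        v1 = rng.chisquare(n1 - 1, size=reps) / (n1 - 1)
        v2 = rng.chisquare(n2 - 1, size=reps) / (n2 - 1)
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        t = (m2 - m1) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        t_crit = stats.t.ppf(1.0 - alpha / 2.0, n1 + n2 - 2)
        reject = np.abs(t) > t_crit
    else:
        raise ValueError(f"unknown measure {measure!r}")
    p_hat = float(reject.mean())
    return p_hat, float(np.sqrt(p_hat * (1 - p_hat) / reps))
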