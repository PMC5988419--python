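"""Cohort construction and proportion estimates.

Applies the survey's flow filters (published after 1974, member of a
significant meta-analysis, extractable gender for both first and last
author), derives analysis covariates (country group, publication period),
and computes adequacy-proportion tables with Wilson score intervals.
"""

from __future__ import annotations

import logging
import warnings
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "country_group",
    "load_country_table",
    "country_sensitivity_levels",
    "period",
    "wilson_ci",
    "apply_filters",
    "build_cohort",
    "proportion_table",
]

PERIODS = ("1975-1985", "1985-1995", "1995-2005", ">2005")
COUNTRY_GROUPS = ("Anglosphere", "Europe", "Non-western")
OTHER_COUNTRIES = "Other countries"

_country_table_cache: dict[str, str] | None = None


def load_country_table() -> dict[str, str]:
    """Bundled country -> {Anglosphere, Europe, Non-western} classification."""
    global _country_table_cache
    if _country_table_cache is None:
        with resources.as_file(
            resources.files("trialpower") / "data" / "country_groups.csv"
        ) as p:
            df = pd.read_csv(p)
        _country_table_cache = dict(zip(df["country"], df["country_group"]))
    return _country_table_cache


def country_group(country: str) -> str:
    """Classify a country; unlisted countries fall back to Non-western.

    Anglosphere = US, UK, Canada, Australia, New Zealand; Europe excludes the
    UK but includes Ireland; the remainder is Non-western.
    """
    table = load_country_table()
    grp = table.get(country)
    if grp is None:
        log.warning("country %r not in classification table; using Non-western",
                    country)
        return "Non-western"
    return grp


def country_sensitivity_levels(countries, min_count: int = 50) -> pd.Series:
    """Individual-country factor levels, collapsing rare countries.

    Countries with at least ``min_count`` trials keep their own level;
    the rest collapse to "Other countries".
    """
    s = pd.Series(countries, dtype=object)
    counts = s.value_counts()
    keep = set(counts[counts >= min_count].index)
    return s.where(s.isin(keep), OTHER_COUNTRIES)


def period(year) -> str:
    """Publication period label; half-open on the left boundary.

    [1975,1985) -> "1975-1985", [1985,1995), [1995,2005), [2005, inf).
    """
    y = np.asarray(year)
    if np.any(y <= 1974):
        raise ValueError("period is defined for years after 1974 only")
    edges = np.array([1985, 1995, 2005])
    idx = np.searchsorted(edges, y, side="right")
    if np.ndim(y) == 0:
        return PERIODS[int(idx)]
    return np.array(PERIODS, dtype=object)[idx]


def wilson_ci(x: int, n: int, conf: float = 0.95):
    """Wilson score interval for a binomial proportion; never leaves [0,1]."""
    x = np.asarray(x, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(n < 1):
        raise ValueError("n must be at least 1")
    if np.any((x < 0) | (x > n)):
        raise ValueError("x must lie in [0, n]")
    z = stats.norm.ppf(0.5 + conf / 2.0)
    p = x / n
    denom = 1.0 + z**2 / n
    center = (p + z**2 / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    lo, hi = center - half, center + half
    # the exact bounds at the boundary counts are 0 and 1; snap rounding noise
    lo = np.where(x == 0, 0.0, np.clip(lo, 0.0, 1.0))
    hi = np.where(x == n, 1.0, np.clip(hi, 0.0, 1.0))
    if np.ndim(lo):
        return lo, hi
    return float(lo), float(hi)


def apply_filters(trials: pd.DataFrame, power_results: pd.DataFrame,
                  assignments: pd.DataFrame):
    """Flow filters: year > 1974, significant true-effect source, known gender.

    Returns (analysis set, unknown-kept set, flow counts).  The unknown-kept
    set retains unknown-combination trials (for the missing-gender
    comparison); the flow table records the count surviving each stage.
    """
    base = trials.drop_duplicates("trial_id")[
        ["trial_id", "year", "measure", "country", "discipline"]
    ]
    merged = base.merge(power_results, on=["trial_id", "measure"], how="left") \
                 .merge(assignments, on="trial_id", how="left")
    stages = [("extracted trials", np.ones(len(merged), dtype=bool))]
    keep = merged["year"].to_numpy() > 1974
    stages.append(("published after 1974", keep))
    keep = keep & np.isfinite(merged["power"].to_numpy(dtype=float))
    stages.append(("in a significant meta-analysis", keep))
    unknown_kept = merged[keep].copy()
    keep_known = keep & (merged["combination"].to_numpy() != "unknown")
    stages.append(("gender known for first and last author", keep_known))
    flow = pd.DataFrame({
        "stage": [s for s, _ in stages],
        "retained": [int(m.sum()) for _, m in stages],
    })
    flow["excluded"] = (-flow["retained"].diff()).fillna(0).astype(int)
    return merged[keep_known].copy(), unknown_kept, flow


def build_cohort(trials, power_results, assignments) -> pd.DataFrame:
    """Analysis-ready cohort with derived covariates.

    One row per retained trial: adequacy flags at each cutoff, author
    combination and genders, year, period, country, country_group,
    discipline.
    """
    analysis, unknown_kept, flow = apply_filters(trials, power_results, assignments)
    table = load_country_table()

    def derive(df):
        df = df.copy()
        df["period"] = period(df["year"].to_numpy())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            df["country_group"] = [table.get(c, "Non-western") for c in df["country"]]
        keep = ["trial_id", "year", "period", "country", "country_group",
                "discipline", "combination", "first_gender", "last_gender",
                "power"] + [c for c in df.columns if c.startswith("adequate_")]
        return df[keep]

    return derive(analysis), derive(unknown_kept), flow


def proportion_table(cohort: pd.DataFrame, group_by, cutoff: float = 0.8,
                     mode: str = "adequacy", conf: float = 0.95) -> pd.DataFrame:
    """Proportion estimates with Wilson intervals per covariate group.

    mode="adequacy": p_hat = adequately powered fraction within each group.
    mode="composition": p_hat = the group's share of all cohort trials.
    Empty groups are omitted.
    """
    if cohort.empty:
        raise ValueError("cohort is empty")
    group_by = list(group_by)
    col = f"adequate_{int(round(cutoff * 100))}"
    if mode == "adequacy" and col not in cohort:
        raise KeyError(f"cohort lacks column {col}")
    grand = len(cohort)
    rows = []
    for key, grp in cohort.groupby(group_by, sort=True, observed=True):
        if not isinstance(key, tuple):
            key = (key,)
        if mode == "adequacy":
            x, n = int(grp[col].sum()), len(grp)
        elif mode == "composition":
            x, n = len(grp), grand
        else:
            raise ValueError("mode must be 'adequacy' or 'composition'")
        lo, hi = wilson_ci(x, n, conf)
        rows.append(dict(zip(group_by, key), x=x, n=n, p_hat=x / n,
                         ci_low=lo, ci_high=hi))
    return pd.DataFrame(rows)
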