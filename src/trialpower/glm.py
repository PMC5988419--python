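"""Multivariable logistic model of trial adequacy.

:class:`AdequacyLogit` fits, by iteratively reweighted least squares, the
logistic regression of "adequately powered" on author combination
(reference: both females), publication year (continuous, centered at the
first cohort year), country (grouped with reference Anglosphere, or
individual countries in the sensitivity analysis) and medical discipline
(reference: allergy & intolerance).  Its :meth:`~AdequacyLogit.fit` returns
an :class:`AdequacyLogitResults` carrying odds ratios, Wald z statistics,
profile-likelihood confidence intervals, the likelihood-ratio test against
the intercept-only model, the factor-level Wald test, and predicted
probabilities averaged across disciplines.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cohort import COUNTRY_GROUPS, country_sensitivity_levels
from .gender import COMBINATIONS
from .scenario import DISCIPLINES

__all__ = ["AdequacyLogit", "AdequacyLogitResults", "SeparationError",
           "build_design"]

COMBINATION_REF = "FF"        # 'both females'
COUNTRY_GROUP_REF = "Anglosphere"
DISCIPLINE_REF = DISCIPLINES[0]   # 'Allergy & intolerance'
SEPARATION_BOUND = 30.0
QUASI_SEPARATION_BOUND = 15.0


class SeparationError(RuntimeError):
    """Complete separation: a coefficient diverges without deviance gain."""


def _dummies(values, levels, ref, prefix, warnings_out):
    """Treatment-coded dummy columns with an explicit reference level."""
    present = [lv for lv in levels if (values == lv).any()]
    dropped = [lv for lv in levels if lv not in present]
    for lv in dropped:
        warnings_out.append(f"{prefix} level {lv!r} has no observations; dropped")
    if ref not in present:
        ref = present[0]
    cols, names = [], []
    for lv in present:
        if lv == ref:
            continue
        cols.append((values == lv).astype(float))
        names.append(f"{prefix}={lv}")
    return cols, names, ref


def build_design(cohort: pd.DataFrame, country_mode: str = "grouped",
                 cutoff: float = 0.8, min_country_count: int = 50):
    """Design matrix, response and term metadata for a cohort.

    Treatment coding with the model's stated reference levels; publication
    year enters centered at the first cohort year.  ``country_mode``
    "individual" uses per-country levels (>=``min_country_count`` trials,
    rest collapsed to "Other countries") with the alphabetically first
    level as reference.
    """
    if cohort.empty:
        raise ValueError("cohort is empty")
    col = f"adequate_{int(round(cutoff * 100))}"
    y = cohort[col].to_numpy(dtype=float)
    first_year = int(cohort["year"].min())
    warnings_out: list[str] = []

    cols = [np.ones(len(cohort))]
    names = ["intercept"]
    combo = cohort["combination"].to_numpy()
    c, n, _ = _dummies(combo, list(COMBINATIONS), COMBINATION_REF,
                       "combination", warnings_out)
    cols += c
    names += n
    cols.append(cohort["year"].to_numpy(dtype=float) - first_year)
    names.append("year")
    if country_mode == "grouped":
        cg = cohort["country_group"].to_numpy()
        c, n, _ = _dummies(cg, list(COUNTRY_GROUPS), COUNTRY_GROUP_REF,
                           "country_group", warnings_out)
        cols += c
        names += n
    elif country_mode == "individual":
        levels = country_sensitivity_levels(cohort["country"].to_numpy(),
                                            min_count=min_country_count)
        uniq = sorted(levels.unique())
        c, n, _ = _dummies(levels.to_numpy(), uniq, uniq[0], "country",
                           warnings_out)
        cols += c
        names += n
    else:
        raise ValueError("country_mode must be 'grouped' or 'individual'")
    disc = cohort["discipline"].to_numpy()
    c, n, _ = _dummies(disc, list(DISCIPLINES), DISCIPLINE_REF, "discipline",
                       warnings_out)
    cols += c
    names += n
    X = np.column_stack(cols)
    return X, y, names, {"first_year": first_year, "warnings": warnings_out,
                         "cutoff": cutoff, "country_mode": country_mode}


def _irls(X, y, offset=None, max_iter=100, tol=1e-10, start=None):
    """Maximum-likelihood logistic fit; returns (beta, deviance, converged)."""
    n, p = X.shape
    beta = np.zeros(p) if start is None else start.copy()
    off = np.zeros(n) if offset is None else offset
    dev_old = np.inf
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta + off, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        z = eta - off + (y - mu) / w
        wx = X * w[:, None]
        beta_new = np.linalg.solve(X.T @ wx, wx.T @ z)
        if np.any(np.abs(beta_new) > SEPARATION_BOUND):
            worst = int(np.argmax(np.abs(beta_new)))
            raise SeparationError(f"coefficient {worst} diverged (complete "
                                  f"separation suspected)")
        beta = beta_new
        dev = _deviance(X, y, beta, off)
        if abs(dev_old - dev) < tol * (abs(dev) + 0.1):
            converged = True
            break
        dev_old = dev
    return beta, _deviance(X, y, beta, off), converged


def _deviance(X, y, beta, offset=0.0):
    eta = np.clip(X @ beta + offset, -30, 30)
    # -2 log-likelihood of the Bernoulli model
    ll = y * eta - np.log1p(np.exp(eta))
    return float(-2.0 * np.sum(ll))


def _null_deviance(y):
    p = y.mean()
    if p in (0.0, 1.0):
        return 0.0
    n = len(y)
    return float(-2.0 * n * (p * np.log(p) + (1 - p) * np.log(1 - p)))


class AdequacyLogit:
    """Logistic model of adequate power on the cohort covariates."""

    def __init__(self, X: np.ndarray, y: np.ndarray, term_names: list[str],
                 info: dict | None = None):
        if X.shape[0] != len(y):
            raise ValueError("X and y disagree on the number of rows")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("design matrix is rank deficient")
        self.X = X
        self.y = y
        self.term_names = list(term_names)
        self.info = info or {}

    @classmethod
    def from_cohort(cls, cohort: pd.DataFrame, country_mode: str = "grouped",
                    cutoff: float = 0.8, min_country_count: int = 50):
        X, y, names, info = build_design(cohort, country_mode=country_mode,
                                         cutoff=cutoff,
                                         min_country_count=min_country_count)
        return cls(X, y, names, info)

    # alias in the from_dataframe idiom
    from_dataframe = from_cohort

    def fit(self, max_iter: int = 100, tol: float = 1e-10) -> "AdequacyLogitResults":
        if len(np.unique(self.y)) < 2:
            raise SeparationError("response is constant; model is degenerate")
        beta, dev, converged = _irls(self.X, self.y, max_iter=max_iter, tol=tol)
        eta = np.clip(self.X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        info_mat = self.X.T @ (self.X * w[:, None])
        cov = np.linalg.inv(info_mat)
        quasi = [self.term_names[j] for j in
                 np.flatnonzero(np.abs(beta) > QUASI_SEPARATION_BOUND)]
        return AdequacyLogitResults(self, beta, cov, dev, converged, quasi)


class AdequacyLogitResults:
    """Estimates, uncertainties and diagnostics of a fitted adequacy model."""

    def __init__(self, model: AdequacyLogit, params, cov_params, deviance,
                 converged, separation_warnings):
        self.model = model
        self.term_names = model.term_names
        self.params = pd.Series(params, index=self.term_names)
        self.cov_params = pd.DataFrame(cov_params, index=self.term_names,
                                       columns=self.term_names)
        self.bse = pd.Series(np.sqrt(np.diag(cov_params)), index=self.term_names)
        self.deviance = deviance
        self.null_deviance = _null_deviance(model.y)
        self.converged = converged
        self.separation_warnings = list(separation_warnings)
        self.n_obs = len(model.y)

    # ------------------------------------------------------------ estimates
    @property
    def odds_ratios(self) -> pd.Series:
        return np.exp(self.params)

    @property
    def wald_z(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(2.0 * stats.norm.sf(np.abs(self.wald_z)),
                         index=self.term_names)

    # ----------------------------------------------------------- model tests
    def lr_test_vs_null(self):
        """(chi2, df, p): deviance drop of the fitted model vs intercept only."""
        chi2 = max(self.null_deviance - self.deviance, 0.0)
        df = len(self.term_names) - 1
        p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
        return chi2, df, p

    def wald_test_factor(self, factor: str = "combination"):
        """Joint Wald test over a factor's coefficient block.

        Returns (chi2, df, p) with df = the number of non-reference dummy
        coefficients.  ``df_levels`` (block size + 1, the number of factor
        levels) is also exposed on the result for comparison with reports
        that count levels rather than contrasts.
        """
        idx = [j for j, t in enumerate(self.term_names)
               if t.startswith(f"{factor}=")]
        if not idx:
            raise ValueError(f"no terms for factor {factor!r}")
        b = self.params.to_numpy()[idx]
        V = self.cov_params.to_numpy()[np.ix_(idx, idx)]
        try:
            chi2 = float(b @ np.linalg.solve(V, b))
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"singular covariance block for factor {factor!r}") from exc
        df = len(idx)
        res = (chi2, df, float(stats.chi2.sf(chi2, df)))
        self.last_factor_df_levels = df + 1
        return res

    # ------------------------------------------------------------ profile CI
    def _profile_deviance(self, j: int, value: float):
        X = self.model.X
        keep = [k for k in range(X.shape[1]) if k != j]
        offset = X[:, j] * value
        start = self.params.to_numpy()[keep]
        _, dev, _ = _irls(X[:, keep], self.model.y, offset=offset,
                          start=start, max_iter=50)
        return dev

    def profile_ci(self, term: str, level: float = 0.95):
        """Profile-likelihood CI on the odds-ratio scale.

        Bounds are where the profiled deviance rises by the chi-square(1)
        quantile above its minimum, found by root search on each side with
        a widening window.
        """
        j = self.term_names.index(term)
        bhat = float(self.params.iloc[j])
        se = float(self.bse.iloc[j])
        crit = stats.chi2.ppf(level, 1)
        dev0 = self.deviance

        def g(v):
            return self._profile_deviance(j, v) - dev0 - crit

        bounds = []
        for sign in (-1.0, +1.0):
            width = 2.0
            root = None
            while width <= 64.0:
                far = bhat + sign * width * se
                if g(far) > 0:
                    lo, hi = sorted((bhat, far))
                    root = optimize.brentq(g, lo, hi, xtol=se * 1e-4)
                    break
                width *= 2.0
            if root is None:
                root = sign * np.inf   # profile never crosses: flagged open bound
            bounds.append(root)
        return float(np.exp(bounds[0])), float(np.exp(bounds[1]))

    def conf_int_profile(self, terms=None, level: float = 0.95) -> pd.DataFrame:
        terms = terms or [t for t in self.term_names if t != "intercept"]
        rows = [self.profile_ci(t, level) for t in terms]
        return pd.DataFrame(rows, index=terms, columns=["ci_low", "ci_high"])

    def conf_int_wald(self, level: float = 0.95) -> pd.DataFrame:
        z = stats.norm.ppf(0.5 + level / 2.0)
        with np.errstate(over="ignore"):   # quasi-separated terms -> inf bound
            lo = np.exp(self.params - z * self.bse)
            hi = np.exp(self.params + z * self.bse)
        return pd.DataFrame({"ci_low": lo, "ci_high": hi})

    # ------------------------------------------------- predicted probabilities
    def predicted_probabilities(self, years, combinations=None,
                                country_groups=None, level: float = 0.95
                                ) -> pd.DataFrame:
        """Mean predicted adequacy probability per (year, combination, group).

        For each grid point the linear predictor is evaluated at every
        discipline level, transformed, and averaged uniformly across
        disciplines; the CI comes from the delta-method SE of that average.
        """
        combinations = combinations or [t.split("=", 1)[1] for t in
                                        self.term_names
                                        if t.startswith("combination=")]
        combinations = sorted(set(combinations) | {COMBINATION_REF}) \
            if COMBINATION_REF not in combinations else combinations
        country_groups = country_groups or list(COUNTRY_GROUPS)
        disc_terms = [t for t in self.term_names if t.startswith("discipline=")]
        n_disc = len(disc_terms) + 1   # + reference discipline
        first_year = self.model.info.get("first_year", int(min(years)))
        z = stats.norm.ppf(0.5 + level / 2.0)
        name_to_idx = {t: j for j, t in enumerate(self.term_names)}
        V = self.cov_params.to_numpy()
        beta = self.params.to_numpy()
        p_dim = len(beta)
        rows = []
        for yr in years:
            for combo in combinations:
                for grp in country_groups:
                    base = np.zeros(p_dim)
                    base[name_to_idx["intercept"]] = 1.0
                    base[name_to_idx["year"]] = yr - first_year
                    t = f"combination={combo}"
                    if t in name_to_idx:
                        base[name_to_idx[t]] = 1.0
                    t = f"country_group={grp}"
                    if t in name_to_idx:
                        base[name_to_idx[t]] = 1.0
                    probs = np.empty(n_disc)
                    grad = np.zeros(p_dim)
                    for d in range(n_disc):
                        x = base.copy()
                        if d > 0:
                            x[name_to_idx[disc_terms[d - 1]]] = 1.0
                        mu = 1.0 / (1.0 + np.exp(-(x @ beta)))
                        probs[d] = mu
                        grad += mu * (1.0 - mu) * x / n_disc
                    mean_p = float(probs.mean())
                    se = float(np.sqrt(grad @ V @ grad))
                    rows.append({"year": yr, "combination": combo,
                                 "country_group": grp, "probability": mean_p,
                                 "ci_low": max(mean_p - z * se, 0.0),
                                 "ci_high": min(mean_p + z * se, 1.0)})
        return pd.DataFrame(rows)

    # ---------------------------------------------------------------- summary
    def summary(self, profile: bool = False, alpha_strict: float = 0.005) -> str:
        chi2, df, p = self.lr_test_vs_null()
        ci = (self.conf_int_profile() if profile else
              self.conf_int_wald().drop(index="intercept"))
        lines = [
            "Adequacy logistic regression",
            f"  n = {self.n_obs}, converged = {self.converged}",
            f"  LR chi2 vs null = {chi2:.1f} (df {df}), p = {p:.3g}",
            f"  deviance = {self.deviance:.1f}, null = {self.null_deviance:.1f}",
            "",
            f"  {'term':<42}{'OR':>8}{'ci_low':>9}{'ci_high':>9}"
            f"{'z':>8}{'p':>11}",
        ]
        for t in self.term_names:
            if t == "intercept":
                continue
            orat = float(np.exp(self.params[t]))
            lo, hi = (ci.loc[t, "ci_low"], ci.loc[t, "ci_high"]) \
                if t in ci.index else (np.nan, np.nan)
            pv = float(self.pvalues[t])
            star = " *" if pv < alpha_strict else ""
            lines.append(f"  {t:<42}{orat:>8.3f}{lo:>9.3f}{hi:>9.3f}"
                         f"{float(self.wald_z[t]):>8.2f}{pv:>11.3g}{star}")
        lines.append("")
        lines.append(f"  * p < {alpha_strict} (strict significance rule)")
        if self.separation_warnings:
            lines.append(f"  quasi-separated terms: {self.separation_warnings}")
        return "\n".join(lines)

    def to_table(self, profile: bool = True) -> pd.DataFrame:
        """Report table: variable, level, odds_ratio, CI, z, p."""
        ci = (self.conf_int_profile() if profile
              else self.conf_int_wald().drop(index="intercept"))
        rows = []
        for t in self.term_names:
            if t == "intercept":
                continue
            var, _, lvl = t.partition("=")
            rows.append({
                "variable": var, "level": lvl or t,
                "odds_ratio": float(np.exp(self.params[t])),
                "ci_low": float(ci.loc[t, "ci_low"]),
                "ci_high": float(ci.loc[t, "ci_high"]),
                "z_value": float(self.wald_z[t]),
                "p_value": float(self.pvalues[t]),
            })
        return pd.DataFrame(rows)
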