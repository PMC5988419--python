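# Methods

## Per-trial power

A trial's post-hoc power is the probability that its two-sided level-α test
rejects the null when the true effect equals the pooled estimate of the
meta-analysis the trial belongs to (α = 0.05 throughout).

**Binary outcomes (OR, RR, RD).** Effects live on the pooling scale (log
odds ratio, log risk ratio, risk difference). Given the trial's control-arm
risk p₁, the treated risk is derived from the effect (OR: p₂ =
OR·p₁/(1−p₁+OR·p₁); RR: p₂ = RR·p₁; RD: p₂ = p₁+θ) and the standard
large-sample variance of the estimator is evaluated *at the alternative*
(log OR: 1/(n₁p₁q₁) + 1/(n₂p₂q₂); log RR: q₁/(n₁p₁) + q₂/(n₂p₂); RD:
p₁q₁/n₁ + p₂q₂/n₂). Then

power = Φ(|θ|/SE − z₀.₉₇₅) + Φ(−|θ|/SE − z₀.₉₇₅).

The control risk is the trial's own observed rate events₁/n₁ — the pooled
estimate fixes the effect, not the baseline, which is trial-specific. When
the control arm is at the boundary (0 or n₁ events) the plug-in rate is
replaced by (events₁+0.5)/(n₁+1) to keep the variance finite.

**Standardized mean difference.** Exact noncentral-t power of the pooled
two-sample t-test: noncentrality λ = d·√(n₁n₂/(n₁+n₂)), df = n₁+n₂−2.
Where scipy's noncentral t loses accuracy (very large df·λ) the asymptotic
normal expression is substituted; both agree to ≪10⁻³ in the overlap.

**Adequacy** is strict: power > cutoff, with cutoffs 0.7/0.8/0.9 and 0.8
primary. Equality at the cutoff has measure zero in practice.

A Monte-Carlo oracle (`mc_power_oracle`) draws arm data at the true
parameters and applies the Wald test (binary; 0.5 continuity correction on
zero cells) or the pooled t-test (SMD). The analytic formulas agree with
the oracle to ±0.01 at moderate information; at very low information
(≈5 expected control events, e.g. risk 0.1 with 50/arm) the normal
approximation genuinely departs from the simulated finite-sample Wald test
by up to ≈0.03 — a known property of the approximation, visible in the
acceptance grid, not an implementation artifact.

Under the alternative-variance convention, power is *not* exactly symmetric
in the sign of a binary effect (negating log OR changes p₂ and hence the
SE); the exact symmetry is arm relabelling, power(θ, p₁, n₁, n₂) =
power(−θ, p₂, n₂, n₁), which the property tests assert. Monotonicity in
|effect| holds on the domain where p₂ stays inside (0,1).

## Pooling and the true-effect proxy

Per-trial estimates use the standard contrasts with a 0.5 continuity
correction on zero cells (binary) and Cohen's d with its large-sample SE
(SMD). Meta-analyses are pooled by DerSimonian–Laird random effects
(fixed-effect by flag); k = 1 degenerates to the single study. Only pooled
estimates with two-sided p < 0.05 serve as true effects — a non-significant
pool is neither reliable nor known. A trial appearing in several
significant meta-analyses takes the one where its inverse-variance weight
fraction is largest (ties: smallest meta id); a "first occurrence" rule is
available. Trials without a significant source are excluded by the flow
filter.

## Gender and cohort

First names map to P(female) through a case-insensitive table; the shipped
`data/synthetic_names.csv` is a **synthetic** stand-in (~190 names with
assigned probabilities, including exact-0.5 ties) — it encodes no real
demographic information. Dichotomization is at 0.5 with exact ties left
unknown (the only symmetric choice); a missing or unlisted name is unknown.
The combination factor is the ordered pair (first, last); any unknown
member makes the combination unknown.

The analysis cohort keeps trials with year ≥ 1975, a significant
true-effect source, and a known combination; a parallel set retains the
unknown-combination trials for the missing-gender comparison. Periods are
half-open on the left ([1975,1985), [1985,1995), [1995,2005), [2005,∞)) —
the printed period labels overlap, so a deterministic convention is
required, and 1985 falls in the second period. Country groups: Anglosphere
= {US, UK, Canada, Australia, New Zealand}; Europe excludes the UK and
includes Ireland; everything else (and any unlisted country, with a logged
warning) is Non-western. The exact Europe membership list is a documented
stand-in. The individual-country sensitivity factor keeps countries with
≥50 trials and collapses the rest to "Other countries".

Proportions are reported with Wilson score intervals,
center (p̂ + z²/2n)/(1+z²/n), half-width z·√(p̂q̂/n + z²/4n²)/(1+z²/n),
whose bounds never leave [0,1] (boundary counts give exactly 0 or 1).

## The adequacy model

`AdequacyLogit` fits logit P(adequate) on combination (reference "both
females"), publication year (continuous, centered at the first cohort year
for conditioning; the per-year OR is unchanged), country group (reference
Anglosphere; or individual countries with an alphabetical reference) and
discipline (reference "Allergy & intolerance"; 31 labels), by IRLS with a
relative-deviance convergence test (tol 10⁻¹⁰). Standard errors come from
the inverse observed information. Empty factor levels are dropped with a
warning. Coefficients exceeding |β| > 30 during iteration raise a
separation error naming the term; converged fits with |β| > 15 are flagged
as quasi-separated (degenerate levels then show OR ≈ 0 with an unbounded
Wald interval, as R's glm would).

Reported per term: OR = exp(β), Wald z, p, and a profile-likelihood 95% CI
— the points where the deviance profiled over the remaining coefficients
rises by χ²₁(0.95) = 3.841, found by a widening bracket plus Brent root
search on each side. Model-level: the LR χ² against the intercept-only
model (grouped mode with all levels present: df = 3 + 1 + 2 + 30 = 36) and
the joint Wald test over the combination block, df = 3 (the number of
non-reference contrasts; the convention that counts levels, df = 4, is
exposed as `last_factor_df_levels` since published reports sometimes print
it). Reports flag P < 0.005 as significant, alongside conventional 0.05.

Predicted probabilities over a (year × combination × country group) grid
average the fitted probability uniformly across all discipline levels; the
CI uses the delta-method SE of that average.

## Synthetic corpora

The generator emulates a Cochrane-like corpus: meta-analyses of
2 + Poisson(mean−2) trials; a measure per meta-analysis (default mix OR
0.45 / RR 0.25 / RD 0.05 / SMD 0.25); a true pooled effect per
meta-analysis (log-scale normals, e.g. log OR ~ N(0.60, 0.15²)) with
between-trial heterogeneity SD τ = 0.05; control risks Beta(2,5) truncated
to keep treated risks valid; publication years 1975–2017 on a linear ramp
(recent years ≈4× the earliest); countries and disciplines from weighted
tables whose group shares are 46.9/32.9/20.2% Anglosphere/Europe/
Non-western. Trials-per-meta and arm-size distributions are stipulations —
no public values exist for them.

**Mechanistic mode** draws arm sizes log-normally (floor 10) and outcomes
binomially (or normal-theory summaries for SMD) at the trial's true effect.

**Planted mode** makes the adequacy logistic model exactly true by
construction: each trial draws a latent combination, covariates, an
adequacy flag ~ Bernoulli(logistic(η)) and a target power (uniform in
(0.8, 0.99] if adequate, [0.06, 0.8) otherwise), and receives equal arm
sizes from power inversion. Because the *downstream* classifier uses the
realized DL pooled estimate and the observed control risk — both functions
of the generated data — inverting against the per-meta true effect would
misclassify far too often (a pooled estimate over mostly-underpowered
trials carries 15–30% relative error). The generator therefore freezes the
outcome quantiles (inverse-CDF binomial/normal draws) and iterates n ←
invert(pooled(data(n)), observed p₁(n), target) to a fixed point (4
rounds), then locally re-adjusts the few trials whose classification still
disagrees (3 rounds). Outcomes remain genuine binomial draws at the true
parameters; only sample sizes are chosen, so downstream power computation
stays honest. Residual disagreement is <1% (integer-n granularity and
unreachable targets at the n = 300,000 cap), and the flags remain exact
Bernoulli draws from the planted model, so coefficient recovery and CI
coverage behave as the model predicts.

`paper_fit_scenario()` plants the published odds ratios at n = 31,873
(1975–2017, cutoff 0.8) and solves the intercept by bisection on the exact
expectation over the discrete covariate grid so the marginal adequacy rate
is 13%. Two of its distributional choices are deliberate departures from
survey realism, made for the scenario's purpose (coefficient recovery):
the known-combination mix is kept balanced-ish (FF 0.22 / MM 0.40 /
FM 0.18 / MF 0.20) and the name-missing rate low (3% per author, ≈6%
unknown), so the analysed cohort stays near the survey scale and every
combination cell is well populated. The mechanistic `default_scenario()`
instead uses the survey-like skew (MM-dominant, ≈70% unknown combinations)
to exercise the flow realistically. Note the recovery SEs this implies
(~0.03–0.05 on the log-OR scale, matching the published CIs): a single
seed's estimate sits within ~7% of the planted OR only with ~85%
probability per term; the profile-CI containment check is the calibrated
statement.

What passing planted-mode tests show: the pipeline's filtering, pooling,
power, classification and modelling are mutually consistent and unbiased
under the generative model. What they do not show: robustness to real-data
features the generator omits — publication bias within reviews, correlated
outcomes per trial, non-random name missingness, country-conditional name
demographics, or misclassified genders.

## Sizes and determinism

All randomness flows from a single integer seed through
`numpy.random.default_rng`; identical scenario + seed reproduce
byte-identical tables (manifest checksums verify this). Default problem
sizes: the recovery run uses the full n = 31,873 corpus (≈10 s end to end
including profile CIs); the CI-coverage study uses 50 seeded replicates at
full scale; unit-level checks use 3,000-trial corpora. The Monte-Carlo
power oracle uses 10⁵ replicates per grid cell.
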