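# Methods

This note documents the statistical models, the synthetic-study
generator, the numerical choices, and the limits of what the test suite
demonstrates.

## Study design being modelled

A paired clutch-enlargement experiment in a precocial shorebird
(Common Ringed Plover as the motivating system): nests with complete
four-egg clutches are paired on estimated laying date; one nest per
pair receives an artificial fifth egg with egg-like thermal properties,
the other serves as control. Defaults follow the field design the
package models: 24 pairs with 2 control nests dropped (46 nests), nests
visited every 2–4 days and daily near the expected hatch, broods
re-found every 2–4 days until fledging (~24 d), and analyses windowed
at ≤ 2 d (hatchlings), ≤ 15 d (growth), ≤ 10 d (survival) and ≤ 22 d
(egg mass loss). All windows are configuration parameters.

Time is measured in float days from a season origin (day 0 = 24 May,
the earliest laying date of the modelled season, so the default mean
laying day 11 is 4 June); laying date is the day the clutch's last egg
was laid.

## Nest survival

The daily survival rate `s` is estimated by maximizing the
interval-censored nest-survival likelihood: an interval of length `t`
observed alive contributes `t·log s`; a terminal failure interval
contributes `log(1 − s^t)`, marginalizing the unknown failure day
rather than assuming the interval midpoint. `s` is logit-linear in an
intercept plus optional date, nest-age and group covariates
(continuous covariates centered at their exposure-weighted means, so
the inverse-logit of the intercept reads as the DSR of an average
nest). Optimization is BFGS on the logit scale with a gradient
tolerance of 1e−8 and a Nelder–Mead polish on non-convergence;
standard errors come from the numerically differentiated Hessian.
All-surviving data sit on the likelihood boundary and are reported as
DSR = 1 with a boundary flag instead of a divergent estimate. The
classical Mayfield estimator (1 − failures/exposure) is kept as a
closed-form cross-check; on unit-interval data the MLE reduces to it
exactly. AICc for DSR models uses total exposure days as the effective
sample size.

Nesting success is `N = DSR^n` at full floating precision, with the
nesting-period length `n` an explicit input: laying-period durations
(defaults 6.5 d control, 8.7 d enlarged) are literature values, not
quantities estimable from these data.

## Egg mass loss

The response is an egg-mass index: measured mass (g) divided by egg
volume (cm³) from `V = 0.47048·L·B² − 0.269` with L, B in cm (the
additive constant makes the formula unit-specific; an mm wrapper is
provided). A fresh egg sits near 1.04 and loses roughly 16% over a
24-day incubation, which matches the scale of the fitted intercept
(1.036) and age slope (−0.007/d). The index interpretation is a design
decision: it puts eggs of different sizes on one scale and makes the
coefficients unit-free; the fitted model is otherwise the standard
one — group, age, age², group × age, group × age², optional centered
laying date, random intercepts for brood and egg-within-brood,
REML via statsmodels MixedLM. Measurements past 22 d of incubation are
excluded (beyond that age only enlarged clutches are still
incubating, so age and group would be confounded).

The generator's variance components (brood SD 0.010, egg SD 0.008,
residual SD 0.006 on the index scale) are chosen as realistic for a
precision balance and ~10 cm³ eggs; no published values exist for
them. Parameter-recovery checks are therefore coverage-based (the
replicate-level 95% CI should contain the generating group × age
coefficient in ≥ 90% of replicates) and do not hinge on the exact
noise scale.

## Hatching statistics

Incubation period is first-hatch day minus laying day for hatched
nests; hatching asynchrony is last minus first chick emergence;
hatching failure is unhatched over surviving eggs, where eggs lost
singly from an otherwise surviving nest (partial clutch loss) leave
the denominator. Group comparisons are Welch t tests (period,
asynchrony) and a 2×2 chi-squared (failure counts), Pearson without
continuity correction by default with a Yates option.

The Monte-Carlo power routine for the failure comparison defaults to
the continuity-corrected chi-squared — the default behaviour of R's
`chisq.test` on a 2×2 table, i.e. the variant a field study analysed
in R would actually have used. At rates 3.1% vs 10.3% with 64/66 eggs
and α = 0.05 the corrected test has ~24% power and the uncorrected
~36%; the flag is exposed. A clustered option draws failures clutch by
clutch with a beta-mixed clutch-level probability; clustering makes
the egg-level chi-squared anticonservative, which the suite checks.

Hatch detection in temperature traces compares a trailing and leading
window (default 3 h) at each sample and flags a level drop above a
threshold or an SD ratio above a threshold (with an absolute SD floor
so noiseless traces cannot divide by zero); flags merge within a 6-h
refractory window and each event is timed at the maximum level shift,
which centres the estimate on the true change point.

## Growth

Population growth curves are fitted per trait by nonlinear least
squares, pooling all broods: logistic `A/(1+e^{−k(t−t0)})`, Gompertz
`A·e^{−b·e^{−ct}}`, Weibull `A(1−e^{−(t/λ)^k})`. Fits use multi-start
Levenberg–Marquardt (9 data-driven starts: asymptote near
1.0–1.3 × max, inflection near the age at half-max) with tolerances of
1e−12; the family is chosen by AICc (residual variance counted as a
parameter), ties breaking toward fewer parameters then family name,
and non-converged families are excluded rather than compared.

Each capture is then reduced to a ratio residual, observed divided by
the population-curve prediction at that age — a multiplicative scale
on which "10% light for its age" means the same at day 2 and day 14.
Mixed models on this scale carry group, age, habitat
(terrestrial/marine), laying date, and the habitat × age and
group × age interactions, with brood and chick random intercepts.
Candidate fixed structures are scored by maximum-likelihood AICc
(REML log-likelihoods are not comparable across fixed structures); the
winner is refitted by REML for reporting. The 85%-CI screen flags
uninformative parameters inside the ΔAICc ≤ 2 competitive set, never
dropping the group term. Hatchling models (captures at ≤ 2 d) use the
trait in its own units with clutch-mean egg volume and laying date as
candidate covariates and a brood random intercept; with fewer than
three broods the fitter falls back to fixed effects with a warning.

## Chick survival

Fates are right-censored at day 10 before fitting. Field deaths are
only known to an inter-visit interval; the generator and the analysis
both place them at the interval midpoint (endpoint conventions are
selectable). Kaplan–Meier estimation (Greenwood-based intervals,
delayed entry supported) is delegated to lifelines. The Cox model for
the group effect is fitted in-package by Newton–Raphson with step
halving on the partial likelihood — Efron tie handling by default,
Breslow optional — converging on a score norm of 1e−9; lifelines, which
offers neither a Breslow option nor a shared frailty, serves as an
independent cross-check in the tests. Complete separation (all events
in one group) is reported as a boundary fit with an infinite hazard
ratio rather than a spurious finite number.

The shared brood frailty is a log-normal random effect on the
log-hazard: for each candidate variance θ the per-brood effects enter
as ridge-penalized coefficients (penalty 1/θ), and θ is chosen by the
Laplace-approximate marginal likelihood over a grid; θ = 0 degenerates
exactly to the plain Cox fit. S10 — the minimum proportion surviving
to day 10 — uses only chicks whose status at day 10 is known (death
observed, or followed past day 10), matching how a field study with
losses to follow-up must compute it.

## Reproductive value

`R = C·N·P·H` and `R10 = R·S10`, with the artificial fifth egg treated
as a real egg (C = 5 enters unmodified and the fake egg shares the
per-egg survival probabilities). S10 is carried as an exact fraction
when counts are available. Percent differences between groups use the
enlarged-group value as denominator by default — the convention the
composed table is internally consistent under — with the control
denominator available via a flag. All internal math is full precision;
the rounded display recomputes the percent differences from the
3-decimal cumulative values so the printed table is consistent cell
for cell (at full precision the R10 difference is −36.5%).

## The synthetic-study generator

`simulate_study` draws, per pair, a laying date (N(11, 4.5²) days);
per nest, an incubation duration (N(23.3, 1.34²) control,
N(26.3, 1.65²) enlarged, truncated at zero), a discovery day within
4 d of laying, and a failure time from the constant daily hazard
−ln(DSR) (0.986/0.988); visit schedules and interval histories follow
the field protocol. Eggs get dimensions N(3.55, 0.12²) ×
N(2.58, 0.06²) cm, an index trajectory from the mass-loss model, and
hatch outcomes from per-egg partial-loss (0/2.35%) and failure
(3.1%/10.3%) probabilities; asynchrony is a zero-truncated normal
(0.69 ± 0.25 / 1.98 ± 1.22 d) and chick emergence times span exactly
that window. Chick lifetimes are exponential with the control rate
solving `e^{−10λ} = 0.789` and the enlarged rate λ·e^{ln 3.5}; a
front-loaded piecewise option doubles the first-week hazard at equal
10-day survival. Because the published hazard ratio is conditional on
a brood frailty while the published survival proportions are marginal,
the two cannot both hold under a constant hazard
(0.789^3.5 ≈ 0.436 ≠ 0.513); a mode flag chooses which is honored
(`conditional`, the default, embeds the hazard ratio; `marginal`
matches both survival targets). Frailty itself defaults to variance 0
with gamma or log-normal options.

Chick morphometrics come from one generating process across all ages:
trait value = population logistic curve × ratio, where the ratio
carries the growth-model fixed effects, a clutch-egg-volume term
(larger-egg chicks start and stay relatively larger), brood and chick
random intercepts, and residual noise. A consequence worth knowing:
the ratio model's age trends systematically deform the *population*
curve away from a pure logistic, so family-selection consistency is
demonstrated on data generated from the logistic curve with the noise
layers but without the deterministic deformation. Hatchling-scale
coefficients in the full simulator are emergent rather than injected;
the printed-scale hatchling and growth coefficient sets are used as
direct generating truth in the dedicated recovery tests.

What the generator does not emulate: renesting, weather and spatial
habitat structure, observer error in aging, non-constant nest hazards,
and any correlation between egg size and survival. Passing tests
therefore show that the estimators recover the effects this structure
encodes at these sample sizes — not that the field data satisfy the
models' assumptions.

## Problem sizes and determinism

Every stochastic operation takes an explicit seed (package default
20220528) and identical (config, seed) reproduce studies and report
bundles byte for byte. The test suite uses the study's own sample
sizes where the check is about study-scale behaviour (18/18 clutches,
61/56 chicks, 64/66 eggs) and larger sizes (300 pairs, 8000 chicks)
where it checks convergence of simulated moments; replicate counts
are 100–500 for recovery experiments and 10,000–20,000 for binomial
power. The acceptance script runs 2000 Cox replicates because the
mean of the skewed hazard-ratio estimator (small-sample mean ≈ 3.8 for
a generating 3.5) converges slowly in the tail.

## Known limitations

- The frailty fit profiles a variance grid with a Laplace
  approximation; it is a diagnostic-grade estimator, not a replacement
  for a full penalized-likelihood implementation with REML-type
  variance estimation.
- DSR covariates are piecewise constant within a visit interval
  (evaluated at the interval midpoint) rather than varying day by day.
- The 2×2 chi-squared and its power simulation treat eggs as
  independent by default; the clustered option exists but the
  within-clutch correlation of real hatching failure is unknown.
- Wald confidence intervals are used throughout (consistent with the
  85% screen); profile-likelihood intervals are not implemented.
- No uncertainty propagation onto R/R10 (delta method or bootstrap):
  the composition is reported as a point chain, as in the table it
  mirrors.
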