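# Methods

## The model and its assumptions

The package analyses a continuous diabetes risk score with a two-level
random-intercept linear model, individuals nested in intersectional
strata. Model 1 (simple intersectional model) contains only an intercept
and stratum effects; model 2 (intersectional interaction model) adds
fixed indicators for the stratum-defining social dimensions (male,
history of migration, middle and low education; references female, no
migration, high education). Both assume Gaussian stratum effects
`u_j ~ N(0, σ_u²)` and residuals `e_ij ~ N(0, σ_e²/w_ij)`, independence
across levels, and — in model 2 — that the fixed terms are constant
within strata (checked implicitly: a violated design raises a
singular-design error only if degenerate; the age term of the
sensitivity variant is the deliberate exception).

Interpretation follows the MAIHDA logic: the model-1 VPC measures the
discriminatory accuracy of the strata; the drop in between-strata
variance from model 1 to model 2 (PCV) is the share attributable to
additive main effects; the shrunken model-2 stratum effects
(stratum-level residuals) measure stratum-specific multiplicative
deviations from additivity.

## Estimation

REML, profiled over the variance ratio ψ = σ_u²/σ_e². For a single
random intercept the marginal covariance is block-diagonal per stratum,
`V_j = diag(1/w) + ψ 1 1ᵀ`, so Sherman–Morrison reduces every REML
quantity (GLS fixed effects, residual quadratic form, log-determinants,
BLUPs) to per-stratum weighted moments. The scalar criterion

`(n − p)·log r'V⁻r + log|V| + log|X'V⁻¹X|`

is minimised over log₁₀ψ ∈ [−10, 6] by bounded Brent search
(`xatol = 1e-10`), with the boundary ψ = 0 evaluated explicitly; a
boundary optimum is reported via the `boundary_` flag and σ_u² is
clamped at exactly 0 (matching lme4 behaviour). An outcome with no
variation at all short-circuits to σ_u² = σ_e² = 0 with the weighted OLS
intercept. Hitting the upper search bound is flagged as
non-convergence, never silently accepted.

Fixed-effect 95% CIs use the normal approximation with covariance
σ̂_e²(X'V⁻¹X)⁻¹. The fit agrees with `lme4::lmer(REML=TRUE, weights=)`
to ~7 significant digits on weighted unbalanced fixtures, with the
balanced-design ANOVA closed form (σ_e² = MSW,
σ_u² = (MSB − MSW)/m, boundary-aware) to 1e-6 relative tolerance, and
with statsmodels `MixedLM` (unweighted) to its optimizer tolerance;
the test suite enforces the latter two.

### Survey weights

Weights are rescaled by dividing by the mean weight (sum = n), the
default single-level behaviour of common rescaling tools; the method
name is recorded in outputs and alternatives are registerable. Rescaled
weights enter the restricted likelihood as individual precision-style
weights (`Var(e_ij) = σ_e²/w_ij`) — exactly how `lmer`'s `weights=`
argument treats them. The original survey's exact rescaling/weighting
choice is not published, so both the method and whether weights are used
at all are configurable; this is a documented limitation, not a detail
the measures are insensitive to.

## Bootstrap confidence intervals

Stratum predictions, stratum residuals and variance components get 95%
CIs from a parametric bootstrap: resimulate outcomes from the fitted
model (fresh `u*` and `e*`, heteroscedastic by weight), refit, recompute
the statistic, B = 1,000 by default, all seeded. For predictions and
residuals the default interval is **point ± 1.96 × SD(bootstrap
replicates)** — the bootstrap estimates a standard error and the
interval is centred on the point estimate. The alternative percentile
interval is available but is *not* the default for a structural reason:
the parametric bootstrap redraws stratum effects from `N(0, σ_u²)`, so
replicate predictions fluctuate around the population level, not around
the stratum's conditional estimate; percentile intervals of those
replicates would always cover 0 for residuals and could never flag an
outlying stratum. Variance-component CIs use percentiles (no centring
issue).

## Synthetic data: what it emulates, what it does not

The generator reproduces, as defaults, the statistical skeleton of a
nationwide telephone survey of German-speaking adults (≥ 18) without
known diabetes: the 12-stratum allocation
(23, 33, 59, 80, 75, 71, 110, 157, 323, 494, 401, 427; total 2,253),
grand mean 38.98 GDRS points, between-/within-strata variances
43.79/269.00 points², the model-2 fixed effects (+4.18 male, −5.83
migration, +1.03 middle, +10.89 low education), and the exclusion
pattern (7 social-dimension and 67 score-component missing out of 2,327
pre-exclusion records, injected completely at random; the published
report gives counts only, so MCAR is the minimal assumption).
Pre-exclusion mode pads the allocation to 2,327 by largest-remainder
proportional allocation. Stratum effects are either drawn fresh from
`N(0, σ_u²)` (recovery studies; the mean REML σ̂_u² over 200 replicates
recovers 43.79 within Monte-Carlo error) or pinned to the published
null-model stratum means (regression tests and demonstrations).

Ages are truncated-normal with a lower mean for respondents with a
migration history (45 vs 53 years, SD 17, clipped to [18, 95]),
mirroring the real age structure and enabling age-confounding
demonstrations; survey weights are lognormal (σ = 0.35, mean ≈ 1).

Component-level mode draws raw risk-factor fields from documented
per-stratum fixture distributions (education shifts BMI, smoking, diet
and activity adversely for lower levels; sex shifts anthropometry);
these distributions are **choices recorded in the output metadata**, not
published quantities — the survey's per-stratum component distributions
are not public, so component-level realism is unverifiable. Passing
tests on synthetic data therefore demonstrate the *correctness of the
machinery* (scoring, filtering, estimation, measure algebra) under the
assumed structure, not substantive conclusions about the real
population. The generator also does not emulate the telephone-survey
sampling design (dual-frame, household selection, nonresponse).

## GDRS scoring

The scoring engine is table-driven: any point table with the published
structure (ten components; numeric components as half-open intervals
partitioning a declared domain, categorical ones as labelled points)
validates on load (coverage, no overlaps, achievable range exactly
0–122) and drives both the scorer and the component-level generator, so
the two can never disagree on category vocabulary. The packaged table
and the sex-specific waist-estimation equations are **synthetic
stand-ins** (files suffixed `_synthetic.json`): the official point
values and coefficients are published elsewhere and are not
redistributed here; the stand-ins satisfy every structural constraint
and are overridable via configuration.

Missing components mark a record unscoreable (a flag, not an
exception), mirroring survey exclusions; an unrecognized category label
raises an error naming the component and value. Risk bands partition
[0, 122] as low [0, 46), still-low [46, 56], elevated (56, 63], high
(63, 122]; fractional model-predicted scores are classified without
rounding, and the two boundaries interior to printed integer bands
(56–57, 63–64) are resolved by attaching the open interval to the lower
band's upper edge, consistent with the published "< 46" and "> 63".

## Design choices and numerical notes

* **PCV from unrounded fits.** The published PCV (77.95%) cannot be
  recovered from the published *rounded* variance components
  (1 − 8.57/43.79 ≈ 80.43%); it was evidently computed from unrounded
  estimates. The package always computes PCV from its own unrounded
  fits and reports it as-is (negative values possible and not clamped).
* **Exclusion order** is social-dimension missingness first, then
  unscoreable GDRS, with percentages on the pre-exclusion denominator —
  matching the published accounting (0.30%, 2.88%).
* **Stratum ordering** is a package convention (itertools.product over
  the dimensions as declared, last dimension fastest, ids from 1); the
  original tables' ordering is not fully specified.
* **Reference-category invariance** of σ_u², σ_e² and the BLUPs holds
  analytically (the design column space is unchanged) and is enforced
  in tests to ~1e-5 relative / 1e-6 points absolute, the precision of
  the 1-d optimizer.
* **Reported precision** is two decimals for GDRS-point quantities and
  percentages.
* **Problem sizes.** Default test and acceptance runs use 200
  simulation replicates at the full n = 2,253 design and bootstrap
  sizes of 200–500 for CI tests (B = 1,000 remains the library
  default); with the moment-based fitter a full fit takes ~2 ms, so
  these sizes keep runs fast while leaving Monte-Carlo error well below
  the tolerances tested.

## Known limitations

* Weighted REML treats survey weights as precision weights; no
  design-based (linearized) variance estimation, and no stratum-level
  weights.
* Continuous outcomes only (no binary/Poisson MAIHDA), two levels only,
  frequentist only.
* The parametric bootstrap conditions on the fitted variance
  components; for very small stratum counts (J = 12) variance-component
  CIs are themselves noisy, as the wide published intervals reflect.
* The packaged point table and waist equations are stand-ins; absolute
  GDRS values from component-level data are not comparable to scores
  computed with the official table, although every structural property
  (range, monotonicity, band mapping) is preserved.
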