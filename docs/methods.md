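# Methods

This note documents the models, estimators, and design choices behind
`rtscale`, and what the synthetic-data experiments do and do not establish.

## 1. Data model and preprocessing

The atomic observation is one person × item response time (RT) in seconds,
tagged with a survey id and date. All analysis happens on the natural log of
seconds; sub-second RTs are floored at 1 s before the log (so log RTs are
non-negative; a `sub_second="drop"` switch removes them instead).

Item eligibility follows web-paradata practice: an item enters the analysis
only if it was shown alone on a page (per-screen timestamps are otherwise
shared across items), is closed-ended, and was completed by at least 75% of
the survey's respondents, where the denominator is the number of persons who
answered any item of that survey. Persons contribute only if they responded
in at least 5 distinct surveys (configurable). Per item, RTs strictly above
the empirical 99th percentile (type-7, linear interpolation) are removed as
extreme outliers. Removal rather than winsorizing is used because the trim's
purpose is to delete invalid screen times (respondents stepping away), not
to bound heavy but genuine tails. Note that re-computing the quantile on
already-trimmed data yields a lower threshold, so the trim is idempotent
only with respect to fixed thresholds; `trim_rts` accepts precomputed
thresholds for that reason. The pipeline order is: item filters → person
filter → trim → log.

A structural property of this trim is worth knowing: when the contamination
rate equals the trimmed share (both 1%), the threshold lands inside the
contaminated mass, and the expected fraction of planted outliers removed is
roughly `1 − 0.4/√m`, with `m` the expected number of contaminated records
per item. Reliable (>90%) outlier removal therefore requires the survey
regime of thousands of respondents per item; the test suite evaluates the
trim in that regime (10,000 respondents × 30 items).

## 2. Item time intensities

TIs come from a cross-classified model of log RTs with crossed person and
item random effects,

    y_ij = μ + p_j + q_i + e_ij,

and are reported as `ti_log = μ̂ + EB(q_i)`, then centered at a 10-second
reference (`ti_centered = ti_log − ln 10`). Two estimators are provided:

- **Gibbs sampling** (default): all conditionals are conjugate (normal for
  μ, p, q; inverse-gamma(0.001, 0.001) for the three variances). Default
  1500 sweeps, 500 burn-in.
- **Profiled REML**: dense Henderson mixed-model equations with the Woodbury
  identity for the REML log-likelihood, optimized by Nelder–Mead over the
  log variance components; empirical-Bayes effects come from the same
  equations. Used as a fast cross-check; a brute-force GLS oracle validates
  the EB algebra in the tests.

TIs enter the downstream model as fixed, known covariates — deliberately a
two-stage procedure; TI estimation uncertainty is not propagated. Items with
fewer than 10 observations are flagged but retained.

An identification caveat: the crossed model identifies only the sum
`μ + q_i`, i.e., each item's expected log RT. Splitting that into a "TI" and
a person-level intercept is a convention, and the two-stage pipeline pins the
expanded model's intercept at the reference point of the *estimated* TIs. If
the population mean log RT at a true TI of ln 10 differs from ln 10, the
estimated-TI covariate absorbs that difference and the fitted intercept
converges to ln 10 rather than the generator's γ00. This is a property of
the procedure, not an estimator defect; parameter-recovery experiments
therefore use the generator's true TIs, while the component-quality
experiments run the full two-stage pipeline (person-level correlations are
invariant to the shift).

## 3. Location-scale models and the sampler

Two models are fit. The plain location-scale model gives each person a
random mean and a random log residual variance; the expanded model adds a
random slope on centered TI, splitting intraindividual RT variability into
*systematic RT adjustments* (slope) and *residual RT variability* (scale).

Estimation is Metropolis-within-Gibbs on the hierarchically centered
parameterization: the person vector `v_j = (α_j[, β_j], s_j)` with
`s_j = log σ_j²` has prior `MVN((γ00[, γ10], ω), τ)`. Then

- `(α_j, β_j) | s_j` is conjugate normal (vectorized 2×2 solves across
  persons),
- `s_j` gets an adaptive random-walk Metropolis step (Robbins–Monro
  adaptation toward 0.44 acceptance during burn-in, frozen afterwards),
- the fixed-effect vector `(γ00[, γ10], ω)` is conjugate normal given the
  `v_j` (prior N(0, 10⁶) per element),
- `τ` is conjugate inverse-Wishart.

Hierarchical centering makes the fixed effects mix essentially
independently; the textbook non-centered scheme (random-walk updates for ω)
mixes poorly here because the conditional posterior of an intercept given
its random effects is far narrower than its marginal. The per-person
likelihood depends on the data only through sufficient statistics
(n, Σy, Σy², Σx, Σxy, Σx²), so one sweep is O(persons) regardless of the
number of records — 2 chains × 3000 iterations on 45,000 records take a few
seconds.

**Priors.** Fixed effects N(0, 10⁶). For τ, inverse-Wishart(Ψ, d+1) with
Ψ = 0.01·I. The scale matters: an identity scale adds ≈1/J to every
posterior-mean variance, which is a 25% distortion for a slope variance of
0.04 at J = 300 persons; 0.01·I keeps the prior's contribution below 0.1%
of realistic variance components while remaining proper.

**Convergence.** Split-R̂ (potential scale reduction) is computed across ≥2
chains for every fixed effect and τ element via ArviZ; a fit is flagged
non-converged when any R̂ exceeds 1.05. Component extraction from a
non-converged fit warns but still returns values.

**Person components.** Point estimates are posterior means (with posterior
SDs reported for attenuation diagnostics), accumulated by running moments
across chains. Persons with very few records are retained; their scale
effects are prior-dominated and their posterior SDs are correspondingly
large (the tests check this monotonicity).

## 4. Quadrature oracle

`marginal_loglik_quadrature` integrates the person random effects out by
adaptive Gauss–Hermite quadrature: per person, a damped Newton search (with
eigenvalue-clipped Hessians — the joint log-density is not concave far from
the mode, so plain Newton/Levenberg steps can stall at saddles) locates the
posterior mode, and the tensor-product Hermite grid is recentered and
rescaled there. τ = 0 short-circuits to the exact closed form. `fit_mml`
maximizes this integrated likelihood over the fixed effects and a
log-Cholesky parameterization of τ (L-BFGS-B with a simplex polish; person
modes are cached between objective evaluations). On 20-person toys the MCMC
posterior means of the fixed effects agree with the MML point estimates to
well under 0.05 — the two routes share no code path beyond the sufficient
statistics.

## 5. Cognitive scores

Reasoning scores live on a T-score metric (mean 50, SD 10) and are carried
through unchanged. The Stop-and-Go Switch task is scored from trial-level
data: persons with fewer than 70% correct trials are excluded (the gate is
computed over all trials by default, or over the mixed condition only);
otherwise the score is the negated average of the median correct-trial
latencies of the mixed condition's switch and nonswitch trials. Medians use
the midpoint convention for even counts and exclude incorrect trials —
latency is defined to the correct response. Negation is the simplest
strictly decreasing transform; any other choice would only flip signs
downstream.

## 6. Association and lagged analyses

Cross-sectional regressions z-score the outcome and the RT components on the
listwise-complete analysis sample, so component coefficients are
standardized betas; categorical demographics enter as unstandardized
indicator contrasts, continuous ones z-scored. Age moderation uses a single
model with a group main effect and group-specific component slopes; the
group difference per component is a linear contrast on the coefficient
covariance (identical to the interaction t-test). OLS point estimation is
delegated to statsmodels; exactness is verified against hand-rolled linear
algebra to 1e-8. No multiple-testing correction is applied; results carry
the number of tests.

The prospective analysis refits the expanded model separately per survey
(reusing the global TIs; per-survey seeds derive from the master seed and
the survey's position, so any survey is reproducible in isolation). Surveys
with fewer than 10 distinct items are skipped; surveys whose items share one
TI value fall back to the plain model with the slope reported missing.
Per-survey components are averaged within person × half-year lag bin — bin k
covers lags in (0.5(k−1), 0.5k] years, bin 1 closed at zero, up to 6.5
years — and feed a pooled regression with bin-specific intercepts and
bin-specific component slopes. Because the outcome repeats across a person's
rows, standard errors come from a person-clustered sandwich (CR0 with a
G/(G−1) factor, written in-repo and checked against both a brute-force
per-cluster computation and statsmodels). Component main effects and
component × lag interactions are cluster-robust Wald tests with F(q, G−1)
reference; the interaction's type-I error is verified at ≈5% over 200 null
replicates. The maximum stable lag is the longest run of consecutive bins
from bin 1 whose 95% CIs exclude zero, in years. Effect sizes follow the
.10/.30/.50 small/medium/large convention on standardized coefficients.

## 7. Synthetic panel generator

The generator draws person effects from MVN(0, τ), item TIs from a normal
truncated to [1.14, 4.04] log seconds (mean 2.29, SD 0.5), and log RTs from
the expanded model; RT seconds are the exponential. Defaults are calibrated
to the marginal structure of a large US probability internet panel: γ00 =
2.33 log seconds, γ10 = 1, and ω derived so the marginal SD of log RT is
0.79 via the decomposition Var = τ00 + (γ10² + τ11)·Var(TI) +
E[exp(ω + u2)] (ω ≈ −1.63 at the default τ = diag(.16, .04, .25)). Persons
enter over a 2-year window and answer every item of a survey every 60 days;
the cognitive test falls just after the last survey, so lags up to 6.5 years
arise with 42 surveys. Demographics are categorical draws with
panel-representative marginals and act only as covariates. Contamination
multiplies a record's seconds by Uniform(10, 50). Cognitive scores are
50 + 10·(Σ β_k z(u_k) + ε) with ε Gaussian and its variance set so the
latent signal explains `r2_cog` of the variance — `r2_cog` parameterizes the
signal share, which is more interpretable than a noise SD. An
`age_moderation` multiplier scales the mean-RT effect for the 40+ group.

One structural point: standardized betas β and R² constrain each other
through the latent correlation matrix (R² = β'R_xβ). For the target pattern
β = (−.28, .50, −.15) with R² = .26, uncorrelated latents are impossible
(Σβ² = .35); `latent_correlations_for_targets` solves R_x·β = r for the
off-diagonals from target bivariate correlations (for r = (−.09, .43, −.12):
ρ ≈ (.30, −.27, −.09), PSD, β'R_xβ ≈ .258), and the generator's noise
convention then reproduces both the betas and R² simultaneously.

What the generator does *not* emulate: device and time-of-day effects,
attrition beyond staggered entry, satisficing or speed-accuracy strategies,
item-content effects, and autocorrelated RTs. Passing tests therefore show
that the estimators recover the assumed generative structure at realistic
sizes and noise levels — not that real panel RTs follow that structure.

## 8. Experiment sizes and estimands

Simulation checks run at desk scale: parameter recovery at 300 persons ×
150 items, TI recovery at 500 × 100, oracle comparisons on 20-person toys,
association recovery on 5000 true latent vectors, and 200-replicate
regression-level simulations for test sizes. At these sizes the dominant
randomness is the finite draw of person effects (e.g., the empirical
variance of 300 draws of u1 has an 8% coefficient of variation), so
recovery is measured against the *realized* estimands — fixed effects
against γ + mean(u), τ against the empirical covariance of the drawn
effects — which isolates estimator error from draw noise. Measured
estimator-only errors are below 0.01 on fixed effects and a few percent on
variance components.

## 9. Known limitations

- The scale (log-variance) effects use random-walk Metropolis; very sparse
  persons (a handful of records) mix slowly and are prior-dominated.
- The two-stage TI procedure ignores TI estimation error; with hundreds of
  respondents per item the attenuation is negligible, but with few
  respondents per item the slope variance will be biased upward.
- The quadrature oracle is limited to ≤3 random-effect dimensions and small
  data; it is a validation tool, not a production estimator.
- Cluster-robust inference uses G−1 denominator df; with very few clusters
  (< 40) a wild-cluster bootstrap would be preferable and is not
  implemented.
- The generator's survey calendar is perfectly regular and completion is
  full; real panels have irregular spacing and missingness patterns that
  the lag binning handles but the tests do not stress.
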