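# rtscale

Inferring cognitive abilities from survey response-time paradata.

Online panel surveys record, as a byproduct, how long each respondent spends
on every question screen. These response times (RTs) carry signal about the
respondent's cognitive functioning. `rtscale` implements a complete analysis
pipeline that turns long-format survey RT records into three person-level RT
components and relates them to cognitive test scores, both cross-sectionally
and prospectively over multi-year lags. It is aimed at survey methodologists
and cognitive-aging researchers working with web-panel paradata.

## The model

Log RTs (natural log of seconds) are modeled with a multilevel
**location-scale model** with person-level random effects on both the mean
and the log residual variance, expanded with a random slope on item **time
intensity** (TI) — the latent expected log time an item requires, the RT
analogue of item difficulty:

```
level 1:  RT_ij = α_j + β_j · TI_i + r_ij ,   r_ij ~ N(0, σ_j²)
level 2:  α_j      = γ00 + u0_j          (mean RT)
          β_j      = γ10 + u1_j          (systematic RT adjustment)
          log σ_j² = ω   + u2_j          (residual RT variability)
          (u0_j, u1_j, u2_j) ~ MVN(0, τ)
```

TIs are estimated first from a cross-classified (persons × items)
random-effects model and centered at 10 s, so `α_j` is person *j*'s
predicted log RT for a 10-second item. The three empirical-Bayes person
scores — mean RT, systematic RT adjustment (how strongly a person calibrates
their speed to item demands), and residual RT variability (spontaneous RT
fluctuation) — then serve as predictors of cognitive test scores
(T-score metric, mean 50, SD 10) in standardized regressions, in
age-moderated regressions, and in a lag-as-moderator design with half-year
lag bins and person-clustered sandwich standard errors.

Estimation is Metropolis-within-Gibbs MCMC (diffuse priors, adaptive
random-walk steps for the scale effects, split-R̂ convergence checks), with
an independent adaptive Gauss–Hermite quadrature route for validation. A
synthetic panel generator reproduces the full data structure — persons ×
items × surveys, staggered entry, a cognitive test after the survey window,
demographics, and optional RT contamination — with known latent truth, so
every stage is testable at desk scale.

## Worked example

```python
import numpy as np
from rtscale import (PanelConfig, generate_panel, preprocess,
                     estimate_time_intensities, LocationScaleSpec,
                     fit_expanded_location_scale, extract_person_components,
                     regress_components)

cfg = PanelConfig(n_persons=200, n_surveys=8, items_per_survey=12, seed=1)
panel = generate_panel(cfg)
clean, report = preprocess(panel.rt_records, panel.items, min_surveys=5)

ti = estimate_time_intensities(clean, seed=2)
spec = LocationScaleSpec(chains=2, iterations=2000, burn_in=800, seed=3)
fit = fit_expanded_location_scale(clean, ti.ti, spec)
print(f"gamma00 = {fit.gamma00:.3f}, gamma10 = {fit.gamma10:.3f}, "
      f"omega = {fit.omega:.3f}")
print(f"tau diag = {np.round(np.diag(fit.tau), 3)}, "
      f"max PSR = {max(fit.psr.values()):.3f}")

components = extract_person_components(fit)
result = regress_components(panel.cognitive_scores, components)
print("standardized betas:", {k: round(v, 2) for k, v in result.betas.items()})
print(f"R^2 = {result.r2:.2f}, F({result.df_model}, {result.df_resid}) "
      f"= {result.f_stat:.1f}")
```

Output:

```
gamma00 = 2.309, gamma10 = 1.006, omega = -1.718
tau diag = [0.168 0.039 0.244], max PSR = 1.003
standardized betas: {'mean_rt': -0.3, 'rt_adjustment': 0.39, 'log_resid_var': -0.1}
R^2 = 0.28, F(3, 196) = 25.9
```

The fit recovers the generator's fixed effects (γ00 = 2.33 up to the
realized person draw, γ10 = 1.0, ω ≈ −1.63) and random-effect variances
(0.16, 0.04, 0.25); all chains converge (PSR ≤ 1.05). The standardized
betas show the expected pattern: slower mean RTs and larger residual RT
variability predict lower scores, stronger systematic RT adjustment predicts
higher scores, together explaining 28% of the score variance in this run.

A command-line interface drives the same stages
(`rtscale simulate | preprocess | ti | fit | run`), and
`rtscale run config.yaml` executes the full pipeline with a reproducibility
manifest.

## Documentation

`docs/methods.md` describes the models, priors, samplers, the synthetic-data
generator's assumptions, numerical choices, and known limitations.
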