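# speccurve

Specification-curve (multiverse) analysis of the relationship between
dysregulated gaming and mental well-being, implemented end to end as a
tested Python package: synthetic Likert-survey generation with known ground
truth, the survey cleaning cascade and scale scoring, one-factor CFA
psychometrics with coefficient-omega reliability, exhaustive fitting of all
justifiable regression specifications, curve summaries, and a crossed
random-effects decomposition of between-specification variance.

## The analytic problem

Survey studies of gaming and well-being involve a *garden of forking
paths*: well-being can be operationalized three ways (general mental
health, absence of depressive mood, life satisfaction), dysregulated-gaming
severity nine ways (five instruments, 9/11-item variants, core-criterion
subsets, and a 15-item composite), sixteen covariates can each be included
or not, and extreme-playtime respondents can be excluded or kept. Rather
than pick one model, a specification curve fits **all** defensible
combinations — here 3 × 9 × 18 × 2 = 972 ordinary least-squares models
(covariate sets: none, each single covariate, all sixteen) — and draws
inference from the distribution of standardized coefficients.

Key quantities:

- **β** — the focal standardized coefficient of the dysregulation measure,
  with outcome and continuous regressors z-scored within each model's
  analysis subset; categorical covariates enter as unstandardized indicator
  contrasts.
- **ΔR²** — the semipartial contribution of the focal predictor, computed
  by refitting without it.
- **Median-model CI** — the 95% interval of the individual model holding
  the central-most estimate (even counts: mean of the two central
  estimates ± t × mean of their SEs).
- **Decomposed variance** — a crossed random-effects null model
  `β_i = μ + u_outcome + u_predictor + u_covset + u_subset + e_i`
  estimated by REML; shares of between-specification variance are reported
  per decision class (normalized to 100% over the four classes).
- **Psychometrics** — one-factor maximum-likelihood CFA per dysregulation
  scale (CFI, RMSEA with 90% noncentral-χ² CI, SRMR) and reliability
  ω = (Σλ)² / ((Σλ)² + Σψ) with a bias-corrected and accelerated (BCa)
  bootstrap interval.

The synthetic generator emulates the study conditions the analysis assumes
(743 starters, 38.9% page-level dropout, 6.6% careless responders among
completers, ~5% playtime outliers, observed-score effect targets
−0.40 / −0.47 / −0.33 per outcome) and records full ground truth, so every
stage can be validated by parameter recovery.

## Worked example

```python
from speccurve import (GeneratorConfig, generate_dataset, clean_dataset,
                       score_dataset, SpecificationCurve,
                       build_default_space)

raw, truth = generate_dataset(GeneratorConfig(seed=1))
cleaned, report = clean_dataset(raw)     # 743 -> 289 incomplete, 30 careless
scored = score_dataset(cleaned)          # scale scores, covariates, outliers
results = SpecificationCurve(scored, build_default_space(scored)).fit()
print(results.summary())
print(results.decompose_variance().summary())
```

prints

```
Specification curve
  models fitted: 972 of 972 (skipped: 0)
  median beta = -0.452  [-0.547, -0.357] (median-model 95% CI)
  range: [-0.590, -0.170]   median dR2 = 0.198
  share of models significant at 0.05: 100.0%
Decomposed variance (crossed random-effects null model, REML; n = 972 effect sizes)
  outcome      sigma2 = 0.012554   ICC = 0.851   share = 87.2%
  predictor    sigma2 = 0.001830   ICC = 0.124   share = 12.7%
  covariates   sigma2 = 0.000015   ICC = 0.001   share = 0.1%
  outliers     sigma2 = 0.000000   ICC = 0.000   share = 0.0%
  residual     sigma2 = 0.000353
```

i.e. every one of the 972 models yields a significant negative association;
at this seed the curve median (−0.45) sits near the generator's configured
per-outcome effects, and the choice of well-being outcome drives most of
the between-model variance — as expected, since the three outcomes were
generated with different true effect sizes while all nine dysregulation
operationalizations share one latent construct.

A command-line pipeline wraps the same stages
(`speccurve all --seed 1 --out run/`, plus `simulate`, `clean`,
`psychometrics`, `curve`, `decompose` and `report` subcommands) and writes
CSV tables, figures (curve + decision panel, per-choice box plots,
variance-share bars, correlation heat map) and a JSON run manifest.

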