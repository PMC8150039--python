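# Methods

This note documents the models, numerical choices and limitations of
`speccurve`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Synthetic survey generator

**Latent structure.** Four focal factors — dysregulation `D` and three
well-being constructs (general mental health, absence of depressive mood,
life satisfaction) — plus eleven covariate factors (eight gaming
motivations, three in-game need satisfactions) and five continuous latents
(age, weekday/weekend hours, session minutes, education propensity) are
drawn jointly multivariate normal with a fixed correlation matrix. The
four-factor block is user-configurable; covariate correlations are weak
defaults (|r| ≤ 0.35) chosen once to mimic a self-selected gamer sample.

**Items.** Each Likert item is generated as
`y* = λ_j F + sqrt(1 − λ_j²) ε`, `ε ~ N(0,1)`, then discretized to 1–5 at
standard-normal thresholds τ₁ < … < τ₄ (`1 + #{τ_k < y*}`) — the standard
graded-response-style mechanism matching one-factor CFA assumptions.
Reverse-keyed items (two of the four open-definition items, one mental-
health item) are generated from `−F` with mirrored thresholds; depressive
mood items load negatively on the "absence of depressive mood" factor and
the scale score is reversed downstream, exercising the reverse-coding
logic. Default loadings cycle through 0.55–0.74 (lower, 0.45–0.62, for the
open-definition scale, whose published reliability is visibly weaker);
default thresholds place dysregulation items near a mean of 2.1, well-being
items near 3.7, depressive symptoms near 2.5. Item-level distributions are
a stated convention, not a reproduction — the source data report only
scale-level descriptives.

**Attenuation compensation.** Discretization and finite reliability
attenuate observed scale-score correlations below the latent correlation.
The generator therefore treats the configured `D`–well-being entries as
*observed-score* targets: it computes each scale's score–factor correlation
α analytically (single- and bivariate-normal orthant probabilities; the
score–factor covariance of a discretized item is λ_j Σ_k φ(τ_k)) and
inflates the latent correlation by `1/(ᾱ_D α_W)`, where ᾱ_D averages the
nine predictor operationalizations. The resulting matrix is checked for
positive semi-definiteness; both the configured targets and the inflated
matrix, per-scale attenuations, and the implied expected score correlation
per (predictor, outcome) pair are recorded in the ground-truth record.
Validation at n = 50,000 shows observed correlations within ±0.01 of the
analytic expectations.

**Pathologies.** Dropout, careless and outlier counts are deterministic
(`round(rate × eligible)`), with membership sampled uniformly; defaults
follow the study conditions: 743 starters, dropout 289/743, careless
30/454 among completers, outliers 5% of completers. Dropouts lose all
items from a randomly chosen abandonment page onward (early pages
weighted, as in self-selected online surveys); careless responders answer
with a constant value or a repeating 1-2-3 pattern and fail at least one
of the two attention checks; outliers receive weekday/weekend hours
implying ≈ 93–120 weekly hours (half also extreme session lengths), far
beyond three standard deviations of the bulk.

## Cleaning and scoring

The cascade is fixed as *incomplete → careless*: respondents with any
missing item are removed first, then completers failing ≥ 1 attention
check; counts are conserved exactly and reported per stage. Sensitivity
mode retains everyone, with scoring returning missing for incomplete
scales and models fitted on complete cases. Scale scores are item means
after reverse coding (`6 − r`); weekly game time is
`5 × weekday + 2 × weekend` hours; education is carried at two levels
(secondary vs tertiary). Playtime outliers are respondents at or above
mean + 3 sample SD on weekly hours **or** session minutes — with the SD
computed on the cleaned sample, before any outlier removal — plus any
respondent reporting zero weekly hours (grouped with the outliers, as the
in/exclusion choice treats them identically). Zero variance disables the
SD rule rather than flagging everyone.

## One-factor CFA, fit indices, omega

The ML discrepancy `F = log|Σ| + tr(SΣ⁻¹) − log|S| − p`, with
`Σ = λλ' + diag(ψ)` and unit factor variance, is minimized by closed-form
EM updates followed by an L-BFGS-B polish with analytic gradients
(`∂F/∂λ = 2Aλ`, `∂F/∂ψ_j = A_jj`, `A = Σ⁻¹(Σ−S)Σ⁻¹`); uniquenesses are
floored at 1e-6. Fits start from a principal-axis solution (SMC
communalities), three seeded random starts, and a null start (λ = 0 is an
EM fixed point); the lowest discrepancy wins, with ties within 1e-10
broken toward the smallest ‖λ‖² — this keeps genuinely independent items
from landing on the unidentified single-item loading ridge. `S` uses
denominator n−1 and `χ² = (n−1)F`; `df = p(p+1)/2 − 2p`; the independence
baseline has free variances and `df_b = p(p−1)/2`.

CFI uses the max(·,0)-guarded ratio of noncentralities; RMSEA is
`sqrt(max(χ²−df,0)/(df(n−1)))` with the 90% CI from inverting the
noncentral-χ² CDF by bisection (df = 0 is reported as undefined with a
caution flag — four-indicator models have only two df); SRMR is the root
mean square of covariance residuals standardized by sample SDs, diagonal
included. The estimator is standard ML: the generator's latents are
multivariate normal, where ML and robust (scaled) estimators agree
asymptotically; a robust correction is deliberately out of scope, so
fit statistics on real, non-normal Likert data will differ. Items are
treated as continuous (no polychoric option).

Reliability is single-factor coefficient omega
`ω = (Σλ)²/((Σλ)² + Σψ)` — the only omega defined for a unidimensional
model, used here where a hierarchical variant is sometimes quoted. Its
confidence interval is a BCa bootstrap over respondents (default B = 1000):
bias constant `z₀ = Φ⁻¹(#{ω* < ω̂}/B)` (clamped to (1/(B+1), B/(B+1))),
acceleration from the jackknife third-moment formula, endpoints at the
adjusted quantiles. Bootstrap and jackknife covariance matrices are formed
vectorized and refit through the batched EM solver warm-started at the
full-sample solution, which keeps a 500-simulation coverage study with
B = 1000 under a minute. A generic `bca_ci` for arbitrary statistics uses
the same endpoint combination.

## Specification-curve engine

Specifications are the Cartesian product of the four axes in fixed
lexicographic order (outcome, predictor, covariate set, outlier rule);
the default space is 3 × 9 × 18 × 2 = 972, and item-level mode swaps in
the fifteen single items of the 11-item DSM-5-style scale plus the four
ICD-11 items (1620 models). Each model is OLS on its analysis subset with
the outcome and all continuous regressors z-scored *within that subset*
(per-model standardization; a global option exists behind the
standardization flag of the scoring table). Gender enters as two
indicators against a female reference with only the male contrast
summarized (the four-person third category stays in the model; its
indicator is dropped automatically if the level is empty in a subset);
education as a secondary-vs-tertiary indicator; both are left
unstandardized. ΔR² is computed by full refit without the focal variable
(the whole indicator block for categorical variables) — exact under
collinearity, unlike analytic shortcuts. p-values are two-sided t with no
multiplicity correction: inference rests on the whole curve, not on any
single model. Zero-variance focal predictors mark the specification
degenerate; it is skipped and logged, never silently dropped.

Curve summaries report median/min/max across models containing the
variable, the median-model 95% CI (odd count: the central model's CI;
even count: mean of the two central estimates ± t × mean of their SEs,
with t on the mean residual df), the median ΔR², and the share of models
significant at 0.05. Plot ordering is ascending β with ties broken by
enumeration index, so figures are deterministic.

Power for the study's sensitivity statement uses the noncentral t
convention: df = n − 2, noncentrality `β√n/√(1−β²)`; at n = 424,
β = 0.16, α = 0.05 this gives 91.5%, matching a 20,000-replicate
simulation within 0.01.

## Decomposed variance

The null model puts independent zero-mean random effects on each decision
class. Estimation is REML: an EM iteration warm-started at a balanced-grid
method-of-moments solve (level-mean variances and the total variance
equated to their expectations), then an L-BFGS-B polish of the REML
log-likelihood with analytic gradients, all through a Woodbury identity on
the stacked indicator matrix (the 972 × 972 covariance never materializes;
effects enter unweighted, per the null-model description). Convergence is
1e-8 on the log-likelihood; failure falls back to the method-of-moments
estimate with a warning. Components are truncated at zero; single-level
classes are fixed at zero. On balanced grids the REML solution matches
the Henderson ANOVA estimator to ~1e-8. Headline shares are normalized
over the four decision classes (summing to 100%, residual excluded);
raw ICCs including the residual are also reported, since it is not
knowable whether published percentages excluded a negligible residual.

## Figures

Box plots use standard 1.5 × IQR whiskers with fliers beyond; a published
caption's "±1.58 × IQR/n" is read as the notch half-width formula
(1.58 · IQR/√n) and not used as a flier rule. Figures are pure functions
of fitted results and are written as PNG and SVG.

## Problem sizes and limitations

Recovery tests use n = 424 with 20 seeds for curve medians (tolerance
±0.03 on the mean), 10×10×10 grids × 50 replicates for variance shares
(±0.05), n = 10⁴ for the omega closed form (±0.02) and 500 simulations ×
B = 1000 for BCa coverage ([0.91, 0.99]) — sizes chosen to keep the full
suite to a couple of minutes while leaving Monte-Carlo error well inside
the tolerances.

What passing these tests does *not* show: the generator gives all nine
dysregulation operationalizations a single latent factor, so the predictor
class contributes much less between-model variance than in real data,
where instruments genuinely measure different blends of criteria (the
open-definition scale's lower loadings reproduce a mild version of this
anomaly); latents are multivariate normal, so robust-vs-ML differences,
floor effects and careless-but-check-passing respondents are not
exercised; missingness is page-level only (no item-level gaps); and
covariate effects are weak and linear by construction. Reported values on
real survey data will accordingly differ from the synthetic
ground-truth-recovery numbers.
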