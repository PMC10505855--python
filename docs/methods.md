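# Methods

## Model

The unit of analysis is a foraging episode ("trip"). Two sub-models share a
common covariate vector and are fitted jointly.

**Patch choice.** Trip *i* chooses patch *X_i = k* from the 7-category patch
taxonomy with categorical probabilities softmax(η_i), where

    η_ik = α_choice[k, season_i] + γ_choice[k, gender_i]
         + δ_choice[k, age_i] + Σ_c β_choice[k, c] · x_ic

Season (ice vs. ice-free) and gender enter as varying intercepts indexed by
patch, so each patch has its own seasonal availability profile and its own
gendered baseline. There is no hard season mask in the default model: a
patch that is out of season is discouraged through its season intercept, not
forbidden. This choice is deliberate — a 7-way softmax is what makes the
prior-predictive mean choice probability 1/7 ≈ 0.14 per patch; masking to
the 5 or 4 in-season patches would move it to ≈ 0.2–0.25. Masked softmax is
still available (`softmax_probs(eta, mask)`) for scenario analysis.

**Harvest success.** Given the chosen patch, Y_i ~ Bernoulli(logit⁻¹(θ_i))
with

    θ_i = α_succ[X_i, season_i] + γ_succ[X_i, gender_i]
        + δ_succ[age_i] + Σ_c β_succ[c] · x_ic

The success model shares one age effect and one coefficient vector across
patches (patch enters only through the intercepts): 281 trips cannot
identify per-patch slopes, so this is an explicit modelling assumption, not
a fact about the data-generating process. Group size enters both sub-models;
either can drop it by shrinking the layout's covariate tuple.

**Covariates.** Household income, sharing-network in-degree and out-degree,
and trip group size, each standardized to mean 0, sample sd 1 (n−1
denominator) over non-missing values. Network degrees count distinct
directed sharing ties per household, computed from survey reports while
excluding each household's own reports (so a household's degree never rests
on its self-description) and dropping self-loops.

**Age effects.** The four ordered age classes sit at integer positions
1..4. Age effects get a zero-mean multivariate-normal prior with
squared-exponential covariance

    K[a, b] = η² · exp(−ρ² · d(a,b)²) + 1{a=b} · σ²

one (η², ρ², σ²) triple for the choice block (shared by all 7 patch rows)
and one for the success block. η² is the marginal variance, ρ² the inverse
squared length-scale, σ² an independent jitter that also guarantees positive
definiteness. The squared-exponential form follows the latent age-varying
skill literature the model descends from; the kernel is isolated in
`gp_age_cov` and straightforward to swap.

**Missing income.** Exactly one household lacks income. All of its trips
share a single latent standardized income (income is a household-level
quantity; 35 independent latents for the 35 affected trips would be an
alternative reading, noted and not taken), with

    income_miss ~ Normal(income_mu, income_sigma)
    income_mu   ~ Normal(0.5, 1)
    income_sigma ~ half-Cauchy(0, 1)

## Priors

Intercepts and coefficients: Normal(0, 1). GP scales: half-Cauchy(0, 1).
These are weakly informative defaults; every scale is exposed through
`PriorConfig` (YAML-loadable). Two properties of the defaults matter more
than their exact values: the choice-block priors are exchangeable across
patches, and the success-block priors are symmetric about zero. Together
they pin the prior-predictive mean patch-choice probability at exactly 1/7
and the mean success probability at exactly 1/2 regardless of the scales —
which is what the acceptance checks test, precisely because it is
scale-invariant. Identification of the softmax uses zero-centered priors on
all 7 patch blocks rather than pinning a reference category, preserving that
exchangeability.

## Inference

The joint log-density (log prior + categorical log-likelihood + Bernoulli
log-likelihood) is implemented and unit-tested as plain functions,
independently of any sampler. Sampling uses emcee's affine-invariant
ensemble algorithm over the packed parameter vector; positive scales (GP
hyperparameters, income_sigma) are sampled as logs with the Jacobian added
to the target density, which removes the heavy-tail boundary pathologies of
half-Cauchy scales. `FitConfig.n_chains` independent ensembles (default 4,
each 2·dim+2 walkers) stand in for chains; split-R-hat and bulk ESS are
computed with arviz and checked against thresholds (1.01 / 400 by default).
A failed check marks the fit WARN — returned and logged, never silent.
Default warmup/draw counts (1000/1000) are artifact decisions; nothing
downstream depends on them.

Correctness of the sampler-model combination is checked against an
independent dense-grid quadrature of the same joint density on a 2-patch,
2-coefficient reduction (posterior means agree within 0.05), and by a
recovery harness (simulate → fit → bias/RMSE/89%-HPD-coverage report). The
test suite runs the harness at reduced scale — a 2-patch model, 6
replicates of 80 trips, plus an analytic calibration check where replicate
"posteriors" are exact normals and coverage must land near 0.89 — sized to
keep the default suite fast; `scripts/recovery_study.py` runs the full
version (50 replicates at n = 281).

## Synthetic data

The generator serves two distinct purposes.

`default_fixture` reproduces the published sample *composition* exactly:
281 trips by 23 harvesters in 13 households; per-patch counts 47 / 38 / 72 /
21 / 75 / 20 / 8; 228 trips by men; group-size quartiles (2, 3, 4); one
missing-income household with 3 hunters and exactly 35 trips. Counts are
satisfied by construction (exact lists, then seeded shuffling), so they hold
for every seed; only success flags and the season of year-round patches are
sampled. The household table is found by deterministic seeded search:
integer degrees (mean ≈ 4, the reference tie count) are hill-climbed until
corr(in, out) = −0.07 ± 0.005 over 13 households, then the 12 known incomes
are tuned by coordinate descent to corr(income, in) = −0.22 and
corr(income, out) = 0.39 ± 0.005. Where composition is unpublished the
fixture takes documented assumptions: 18 men / 5 women harvesters, age
classes spread over all four bins, a skewed per-harvester trip-count
vector, incomes in arbitrary currency units (only standardized income enters
the model), and no woman in the winter marine patch. Success flags are drawn
from the default ground-truth success model, whose winter-marine baseline is
0.225 — inside the 20–25% range that patch is known for — with tidal
gathering near-certain (0.95) and income having no success effect.

`simulate_trips` is the generative direction of the model itself: patch from
the softmax at the trip's covariates, success from the logistic model given
the drawn patch, fully reproducible from a seed. It is the source of
ground-truth datasets for recovery tests.

What the fixture does **not** emulate: real spatial structure (toponyms),
harvest quantities, species detail, within-household correlation beyond
shared covariates, or any real trip sequence. Tests passing on this fixture
show the pipeline computes the intended quantities, not that the published
substantive estimates are correct — those rest on confidential data this
package deliberately does not attempt to reconstruct.

## Predictions

Counterfactual profiles are specified in raw units (e.g. "in-degree 4") and
converted with the CovariateScaling stored on the fitted draws. Income
sweeps refuse grid points outside the observed income range (error, not
silent clamping): predictions are never extrapolated. HPD intervals use the
deterministic shortest-sorted-window construction: the narrowest window
containing ⌈0.89·n⌉ sorted draws, leftmost window on ties. Patch-removal
scenarios renormalize each draw's choice probabilities over the remaining
patches — equivalently, a masked softmax — leaving success probabilities
untouched; the fitted model is not re-run (refitting under a restricted
choice set would answer a different, behavioural-adaptation question).
Profile presets cover the published panels; because "young adult" is
ambiguous between the two younger age classes, both variants exist
(`fig3a_highincome`, `fig3a_highincome_30to40`).

## Numerical choices

- Softmax via max-subtraction; finite for |η| ≤ 700. Masked entries are
  exactly 0, not tiny.
- Bernoulli log-likelihood in log-sum-exp form, finite for any finite θ.
- GP prior density via Cholesky; a non-PD covariance (impossible for
  positive hyperparameters, but reachable by pathological proposals) yields
  −∞ rather than an exception.
- Quantiles everywhere use linear interpolation between order statistics.
- Ties in the HPD window search break to the leftmost window.
- Degenerate prior scales (0) are honoured as point masses when *sampling*
  the prior (used by exactness tests) but rejected by `log_prior`, which
  requires strictly positive scales.

## Known limitations

- The ensemble sampler needs many walkers in high dimensions; the full
  129-parameter model at 4 × 1000/1000 defaults is minutes of CPU, and
  short runs will (correctly) come back WARN.
- Trips-per-harvester quantiles are reported but not pinned by the fixture:
  the published median (7.5 over 23 harvesters) is not reproducible under
  the middle-order-statistic convention for odd n, so the underlying
  convention is unknowable from the text.
- Per-patch success slopes, alternative GP kernels, and refitting under
  restricted choice sets are out of scope by design; the seams where they
  would attach (`ModelLayout`, `gp_age_cov`, `scenario_patch_removal`) are
  noted above.
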