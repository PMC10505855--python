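# patchchoice

Joint Bayesian modelling of Arctic foraging **patch choice** and
**within-patch harvest success**, built for trip-diary data from Inuit
communities with mixed cash–subsistence economies. It is aimed at human
behavioural ecologists and quantitative anthropologists who want to ask how
socio-economic position — household income, gender, age, and embeddedness in
the community food-sharing network — shapes which foraging activities people
pursue and how often those activities succeed.

## The model

Each foraging episode *i* records a harvester, a season, and a chosen patch
*X<sub>i</sub>* ∈ {1, …, 7} — a category of foraging activity defined by
season, habitat, target species and method (winter inland, winter marine,
spring inland, summer/autumn inland, summer/autumn marine, tidal,
incidental). Patch choice is categorical with softmax probabilities

> Pr(X<sub>i</sub> = k) = exp(η<sub>ik</sub>) / Σ<sub>j</sub> exp(η<sub>ij</sub>),
> η<sub>ik</sub> = α<sub>k,season(i)</sub> + γ<sub>k,gender(i)</sub> + δ<sub>k,age(i)</sub> + β<sub>k</sub>ᵀ x<sub>i</sub>

and harvest success *Y<sub>i</sub>* ∈ {0, 1} is Bernoulli with a logistic
link on an analogous linear predictor that conditions on the chosen patch
through its intercepts. The covariate vector x<sub>i</sub> holds
standardized household income, sharing-network in-degree and out-degree, and
trip group size. The age effects δ<sub>k,·</sub> follow a latent
Gaussian-process prior over the four ordered age classes (&lt;30, 30–40,
40–50, &gt;50) with a squared-exponential kernel, so nearby cohorts have
correlated effects. One household's missing income is imputed jointly via a
latent standardized income with Normal(0.5, 1) / half-Cauchy(0, 1)
hyper-priors. Sampling uses an affine-invariant ensemble MCMC over the full
joint density, with split-R-hat and effective-sample-size diagnostics.

Because the field data are confidential, the package ships a synthetic-data
generator that reproduces the published sample composition exactly (trip
counts per patch, the men/women split, group-size quartiles, one
missing-income household with 3 hunters and 35 trips, and the published
income–network-degree correlation structure), plus a model-based simulator
with known ground truth for parameter-recovery testing.

## Worked example

```python
import patchchoice as pc

# generate the synthetic study fixture (281 trips, 23 harvesters, 13 households)
trips, households = pc.default_fixture()
summary = pc.summarize_sample(trips, households)
print("trips:", summary.n_trips)                      # trips: 281
print("men's trips:", summary.trips_per_gender["man"])  # men's trips: 228
print("r(income, out-degree):", round(summary.corr_income_out_degree, 3))  # 0.389
print("r(income, in-degree):", round(summary.corr_income_in_degree, 3))    # -0.218

# prior predictive check at a reference profile
profile = pc.HarvesterProfile(gender="man", age_class="40to50", income=0.0,
                              in_degree=0.0, out_degree=0.0, group_size=0.0,
                              season="ice", standardized=True)
pp = pc.sample_prior_predictive(pc.PriorConfig.default(), profile,
                                n_draws=10_000, seed=1)
print(round(pp.choice_probs[:, 0].mean(), 3))   # 0.138  (≈ 1/7 by prior symmetry)
print(round(pp.success_probs.mean(), 3))        # 0.502  (≈ 1/2 by prior symmetry)
```

The fixture counts are the published sample margins; the household
correlations land within ±0.005 of the published values (0.39 and −0.22 over
the 12 income-known households). The prior-predictive means sit at 1/7 and
1/2 because the default priors are symmetric across patches and around zero
— a structural check that the model's prior carries no hidden preference for
any patch or outcome.

A full analysis runs from the shell:

```sh
patchchoice simulate --fixture --out simdata
patchchoice fit --trips simdata/trips.csv --chains 4 --warmup 1000 --draws 1000 --out fit
patchchoice predict --fit-dir fit --preset fig2_reference --sweep income --out predictions
patchchoice predict --fit-dir fit --preset fig3b_lowincome --remove-patch winter_marine --out predictions
```

`predict` writes per-patch posterior means with 89% highest-posterior-density
intervals for counterfactual harvester profiles, income sweeps over the
observed income range, and patch-removal scenarios (e.g. winter marine
becoming inaccessible through poor ice) in which choice probabilities are
renormalized over the remaining patches.

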