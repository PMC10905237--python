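# mpnull

**Null models and comparative statistics for multiple paternity in birds and
mammals.**

Parentage studies report, for each studied population, how many broods or
litters were genotyped, the mean brood size k̄, the mean number of sires per
brood s̄, and the proportion of broods with more than one sire (the observed
probability of multiple paternity, *p*). `mpnull` asks the question such
compilations raise: *how much multiple paternity should we expect if every
mated male had an equal chance of siring offspring?* — and provides the full
comparative toolkit built around that null model.

## The model

Brood sizes follow a zero-truncated Poisson, K ~ ZTP(λ); conditional on
K = k, the number of sires S follows a Poisson with rate θ doubly truncated
to {1, …, k} (a brood has at least one and at most k sires). The null
expectation of multiple paternity is

```
pB(θ, λ) = Σ_k  P(K = k | λ) · P(S > 1 | θ, k)
```

and a population's deviation from the null is **pB − p**. θ and λ are
estimated per population from the reported (k̄, s̄, n) by adaptive
Metropolis-within-Gibbs MCMC with gamma priors; pB and its 95% credible
interval are derived from the posterior draws. pB rises steeply with brood
size at small broods and plateaus near brood size 10.

Around the null model the package implements the comparative analyses such a
meta-analysis needs:

- **io/records** — delimited population tables, record invariants
  (1 + p ≤ s̄ ≤ k̄, p·n near-integer), the six-bin mean-brood-size clustering
  (≤2.5, …, >6.5), and species pooling;
- **group statistics** — Cochran–Mantel–Haenszel common odds ratio with
  exact or Monte-Carlo permutation inference over brood-size strata,
  per-stratum log odds ratios, a clustered Wilcoxon rank-sum test with
  within-cluster permutations, Welch t-tests, and Krippendorff's alpha with
  bootstrap confidence intervals for the consistency of repeat studies of
  one species;
- **phylogenetics** — Newick IO, majority-rule consensus, tree grafting,
  phylogenetic correlation matrices, and Bayesian phylogenetic mixed models
  (Gaussian, and binary on the logistic liability scale) yielding the
  phylogenetic heritability h = σ²ₚ/(σ²ₚ + σ²ₑ) and phylogeny-adjusted group
  contrasts (δ, LOR);
- **synthetic data** — a first-class generator producing literature-style
  cohorts (ZTP broods, Dirichlet mate-monopolization calibrated to a target
  mean p, repeat-study species, Yule trees, traits at controlled h).

## Worked example

```python
from mpnull import NullModelConfig, PopulationRecord, fit_null_model

record = PopulationRecord(
    species_name="Synthea exempli", population_id="demo/1",
    clade="bird", technique="microsatellite", mating_system="monogamous",
    n_broods=50, mean_brood_size=3.6, mean_n_sires=1.25, prop_mp=0.20,
)
fit = fit_null_model(record, NullModelConfig(
    n_iter=4000, n_burnin=1000, n_chains=2, seed=11))
```

prints (via `python examples/fit_population.py`):

```
posterior null prediction pB = 0.412  (95% CI 0.357-0.471)
observed multiple paternity p = 0.200
deviation pB - p = +0.212 (CI +0.157 to +0.271)
sampler diagnostics: split R-hat 1.002, ESS(theta) ~ 1362
```

Under equal siring success, a population with broods of ~3.6 and 1.25 sires
per brood should show multiple paternity in about 41% of broods; observing
20% puts it about 21 percentage points below the null — the typical pattern
in birds, which sit far below the null on average, while mammals sit closer
to it.

The `examples/` directory has one short script per capability
(`null_model_curve.py`, `fit_population.py`, `compare_groups.py`,
`phylo_heritability.py`, `full_pipeline.py`), and the `mpnull` CLI exposes
the pipeline stages (`simulate`, `fit-null`, `compare`, `phylo`) over a YAML
run config.

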