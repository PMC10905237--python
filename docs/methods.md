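# Methods

## The null model

A population is summarised by (n, k̄, s̄, p): broods genotyped, mean brood
size, mean sires per brood, and the proportion of broods with more than one
sire. The null model assumes every mated male has the same chance of siring
each offspring, and asks what p would then look like.

- **Brood sizes** K ~ zero-truncated Poisson(λ). The ZTP mean is
  λ/(1 − e^{−λ}); given a mean brood size k̄ > 1 the rate is recovered by
  monotone bisection (`ztp_lambda_from_mean`). k̄ ≤ 1 is a degenerate
  distribution (every brood has one offspring): multiple paternity is then
  impossible and the fit short-circuits to pB ≡ 0.
- **Sire counts** S | K = k ~ Poisson(θ) doubly truncated to {1, …, k}: a
  brood has at least one sire and cannot have more sires than offspring.
  The per-potential-sire success probability is q = θ/k.
- **Null prediction** pB(θ, λ) = Σ_k P(K = k | λ)(1 − P(S = 1 | θ, k)),
  evaluated by direct summation with the series truncated at
  k ≤ λ + 10√λ + 25, beyond which the Poisson tail mass is far below 1e−10
  (weights are renormalised over the retained range). Non-integer mean brood
  sizes are handled by integrating over the ZTP distribution, never by
  evaluating the sire law at a fractional k.

### Estimation

θ and λ are estimated per population from the summary statistics with a
Gaussian pseudo-likelihood at the summary level:

- k̄_obs ~ Normal(E[K | λ], sd(K | λ)/√n),
- s̄_obs ~ Normal(μ_s, sd(S | θ, λ)/√n),

where sd(S) comes from the law of total variance over the ZTP brood mix. A
small floor (0.005) is added to each sampling sd so that populations with
s̄ = 1 exactly (zero observed variance) remain numerically well posed.

Two conventions relate s̄ to θ, both implemented and switchable:

- **rate_plugin** (default): μ_s = θ — the observed mean sire count
  identifies the Poisson rate before truncation. This reproduces the
  magnitude of published null predictions for birds (pB ≈ 0.42–0.55 at the
  bird-wide means k̄ = 3.64, s̄ = 1.25) and keeps pB strictly positive for
  populations that observed no multiple paternity at all.
- **mean_calibrated**: μ_s = E[S | θ, λ] — the self-consistent convention
  for data actually generated by the null process. Parameter-recovery and
  all-null calibration checks use this convention, because under it θ is
  identified without bias from null-simulated broods.

The exact likelihood used in the original rjags analysis this package
parallels is not published in accessible form; the two conventions bracket
the reasonable reconstructions, and the defaults reproduce the qualitative
structure (strong positive deviations in birds, weaker in mammals) with
somewhat smaller magnitudes than the printed means (about 0.20 vs 0.34 for
birds, 0.07–0.09 vs 0.14 for mammals at the package's study-structured
synthetic cohort). The distribution-level properties — closed forms vs
simulation, monotonicity, coverage — are exact and are what the test suite
enforces quantitatively.

Priors are Gamma(1, 0.5) on θ and Gamma(1, 0.25) on λ (weakly informative,
positive support). The sampler is Metropolis-within-Gibbs on (log θ, log λ)
with per-coordinate Gaussian random walks whose scales adapt during burn-in
toward a 20–50% acceptance rate. Defaults: 3 chains × 10,000 iterations with
2,000 burn-in, per-chain seeds spawned deterministically from the config
seed. Convergence is summarised by the split-chain potential scale reduction
factor (warning above 1.01) and an autocorrelation-based effective sample
size. Credible intervals are equal-tailed 2.5/97.5 percentiles. The
acceptance script and the heavier tests run 2 chains × 2,000–3,000
iterations per population — at two parameters per fit the posterior is
effectively exact well below the defaults, and 202 fits complete in under a
minute.

## Group comparisons

- **Brood-size clustering**: mean brood sizes are binned into six clusters —
  ≤ 2.5, then unit bins centred on 3, 4, 5, 6, and > 6.5 — so comparisons
  can control for the strong nonlinear dependence of multiple paternity on
  brood size.
- **CMH**: the Mantel–Haenszel common odds ratio Σaᵢdᵢ/nᵢ / Σbᵢcᵢ/nᵢ over
  the 2×2×6 table. Inference permutes group labels within each stratum with
  margins fixed, making the stratum "a" cells independent central
  hypergeometric draws; `exact` mode enumerates the joint distribution when
  the state space is small enough, otherwise Monte Carlo with the +1/(N+1)
  correction. Two-sided on |common log odds ratio|. Per-stratum log odds
  ratios apply a 0.5 continuity constant only to strata containing a zero
  cell. The asymptotic chi-square CMH test is deliberately not the primary
  p-value; permutation inference is.
- **Clustered Wilcoxon rank-sum**: within each cluster, values are
  mid-ranked; group A's rank sum is centred at its permutation expectation
  and the total is scaled by the root of the summed within-cluster
  permutation variances (tie-corrected). Clusters containing only one group
  contribute nothing. Significance from 2,000 within-cluster label
  permutations by default, two-sided on |W|.
- **Welch t-tests** (scipy) compare clade means of the reported summaries.
- **Krippendorff's alpha** (interval metric by default; ratio available)
  measures the consistency of repeated population measurements within
  species: α = 1 − D_obs/D_exp over pairable values, units with fewer than
  two values ignored. Confidence intervals by percentile bootstrap over
  units. There is no suitable alpha implementation among the package's
  dependencies, so it is implemented here and checked against hand-computed
  enumerations.

All permutation and bootstrap seeds are mandatory inputs recorded in the
result objects; p-values are two-sided throughout (sidedness is a package
choice).

## Phylogenetic mixed models

Trees are rooted, ultrametric, handled through dendropy; the correlation
matrix C has C[i,j] = shared root-to-MRCA path length divided by tree depth.
Grafting two clade trees under a new root at a chosen divergence time
rescales all correlations by subtree-depth/divergence-time; since C is
depth-normalised, the absolute calibration of the divergence time affects
nothing downstream.

- **Gaussian model**: y = β0 + δx + u + e, u ~ N(0, σ²ₚC), e ~ N(0, σ²ₑI).
  The phylogenetic effect is marginalised analytically — y ~ N(Xβ, σ²ₚC +
  σ²ₑI) — and sampled in the eigenbasis of C, where each likelihood
  evaluation is O(n): β by its Gaussian (GLS) full conditional, the two log
  variances by adaptive random-walk Metropolis. This marginal sampler was
  chosen over single-site Gibbs on (u, σ²ₚ) because the latter mixes
  pathologically (σ²ₚ can stick near zero) when C is nearly singular, as it
  is for large simulated trees with short terminal branches.
- **Binary model**: P(y = 1) = logistic(β0 + LOR·x + u), residual variance
  fixed at π²/3 so the group effect is directly a log odds ratio. u is
  updated by elliptical slice sampling, β by adaptive Metropolis, σ²ₚ by its
  conjugate inverse-gamma conditional. h = σ²ₚ/(σ²ₚ + π²/3). A probit link
  is not offered.
- Priors: Normal(0, 100²) on fixed effects; inverse-gamma(0.01, 0.01) on
  variances (near scale-invariant, so h is insensitive to the response
  scale). Responses are aggregated to one value per species (unweighted mean
  over populations) before fitting; body-mass analyses use log10 grams since
  mass spans orders of magnitude.

## The synthetic-data generator

The generator emulates a compiled literature dataset; its defaults encode
the study conditions of the microsatellite compilation it parallels:

| quantity | bird | mammal |
|---|---|---|
| populations | 138 | 64 |
| species | 120 | 61 |
| mean brood size | 3.64 | 3.92 |
| target mean p | 0.195 | 0.456 |
| broods/population (lognormal mean) | 51.2 | 37.7 |
| socially monogamous fraction | 0.75 | 0.10 |

Mechanism: per species, a brood rate λ (lognormal around the clade mean,
log-sd 0.30, mean-centred) and a target p (Beta with concentration 4 around
the clade mean); per population, a target p re-drawn around the species
value (concentration 5) — so brood size is more repeatable across studies of
one species than multiple paternity, as the consistency analysis expects.
Siring success is concentrated by giving each brood's k mates symmetric
Dirichlet(w) shares and assigning offspring multinomially; the chance a
brood of size k is singly sired is then M·(w)ₖ/(Mw)ₖ in rising factorials,
which lets w be calibrated by bisection so each population's expected p
equals its target — the generator hits the study's mean p by construction,
not tuning. Targets above the equal-share ceiling (small broods cannot show
much multiple paternity) saturate at the ceiling, which pulls the realised
mammal mean a few points below 0.456; this is a structural property of the
mechanism, not noise. The equal-success branch (`siring="null"`) delegates
to the null model's own brood simulator and is the basis of the end-to-end
calibration checks.

Trees are Yule (pure birth) with relabelled tips; Gaussian traits are
β0 + δx + N(0, hC) + N(0, (1−h)I) on a unit-variance scale; binary traits
threshold a logistic liability with σ²ₚ = h/(1−h)·π²/3.

What the generator does **not** emulate: real species identities or
phylogenies, any coupling between mating system and multiple paternity
(none was found in the data the package parallels), technique-specific
detection bias (the fingerprint-vs-microsatellite contrast is supported as a
generic two-level grouping only), body-mass allometry, or geographic/
life-history covariates. Passing tests therefore demonstrate that the
machinery is correct under the stated generative assumptions — not that
those assumptions describe any particular real dataset.

## Numerical choices and degenerate inputs

- Series truncation k ≤ λ + 10√λ + 25 (capped by `max_k`), weights
  renormalised; sire-count tables computed with a max-shifted exponential to
  avoid overflow.
- Record validation reports rather than raises; invalid records are
  excluded from fitting by default (`keep_invalid` retains them for
  descriptive statistics). p·n integer consistency uses a 0.51 tolerance
  because published proportions are rounded.
- k̄ ≤ 1 → degenerate fit (pB ≡ 0, deviation −p, flagged). Degenerate CMH
  tables (a zero margin in every stratum) → p = 1 with a warning. All-tied
  rank-sum inputs → W = 0, p = 1. Constant binary PMM responses → warning,
  prior-dominated posterior.
- Correlation matrices from trees with near-zero branches can be
  numerically singular; the binary model's Cholesky adds a 1e−8 ridge with
  a warning, and the Gaussian model's eigendecomposition clips negative
  eigenvalues at zero.
- Exact CMH enumeration falls back to Monte Carlo (with a warning) above a
  configurable state-space budget (default 2×10⁶ joint states).

## Known limitations

- The summary-level Gaussian pseudo-likelihood is an approximation to a
  brood-level likelihood; for very small n (< ~10 broods) the normal
  approximation of k̄ and s̄ is rough.
- The rate_plugin convention is a reconstruction; published per-population
  deviation magnitudes depend on the original estimation code, which is not
  reproducible from the printed record. Deviation *orderings* and signs are
  robust to the convention; magnitudes shift by roughly a third between
  conventions.
- Heritability estimates from the binary model depend on the fixed logistic
  residual scale, as in any threshold model; h values are comparable within
  this package, not across link functions.
- The consistency alphas from the generator run higher than typical
  literature values for p because the generator's within-species
  heterogeneity is a single dispersion knob, not study-level methodological
  variation.
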