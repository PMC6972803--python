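# Methods

This note records the model, its numerical implementation, the synthetic
data generator, and the design choices made where more than one reasonable
option existed. Everything quantitative stated here is computed by the
test suite or by `scripts/acceptance.py`.

## Model and assumptions

The data are detection counts N_ijk for species i = 1..I, spatial unit
j = 1..J and status k (dead/alive), with per-unit surface S_j (km²) and
kilometres driven V_j. The observation level assumes

* counts are conditionally independent Poisson given the log intensity
  s_j + a_ij + e_jk + p_ik;
* dead-status effort is proportional to kilometres driven — any
  proportionality constant is absorbed into a_ij, which is legitimate
  because a_ij is a *relative* abundance, defined only up to a
  species-specific constant;
* alive-status effort e_j2 is a free per-unit parameter shared by all
  species — this is why the model is fitted to the full multi-species
  registry rather than the focal species alone;
* detectability offsets satisfy p_i1 = 0 for every species and p_1k = 0
  for the reference species (species index 0; configurable). These
  constraints follow algebraically from the natural-parameter
  factorization S·A·E·P and make all remaining parameters identifiable —
  the package verifies the equivalence numerically
  (`natural_to_reduced`, tested to 1e-10).

The selection level places a Gaussian regression with Kuo–Mallick
spike-and-slab structure on the focal species' a_bj. Every Normal in the
model is parameterized by **precision** (inverse variance), the convention
of the Gibbs-sampling software family this class of models is usually
fitted with. Hence β_r ~ N(0, precision 0.01), i.e. sd 10 — genuinely
vague; reading 0.01 as a variance would be a sharply informative prior,
contradicting its role. τ carries a Uniform(0.0001, 1000) prior on the
precision scale, exactly as printed.

Priors not fully pinned down by the source model description, chosen here
and documented as this package's own choices:

* intercept a0: N(0, precision 0.01), conjugate Gibbs update;
* nuisance observation parameters (non-focal a_ij, e_j2, p_i2):
  N(0, precision 0.01) — vague, proper, and stabilizing for units with
  zero counts.

The model deliberately ignores residual spatial autocorrelation and
covariates on detectability; absolute density is unidentifiable by design.

## Sampler

Metropolis-within-Gibbs. One sweep:

1. element-wise Gaussian random-walk Metropolis on all a_ij, e_j2, p_i2.
   Given the other blocks the Poisson likelihood factorizes over the
   updated elements, so the whole block is proposed and accepted
   element-wise in one pass. The focal row's ratio includes the
   N(μ_j, τ) regression term; all other elements use their N(0, 0.01)
   priors.
2. Gibbs: a0 (conjugate Normal), then each (γ_r, β_r) pair — γ_r from the
   two-point conditional with β_r held fixed, computed on the log scale;
   β_r from the prior when excluded (the Kuo–Mallick "detached" draw) or
   from the conjugate Normal when included.
3. τ from its truncated Gamma(J/2 + 1, SSR/2) full conditional by inverse
   CDF on the truncated region. When SSR underflows to exactly zero the
   conditional is the pure power law τ^(J/2) on the support, sampled by
   its closed-form inverse CDF; when the Gamma places numerically zero
   mass inside the support an exponential-tilt approximation at the
   nearer boundary is used.

Protocol defaults mirror the study: 3 chains, 1,000 burn-in sweeps,
300,000 recorded sweeps thinned by 100. The package's tests and examples
use the scaled-down `quick_profile` (3 chains × 2,000 + 20,000, thin 10),
which on the lowland-preset problem (J = 500, I = 6, R = 13) delivers
inclusion probabilities with cross-chain differences around 0.01 in under
a minute per fit; the problem sizes used by each test are stated in the
tests themselves.

Numerical choices:

* Proposal scales adapt per element toward 0.35 acceptance during burn-in
  only (multiplicative updates every 50 sweeps, clipped to [1e-3, 10]);
  the post-burn-in kernel is fixed, so the chain is a genuine
  time-homogeneous Markov chain where it is recorded. Post-adaptation
  acceptance rates on generator-default scenarios sit in [0.1, 0.6]
  (asserted as a smoke check).
* Initial values: a_ij from the dead-status crude rate
  log((N_ij1 + 0.5)/(S_j V_j)); e_j2 from log V_j plus the unit's pooled
  log alive/dead count ratio (a moment-matched start — starting e_j2 at 0
  would place it ~10 log units from its posterior mass at realistic
  kilometre scales and waste most of a short burn-in); p_i2 = 0;
  γ_r ~ Bernoulli(0.5); β_r = 0; a0 = mean of the focal starting row;
  τ = 1.
* Chain c is seeded with seed + c; runs are bit-reproducible given the
  seed. The sweep kernel is numba-compiled with a pure-Python fallback of
  identical code.
* log(N!) via the log-gamma function; all accumulation in double
  precision; a non-finite sampler state raises rather than propagating.
* Units with V_j = 0 are dropped with a logged warning (their dead-status
  offset would be −∞).
* Retained draws per chain: γ, β, a0, τ, the focal row a_b, e_alive and
  p_alive. Non-focal a_ij draws are not retained — they are high-volume
  nuisance output with no downstream consumer in the pipeline.

## Correctness testing

Two independent oracles back the sampler:

* **Exact enumeration.** With the observation level replaced by a fixed
  Gaussian response and τ fixed, the marginal likelihood of every
  inclusion pattern is a closed-form multivariate normal; posterior model
  probabilities from the Gibbs sampler match enumeration over all 2³
  models within Monte-Carlo error (batch-means standard errors).
* **Geweke successive-conditional test.** Alternating a Gibbs sweep over
  (γ, β, a0) with a redraw of the response from the model leaves the
  prior × model joint invariant; bounded statistics match direct prior
  sampling. The test fixes τ: with τ free (or large), an included
  coefficient's conjugate update has shrinkage factor
  τΣx²/(0.01 + τΣx²) ≈ 1, a near-unit-root random walk whose Monte-Carlo
  error cannot be estimated at feasible chain lengths. τ's conditional is
  instead checked against a rejection-sampling oracle (two-sample KS),
  and the conjugate β and a0 draws against their closed forms exactly
  (identically seeded streams).

Parameter recovery is tested on ten replicates of the lowland preset:
clean separation (all active p_r > .5, all inactive < .5) is required in
at least nine, and the refit 95% intervals must cover the generating
coefficients in at least 90% of coefficient-replicates. The recovered
coefficients show the expected slight attenuation (a few percent toward
zero) because a_bj is latent and estimated from finite counts.

## Synthetic data generator

The generator draws covariates, nuisance parameters, the focal regression
and the Poisson counts from exactly the model the sampler assumes, so
recovery tests are well-posed. Defaults emulate a national multi-year
roadside registry:

| quantity | default | rationale |
|---|---|---|
| V_j (km) | log-normal(meanlog 11, sdlog 0.7) | tens of thousands of km per unit over a multi-year window |
| S_j (km²) | log-normal(meanlog 6.6, sdlog 0.8) | units of a few hundred km², right-skewed |
| focal a0 | −15.4 | ≈ 10–15 focal detections per unit at the above effort/surface scales |
| τ (focal noise precision) | 25 | residual sd 0.2 on the log scale |
| non-focal a_ij | N(a0, sd 0.5) | species detected at rates comparable to the focal species |
| e_j2 | N(log V_j − 1, sd 0.3) | alive-detection effort correlated with, but distinct from, km; yields ≈ 25–27% alive detections |
| p_i2 (i ≥ 2) | N(0, sd 0.5) | species-specific alive detectability offsets |
| covariate correlation (lowland preset) | 0.3 | environmental layers over one landscape are moderately correlated |

The `lowland` preset fixes J = 500, I = 6 (badger focal), R = 13 named
covariates with active effects earthworm +0.461, fruit +0.400, pasture
+0.541, edge −0.407 and τ = 25. Non-focal a_ij are centred on a0 rather
than 0: with effort anchored to real kilometre scales, a species at
a_ij ≈ 0 would produce ~10⁷ detections per cell, which no roadside survey
resembles; centring on a0 keeps all species in the registry's regime.

A single seed drives everything through per-component sub-streams
(covariates, effort, nuisance, focal noise, counts), so reconfiguring one
component leaves the others' draws untouched.

What the generator does **not** emulate — and hence what passing recovery
tests do not establish about field data: spatial autocorrelation in
covariates or abundance, overdispersion relative to Poisson, seasonal or
interannual dynamics, species misidentification, and covariate
measurement error.

## Summaries and open choices

* "Best model" = the most frequently visited γ-pattern; the model table
  reports visit frequencies of all visited patterns (sums to 1; the
  inclusion probability p_r equals its marginal, checked exactly).
* Selection threshold: strictly p_r > 0.5. The refit freezes γ (selected
  = 1, others = 0) and reruns the sampler with no indicator updates;
  intervals are equal-tailed 2.5/97.5 percentiles.
* Abundance-index rescaling: min–max on the per-unit posterior means of
  a_bj — the simplest map achieving a [0, 1] index; rank-based
  alternatives would also satisfy the stated endpoints, and the choice is
  recorded as open. In the two-strata pipeline the index is rescaled
  within each stratum, since strata are fitted (and their a_b scales
  anchored) separately.
* Elevation split: units with mean elevation exactly at the threshold
  (default 400 m) go to the mountain group; the source material never
  places a unit exactly at the boundary, so the convention is ours.
* Climate PCA runs on the correlation matrix of the 24 monthly columns,
  with each retained axis's sign fixed so its largest-magnitude loading
  is positive (reproducible across linear-algebra backends).
* Column standardization uses the sample (J−1) standard deviation.

## Known limitations

* The Kuo–Mallick detached draw makes re-entry of a strongly supported
  covariate a waiting-time event (the prior must propose a plausible β);
  with sd-10 priors this costs tens of sweeps per re-entry. The default
  protocols are long enough that this is immaterial, but very short
  custom runs may under-mix γ.
* Inclusion probabilities very near 0 or 1 are reported as exactly 0 or 1
  at finite chain length.
* The sampler is single-threaded; chains run sequentially.
* Attenuation of refit coefficients (latent-response regression) is not
  corrected; at registry-scale counts it is a few percent.
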