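# abundsel

Effort-corrected **relative abundance** from multi-species count surveys,
with Bayesian **spike-and-slab selection** of the environmental drivers of
one focal species.

## The problem

National roadside registries record where officers encountered animals —
dead (roadkill) or alive — of a set of monitored species, together with the
kilometres driven in each spatial unit. Counts of detections confound true
abundance with sampling effort and detectability, so raw counts cannot be
compared across regions. `abundsel` fits a two-level hierarchical model
that separates these ingredients and then asks which environmental
covariates (food resources, soil, landscape, climate, urbanization) drive
the focal species' abundance. The motivating application is the European
badger (*Meles meles*) surveyed alongside five other mustelids across the
small agricultural regions of France, but the model applies to any
registry with the same structure.

## The model

**Observation level.** The count of species *i* in unit *j* with status
*k* (1 = dead, 2 = alive) is Poisson:

    N_ijk ~ Poisson(λ_ijk),   λ_ijk = S_j · A_ij · E_jk · P_ik

with unit surface S_j, true density A_ij, effort E_jk and detectability
P_ik. These factors are not separately identifiable; the model is fitted
in the equivalent log-linear form

    log λ_ijk = s_j + a_ij + e_jk + p_ik

with s_j = log S_j fixed, dead-status effort anchored to kilometres
(e_j1 = log V_j), and constraints p_i1 = 0 ∀i, p_1k = 0 for the reference
species. Every free parameter is then identifiable and a_ij is species
*i*'s **log-relative abundance** (true density times an unknown
species-specific constant). Pooling all monitored species identifies the
shared per-unit alive-status effort e_j2.

**Selection level.** For the focal species *b* only,

    a_bj ~ Normal(μ_j, precision τ),   μ_j = a0 + Σ_r γ_r β_r X_jr

over R standardized covariates, with Kuo–Mallick indicators
γ_r ~ Bernoulli(0.5), vague β_r ~ Normal(0, precision 0.01), and
τ ~ Uniform(0.0001, 1000). The posterior inclusion probability
p_r = Pr(γ_r = 1 | data) ranks the covariates; those with p_r > 0.5 are
refitted with γ frozen to give coefficient estimates with 95% credible
intervals, and the posterior mean a_bj is min–max rescaled into a [0, 1]
abundance index per unit.

Sampling is Metropolis-within-Gibbs (random-walk updates for the
observation level, conjugate/Kuo–Mallick Gibbs updates for the selection
level), three chains by default, with mixing judged by cross-chain
agreement of the p_r.

## Worked example

Simulate a survey with known truth (the `lowland` preset: 500 units, 6
species with the badger focal, 13 correlated covariates of which earthworm
+0.461, fruit +0.400, pasture +0.541 and edge −0.407 act on badger
abundance, noise precision τ = 25), fit it with the scaled-down test
profile, and summarize:

```python
from abundsel import (lowland_scenario, generate_covariates, simulate_survey,
                      quick_profile, run_mcmc, check_chain_agreement,
                      inclusion_probabilities, select_and_refit, abundance_index)

spec = lowland_scenario(seed=101)
X = generate_covariates(spec.J, spec.R, spec.covariate_correlation,
                        spec.seed, names=spec.covariate_names)
data, truth_obs, truth_sel = simulate_survey(spec, X)

draws = run_mcmc(data, X, quick_profile(seed=101))
print(check_chain_agreement(draws))
fit = select_and_refit(draws, data, X, config=quick_profile(seed=101))
print(fit.table)
index = abundance_index(fit)
```

Output:

```
cross-chain agreement PASS: max |Δp_r| = 0.0110 (climate_alpine), tolerance 0.05
    variable  p_r  beta_mean    ci_low   ci_high
0       edge  1.0  -0.416769 -0.451982 -0.381616
1  earthworm  1.0   0.446713  0.413154  0.480025
2    pasture  1.0   0.524748  0.492446  0.557738
3      fruit  1.0   0.421727  0.387943  0.454986
```

All four generating covariates are recovered with inclusion probability
1.0 (the nine inactive ones stay below 0.01), each 95% interval covers its
generating value, and `index` maps every unit onto [0, 1] with the least
and most abundant units at the endpoints.

The same pipeline is available from the shell:

```sh
abundsel simulate --preset lowland --seed 101 --out sim/
abundsel fit --counts sim/counts.csv --effort sim/effort.csv \
             --covariates sim/covariates.csv --profile test --out fit/
abundsel summarize --draws-dir fit/ --out summary/
```

For real data, `abundsel prep` standardizes raw covariate tables (and can
append principal components of 24 monthly climate columns), and
`abundsel run-all` drives the whole pipeline, optionally splitting units
into lowland/mountain strata at a 400 m elevation threshold and fitting
each stratum separately.

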