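# nmixsdm

Tools for two questions that arise together in invasion ecology and applied
conservation:

1. **How many animals are really there?** Repeated visual counts miss
   individuals, so raw counts confound abundance with detectability.
   `nmixsdm` fits hierarchical binomial N-mixture models — latent site
   abundance `N_i ~ dist(λ_i)` with counts `y_ij ~ Binomial(N_i, p_ij)` —
   with covariates on both levels (`log λ` linear in site covariates such as
   invader presence and habitat; `logit p` linear in survey covariates such
   as cloud cover), Poisson / negative-binomial / zero-inflated-Poisson
   abundance distributions, AICc model ranking with Akaike weights, and a
   parametric-bootstrap chi-squared goodness-of-fit test with a `c-hat`
   over-dispersion diagnostic.
2. **Where could the species live?** From presence-only points and gridded
   environmental layers, `nmixsdm` builds ensemble species distribution
   models: per-cell deduplication, pairwise collinearity screening
   (|r| < 0.7), uniform background pseudo-absences at 10x presences,
   repeated stratified 80/20 splits across five base learners, an AUC > 0.7
   inclusion filter, a cell-wise **median** ensemble map, binarization at
   the sensitivity+specificity-maximising threshold, and derived range
   metrics — area, directional range overlap, combined ranges, Levins'
   niche breadth, and distances from known subpopulations to a predicted
   range.

A synthetic-data module generates count data from a known N-mixture process
and landscapes/occurrences from a known suitability surface, so every stage
can be validated against ground truth. See `docs/methods.md` for the models,
conventions and their limitations.

## Worked example

```python
import numpy as np
import nmixsdm as nx

# a 21-site x 6-survey count matrix from a known zero-inflated process
truth = nx.default_truth("zip")
data, truth = nx.simulate_counts(truth, n_sites=21, n_surveys=6, seed=42)

spec = nx.ModelSpec(family="zip", abundance_terms=["status"],
                    detection_terms=["cloud", "habitat"])
fit = nx.fit(data, spec)
print(f"logLik = {fit.log_likelihood:.2f}, K = {fit.n_params}, "
      f"AICc = {nx.aicc(fit.log_likelihood, fit.n_params, data.n_sites):.1f}")

for status in ("absent", "present"):
    p = nx.predict(fit, "abundance", {"status": status})
    print(f"abundance, invader {status}: {p.estimate:.1f} "
          f"(95% CI {p.lower:.1f}-{p.upper:.1f})")

a = nx.predict(fit, "abundance", {"status": "absent"}).estimate
b = nx.predict(fit, "abundance", {"status": "present"}).estimate
print(f"decline: {nx.percent_decline(a, b):.0f}%")

gof = nx.parametric_bootstrap_gof(data, fit, n_boot=30, seed=1)
print(f"GOF: p = {gof.p_value:.2f}, c-hat = {gof.c_hat:.2f}")
```

prints

```
logLik = -161.41, K = 7, AICc = 345.4
abundance, invader absent: 15.1 (95% CI 8.6-21.7)
abundance, invader present: 1.9 (95% CI 0.3-3.5)
decline: 88%
GOF: p = 0.47, c-hat = 1.04
```

The generating process had mean abundance 13.3 at uninvaded sites and 1.6 at
invaded ones; the model recovers 15.1 and 1.9 with intervals covering the
truth, an 88% decline attributable to the invader, and a goodness-of-fit
test that (correctly) finds nothing wrong with the generating family
(`c-hat ≈ 1`: no over-dispersion beyond the model).

The SDM side is one call once occurrences and layers exist:

```python
env = nx.simulate_landscape(n_layers=3, n_rows=100, n_cols=100,
                            smoothness=12, seed=2)
truth = nx.SuitabilityTruth(layer_coefs={"env_1": 12.0, "env_2": -8.0},
                            intercept=-5.0)
occ = nx.deduplicate(nx.simulate_occurrences(env, truth, 300, seed=3), env)
ens = nx.run_ensemble(occ, env, learners=["glm", "gam", "rf", "gbm", "maxent"],
                      n_reps=10, auc_min=0.7, seed=4)
print(f"ensemble AUC {ens.auc:.2f}, threshold {ens.threshold:.2f}, "
      f"range {nx.range_area(ens.binary_map):.2f} km^2")
```

## Command line

A thin CLI wraps the library:

```sh
nmixsdm simulate counts --seed 1 --out data/
nmixsdm fit-abundance --counts data/counts.csv \
    --site-covariates data/site_covariates.csv \
    --obs-covariates data/obs_covariates.csv \
    --family zip --abundance status --detection cloud+habitat
nmixsdm sdm --occurrences occ.csv --species invader --layers layers/ --out out/
nmixsdm metrics overlap --map-a out/range_invader.asc --map-b out/range_endemic.asc
nmixsdm run-all --config config.yaml --out run/
```

`run-all` executes the whole pipeline (simulate → fit 19 candidate models →
AICc table → GOF → predictions → two-species ensemble SDMs → range metrics)
from one YAML config and writes a manifest with seeds and SHA-256 digests of
every output; the same config always reproduces byte-identical results.

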