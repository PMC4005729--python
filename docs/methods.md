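# Methods

## The abundance model

`nmixsdm` estimates site abundance from repeated counts without assuming
every animal present is seen. The hierarchical (binomial N-mixture) model
is

    N_i ~ dist(lambda_i)                    latent abundance at site i
    y_ij | N_i ~ Binomial(N_i, p_ij)        count at site i, survey j

with `log lambda_i = x_i' beta` (site-level covariates: invader status,
habitat class) and `logit p_ij = w_ij' alpha` (observation-level covariates:
cloud cover in percent, temperature in deg C; site-level covariates may also
enter detection). `dist` is Poisson, negative binomial or zero-inflated
Poisson (ZIP). The negative binomial is parameterised by mean `lambda` and
size `k`, with variance `lambda + lambda^2/k`; ZIP mixes a point mass at
zero (probability `psi`, intercept-only on the logit scale) with a Poisson.

The likelihood integrates out `N_i` by direct summation from the largest
count observed at the site up to a truncation bound `K`:

    L_i = sum_{N}^{K} f(N | lambda_i) prod_j C(N, y_ij) p_ij^y_ij (1-p_ij)^(N-y_ij)

`K` defaults to the maximum observed count plus 100. The choice is checked
in the test suite by verifying that raising `K` by 50 changes the maximized
log-likelihood by less than 1e-6; users fitting data with very heavy-tailed
abundance (negative binomial with small size) should raise it. Missing
surveys are simply dropped from the inner product; the model assumes
closure within the survey day and independence between sites.

### Numerical choices

* All pmf evaluations are in log space; the latent sum uses `logsumexp`.
  Binomial coefficients come from a cached `gammaln` table; site blocks of
  512 bound memory at large site counts.
* Maximisation is quasi-Newton (BFGS, numerical gradient, `gtol = 1e-5`)
  with a Nelder-Mead polish if BFGS reports failure. Default starts: the
  abundance intercept from mean site maxima assuming p = 0.5, zeros
  elsewhere, size 1 for the negative binomial, `psi ~ 0.27` for ZIP.
* Standard errors come from the inverse of the numerically evaluated
  observed information. When an estimate sits on the parameter-space
  boundary (e.g. `psi -> 0` when the invaded stratum alone absorbs the
  zeros) the corresponding information row vanishes; the remaining block is
  inverted on its own and the boundary parameter's variance is reported as
  unavailable rather than silently wrong. A `boundary` flag is raised when
  any link-scale parameter exceeds 10 in magnitude or any fitted rate is
  pinned at its edge (`lambda < 0.01`, `p < 0.001` or `p > 0.999`).
* Confidence intervals are 95% Wald intervals by the delta method on the
  response scale; abundance is floored at 0, detection clipped to [0, 1].
  This matches the convention of reporting intervals like "0.0-3.2" for a
  nearly extirpated stratum. Link-scale intervals would never touch zero.
* Categorical covariates use treatment contrasts with the alphabetically
  first level as reference (absent; building).

## Model selection and adequacy

Candidates are ranked by the small-sample corrected AIC,
`AICc = -2l + 2K + 2K(K+1)/(n-K-1)`, with Akaike weights
`w_m = exp(-delta_m/2) / sum exp(-delta/2)`. The likelihood unit of an
N-mixture model is the site, so `n` defaults to the number of sites
(21 in the reference design, hence n/K < 40 and the corrected criterion).

Adequacy uses a parametric-bootstrap Pearson chi-squared test. The
statistic is `T = sum_ij (y_ij - E_ij)^2 / (E_ij + 0.5)` with
`E_ij = lambda_i p_ij` (scaled by `1 - psi` under ZIP); the 0.5 in the
denominator keeps cells with near-zero expectation finite and bounded, and
is applied identically to observed and bootstrap statistics so the test's
calibration is unaffected. Each bootstrap replicate simulates counts from
the fitted model, refits the same specification (starting from the original
estimates, for speed and stability), and recomputes `T`; the p-value is the
proportion of bootstrap statistics at least as large as the observed one,
over successful refits. `c_hat = T_obs / mean(T_boot)` diagnoses
over-dispersion: fitting the generating Poisson model yields `c_hat ~ 1`,
while fitting Poisson to strongly over-dispersed negative-binomial counts
drives `c_hat` above 1 — the classic reason to move from Poisson to
negative-binomial or zero-inflated families.

## The ensemble distribution model

Occurrences are first thinned to one per grid cell; layers pass a greedy
pairwise-collinearity screen (retain a layer iff |Pearson r| < 0.7 against
everything already retained, scanning in a user-supplied priority order —
the retained set is order-dependent by construction, and deterministic
given the order). Background pseudo-absences are drawn uniformly without
replacement from valid cells holding no presence, at 10 per presence, once
per species.

The ensemble repeats a stratified 80/20 split of the pooled
presence/background table 10 times and fits five base learners per split —
logistic regression, penalized spline logistic regression (the additive
smooth role), random forest, gradient-boosted trees, and an L1-penalized
logistic regression on quadratic feature expansions (the maximum-entropy
role). Each member is scored by ROC AUC (Mann-Whitney rank form, half
credit for ties) on its held-out 20%; members with AUC <= 0.7 are excluded.
The ensemble map is the cell-wise **median** of the included members'
predictions — less outlier-sensitive than the mean. The map is binarized
at the threshold maximising sensitivity + specificity (Youden's J) over the
pooled point scores, with the classification rule `score >= threshold`,
candidates at midpoints of consecutive unique scores, and ties resolved to
the smallest maximising threshold.

Design points that were genuinely open and the choices made:

* The 80/20 split applies to the pooled presence+background table,
  stratified by class so both classes appear on each side.
* Pseudo-absences are drawn once per species, not per repetition.
* A single map-level threshold is fitted on the full pooled set using
  ensemble scores (one sensitivity/specificity pair per species).
* All algorithms x repetitions pool into one median ensemble
  (5 x 10 = 50 candidate members per species).

## Range metrics

From binary maps: area = presence cells x cell area; directional overlap
`100 |A ∩ B| / |A|` (undefined, reported missing, for an empty range);
combined ranges by cell-wise OR. Levins' standardized niche breadth over
cells, `B = (1/sum p_i^2 - 1) / (n - 1)` with `p_i` the suitability share
of cell i, is 0 when one cell is suitable and 1 when all are; it is
computed on binary maps in the pipeline but accepts continuous
suitabilities (and is invariant to uniform rescaling). Distances from
points to a range are Euclidean point-to-nearest-presence-cell-center
(0 inside the range) — a convention that can differ from cell-edge
distance by at most half a cell diagonal — binned with right-closed edges
at 50/200/500/1000/1500 m by default, successive bins disjoint.

## What the synthetic generators emulate

`simulate_counts` mirrors a 21-site, 6-survey visual-count design: invader
present at 10 of 21 sites, habitats split 4 building / 4 non-palm /
13 palm, cloud uniform on [0, 100]%, temperature normal (28 ± 3 °C). The
default generating process reflects the reference analysis's fitted
magnitudes: mean abundance 13.3 without the invader vs 1.6 with it,
detection near 0.53/0.47/0.37 across building/palm/non-palm at 50% cloud
with slope −0.01 per % cloud, and (for ZIP) `psi = 0.2`, consistent with
endemics having vanished from a minority of invaded sites. Values the
reference analysis does not pin down (the cloud slope, `psi`, the negative
binomial size 1.5) were fixed once at these plausible magnitudes.

`simulate_landscape` produces standardized Gaussian-filtered white-noise
layers — spatially autocorrelated but stationary and Gaussian, which real
climate/terrain layers are not (no gradients, no coastlines, no
cross-layer physical structure). `simulate_occurrences` samples presence
cells proportionally to a known logistic suitability surface with no
observation bias, dispersal limitation or spatial clustering of effort.
Passing tests therefore demonstrate that the machinery recovers truth
under the model's own assumptions; they do not certify performance on
biased, spatially structured real survey data.

The recovery benchmark uses a 100 x 100 grid (30 m cells), three layers at
smoothness 12 cells, 300 presences, and a steep minority-prevalence
surface (`logit s = -5 + 12 env_1 - 8 env_2`, suitable fraction ~0.35):
a well-sampled, strongly structured species for which the ensemble's
binary map should agree with the true suitable region in >= 95% of cells.
The simulation sizes throughout (200-replicate recovery and coverage runs,
19-39 bootstrap replicates for goodness of fit, 40 x 40 pipeline grids in
the determinism check) were chosen as the smallest runs whose Monte-Carlo
error is comfortably inside the asserted bands.

## Known limitations

* No spatial dependence between sites; no open-population dynamics.
* ZIP zero-inflation is intercept-only; no covariates on `psi`.
* Wald intervals can undercover for boundary-adjacent parameters (tiny
  invaded-stratum abundance); profile or bootstrap intervals are not
  implemented.
* Planar geometry throughout — no CRS handling, no geodesic distances.
* The ASCII-grid raster interface is minimal (single NODATA value, no
  tiling); it exists for interoperability and inspectability, not scale.
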