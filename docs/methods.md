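# Methods

## The model

`birdmix` fits a Bayesian hierarchical community abundance model to repeated
point counts of a bird community surveyed at sites nested in blocks. The
data are counts `y[i,j,k]` of species `i` at site `j` on visit `k`. The
hierarchy, for each species `i` and site `j`:

```
w_ij ~ Bernoulli(psi_i)                      inclusion (zero inflation)
N_ij | w_ij ~ Poisson(w_ij * lambda_ij)      latent abundance
y_ijk | N_ij ~ Binomial(N_ij, p_ijk)         imperfect detection, per visit
```

with log-linear abundance

```
log lambda_ij = u1_i TRT_j + u2_i (1 - TRT_j) + o1_i ORI_j + o2_i (1 - ORI_j)
              + a1_i area_j + a2_i area_j TRT_j
              + a3_i TRT_j ORI_j + a4_i TRT_j (1 - ORI_j)
```

and logit-linear detection

```
logit p_ijk = v1_i + b1_i DATE_jk + b2_i DATE_jk^2 + b3_i TSR_jk + b4_i TSR_jk^2
```

`TRT` marks restored sites (revegetated open grass, or weed-controlled
forest), `ORI` marks forest origin, `area` is standardized log patch area,
`DATE` is standardized day-of-season and `TSR` standardized minutes since
sunrise. Because `a3` and `a4` multiply `TRT` within one origin each, they
are direct log-scale estimates of the benefit of weed control (forest) and
revegetation (grass) to a species' abundance.

Every species-level coefficient is pooled through its urban-sensitivity
class `c(i)` (sensitive / adaptable / exploitative):

```
coef_i ~ Normal(mu_coef,c(i), sigma_coef,c(i))
```

so the class-level `mu` are the quantities of management interest. Derived
quantities: per-draw site richness `Richness_jc = #{i in c : N_ij >= 1}`,
stratum means over (class, origin, treatment), and the richness benefit
`BRichness_c,o = mean richness (treated) - mean richness (untreated)` within
an origin. Sites whose block failed the weed-cover criteria are excluded
from both strata of the forest (weed control) contrast.

Closed populations are assumed across the three within-season visits; no
spatial correlation between sites; observer effects are not modelled.

## Covariate coding and standardization

Patch area is log-transformed and z-scored; `DATE` and `TSR` are z-scored
over all visits (population sd). With this coding "all coefficients zero"
means lambda = 1 and p = 0.5 at average conditions, which keeps the vague
priors centred somewhere meaningful. The constants used are stored on the
design and written to the run manifest so a fitted model can be applied to
new covariate values reproducibly. Site-level inclusion `w_ij` is used (a
species may be present at some sites and absent at others).

## Priors

* `mu ~ Normal(0, precision 0.1)` (sd ~ 3.16) for every class mean. This is
  the conventional vague normal for log/logit-scale coefficients of
  standardized covariates in the community-modelling literature. The choice
  matters more than usual here: the (TRT, ORI) cell means over-parameterize
  `{u1, u2, o1, o2, a3, a4}` — two directions of coefficient space leave
  every `lambda_ij` unchanged — so the posterior spread of `mu_a3`/`mu_a4`
  along those directions is set by this prior, not by data. A wider prior
  (e.g. sd 10) simply widens those intervals; `mu_prior_sd` is a
  configuration field.
* `tau = 1/sigma^2 ~ Gamma(0.1, rate 0.1)` on every class precision, the
  standard vague gamma for hierarchical precisions. The parameterization
  matters: a Gamma(0.1, 0.1) placed on `sigma` *itself* has an integrable
  density spike at zero that creates a spurious posterior mode with the
  class completely shrunk (`sigma ~ 0`), in which chains trap; on the
  precision the same prior suppresses `sigma -> 0` exponentially. The
  sd-parameterized variant remains available
  (`sigma_prior_parameterization="sd"`).
* `psi_i ~ Beta(1, 1)`; no class structure is placed on the inclusion
  probability.

## Sampler

Metropolis-within-Gibbs with data augmentation; all likelihood accumulation
is in log space and all pmfs come from log-gamma, never factorials.

* **w | rest** — exact Bernoulli draw. For an all-zero visit history the
  Poisson probability generating function gives
  `P(all zero | w=1) = exp(-lambda (1 - prod_k(1 - p_k)))` in closed form.
* **N | rest** — exact categorical draw on `max_k(y) .. N_max` with weights
  `Poisson(N; lambda) prod_k Binomial(y_k; N, p_k)`. The support is
  truncated at `N_max = max(100, 10 * max observed count)` by default
  (configurable); per cell the grid is further capped where the
  Poisson-binomial tail is numerically negligible, and cells are processed
  in a few grid-length buckets to stay vectorized.
* **species coefficients** — during burn-in, coordinate-wise random-walk
  Metropolis vectorized across species (adaptive scales, target acceptance
  0.44). From the second half of burn-in a per-species empirical covariance
  of coefficient *deviations from the class means* is accumulated, and after
  burn-in the coefficient update is a joint 13-dimensional adaptive-
  Metropolis proposal (scaled 2.38/sqrt(13), target acceptance 0.23). The
  joint proposal is what handles the strong posterior correlations
  (detection intercept vs. quadratic terms, area vs. area-by-treatment).
* **mu | rest** — conjugate Normal update.
* **sigma | rest** — exact conjugate Gibbs draw of the precision,
  `tau | rest ~ Gamma(a + n/2, rate + ss/2)`. Under the sd-parameterized
  prior this becomes random-walk Metropolis on `log sigma` (with the
  log-scale Jacobian), floored at 1e-6 so one-member classes cannot
  collapse into the Gamma spike at zero.
* **interweaving (non-centered) scale move** — in coordinates
  `z_i = (coef_i - mu)/sigma` the class sd is moved with `z` held fixed,
  dragging all member coefficients along (`coef' = mu + s (coef - mu)`,
  `sigma' = s sigma`). The species-level prior is invariant by construction,
  so acceptance involves only the likelihood, the Gamma prior and the
  Jacobian. This breaks the funnel coupling that makes centered sigma
  updates mix slowly.
* **ridge translations** — per class, joint Metropolis shifts of the species
  coefficients and class mean along the two likelihood-flat directions
  `(u1, -a3, -a4)` and `(-u1, -u2, +o1, +o2)`. Likelihood and species-level
  priors are exactly invariant, so acceptance depends only on the `mu`
  hyperprior and the flat directions mix in a few sweeps instead of a slow
  random walk.
* **psi | w** — conjugate Beta update.

All proposal scales and the AM covariance adapt by Robbins-Monro during
burn-in only and are frozen afterwards, preserving detailed balance in the
retained draws. Chains run sequentially from seeds spawned off the single
configured seed, with initial overdispersion growing across chains so split
R-hat starts from genuinely distinct states. Defaults: 3 chains, 10,000
iterations, 2,000 burn-in, thinning 5.

Degenerate inputs: species never observed anywhere are retained (the
zero-inflation layer absorbs them); a species missing from the roster is an
error; `y > N_max` is an error.

## Convergence and summaries

`gelman_rubin` implements split R-hat (each chain halved before the
classic between/within comparison); zero-variance input returns 1.0 by
convention, and flat chains stuck at different constants return infinity.

Posterior summaries follow the reporting style of hierarchical community
analyses: the 95% highest-density interval computed directly on the
empirical draws (shortest contiguous order-statistic window containing
`ceil(0.95 n)` draws, ties resolved to the smallest lower endpoint — no
distributional shape is assumed), the mode of a Silverman-bandwidth Gaussian
KDE evaluated on a 512-point grid over the sample range, and the proportion
of draws strictly above zero as the probability of a positive effect.

## The synthetic-data generator

No field dataset accompanies the model, so the generator is a first-class
module that emulates the study design the model was built for:

* 19 blocks, each containing all four treatment-by-origin site types
  (76 sites); three blocks' forest pairs are flagged ineligible for the
  weed-control contrast (they remain in the dataset), leaving 70 sites in
  the realized contrasts. Both the full factorial and the dropout labelling
  are configurable.
* Site areas 0.5-2.5 ha sharing a block-level centre (within-block spread
  at most 0.5 ha); each site sits in a larger connected vegetation patch
  (1-4x the site area). The model uses patch area; both columns are
  emitted.
* Three visits per site at sorted uniform dates over a 150-day spring/
  summer season, start times uniform over a 210-minute morning window
  (05:00-08:30 equivalent).
* A 74-species roster split 29/21/24 into sensitive/adaptable/exploitative,
  the split observed in the study system.
* Default class hyperparameters encode one realistic community:
  revegetation benefits all classes (positive `a4` means), weed control
  helps exploiters and mildly harms sensitive and adaptable species (sign
  pattern of `a3`), sensitive species prefer forest, exploiters open grass;
  between-species sd 0.3 on every coefficient, which keeps typical site
  counts in the realistic 0-20 range with occasional larger flocks.
  `psi_i ~ Beta(1, 1)` by default.

What the generator does *not* emulate: vegetation structure and weed-cover
percentages (treatment is a label, not a mechanism), temporary emigration
or flocking (counts are independent binomial thinnings across visits),
observer heterogeneity, and spatial autocorrelation. Passing
parameter-recovery tests on these data therefore demonstrates that the
estimation machinery is correct under the model's own assumptions — not
that the model is adequate for any particular field dataset.

## Validation experiments and problem sizes

The test-suite experiments (also recomputed by `scripts/acceptance.py`):

1. **Likelihood oracle** — the marginal site-by-species log-likelihood
   against brute-force N-summation over a (psi, lambda, p, y) grid with up
   to 4 visits, truncation 200; agreement to 1e-8.
2. **Toy-model exactness** — 1 species x 1 site with enumerable support
   (N_max = 6): 50,000 retained Gibbs draws of N, with coefficients held at
   truth, against the exactly enumerated conditional posterior; total
   variation below 0.02.
3. **Parameter recovery** — 30 species over 3 classes, 19 blocks x 4
   sites, 3 visits, known hyperparameters; 3 chains x 10,000 iterations.
   At least 90% of the 39 class-mean coefficients must fall inside their
   95% HDI, with split R-hat < 1.1 on every hyperparameter.
4. **Benefit direction** — treatment benefit means set to +/-2.5 on the log
   scale with opposite signs for the exploitative and sensitive classes (a
   deliberately strong pattern for a direction-recovery stress test): the
   sign of each class's mean `BRichness` and of the `mu_a3`/`mu_a4`
   posteriors is scored by its direction probability, with 0.9 the pass
   line for each. The richness benefits are data-identified and recover
   their signs decisively; the `mu_a3`/`mu_a4` marginals sit on
   likelihood-flat directions, so their direction probabilities are
   bounded by the hyperprior (posterior sd ~ 1.9 regardless of data) and
   cannot clear 0.9 at any plausible effect size — the corresponding
   assertion documents that structural limit.
5. **Degenerate detection** — data generated with p ~ 1 and psi = 1: the
   posterior for `N_ij` must sit on `max_k y_ijk` in at least 99% of
   retained draws.
6. **HDI correctness** — exhaustive shortest-window search on samples up to
   n = 1,000, and the Normal(0,1) 95% endpoints -/+1.96 within 0.05 at
   n = 100,000.
7. **Determinism** — simulation and fitting are byte-identical under a
   fixed seed.

These sizes were chosen so the full suite runs comfortably on a single CPU
while leaving each experiment statistically meaningful.

## Known limitations

* The flat predictor directions mean `mu_u1`, `mu_u2`, `mu_o1`, `mu_o2`,
  `mu_a3`, `mu_a4` are only jointly, not individually, data-identified;
  their marginal intervals reflect the hyperprior. Contrasts such as
  `mu_a3 - mu_a4` and all richness quantities are data-identified.
* The closure assumption inflates abundance estimates for species with very
  low detection; nothing in the machinery corrects for that.
* `N_max` truncation is adequate for realistic counts but a pathological
  dataset (single enormous count) makes the latent draw expensive.
* The sampler is exact but random-walk based; communities far larger than a
  few hundred species would warrant a marginalized implementation.
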