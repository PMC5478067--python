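# birdmix

Hierarchical Bayesian community N-mixture modelling of repeated bird
counts, built for the question urban land managers actually ask: *which
restoration action — revegetating mowed grass, or controlling weeds in
remnant forest — benefits which kinds of birds?*

Repeated point counts underestimate abundance because detection is
imperfect, and community surveys are dominated by zeros. `birdmix` fits a
zero-inflated Poisson N-mixture model to a species × site × visit count
tensor: for species *i* at site *j*,

```
w_ij ~ Bernoulli(psi_i)                        site-level inclusion
N_ij | w_ij ~ Poisson(w_ij * lambda_ij)        latent true abundance
y_ijk | N_ij ~ Binomial(N_ij, p_ijk)           counts on visit k
```

with `log lambda_ij` linear in treatment (TRT), site origin (ORI = forest
vs. grass), standardized log patch area and their interactions — the
interaction terms `a3` (TRT×ORI) and `a4` (TRT×(1−ORI)) are direct
log-scale estimates of the weed-control and revegetation benefits — and
`logit p_ijk` quadratic in day-of-season and time since sunrise. Every
species-level coefficient is drawn from hyperparameters of its
urban-sensitivity class (sensitive / adaptable / exploitative), so the
model reports class-level posteriors a manager can act on. Fitting is by
Metropolis-within-Gibbs with exact latent-variable draws; results are
summarized the way this literature reports them: 95% highest-density
intervals, kernel-density modes, and the proportion of posterior mass
above zero. Derived richness per draw (`N_ij >= 1`) yields the posterior
richness benefit `BRichness` of each treatment per class.

No field dataset ships with the package; a first-class synthetic-data
generator reproduces the blocked study design (19 blocks × 4 site types ×
3 morning visits, ~74 species) with full latent truth, which is what the
validation suite fits against. See `docs/methods.md` for the model,
sampler and generator details.

## Worked example

```python
from birdmix import (CommunityAbundanceModel, DesignSpec,
                     default_roster, simulate_dataset)

bundle = simulate_dataset(spec=DesignSpec(n_blocks=19, seed=1),
                          roster=default_roster(20), seed=1)
model = CommunityAbundanceModel(bundle.counts, bundle.design, bundle.roster)
results = model.fit(chains=3, iterations=10000, burnin=2000, thin=5, seed=1)

print("max split R-hat:", round(results.max_rhat(), 3))
table = results.summary()
print(table[table["parameter"].str.startswith("mu_a4")].round(3).to_string(index=False))
print(results.benefit_summary().round(3).to_string(index=False))
```

prints

```
max split R-hat: 1.182
         parameter  hdi_lower  mode  hdi_upper  prop_above_0
   mu_a4_sensitive     -3.322 0.610      4.168         0.609
   mu_a4_adaptable     -3.071 0.598      4.729         0.646
mu_a4_exploitative     -2.880 0.600      4.598         0.665

                    parameter  hdi_lower   mode  hdi_upper  prop_above_0
    BRichness_sensitive_grass      0.368  0.782      1.158         1.000
   BRichness_sensitive_forest     -1.188 -0.822     -0.438         0.000
    BRichness_adaptable_grass     -0.368  0.073      0.474         0.620
   BRichness_adaptable_forest     -1.375 -0.662     -0.312         0.005
 BRichness_exploitative_grass      0.211  0.420      0.579         0.998
BRichness_exploitative_forest      0.000  0.251      0.438         0.984
```

Reading it: the synthetic community was generated with revegetation
helping all classes and weed control mildly harming sensitive and
adaptable species. The richness benefits recover exactly that —
revegetating grass adds ~0.8 sensitive species per site with probability
1.00, while weed control *costs* ~0.8 sensitive species (probability of a
positive effect 0.000). The class-mean abundance coefficients (`mu_a4`
rows) stay wide and inconclusive even here: those coefficients sit on
likelihood-flat directions of the predictor, so their marginals are
prior-bound — richness benefits, not raw abundance coefficients, are the
decision-relevant output (see `docs/methods.md`).

## Command line

```bash
birdmix simulate --out data/ --seed 1                 # design + counts + truth
birdmix fit --data data/ --out run/ --seed 1 --chains 3 --iters 10000
birdmix summarize --run run/ --mass 0.95              # hyperparameter + richness tables
birdmix diagnose --run run/                           # split R-hat table + traces
```

All randomness flows from `--seed`; identical invocations produce
byte-identical outputs.

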