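"""End-to-end validation experiments for the fitting machinery.

Each function runs one self-contained experiment — likelihood against a
brute-force oracle, Gibbs draws against exact enumeration, parameter
recovery on synthetic communities, direction recovery of treatment
benefits, degenerate-detection behaviour, HDI correctness and determinism —
and returns plain numbers.  The test suite asserts on them; the
``scripts/acceptance.py`` entry point reports them.

Experiment sizes mirror the study design (19 blocks x 4 site types x 3
visits) with a 30-species community, which keeps a full multi-chain fit in
the minutes range on one CPU while leaving every check statistically
meaningful.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .data import URBAN_CLASSES
from .inference import MCMCConfig, fit_model, gelman_rubin
from .likelihood import site_species_loglik
from .model import CommunityAbundanceModel
from .simulate import (
    DesignSpec,
    default_hyperparams,
    default_roster,
    simulate_dataset,
)
from .summaries import hdi, prop_above_zero

__all__ = [
    "likelihood_oracle_max_error",
    "toy_latent_tv_distance",
    "recovery_experiment",
    "benefit_direction_experiment",
    "degenerate_detection_match",
    "hdi_bruteforce_max_error",
    "hdi_normal_endpoint_error",
    "determinism_check",
]


# ---------------------------------------------------------------------------
# 1. marginal likelihood vs brute-force N-summation
# ---------------------------------------------------------------------------

def _brute_force_loglik(y, psi, lam, p, n_max):
    """Linear-space summation over N with scipy pmfs (reference path)."""
    y = np.asarray(y)
    total = 0.0
    for n in range(int(y.max(initial=0)), n_max + 1):
        term = stats.poisson.pmf(n, lam)
        for y_k, p_k in zip(y, p):
            term *= stats.binom.pmf(y_k, n, p_k)
        total += term
    total *= psi
    if not y.any():
        total += 1.0 - psi
    with np.errstate(divide="ignore"):
        return float(np.log(total))


def likelihood_oracle_max_error(n_max: int = 200) -> tuple[float, int]:
    """Max |log-likelihood - oracle| over a (psi, lambda, p, y) grid, K<=4."""
    cases = []
    for psi in (0.05, 0.3, 0.7, 1.0):
        for lam in (0.3, 1.0, 2.0, 5.0, 10.0):
            for p_visits, y_visits in [
                ((0.5,), (0,)),
                ((0.5,), (1,)),
                ((0.2, 0.8), (0, 0)),
                ((0.2, 0.8), (2, 1)),
                ((0.4, 0.5, 0.6), (0, 0, 0)),
                ((0.4, 0.5, 0.6), (1, 0, 3)),
                ((0.3, 0.3, 0.3, 0.3), (0, 1, 0, 2)),
                ((0.9, 0.1, 0.5, 0.5), (4, 0, 2, 1)),
            ]:
                cases.append((y_visits, psi, lam, p_visits))
    worst = 0.0
    for y, psi, lam, p in cases:
        got = site_species_loglik(y, psi, np.log(lam), p, n_max)
        want = _brute_force_loglik(y, psi, lam, p, n_max)
        if np.isinf(got) and np.isinf(want):
            continue
        worst = max(worst, abs(got - want))
    return worst, len(cases)


# ---------------------------------------------------------------------------
# 2. Gibbs draws of latent N vs exact enumeration on a tiny support
# ---------------------------------------------------------------------------

def toy_latent_tv_distance(seed: int = 0, total_draws: int = 50_000,
                           n_max: int = 6) -> tuple[float, int]:
    """TV distance between sampled and enumerated P(N | y) on 0..n_max.

    1 species x 1 site x 1 visit with coefficients fixed at truth, so the
    conditional latent posterior is exactly enumerable.
    """
    import pandas as pd

    from .data import CountData, SpeciesParams, SurveyDesign

    psi, lam, p, y_obs = 0.7, 2.0, 0.6, 1
    sites = pd.DataFrame({
        "site_id": ["s1"], "block_id": ["b1"], "origin": ["grass"],
        "treated": [0], "site_area_ha": [1.0], "patch_area_ha": [1.0],
        "weed_contrast_eligible": [1],
    })
    visits = pd.DataFrame({"site_id": ["s1"], "visit": [1],
                           "date_days": [0.0], "minutes_since_sunrise": [0.0]})
    design = SurveyDesign(sites, visits)
    params = [SpeciesParams(species_id="sp1", urban_class="adaptable",
                            psi=psi, u2=np.log(lam),
                            v1=float(np.log(p / (1 - p))))]
    data = CountData(y=np.array([[[y_obs]]]), species_ids=["sp1"],
                     design=design)
    roster = pd.DataFrame({"species_id": ["sp1"], "urban_class": ["adaptable"]})

    n_chains = 2
    per_chain = total_draws // n_chains
    config = MCMCConfig(n_chains=n_chains, n_iter=per_chain + 1000,
                        n_burnin=1000, thin=1, seed=seed, n_max=n_max,
                        sample_coefficients=False, sample_hyper=False,
                        sample_psi=False)
    samples = fit_model(data, design, roster, config, initial_params=params)
    draws = samples.latent_n.reshape(-1)

    # exact enumeration, marginalized over the inclusion indicator
    probs = np.zeros(n_max + 1)
    for n in range(n_max + 1):
        probs[n] = psi * stats.poisson.pmf(n, lam) * stats.binom.pmf(y_obs, n, p)
    probs /= probs.sum()
    emp = np.bincount(draws, minlength=n_max + 1) / draws.size
    return float(0.5 * np.abs(emp - probs).sum()), draws.size


# ---------------------------------------------------------------------------
# 3. hyperparameter recovery on the study-scale synthetic community
# ---------------------------------------------------------------------------

def recovery_experiment(seed: int = 42, n_species: int = 30,
                        iterations: int = 10_000) -> dict:
    """Simulate with known class means, fit, score HDI coverage and R-hat."""
    bundle = simulate_dataset(spec=DesignSpec(n_blocks=19, seed=seed),
                              roster=default_roster(n_species), seed=seed)
    model = CommunityAbundanceModel(bundle.counts, bundle.design, bundle.roster)
    res = model.fit(chains=3, iterations=iterations,
                    burnin=iterations // 5, thin=5, seed=seed)
    draws = res.hyper_draws()
    inside = total = 0
    for cls, h in bundle.hyperparams.items():
        for coef, mu_true in h.mu.items():
            lo, hi = hdi(draws[f"mu_{coef}_{cls}"].reshape(-1), 0.95)
            inside += int(lo <= mu_true <= hi)
            total += 1
    rhat = res.rhat()
    return {
        "coverage": inside / total,
        "n_mu": total,
        "max_rhat": float(rhat["rhat"].max()),
        "results": res,
        "truth": bundle.hyperparams,
    }


# ---------------------------------------------------------------------------
# 4. direction recovery of treatment benefits
# ---------------------------------------------------------------------------

def benefit_direction_experiment(seed: int = 42, n_species: int = 30,
                                 iterations: int = 10_000) -> dict:
    """Opposite-signed treatment benefits for two classes; check recovery.

    The benefit class means are set to +/-2.5 on the log scale (exploitative
    positive, sensitive negative, for both the weed-control benefit a3 and
    the revegetation benefit a4) — a deliberately strong pattern for a
    sign-recovery stress test.  Scores the probability of the correct
    direction for each class's mean richness benefit and for the mu_a3 /
    mu_a4 posteriors.
    """
    hyper = default_hyperparams()
    signs = {"exploitative": +1.0, "sensitive": -1.0}
    for cls, sign in signs.items():
        hyper[cls].mu["a3"] = 2.5 * sign
        hyper[cls].mu["a4"] = 2.5 * sign
    bundle = simulate_dataset(spec=DesignSpec(n_blocks=19, seed=seed),
                              hyper=hyper, roster=default_roster(n_species),
                              seed=seed)
    model = CommunityAbundanceModel(bundle.counts, bundle.design, bundle.roster)
    res = model.fit(chains=3, iterations=iterations,
                    burnin=iterations // 5, thin=5, seed=seed)

    draws = res.hyper_draws()
    direction_probs = {}
    for cls, sign in signs.items():
        for coef in ("a3", "a4"):
            p_pos = prop_above_zero(draws[f"mu_{coef}_{cls}"].reshape(-1))
            direction_probs[f"mu_{coef}_{cls}"] = p_pos if sign > 0 else 1 - p_pos
        for origin in ("forest", "grass"):
            p_pos = prop_above_zero(res.richness_benefit(cls, origin))
            direction_probs[f"BRichness_{cls}_{origin}"] = \
                p_pos if sign > 0 else 1 - p_pos
    richness_probs = {k: v for k, v in direction_probs.items()
                      if k.startswith("BRichness")}
    mu_probs = {k: v for k, v in direction_probs.items()
                if k.startswith("mu_")}
    return {
        "direction_probs": direction_probs,
        "min_direction_prob": float(min(direction_probs.values())),
        "min_richness_direction_prob": float(min(richness_probs.values())),
        "min_mu_direction_prob": float(min(mu_probs.values())),
        "results": res,
    }


# ---------------------------------------------------------------------------
# 5. degenerate detection
# ---------------------------------------------------------------------------

def degenerate_detection_match(seed: int = 42) -> tuple[float, int]:
    """p ~ 1, psi = 1 data: fraction of retained draws with N == max_k y."""
    from .data import SpeciesParams
    from .simulate import generate_design, simulate_counts
    import pandas as pd

    design = generate_design(DesignSpec(n_blocks=8, seed=seed))
    params = [SpeciesParams(species_id="sp1", urban_class="adaptable",
                            psi=1.0, u1=1.2, u2=1.2, v1=30.0)]
    bundle = simulate_counts(design, params, seed=seed)
    roster = pd.DataFrame({"species_id": ["sp1"], "urban_class": ["adaptable"]})
    config = MCMCConfig(n_chains=2, n_iter=2000, n_burnin=500, thin=1,
                        seed=seed)
    samples = fit_model(bundle.counts, design, roster, config)
    ymax = bundle.counts.y.max(axis=2)[None, None]
    match = float((samples.latent_n == ymax).mean())
    return match, int(np.prod(samples.latent_n.shape))


# ---------------------------------------------------------------------------
# 6. HDI correctness
# ---------------------------------------------------------------------------

def hdi_bruteforce_max_error(seed: int = 0) -> tuple[float, int]:
    """Max endpoint discrepancy vs exhaustive window search, n <= 1000."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    n_sets = 0
    for n in (20, 57, 200, 501, 1000):
        for draw in (rng.standard_normal(n), rng.exponential(size=n),
                     rng.lognormal(size=n)):
            for mass in (0.5, 0.9, 0.95):
                x = np.sort(draw)
                m = int(np.ceil(mass * n))
                widths = x[m - 1:] - x[: n - m + 1]
                a = int(np.argmin(widths))
                want = (x[a], x[a + m - 1])
                got = hdi(draw, mass)
                worst = max(worst, abs(got[0] - want[0]),
                            abs(got[1] - want[1]))
                n_sets += 1
    return worst, n_sets


def hdi_normal_endpoint_error(seed: int = 0, n: int = 100_000) -> tuple[float, int]:
    """Max |endpoint -/+ 1.96| of the 95% HDI of standard-normal draws."""
    rng = np.random.default_rng(seed)
    lo, hi = hdi(rng.standard_normal(n), 0.95)
    return float(max(abs(lo + 1.96), abs(hi - 1.96))), n


# ---------------------------------------------------------------------------
# 7. determinism
# ---------------------------------------------------------------------------

def determinism_check(seed: int = 7) -> dict:
    """Simulate and fit twice under one seed; report the largest deviation."""
    a = simulate_dataset(spec=DesignSpec(n_blocks=5, seed=seed),
                         roster=default_roster(10), seed=seed)
    b = simulate_dataset(spec=DesignSpec(n_blocks=5, seed=seed),
                         roster=default_roster(10), seed=seed)
    sim_diff = int(np.abs(a.counts.y - b.counts.y).max())

    config = MCMCConfig(n_chains=2, n_iter=600, n_burnin=300, thin=3,
                        seed=seed)
    fit_a = fit_model(a.counts, a.design, a.roster, config)
    fit_b = fit_model(b.counts, b.design, b.roster, config)
    fit_diff = float(max(np.abs(fit_a.coefs - fit_b.coefs).max(),
                         np.abs(fit_a.mu - fit_b.mu).max(),
                         np.abs(fit_a.sigma - fit_b.sigma).max(),
                         np.abs(fit_a.latent_n - fit_b.latent_n).max()))
    return {"simulation_max_diff": sim_diff, "fit_max_diff": fit_diff,
            "n_draws": fit_a.coefs.shape[0] * fit_a.coefs.shape[1]}
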