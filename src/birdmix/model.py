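"""Model / Results front end for the hierarchical community abundance model.

:class:`CommunityAbundanceModel` is built from a count tensor, a survey
design and a species roster (or directly from the CSV dialects via
``from_csv``); ``fit`` runs the Metropolis-within-Gibbs sampler and returns
a :class:`CommunityAbundanceResults` carrying the posterior draws, derived
richness quantities, convergence diagnostics and a table-style ``summary``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import COEF_NAMES, URBAN_CLASSES, CountData, SurveyDesign
from .inference import MCMCConfig, PosteriorSamples, fit_model, gelman_rubin
from .summaries import (
    hdi,
    posterior_mode,
    prop_above_zero,
    richness_benefit,
    richness_per_iteration,
    richness_stratum_means,
    summarize,
)

__all__ = ["CommunityAbundanceModel", "CommunityAbundanceResults"]


class CommunityAbundanceModel:
    """Zero-inflated Poisson N-mixture model with urban-class hyperparameters.

    Parameters
    ----------
    counts : CountData
        Dense (species, site, visit) count tensor tied to ``design``.
    design : SurveyDesign
        Site and visit covariates (standardized internally).
    roster : DataFrame
        species_id -> urban_class map; every observed species must appear.
    n_max : int, optional
        Truncation of the latent abundance support; defaults to
        max(100, 10 * largest observed count).
    """

    def __init__(self, counts: CountData, design: SurveyDesign,
                 roster: pd.DataFrame, n_max: int | None = None):
        self.counts = counts
        self.design = design
        self.roster = roster
        self.n_max = n_max

    @classmethod
    def from_csv(cls, sites_csv, visits_csv, counts_csv, species_csv,
                 n_max: int | None = None) -> "CommunityAbundanceModel":
        from .io import read_dataset
        design, counts, roster = read_dataset(
            sites_csv, visits_csv, counts_csv, species_csv)
        return cls(counts, design, roster, n_max=n_max)

    def fit(self, chains: int = 3, iterations: int = 10_000,
            burnin: int = 2_000, thin: int = 5, seed: int = 0,
            config: MCMCConfig | None = None) -> "CommunityAbundanceResults":
        """Run the sampler; see :func:`birdmix.inference.fit_model`."""
        if config is None:
            config = MCMCConfig(n_chains=chains, n_iter=iterations,
                                n_burnin=burnin, thin=thin, seed=seed,
                                n_max=self.n_max)
        samples = fit_model(self.counts, self.design, self.roster, config)
        return CommunityAbundanceResults(self, samples)


class CommunityAbundanceResults:
    """Posterior draws plus the derived quantities the analysis reports."""

    def __init__(self, model: CommunityAbundanceModel,
                 samples: PosteriorSamples):
        self.model = model
        self.samples = samples
        self._richness = None

    # -- diagnostics ----------------------------------------------------
    @property
    def acceptance_rates(self) -> dict[str, float]:
        return self.samples.acceptance

    def rhat(self) -> pd.DataFrame:
        """Split R-hat for every class-level hyperparameter."""
        rows = [{"parameter": name, "rhat": gelman_rubin(draws)}
                for name, draws in self.samples.hyper_draws().items()]
        return pd.DataFrame(rows)

    def max_rhat(self) -> float:
        return float(self.rhat()["rhat"].max())

    # -- posterior access -----------------------------------------------
    def hyper_draws(self) -> dict[str, np.ndarray]:
        return self.samples.hyper_draws()

    def richness_draws(self) -> np.ndarray:
        """(total draws, sites, classes) richness tensor across chains."""
        if self._richness is None:
            s = self.samples
            flat_n = s.latent_n.reshape(-1, *s.latent_n.shape[2:])
            present = flat_n >= 1                     # (draws, species, sites)
            out = np.empty((flat_n.shape[0], self.model.design.n_sites,
                            len(URBAN_CLASSES)), dtype=int)
            for ci in range(len(URBAN_CLASSES)):
                members = np.where(s.class_index == ci)[0]
                out[:, :, ci] = present[:, members, :].sum(axis=1)
            self._richness = out
        return self._richness

    def richness_stratum_means(self) -> dict[str, np.ndarray]:
        return richness_stratum_means(self.richness_draws(), self.model.design)

    def richness_benefit(self, urban_class: str, origin: str) -> np.ndarray:
        """BRichness draws: treated minus untreated mean richness."""
        return richness_benefit(self.richness_draws(), self.model.design,
                                urban_class, origin)

    # -- tables ----------------------------------------------------------
    def summary(self, mass: float = 0.95,
                include: str = "hyper") -> pd.DataFrame:
        """Summary table (parameter, hdi_lower, mode, hdi_upper, prop_above_0).

        ``include`` selects the parameter set: "hyper" (class-level mu and
        sigma), "richness" (stratum means and benefits), or "all".
        """
        draws: dict[str, np.ndarray] = {}
        if include in ("hyper", "all"):
            draws.update(self.hyper_draws())
        if include in ("richness", "all"):
            draws.update(self.richness_stratum_means())
            for cls in URBAN_CLASSES:
                for origin in ("grass", "forest"):
                    try:
                        draws[f"BRichness_{cls}_{origin}"] = \
                            self.richness_benefit(cls, origin)
                    except ValueError:
                        pass
        return summarize(draws, mass=mass)

    def benefit_summary(self, mass: float = 0.95) -> pd.DataFrame:
        """HDI / mode / P(>0) for every class-by-origin richness benefit."""
        rows = {}
        for cls in URBAN_CLASSES:
            for origin in ("grass", "forest"):
                rows[f"BRichness_{cls}_{origin}"] = \
                    self.richness_benefit(cls, origin)
        return summarize(rows, mass=mass)
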