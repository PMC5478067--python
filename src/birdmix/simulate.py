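"""Synthetic survey designs and count data with the model's exact generative
structure.

The generator emulates a blocked space-for-time design: blocks each holding
the four treatment-by-origin site types (revegetated grass, open-mowed grass,
weed-controlled forest, weedy forest), three early-morning visits per site
over a single breeding season, and a community of species partitioned into
urban-sensitivity classes.  Latent truth (N, w, species coefficients, class
hyperparameters) is retained for parameter-recovery experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .data import (
    COEF_NAMES,
    URBAN_CLASSES,
    ClassHyperparams,
    CountData,
    SpeciesParams,
    SurveyDesign,
    normalize_roster,
)

__all__ = [
    "DesignSpec",
    "TruthBundle",
    "generate_design",
    "draw_species_params",
    "simulate_counts",
    "default_hyperparams",
    "default_roster",
    "simulate_dataset",
]


@dataclass
class DesignSpec:
    """Knobs of the synthetic survey design.

    Defaults reproduce the study layout: 19 blocks, each with all four site
    types, three visits per site between 05:00 and 08:30 across a 150-day
    spring/summer season, site areas 0.5-2.5 ha varying by at most 0.5 ha
    within a block, and 3 blocks whose forest pair fails the weed-cover
    criteria and is flagged out of the weed-control contrast (so 70 of the 76
    sites participate in the realized contrasts).
    """

    n_blocks: int = 19
    n_visits: int = 3
    area_range: tuple[float, float] = (0.5, 2.5)
    within_block_area_jitter: float = 0.5
    weed_block_dropout: int = 3
    season_days: float = 150.0
    tsr_minutes: float = 210.0
    seed: int = 0

    def __post_init__(self):
        if self.n_blocks < 1:
            raise ValueError("need at least one block")
        if self.n_visits < 2:
            raise ValueError("detection is not identifiable with fewer than 2 visits")
        if self.weed_block_dropout > self.n_blocks:
            raise ValueError("cannot drop more blocks than exist")


#: The four site types present in every block: (origin, treated).
_SITE_TYPES = (
    ("grass", 0),   # open-mowed grass (revegetation counterfactual)
    ("grass", 1),   # revegetated
    ("forest", 0),  # weedy forest (weed-control counterfactual)
    ("forest", 1),  # weed-controlled forest
)


def generate_design(spec: DesignSpec) -> SurveyDesign:
    """Draw a blocked survey design with 4 sites per block.

    Site areas share a block-level centre so paired sites are of similar
    size; each site sits inside a larger vegetation patch (patch area is a
    1-4x multiple of site area).  Visit dates are sorted uniform draws over
    the season; start times are uniform over the morning window.  Forest
    sites of ``weed_block_dropout`` blocks are labelled ineligible for the
    weed-control contrast but are not deleted.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.area_range
    half = spec.within_block_area_jitter / 2.0

    rows = []
    for b in range(spec.n_blocks):
        block_id = f"B{b + 1:02d}"
        centre = rng.uniform(lo + half, hi - half)
        for origin, treated in _SITE_TYPES:
            site_area = centre + rng.uniform(-half, half)
            patch_area = site_area * rng.uniform(1.0, 4.0)
            rows.append({
                "site_id": f"{block_id}-{origin[0].upper()}{treated}",
                "block_id": block_id,
                "origin": origin,
                "treated": treated,
                "site_area_ha": round(site_area, 4),
                "patch_area_ha": round(patch_area, 4),
                "weed_contrast_eligible": 1,
            })
    sites = pd.DataFrame(rows)

    dropped = rng.choice(spec.n_blocks, size=spec.weed_block_dropout, replace=False)
    dropped_ids = {f"B{b + 1:02d}" for b in dropped}
    forest = sites["origin"] == "forest"
    sites.loc[forest & sites["block_id"].isin(dropped_ids),
              "weed_contrast_eligible"] = 0

    visit_rows = []
    for site_id in sites["site_id"]:
        dates = np.sort(rng.uniform(0.0, spec.season_days, size=spec.n_visits))
        for k in range(spec.n_visits):
            visit_rows.append({
                "site_id": site_id,
                "visit": k + 1,
                "date_days": round(float(dates[k]), 2),
                "minutes_since_sunrise": round(float(rng.uniform(0.0, spec.tsr_minutes)), 1),
            })
    visits = pd.DataFrame(visit_rows)
    return SurveyDesign(sites, visits)


def default_roster(n_species: int = 74) -> pd.DataFrame:
    """Species roster with the study's class split (29/21/24 at n=74).

    Other community sizes keep the same class proportions.
    """
    base = {"sensitive": 29, "adaptable": 21, "exploitative": 24}
    total = sum(base.values())
    counts = {c: int(round(n_species * base[c] / total)) for c in URBAN_CLASSES}
    counts["exploitative"] += n_species - sum(counts.values())
    rows = []
    i = 0
    for c in URBAN_CLASSES:
        for _ in range(counts[c]):
            i += 1
            rows.append({"species_id": f"sp{i:03d}",
                         "common_name": f"synthetic species {i}",
                         "urban_class": c})
    return pd.DataFrame(rows)


def default_hyperparams() -> dict[str, ClassHyperparams]:
    """One realistic community configuration, used as the generator default.

    Qualitative structure: all classes gain from revegetating open grass
    (positive a4 means), weed control favours exploiters and mildly harms
    sensitive and adaptable species (sign pattern of a3), sensitive species
    sit in forest (o1 > o2) while exploiters lean the other way, detection is
    moderate with gentle seasonal and time-of-morning curvature.  Between-
    species spread is 0.3 on every coefficient, which keeps typical site
    counts in the 0-20 range with occasional large flocks.
    """
    mu = {
        "sensitive": dict(u1=0.0, u2=0.0, o1=0.6, o2=-0.6, a1=0.2, a2=0.0,
                          a3=-0.5, a4=0.7, v1=-0.4, b1=0.2, b2=-0.1,
                          b3=-0.2, b4=-0.1),
        "adaptable": dict(u1=0.3, u2=0.3, o1=0.2, o2=0.0, a1=0.2, a2=0.0,
                          a3=-0.4, a4=1.0, v1=-0.2, b1=0.1, b2=-0.1,
                          b3=-0.2, b4=-0.1),
        "exploitative": dict(u1=0.4, u2=0.4, o1=-0.3, o2=0.5, a1=0.2, a2=0.0,
                             a3=0.6, a4=0.8, v1=0.0, b1=0.1, b2=-0.1,
                             b3=-0.3, b4=-0.1),
    }
    sigma = {c: 0.3 for c in COEF_NAMES}
    return {
        c: ClassHyperparams(urban_class=c, mu=mu[c], sigma=dict(sigma))
        for c in URBAN_CLASSES
    }


def draw_species_params(
    hyper: dict[str, ClassHyperparams],
    roster: pd.DataFrame,
    seed: int,
    psi_beta: tuple[float, float] = (1.0, 1.0),
) -> list[SpeciesParams]:
    """Draw species coefficients from their class hyperparameters.

    Each coefficient of species i in class c is Normal(mu_c, sigma_c); the
    inclusion probability psi_i is Beta(*psi_beta) (flat by default — the
    zero-inflation layer carries no class structure).
    """
    roster = normalize_roster(roster)
    rng = np.random.default_rng(seed)
    out = []
    for _, row in roster.iterrows():
        h = hyper[row["urban_class"]]
        coefs = {
            c: float(rng.normal(h.mu[c], h.sigma[c])) for c in COEF_NAMES
        }
        psi = float(rng.beta(*psi_beta))
        out.append(SpeciesParams(species_id=row["species_id"],
                                 urban_class=row["urban_class"],
                                 psi=psi, **coefs))
    return out


@dataclass
class TruthBundle:
    """A simulated dataset plus everything that generated it."""

    design: SurveyDesign
    species_params: list[SpeciesParams]
    counts: CountData
    hyperparams: dict[str, ClassHyperparams] | None = None
    roster: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def N(self) -> np.ndarray:
        return self.counts.N

    @property
    def w(self) -> np.ndarray:
        return self.counts.w


def simulate_counts(
    design: SurveyDesign, params: list[SpeciesParams], seed: int
) -> TruthBundle:
    """Simulate counts through the model's own hierarchy.

    w_ij ~ Bernoulli(psi_i); N_ij ~ Poisson(w_ij * lambda_ij);
    y_ijk ~ Binomial(N_ij, p_ijk) independently across visits.
    """
    if not params:
        raise ValueError("no species parameters supplied")
    rng = np.random.default_rng(seed)
    X_ab = design.abundance_design_matrix()       # (J, 8)
    X_det = design.detection_design_matrix()      # (J, K, 5)

    coefs = np.array([p.coefficients() for p in params])     # (I, 13)
    psi = np.array([p.psi for p in params])
    log_lam = coefs[:, :8] @ X_ab.T                           # (I, J)
    p_det = expit(np.einsum("ic,jkc->ijk", coefs[:, 8:], X_det))

    w = (rng.random(log_lam.shape) < psi[:, None]).astype(int)
    N = rng.poisson(np.where(w == 1, np.exp(log_lam), 0.0))
    y = rng.binomial(N[:, :, None], p_det)

    roster = pd.DataFrame({
        "species_id": [p.species_id for p in params],
        "urban_class": [p.urban_class for p in params],
    })
    counts = CountData(y=y, species_ids=[p.species_id for p in params],
                       design=design, N=N, w=w)
    return TruthBundle(design=design, species_params=params, counts=counts,
                       roster=roster)


def simulate_dataset(
    spec: DesignSpec | None = None,
    hyper: dict[str, ClassHyperparams] | None = None,
    roster: pd.DataFrame | None = None,
    seed: int = 0,
    psi_beta: tuple[float, float] = (1.0, 1.0),
) -> TruthBundle:
    """Convenience pipeline: design -> species parameters -> counts.

    Sub-seeds for the three stages are spawned deterministically from
    ``seed``, so the whole bundle regenerates bit-identically.
    """
    ss = np.random.SeedSequence(seed)
    s_design, s_params, s_counts = (int(s.generate_state(1)[0] % (2 ** 31))
                                    for s in ss.spawn(3))
    if spec is None:
        spec = DesignSpec(seed=s_design)
    if hyper is None:
        hyper = default_hyperparams()
    if roster is None:
        roster = default_roster()
    design = generate_design(spec)
    params = draw_species_params(hyper, roster, seed=s_params, psi_beta=psi_beta)
    bundle = simulate_counts(design, params, seed=s_counts)
    bundle.hyperparams = hyper
    return bundle
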