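"""Posterior summaries: richness, treatment benefit, HDI / mode / P(>0).

Results are reported the way hierarchical community analyses tabulate
them: for every parameter a highest-density interval, a kernel-density mode and the
proportion of posterior mass above zero (the probability the effect is
positive).  Richness at a site is the number of species of a class with
latent abundance N >= 1; the benefit of a treatment is the posterior
difference between treated and untreated stratum mean richness within an
origin.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .data import URBAN_CLASSES, SurveyDesign, normalize_roster

__all__ = [
    "richness_per_iteration",
    "richness_stratum_means",
    "richness_benefit",
    "hdi",
    "posterior_mode",
    "prop_above_zero",
    "summarize",
]


def richness_per_iteration(N_draw: np.ndarray, roster: pd.DataFrame,
                           species_ids: list[str] | None = None) -> np.ndarray:
    """Per-site, per-class species richness of one latent-abundance draw.

    ``N_draw`` is (species, sites); returns an integer (sites, classes)
    matrix counting species with N >= 1, classes in URBAN_CLASSES order.
    """
    roster = normalize_roster(roster)
    N_draw = np.asarray(N_draw)
    if species_ids is None:
        species_ids = roster["species_id"].tolist()
    cls_of = dict(zip(roster["species_id"], roster["urban_class"]))
    missing = [s for s in species_ids if s not in cls_of]
    if missing:
        raise ValueError(f"roster does not cover species: {missing}")
    class_idx = np.array([URBAN_CLASSES.index(cls_of[s]) for s in species_ids])
    present = (N_draw >= 1)
    out = np.zeros((N_draw.shape[1], len(URBAN_CLASSES)), dtype=int)
    for ci in range(len(URBAN_CLASSES)):
        out[:, ci] = present[class_idx == ci].sum(axis=0)
    return out


def _stratum_sites(design: SurveyDesign, origin: str, treated: int) -> np.ndarray:
    origin = origin.lower()
    if origin not in ("forest", "grass"):
        raise ValueError(f"unknown origin {origin!r}")
    sites = design.sites
    mask = (sites["origin"] == origin) & (sites["treated"] == treated)
    if origin == "forest":
        # sites whose block failed the weed-cover criteria are omitted from
        # the weed-control contrast
        mask &= sites["weed_contrast_eligible"] == 1
    return np.where(mask.to_numpy())[0]


def richness_stratum_means(richness_draws: np.ndarray, design: SurveyDesign
                           ) -> dict[str, np.ndarray]:
    """Mean richness per (class, origin, treatment) stratum, per draw.

    ``richness_draws`` is (draws, sites, classes).  Returns a map
    ``muRichness_<class>_<origin>_<treated|untreated>`` -> (draws,) arrays.
    """
    out = {}
    for ci, cls in enumerate(URBAN_CLASSES):
        for origin in ("grass", "forest"):
            for treated, label in ((1, "treated"), (0, "untreated")):
                idx = _stratum_sites(design, origin, treated)
                if idx.size == 0:
                    continue
                out[f"muRichness_{cls}_{origin}_{label}"] = \
                    richness_draws[:, idx, ci].mean(axis=1)
    return out


def richness_benefit(richness_draws: np.ndarray, design: SurveyDesign,
                     urban_class: str, origin: str) -> np.ndarray:
    """Posterior draws of BRichness = treated minus untreated mean richness.

    For forest origin this is the weed-control benefit; for grass origin the
    revegetation benefit.  Sites flagged out of the weed contrast are
    omitted from both strata.
    """
    if urban_class not in URBAN_CLASSES:
        raise ValueError(f"unknown urban class {urban_class!r}")
    ci = URBAN_CLASSES.index(urban_class)
    treated_idx = _stratum_sites(design, origin, 1)
    untreated_idx = _stratum_sites(design, origin, 0)
    if treated_idx.size == 0 or untreated_idx.size == 0:
        raise ValueError(f"empty stratum for origin {origin!r}")
    draws = np.asarray(richness_draws, dtype=float)
    return draws[:, treated_idx, ci].mean(axis=1) \
        - draws[:, untreated_idx, ci].mean(axis=1)


def hdi(samples, mass: float = 0.95) -> tuple[float, float]:
    """Highest-density interval from empirical samples.

    The shortest contiguous window of order statistics containing
    ceil(mass * n) samples; ties go to the smallest lower endpoint.  Working
    on the samples themselves avoids assuming a distributional shape.
    """
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if n < 20:
        raise ValueError("need at least 20 samples for an HDI")
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must lie in (0, 1)")
    m = int(np.ceil(mass * n))
    widths = x[m - 1:] - x[: n - m + 1]
    a = int(np.argmin(widths))  # argmin takes the first minimum: lowest lower end
    return float(x[a]), float(x[a + m - 1])


def posterior_mode(samples) -> float:
    """Mode of a continuous posterior via Gaussian KDE.

    Argmax of a Silverman-bandwidth Gaussian kernel density estimate over a
    512-point grid spanning the sample range.  Degenerate (zero-variance)
    samples return their common value.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 20:
        raise ValueError("need at least 20 samples for a mode estimate")
    if np.ptp(x) == 0.0:
        return float(x[0])
    if np.var(x) == 0.0:  # spread too small for a KDE bandwidth (underflow)
        return float(np.median(x))
    kde = stats.gaussian_kde(x, bw_method="silverman")
    grid = np.linspace(x.min(), x.max(), 512)
    return float(grid[np.argmax(kde(grid))])


def prop_above_zero(samples) -> float:
    """Fraction of draws strictly greater than zero."""
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("need at least one sample")
    return float(np.mean(x > 0))


def summarize(draws: dict[str, np.ndarray], mass: float = 0.95) -> pd.DataFrame:
    """One summary row per parameter: HDI, mode, proportion above zero."""
    rows = []
    for name, samples in draws.items():
        samples = np.asarray(samples, dtype=float).reshape(-1)
        lo, hi = hdi(samples, mass)
        rows.append({
            "parameter": name,
            "hdi_lower": lo,
            "mode": posterior_mode(samples),
            "hdi_upper": hi,
            "prop_above_0": prop_above_zero(samples),
        })
    return pd.DataFrame(rows, columns=["parameter", "hdi_lower", "mode",
                                       "hdi_upper", "prop_above_0"])
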