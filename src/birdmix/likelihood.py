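"""Probability kernel of the zero-inflated community N-mixture model.

One species at one site: inclusion w ~ Bernoulli(psi); latent abundance
N | w ~ Poisson(w * lambda) with log(lambda) a linear function of treatment,
origin and patch-area covariates; repeated counts y_k | N ~ Binomial(N, p_k)
with logit(p_k) quadratic in date-of-season and time-since-sunrise.

These scalar functions are the single source of truth for the model density:
the sampler's vectorized kernels and the synthetic-data generator are both
checked against them in the test suite.  All accumulation is in log space;
Poisson and binomial log-pmfs come from scipy (log-gamma based, never
factorials).
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.special import expit, logsumexp

from .data import SiteCovariates, SpeciesParams, VisitCovariates

__all__ = [
    "compute_log_lambda",
    "compute_detection_prob",
    "site_species_loglik",
    "conditional_inclusion_prob",
    "default_n_max",
]


def default_n_max(y_max: int) -> int:
    """Truncation bound for the latent-abundance support.

    ``max(100, 10 * max observed count)`` leaves negligible Poisson tail mass
    for any rate the data plausibly support while staying cheap to enumerate.
    """
    return max(100, 10 * int(y_max))


def compute_log_lambda(params: SpeciesParams, site: SiteCovariates) -> float:
    """Log expected abundance of one species at one site.

    log(lambda) = u1*TRT + u2*(1-TRT) + o1*ORI + o2*(1-ORI)
                + a1*area + a2*area*TRT + a3*TRT*ORI + a4*TRT*(1-ORI)

    where TRT is the treatment indicator, ORI the forest-origin indicator and
    ``area`` the standardized log patch area.  a3 and a4 are direct estimates
    of the treatment benefit at forest- and grass-origin sites respectively.
    """
    trt, ori, area = site.trt, site.ori, site.area
    return (
        params.u1 * trt
        + params.u2 * (1 - trt)
        + params.o1 * ori
        + params.o2 * (1 - ori)
        + params.a1 * area
        + params.a2 * area * trt
        + params.a3 * trt * ori
        + params.a4 * trt * (1 - ori)
    )


def compute_detection_prob(params: SpeciesParams, visit: VisitCovariates) -> float:
    """Per-visit detection probability, strictly inside (0, 1).

    logit(p) = v1 + b1*DATE + b2*DATE^2 + b3*TSR + b4*TSR^2 with DATE and TSR
    standardized.  ``expit`` saturates smoothly, so extreme intercepts give
    probabilities arbitrarily close to, but never exactly, 0 or 1.
    """
    logit_p = (
        params.v1
        + params.b1 * visit.date
        + params.b2 * visit.date ** 2
        + params.b3 * visit.tsr
        + params.b4 * visit.tsr ** 2
    )
    return float(expit(logit_p))


def _validate_inputs(y, psi, p, n_max=None):
    y = np.asarray(y, dtype=int)
    if y.ndim != 1 or (y < 0).any():
        raise ValueError("y_visits must be a 1-D array of non-negative counts")
    if not 0.0 <= psi <= 1.0:
        raise ValueError(f"psi must lie in [0, 1], got {psi}")
    p = np.asarray(p, dtype=float)
    if p.shape != y.shape:
        raise ValueError("p_visits must align with y_visits")
    if ((p <= 0) | (p >= 1)).any():
        raise ValueError("detection probabilities must lie strictly in (0, 1)")
    if n_max is not None and y.max(initial=0) > n_max:
        raise ValueError(
            f"N_max={n_max} is below the largest observed count {y.max()}"
        )
    return y, p


def site_species_loglik(
    y_visits, psi: float, log_lambda: float, p_visits, n_max: int
) -> float:
    """Marginal log-likelihood of one species' counts at one site.

    Sums the latent inclusion w and abundance N out of the hierarchy:

        (1 - psi) * 1{all y = 0}
        + psi * sum_{N=max(y)}^{N_max} Poisson(N; lambda) prod_k Bin(y_k; N, p_k)

    evaluated in log space with log-sum-exp over the truncated N support.
    """
    y, p = _validate_inputs(y_visits, psi, p_visits, n_max)
    if not np.isfinite(log_lambda):
        raise ValueError("log_lambda must be finite")
    lam = np.exp(log_lambda)
    all_zero = not y.any()

    if psi == 0.0:
        return 0.0 if all_zero else -np.inf

    ns = np.arange(y.max(initial=0), int(n_max) + 1)
    log_terms = stats.poisson.logpmf(ns, lam)
    for y_k, p_k in zip(y, p):
        log_terms = log_terms + stats.binom.logpmf(y_k, ns, p_k)
    log_included = logsumexp(log_terms)

    if psi == 1.0 or not all_zero:
        return float(np.log(psi) + log_included)
    return float(np.logaddexp(np.log1p(-psi), np.log(psi) + log_included))


def conditional_inclusion_prob(y_visits, psi: float, lam: float, p_visits) -> float:
    """P(w = 1 | y, psi, lambda, p) for one species at one site.

    Any positive count proves presence.  For an all-zero history the Poisson
    probability generating function gives the closed form
    P(all zero | w=1) = exp(-lambda * (1 - prod_k(1 - p_k))), so

        P(w=1 | y=0) = psi * e^{-lambda(1-q)} / (psi * e^{-lambda(1-q)} + 1 - psi)

    with q = prod_k (1 - p_k).
    """
    y, p = _validate_inputs(y_visits, psi, p_visits)
    if not (np.isfinite(lam) and lam >= 0):
        raise ValueError("lambda must be finite and non-negative")
    if y.any():
        if psi == 0.0:
            raise ValueError("psi = 0 is inconsistent with a positive count")
        return 1.0
    if psi in (0.0, 1.0):
        return float(psi)
    q = np.exp(np.log1p(-p).sum())  # prod_k (1 - p_k)
    num = np.log(psi) - lam * (1.0 - q)
    den = np.logaddexp(num, np.log1p(-psi))
    return float(np.exp(num - den))
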