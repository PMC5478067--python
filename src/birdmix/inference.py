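"""Metropolis-within-Gibbs sampler for the hierarchical community model.

Posterior over {psi_i, 13 species coefficients per species, class-level
(mu, sigma) hyperparameters, latent abundance N_ij, inclusion w_ij}, with
data augmentation:

  (a) w_ij | rest      exact Bernoulli (closed-form all-zero probability)
  (b) N_ij | rest      exact categorical draw on max(y)..N_max
  (c) coefficients     coordinate-wise random-walk Metropolis during
                       burn-in, then joint 13-dim adaptive Metropolis with
                       a covariance learned on late burn-in
  (d) class mu         conjugate Normal update given species coefficients
  (e) class sigma      conjugate Gibbs draw of the precision (default), or
                       random-walk Metropolis on log(sigma) under a Gamma
                       prior on sigma itself
  (f) psi_i            conjugate Beta update given w
  (g) ridge moves      likelihood-invariant joint translations of
                       (u1, a3, a4) and (u1, u2, o1, o2) per class
  (h) interweaving     non-centered rescaling of (sigma, coefficients)

Step (g) exists because the treatment/origin cell means over-parameterize
the log-linear predictor: two directions of coefficient space leave every
lambda_ij unchanged and are constrained only by the vague hyperprior.
Shifting species coefficients and their class mean together keeps likelihood
and species-level priors fixed, so the acceptance ratio involves only the mu
hyperprior and the flat directions mix in a few sweeps instead of a long
random walk.

Proposal scales adapt by Robbins-Monro during burn-in only and are frozen
afterwards, preserving detailed balance in the retained draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .data import (
    COEF_NAMES,
    URBAN_CLASSES,
    ClassHyperparams,
    CountData,
    SpeciesParams,
    SurveyDesign,
    normalize_roster,
)
from .likelihood import default_n_max

__all__ = ["MCMCConfig", "PosteriorSamples", "fit_model", "gelman_rubin",
           "log_posterior"]

_N_AB = 8          # abundance coefficients u1..a4
_N_DET = 5         # detection coefficients v1..b4
_TARGET_ACC = 0.44  # scalar random-walk target acceptance rate

# Likelihood-invariant directions of the abundance predictor, as +/-1 loads
# on COEF_NAMES[:8].  Cell means m_{TRT,ORI} are unchanged along both.
_RIDGE_DIRECTIONS = (
    {"u1": 1.0, "a3": -1.0, "a4": -1.0},
    {"u1": -1.0, "u2": -1.0, "o1": 1.0, "o2": 1.0},
)


@dataclass
class MCMCConfig:
    """Sampler configuration and priors.

    Priors: mu ~ Normal(0, precision=0.1) on every class mean (the
    conventional vague normal on log/logit scales of standardized
    covariates), tau = 1/sigma^2 ~ Gamma(0.1, rate=0.1) on every class
    precision (a Gamma prior on sigma itself is a config switch),
    psi_i ~ Beta(1, 1).
    """

    n_chains: int = 3
    n_iter: int = 10_000
    n_burnin: int = 2_000
    thin: int = 5
    seed: int = 0
    n_max: int | None = None
    adapt: bool = True
    initial_scale: float = 0.3
    mu_prior_sd: float = 10.0 ** 0.5  # precision-0.1 vague normal
    sigma_prior_shape: float = 0.1
    sigma_prior_rate: float = 0.1
    # "precision": Gamma prior on tau = 1/sigma^2 (conjugate Gibbs update);
    # "sd": Gamma prior on sigma itself (log-scale Metropolis update)
    sigma_prior_parameterization: str = "precision"
    psi_prior: tuple[float, float] = (1.0, 1.0)
    # toggles used for conditional-correctness experiments
    sample_coefficients: bool = True
    sample_hyper: bool = True
    sample_psi: bool = True

    def __post_init__(self):
        if self.n_chains < 2:
            raise ValueError("at least 2 chains are required for diagnostics")
        if self.n_iter <= self.n_burnin:
            raise ValueError("n_iter must exceed n_burnin")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.initial_scale <= 0:
            raise ValueError("proposal scales must be positive")
        if self.sigma_prior_parameterization not in ("precision", "sd"):
            raise ValueError("sigma prior must be on 'precision' or 'sd'")


@dataclass
class PosteriorSamples:
    """Retained post-burn-in draws, organized (chain, draw, ...).

    ``coefs`` is (chains, draws, species, 13) in COEF_NAMES order; ``mu`` and
    ``sigma`` are (chains, draws, 3, 13) in URBAN_CLASSES order; ``latent_n``
    is (chains, draws, species, sites) int16.
    """

    coefs: np.ndarray
    psi: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    latent_n: np.ndarray
    species_ids: list[str]
    class_index: np.ndarray
    config: MCMCConfig
    acceptance: dict[str, float] = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.coefs.shape[0]

    @property
    def n_draws(self) -> int:
        return self.coefs.shape[1]

    def hyper_draws(self) -> dict[str, np.ndarray]:
        """Flat name -> (chains, draws) map of every hyperparameter."""
        out = {}
        for ci, cls in enumerate(URBAN_CLASSES):
            for pi, coef in enumerate(COEF_NAMES):
                out[f"mu_{coef}_{cls}"] = self.mu[:, :, ci, pi]
                out[f"sigma_{coef}_{cls}"] = self.sigma[:, :, ci, pi]
        return out

    def to_long_dataframe(self, include_species: bool = True) -> pd.DataFrame:
        """Long (chain, iter, parameter, value) table of scalar parameters."""
        records = {}
        for name, draws in self.hyper_draws().items():
            records[name] = draws
        if include_species:
            for si, sp in enumerate(self.species_ids):
                records[f"psi[{sp}]"] = self.psi[:, :, si]
                for pi, coef in enumerate(COEF_NAMES):
                    records[f"{coef}[{sp}]"] = self.coefs[:, :, si, pi]
        n_chains, n_draws = self.n_chains, self.n_draws
        chain = np.repeat(np.arange(n_chains), n_draws)
        it = np.tile(np.arange(n_draws), n_chains)
        frames = []
        for name, draws in records.items():
            frames.append(pd.DataFrame({
                "chain": chain, "iter": it,
                "parameter": name, "value": draws.reshape(-1),
            }))
        return pd.concat(frames, ignore_index=True)


def gelman_rubin(chains: np.ndarray) -> float:
    """Split potential-scale-reduction factor (split R-hat) of one scalar.

    Each of the m chains of length n is split in half; R-hat compares the
    between- and within-half variances.  Degenerate input with zero total
    variance returns 1.0 by convention.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need >= 2 chains of equal length")
    n = chains.shape[1]
    if n < 10:
        raise ValueError("chains too short for a meaningful R-hat")
    half = n // 2
    halves = np.concatenate([chains[:, :half], chains[:, n - half:]], axis=0)
    m, n = halves.shape
    means = halves.mean(axis=1)
    w = halves.var(axis=1, ddof=1).mean()
    b = n * means.var(ddof=1)
    if w <= 0.0 or not np.isfinite(w):
        # zero within-variance: flat chains agree -> 1.0 by convention;
        # flat chains at different constants are maximally unconverged
        return 1.0 if b <= 0.0 else float("inf")
    var_plus = (n - 1) / n * w + b / n
    return float(math.sqrt(var_plus / w))


# ---------------------------------------------------------------------------
# internal vectorized state
# ---------------------------------------------------------------------------

class _FixedData:
    """Precomputed immutable arrays shared by every chain."""

    def __init__(self, data: CountData, design: SurveyDesign,
                 roster: pd.DataFrame, config: MCMCConfig):
        roster = normalize_roster(roster)
        cls_of = dict(zip(roster["species_id"], roster["urban_class"]))
        missing = [s for s in data.species_ids if s not in cls_of]
        if missing:
            raise ValueError(f"species without an urban class: {missing}")
        self.species_ids = list(data.species_ids)
        self.class_index = np.array(
            [URBAN_CLASSES.index(cls_of[s]) for s in self.species_ids]
        )
        self.y = np.asarray(data.y, dtype=np.int64)          # (I, J, K)
        self.I, self.J, self.K = self.y.shape
        self.X_ab = design.abundance_design_matrix()          # (J, 8)
        self.X_det = design.detection_design_matrix()         # (J, K, 5)
        self.y_max = self.y.max(axis=2)                       # (I, J)
        self.y_sum = self.y.sum(axis=2)                       # (I, J)
        self.all_zero = self.y_sum == 0
        self.n_max = config.n_max if config.n_max is not None \
            else default_n_max(self.y.max(initial=0))
        if self.y.max(initial=0) > self.n_max:
            raise ValueError("n_max is below the largest observed count")
        grid = np.arange(self.n_max + 1)
        self.n_grid = grid
        # lgamma[n] = log(n!) for n on the truncated latent support
        self.lgamma = gammaln(np.arange(self.n_max + 2) + 1.0)
        # gammaln(N - y + 1) lookups: (I, J, K, Ngrid) is too big; instead
        # precompute gammaln table and index per sweep.
        # class membership masks
        self.class_members = [np.where(self.class_index == ci)[0]
                              for ci in range(len(URBAN_CLASSES))]
        self.class_sizes = np.array([len(m) for m in self.class_members])


class _ChainState:
    def __init__(self, fx: _FixedData, config: MCMCConfig, rng, overdispersion,
                 initial_params=None):
        I, J = fx.I, fx.J
        self.rng = rng
        if initial_params is not None:
            self._init_from_params(fx, config, initial_params)
            return
        # crude data-informed initialisation plus chain-specific jitter
        lam0 = np.maximum(fx.y_max.mean(axis=1), 0.2)
        base = np.log(lam0)
        self.coefs = np.zeros((I, len(COEF_NAMES)))
        self.coefs[:, :4] = base[:, None] / 2.0
        self.coefs += rng.normal(0.0, overdispersion, size=self.coefs.shape)
        if config.sample_psi:
            seen = 1.0 - fx.all_zero.mean(axis=1)
            self.psi = np.clip(seen + rng.normal(0, 0.05, I), 0.02, 0.98)
        else:
            self.psi = np.full(I, 0.5)
        self.w = np.where(fx.all_zero, (rng.random((I, J)) < self.psi[:, None]),
                          True).astype(np.int8)
        self.N = np.where(self.w == 1, fx.y_max, 0).astype(np.int64)
        self.mu = np.zeros((len(URBAN_CLASSES), len(COEF_NAMES)))
        for ci, members in enumerate(fx.class_members):
            if len(members):
                self.mu[ci] = self.coefs[members].mean(axis=0)
        self.mu += rng.normal(0.0, overdispersion, size=self.mu.shape)
        self.sigma = np.full_like(self.mu, 0.5)
        # per-species-per-coefficient proposal scales; per-class-per-coef for
        # log-sigma
        self.scale_coef = np.full((I, len(COEF_NAMES)), config.initial_scale)
        self.scale_sigma = np.full_like(self.mu, config.initial_scale)
        self.scale_interweave = np.full_like(self.mu, config.initial_scale)
        self._init_am(fx)
        self.refresh_predictors(fx)

    def _init_am(self, fx):
        k = len(COEF_NAMES)
        self.am_mean = np.zeros((fx.I, k))
        self.am_cov = np.zeros((fx.I, k, k))
        self.am_count = 0
        self.am_chol = np.broadcast_to(0.1 * np.eye(k), (fx.I, k, k)).copy()
        self.scale_am = np.full(fx.I, 2.38 / np.sqrt(k))
        self.use_am = False

    def _init_from_params(self, fx, config, params):
        """Start exactly at supplied species parameters (no jitter); used to
        run the latent-variable Gibbs steps conditional on known truth."""
        if len(params) != fx.I:
            raise ValueError("one SpeciesParams per observed species required")
        self.coefs = np.array([p.coefficients() for p in params])
        self.psi = np.array([p.psi for p in params], dtype=float)
        self.w = np.where(fx.all_zero,
                          self.rng.random((fx.I, fx.J)) < self.psi[:, None],
                          True).astype(np.int8)
        self.N = np.where(self.w == 1, fx.y_max, 0).astype(np.int64)
        self.mu = np.zeros((len(URBAN_CLASSES), len(COEF_NAMES)))
        for ci, members in enumerate(fx.class_members):
            if len(members):
                self.mu[ci] = self.coefs[members].mean(axis=0)
        self.sigma = np.full_like(self.mu, 0.5)
        self.scale_coef = np.full((fx.I, len(COEF_NAMES)), config.initial_scale)
        self.scale_sigma = np.full_like(self.mu, config.initial_scale)
        self.scale_interweave = np.full_like(self.mu, config.initial_scale)
        self._init_am(fx)
        self.refresh_predictors(fx)

    def refresh_predictors(self, fx: _FixedData):
        self.log_lam = self.coefs[:, :_N_AB] @ fx.X_ab.T             # (I, J)
        self.logit_p = np.einsum("ic,jkc->ijk",
                                 self.coefs[:, _N_AB:], fx.X_det)     # (I, J, K)


def _log_sigmoid(x):
    return -np.logaddexp(0.0, -x)


def _detection_loglik(fx, N, logit_p):
    """Per-species binomial terms depending on the detection predictor."""
    log_p = _log_sigmoid(logit_p)
    log_1mp = _log_sigmoid(-logit_p)
    return ((fx.y * log_p) + (N[:, :, None] - fx.y) * log_1mp).sum(axis=(1, 2))


def _abundance_loglik(fx, state):
    """Poisson terms depending on log-lambda: sum_j w [N loglam - lam]."""
    lam = np.exp(state.log_lam)
    return np.where(state.w == 1, state.N * state.log_lam - lam, 0.0).sum(axis=1)


def _step_inclusion(fx, state):
    """(a) Exact Gibbs draw of w at all-zero cells (others are forced to 1)."""
    log_1mp = _log_sigmoid(-state.logit_p)         # (I, J, K)
    q = np.exp(log_1mp.sum(axis=2))                # prod_k (1 - p)
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        lam = np.exp(state.log_lam)
        log_num = np.log(state.psi)[:, None] - lam * (1.0 - q)
        log_den = np.logaddexp(log_num, np.log1p(-state.psi)[:, None])
        p_in = np.exp(log_num - log_den)
    p_in = np.where(state.psi[:, None] >= 1.0, 1.0, p_in)
    p_in = np.where(state.psi[:, None] <= 0.0, 0.0, p_in)
    draw = state.rng.random(p_in.shape) < p_in
    state.w = np.where(fx.all_zero, draw, True).astype(np.int8)
    state.N = np.where(state.w == 1, state.N, 0)


def _step_latent_n(fx, state):
    """(b) Exact categorical draw of N on max(y)..n_max for included cells.

    The support grid starts at each cell's max observed count and stops where
    the Poisson-binomial tail is negligible (lambda*q + 10*sqrt + counts + 25
    beyond the origin, capped at n_max), so cheap cells get short grids.
    Cells are processed in a few length buckets to stay vectorized.
    """
    rows, cols = np.nonzero(state.w == 1)
    if rows.size == 0:
        return
    loglam = np.clip(state.log_lam[rows, cols], -700.0, 700.0)   # (C,)
    with np.errstate(over="ignore"):
        lam = np.exp(loglam)
    s_log1mp = _log_sigmoid(-state.logit_p[rows, cols, :]).sum(axis=1)
    y = fx.y[rows, cols, :]                                       # (C, K)
    ymax = fx.y_max[rows, cols]
    ysum = fx.y_sum[rows, cols]
    with np.errstate(over="ignore", invalid="ignore"):
        span = np.where(np.isfinite(lam),
                        np.ceil(lam + 10.0 * np.sqrt(lam)), np.inf)
    n_hi = np.minimum(fx.n_max, ymax + ysum + span + 25).astype(np.int64)
    length = n_hi - ymax + 1                                      # (C,)
    draw = np.empty(rows.size, dtype=np.int64)

    # bucket by grid length: powers of four keep at most a handful of passes
    bucket = np.maximum(16, 4 ** np.ceil(np.log2(length) / 2.0).astype(int))
    for G in np.unique(bucket):
        sel = np.nonzero(bucket == G)[0]
        grid = np.arange(G)
        n = ymax[sel, None] + grid[None, :]                       # (S, G)
        # log weight(N) = N (loglam + sum_k log(1-p_k)) + (K-1) log(N!)
        #              - sum_k log((N - y_k)!) + const(y)
        logw = n * (loglam[sel] + s_log1mp[sel])[:, None] \
            + (fx.K - 1) * fx.lgamma[np.minimum(n, fx.n_max + 1)]
        for k in range(fx.K):
            logw = logw - fx.lgamma[np.minimum(n - y[sel, k:k + 1],
                                               fx.n_max + 1)]
        logw[n > n_hi[sel, None]] = -np.inf
        logw -= logw.max(axis=1, keepdims=True)
        wts = np.exp(logw)
        cum = np.cumsum(wts, axis=1)
        u = state.rng.random(sel.size) * cum[:, -1]
        idx = (cum < u[:, None]).sum(axis=1)
        draw[sel] = ymax[sel] + np.minimum(idx, G - 1)
    state.N[rows, cols] = np.minimum(draw, fx.n_max)


def _step_coefficients(fx, state, config, adapt_step):
    """(c) Column-wise random-walk Metropolis on species coefficients."""
    I = fx.I
    mu_i = state.mu[fx.class_index]        # (I, 13)
    sig_i = state.sigma[fx.class_index]
    acc = np.zeros(len(COEF_NAMES))
    with np.errstate(over="ignore"):
        cur_ab = np.where(state.w == 1,
                          state.N * state.log_lam - np.exp(state.log_lam),
                          0.0).sum(axis=1)
    cur_det = _detection_loglik(fx, state.N, state.logit_p)
    for pi in range(len(COEF_NAMES)):
        cur = state.coefs[:, pi]
        step = state.rng.normal(0.0, 1.0, I) * state.scale_coef[:, pi]
        prop = cur + step
        d_prior = (cur - mu_i[:, pi]) ** 2 - (prop - mu_i[:, pi]) ** 2
        d_prior /= 2.0 * sig_i[:, pi] ** 2
        if pi < _N_AB:
            d_pred = step[:, None] * fx.X_ab[:, pi][None, :]          # (I, J)
            new_log_lam = state.log_lam + d_pred
            with np.errstate(over="ignore"):
                new_ll = np.where(state.w == 1,
                                  state.N * new_log_lam - np.exp(new_log_lam),
                                  0.0).sum(axis=1)
            d_lik = new_ll - cur_ab
        else:
            di = pi - _N_AB
            d_pred = step[:, None, None] * fx.X_det[:, :, di][None, :, :]
            new_logit_p = state.logit_p + d_pred
            new_ll = _detection_loglik(fx, state.N, new_logit_p)
            d_lik = new_ll - cur_det
        log_alpha = d_lik + d_prior
        accept = np.log(state.rng.random(I)) < log_alpha
        state.coefs[accept, pi] = prop[accept]
        if pi < _N_AB:
            state.log_lam[accept] = new_log_lam[accept]
            cur_ab[accept] = new_ll[accept]
        else:
            state.logit_p[accept] = new_logit_p[accept]
            cur_det[accept] = new_ll[accept]
        acc[pi] = accept.mean()
        if adapt_step is not None:
            state.scale_coef[:, pi] *= np.exp(
                adapt_step * (accept.astype(float) - _TARGET_ACC))
    return acc


def _update_am_stats(fx, state):
    """Running per-species covariance of coefficient deviations.

    Deviations from the current class means are tracked instead of raw
    coefficients: the flat translation directions drift with mu, and raw
    covariances would be inflated far beyond the conditional posterior the
    joint proposal actually targets.
    """
    x = state.coefs - state.mu[fx.class_index]
    n = state.am_count + 1
    delta_old = x - state.am_mean
    state.am_mean = state.am_mean + delta_old / n
    delta_new = x - state.am_mean
    state.am_cov = ((n - 1) * state.am_cov
                    + np.einsum("ij,ik->ijk", delta_old, delta_new)) / n
    state.am_count = n


def _refresh_am_chol(state):
    cov = state.am_cov + 1e-4 * np.eye(state.am_cov.shape[-1])[None]
    state.am_chol = np.linalg.cholesky(cov)


def _step_am(fx, state, config, adapt_step):
    """(c') Joint adaptive-Metropolis update of all 13 coefficients per
    species, with proposal covariance learned during burn-in.

    Handles the strong posterior correlations the single-coordinate walks
    cannot (detection intercept vs quadratic terms, area vs area-by-treatment)
    because the proposal aligns with the local covariance.
    """
    I = fx.I
    mu_i = state.mu[fx.class_index]
    sig_i = state.sigma[fx.class_index]
    z = state.rng.normal(0.0, 1.0, (I, len(COEF_NAMES)))
    delta = np.einsum("ijk,ik->ij", state.am_chol, z) * state.scale_am[:, None]
    prop = state.coefs + delta

    new_log_lam = prop[:, :_N_AB] @ fx.X_ab.T
    new_logit_p = np.einsum("ic,jkc->ijk", prop[:, _N_AB:], fx.X_det)
    with np.errstate(over="ignore"):
        cur_ab = np.where(state.w == 1,
                          state.N * state.log_lam - np.exp(state.log_lam),
                          0.0).sum(axis=1)
        new_ab = np.where(state.w == 1,
                          state.N * new_log_lam - np.exp(new_log_lam),
                          0.0).sum(axis=1)
    d_lik = new_ab - cur_ab \
        + _detection_loglik(fx, state.N, new_logit_p) \
        - _detection_loglik(fx, state.N, state.logit_p)
    d_prior = (((state.coefs - mu_i) ** 2 - (prop - mu_i) ** 2)
               / (2.0 * sig_i ** 2)).sum(axis=1)
    accept = np.log(state.rng.random(I)) < d_lik + d_prior
    state.coefs[accept] = prop[accept]
    state.log_lam[accept] = new_log_lam[accept]
    state.logit_p[accept] = new_logit_p[accept]
    if adapt_step is not None:
        # 0.23 is the classic multivariate random-walk target
        state.scale_am *= np.exp(adapt_step * (accept.astype(float) - 0.23))
    return float(accept.mean())


def _step_ridge(fx, state, config):
    """(g) Joint translation along likelihood-invariant directions, per class."""
    sd0 = config.mu_prior_sd
    for direction in _RIDGE_DIRECTIONS:
        idx = np.array([COEF_NAMES.index(c) for c in direction])
        load = np.array([direction[c] for c in direction])
        for ci, members in enumerate(fx.class_members):
            if len(members) == 0:
                continue
            c = state.rng.normal(0.0, 2.0)
            mu_cur = state.mu[ci, idx]
            mu_prop = mu_cur + c * load
            d = (mu_cur ** 2 - mu_prop ** 2).sum() / (2.0 * sd0 ** 2)
            if np.log(state.rng.random()) < d:
                state.mu[ci, idx] = mu_prop
                state.coefs[np.ix_(members, idx)] += c * load[None, :]
    # predictors are invariant: no refresh needed (verified in tests)


def _step_hyper_mu(fx, state, config):
    """(d) Conjugate Normal update of class means."""
    sd0 = config.mu_prior_sd
    for ci, members in enumerate(fx.class_members):
        n_c = len(members)
        if n_c == 0:
            continue
        prec = n_c / state.sigma[ci] ** 2 + 1.0 / sd0 ** 2
        mean = state.coefs[members].sum(axis=0) / state.sigma[ci] ** 2 / prec
        state.mu[ci] = mean + state.rng.normal(0.0, 1.0, len(COEF_NAMES)) \
            / np.sqrt(prec)


def _log_sigma_prior(sigma, config):
    """Unnormalized log prior density of the class sd, either
    parameterization."""
    a, r = config.sigma_prior_shape, config.sigma_prior_rate
    if config.sigma_prior_parameterization == "precision":
        # tau = sigma^-2 ~ Gamma(a, r); change of variables to sigma
        return -(2.0 * a + 1.0) * np.log(sigma) - r / sigma ** 2
    return (a - 1.0) * np.log(sigma) - r * sigma


def _step_hyper_sigma(fx, state, config, adapt_step):
    """(e) Class-sd update.

    Precision parameterization: exact conjugate Gibbs draw
    tau | rest ~ Gamma(a + n/2, rate r + ss/2).  sd parameterization:
    random-walk Metropolis on log(sigma) under the Gamma prior.
    """
    a, r = config.sigma_prior_shape, config.sigma_prior_rate
    conjugate = config.sigma_prior_parameterization == "precision"
    acc_total, cnt = 0.0, 0
    for ci, members in enumerate(fx.class_members):
        n_c = len(members)
        if n_c == 0:
            continue
        dev = state.coefs[members] - state.mu[ci][None, :]
        ss = (dev ** 2).sum(axis=0)
        if conjugate:
            tau = state.rng.gamma(a + n_c / 2.0, 1.0 / (r + ss / 2.0))
            state.sigma[ci] = 1.0 / np.sqrt(np.maximum(tau, 1e-300))
            acc_total += 1.0
            cnt += 1
            continue
        cur = state.sigma[ci]
        step = state.rng.normal(0.0, 1.0, len(COEF_NAMES)) * state.scale_sigma[ci]
        # floor keeps 1-member classes from collapsing into the Gamma(0.1)
        # spike at 0 and overflowing the conjugate-mean division
        prop = np.maximum(cur * np.exp(step), 1e-6)
        def logpost(s):
            return (-n_c * np.log(s) - ss / (2.0 * s ** 2)
                    + _log_sigma_prior(s, config))
        # + log-Jacobian of the log-scale walk: + log(sigma)
        log_alpha = logpost(prop) - logpost(cur) + np.log(prop) - np.log(cur)
        accept = np.log(state.rng.random(len(COEF_NAMES))) < log_alpha
        state.sigma[ci] = np.where(accept, prop, cur)
        if adapt_step is not None:
            state.scale_sigma[ci] *= np.exp(
                adapt_step * (accept.astype(float) - _TARGET_ACC))
        acc_total += accept.mean()
        cnt += 1
    return acc_total / max(cnt, 1)


def _step_scale_interweave(fx, state, config, adapt_step):
    """(h) Non-centered rescaling of (sigma, coefficients) per class/column.

    In non-centered coordinates z_i = (coef_i - mu)/sigma the class sd can be
    moved with z held fixed, which drags every member's coefficient along:
    coef_i' = mu + s * (coef_i - mu), sigma' = s * sigma.  The species-level
    prior is invariant by construction, so acceptance needs only the
    likelihood ratio, the Gamma prior and the log-walk Jacobian.  This breaks
    the funnel coupling that makes centered sigma updates mix slowly.
    """
    mu_i = state.mu[fx.class_index]                     # (I, 13)
    n_classes = len(URBAN_CLASSES)
    acc_total, n_moves = 0.0, 0
    with np.errstate(over="ignore"):
        cur_ab = np.where(state.w == 1,
                          state.N * state.log_lam - np.exp(state.log_lam),
                          0.0).sum(axis=1)
    cur_det = _detection_loglik(fx, state.N, state.logit_p)
    for pi in range(len(COEF_NAMES)):
        s_cls = np.exp(state.rng.normal(0.0, 1.0, n_classes)
                       * state.scale_interweave[:, pi])
        s_i = s_cls[fx.class_index]
        cur = state.coefs[:, pi]
        prop = mu_i[:, pi] + s_i * (cur - mu_i[:, pi])
        step = prop - cur
        if pi < _N_AB:
            new_log_lam = state.log_lam + step[:, None] * fx.X_ab[:, pi][None, :]
            with np.errstate(over="ignore"):
                new_ll = np.where(state.w == 1,
                                  state.N * new_log_lam - np.exp(new_log_lam),
                                  0.0).sum(axis=1)
            d_lik = new_ll - cur_ab
        else:
            di = pi - _N_AB
            new_logit_p = state.logit_p \
                + step[:, None, None] * fx.X_det[:, :, di][None, :, :]
            new_ll = _detection_loglik(fx, state.N, new_logit_p)
            d_lik = new_ll - cur_det
        u = np.log(state.rng.random(n_classes))
        for ci, members in enumerate(fx.class_members):
            if len(members) == 0:
                continue
            sig_cur = state.sigma[ci, pi]
            sig_prop = sig_cur * s_cls[ci]
            if sig_prop < 1e-6:
                accept = False
            else:
                d = d_lik[members].sum() \
                    + _log_sigma_prior(sig_prop, config) \
                    - _log_sigma_prior(sig_cur, config) \
                    + np.log(s_cls[ci])  # Jacobian of the log-scale walk
                accept = u[ci] < d
            if accept:
                state.sigma[ci, pi] = sig_prop
                state.coefs[members, pi] = prop[members]
                if pi < _N_AB:
                    state.log_lam[members] = new_log_lam[members]
                    cur_ab[members] = new_ll[members]
                else:
                    state.logit_p[members] = new_logit_p[members]
                    cur_det[members] = new_ll[members]
            if adapt_step is not None:
                state.scale_interweave[ci, pi] *= np.exp(
                    adapt_step * (float(accept) - _TARGET_ACC))
            acc_total += float(accept)
            n_moves += 1
    return acc_total / max(n_moves, 1)


def _step_psi(fx, state, config):
    """(f) Conjugate Beta update of inclusion probabilities."""
    a0, b0 = config.psi_prior
    k = state.w.sum(axis=1)
    state.psi = state.rng.beta(a0 + k, b0 + fx.J - k)


def _run_chain(fx: _FixedData, config: MCMCConfig, chain_seed, overdispersion,
               initial_params=None):
    rng = np.random.default_rng(chain_seed)
    state = _ChainState(fx, config, rng, overdispersion, initial_params)
    n_keep = (config.n_iter - config.n_burnin) // config.thin
    I, J = fx.I, fx.J
    out = {
        "coefs": np.empty((n_keep, I, len(COEF_NAMES))),
        "psi": np.empty((n_keep, I)),
        "mu": np.empty((n_keep, len(URBAN_CLASSES), len(COEF_NAMES))),
        "sigma": np.empty((n_keep, len(URBAN_CLASSES), len(COEF_NAMES))),
        "latent_n": np.empty((n_keep, I, J), dtype=np.int16),
    }
    acc_am = 0.0
    acc_sigma = 0.0
    acc_iw = 0.0
    n_acc = 0
    kept = 0
    for t in range(config.n_iter):
        in_burnin = t < config.n_burnin
        adapt_step = (min(0.25, (t + 1.0) ** -0.6)
                      if (config.adapt and in_burnin) else None)
        _step_inclusion(fx, state)
        _step_latent_n(fx, state)
        if config.sample_coefficients:
            if in_burnin:
                a_cols = _step_coefficients(fx, state, config, adapt_step)
                a = float(np.mean(a_cols))
                # learn the joint proposal covariance on the second half of
                # burn-in only, past the initialisation transient
                if t >= config.n_burnin // 2:
                    _update_am_stats(fx, state)
                    if state.am_count == 50 or                             (state.am_count > 50 and t % 100 == 0):
                        _refresh_am_chol(state)
                    if state.am_count > 60:
                        a = _step_am(fx, state, config, adapt_step)
                if t == config.n_burnin - 1:
                    state.use_am = state.am_count >= 300
                    if state.use_am:
                        _refresh_am_chol(state)
            elif state.use_am:
                a = _step_am(fx, state, config, None)
            else:
                a_cols = _step_coefficients(fx, state, config, None)
                a = float(np.mean(a_cols))
            if config.sample_hyper:
                _step_ridge(fx, state, config)
        if config.sample_hyper:
            _step_hyper_mu(fx, state, config)
            s = _step_hyper_sigma(fx, state, config, adapt_step)
            if config.sample_coefficients:
                iw = _step_scale_interweave(fx, state, config, adapt_step)
        if config.sample_psi:
            _step_psi(fx, state, config)
        if not in_burnin:
            if config.sample_coefficients:
                acc_am += a
            if config.sample_hyper:
                acc_sigma += s
                if config.sample_coefficients:
                    acc_iw += iw
            n_acc += 1
            if (t - config.n_burnin) % config.thin == 0 and kept < n_keep:
                out["coefs"][kept] = state.coefs
                out["psi"][kept] = state.psi
                out["mu"][kept] = state.mu
                out["sigma"][kept] = state.sigma
                out["latent_n"][kept] = state.N
                kept += 1
    acc = {}
    if n_acc:
        if config.sample_coefficients:
            acc["species_block"] = float(acc_am / n_acc)
            if config.sample_hyper:
                acc["interweave"] = float(acc_iw / n_acc)
        # the conjugate precision draw is Gibbs, not Metropolis: no rate
        if config.sample_hyper and \
                config.sigma_prior_parameterization == "sd":
            acc["log_sigma"] = float(acc_sigma / n_acc)
    return out, acc


def fit_model(
    data: CountData,
    design: SurveyDesign,
    roster: pd.DataFrame,
    config: MCMCConfig | None = None,
    initial_params: list[SpeciesParams] | None = None,
) -> PosteriorSamples:
    """Fit the hierarchical community model by Metropolis-within-Gibbs.

    Chains run sequentially with seeds spawned from ``config.seed``; chain c
    is initialized with overdispersion growing in c so convergence
    diagnostics start from genuinely distinct states.  All-zero species are
    retained — the zero-inflation layer absorbs them.
    """
    if config is None:
        config = MCMCConfig()
    fx = _FixedData(data, design, roster, config)
    ss = np.random.SeedSequence(config.seed)
    chain_seeds = ss.spawn(config.n_chains)
    results, accs = [], []
    for c in range(config.n_chains):
        overdispersion = 0.1 + 0.5 * c / max(config.n_chains - 1, 1)
        res, acc = _run_chain(fx, config, chain_seeds[c], overdispersion,
                              initial_params)
        results.append(res)
        accs.append(acc)
    stack = {k: np.stack([r[k] for r in results]) for k in results[0]}
    acceptance = {}
    for key in accs[0]:
        acceptance[key] = float(np.mean([a[key] for a in accs]))
    return PosteriorSamples(
        coefs=stack["coefs"], psi=stack["psi"], mu=stack["mu"],
        sigma=stack["sigma"], latent_n=stack["latent_n"],
        species_ids=fx.species_ids, class_index=fx.class_index,
        config=config, acceptance=acceptance,
    )


def log_posterior(
    data: CountData,
    design: SurveyDesign,
    params: list[SpeciesParams],
    hyperparams: dict[str, ClassHyperparams],
    config: MCMCConfig | None = None,
) -> float:
    """Unnormalized joint log density at the current latent state.

    Uses the latent truth (N, w) carried by ``data``; nothing is
    marginalized.  Out-of-support states (y > N, sigma <= 0, psi outside
    [0, 1]) return -inf.
    """
    if config is None:
        config = MCMCConfig()
    if data.N is None or data.w is None:
        raise ValueError("log_posterior requires latent N and w on the data")
    y = np.asarray(data.y)
    N = np.asarray(data.N)
    w = np.asarray(data.w)
    if (y.max(axis=2) > N).any() or (N[w == 0] != 0).any():
        return -np.inf

    coefs = np.array([p.coefficients() for p in params])
    psi = np.array([p.psi for p in params])
    if ((psi < 0) | (psi > 1)).any():
        return -np.inf
    X_ab = design.abundance_design_matrix()
    X_det = design.detection_design_matrix()
    log_lam = coefs[:, :_N_AB] @ X_ab.T
    logit_p = np.einsum("ic,jkc->ijk", coefs[:, _N_AB:], X_det)

    total = 0.0
    # w | psi
    with np.errstate(divide="ignore"):
        total += np.where(w == 1, np.log(psi)[:, None],
                          np.log1p(-psi)[:, None]).sum()
    if not np.isfinite(total):
        return -np.inf
    # N | w, lambda  (w=0 cells are the degenerate point mass at 0)
    lam = np.exp(log_lam)
    total += np.where(w == 1,
                      N * log_lam - lam - gammaln(N + 1.0), 0.0).sum()
    # y | N, p
    log_p = _log_sigmoid(logit_p)
    log_1mp = _log_sigmoid(-logit_p)
    logC = (gammaln(N[:, :, None] + 1.0) - gammaln(y + 1.0)
            - gammaln(N[:, :, None] - y + 1.0))
    total += (logC + y * log_p + (N[:, :, None] - y) * log_1mp).sum()
    # species coefficients | class hyperparameters
    a0, b0 = config.psi_prior
    for p in params:
        h = hyperparams[p.urban_class]
        for cname in COEF_NAMES:
            mu, sd = h.mu[cname], h.sigma[cname]
            if sd <= 0:
                return -np.inf
            x = getattr(p, cname)
            total += -0.5 * ((x - mu) / sd) ** 2 - np.log(sd) \
                - 0.5 * np.log(2.0 * np.pi)
        if 0.0 < p.psi < 1.0:
            total += (a0 - 1.0) * np.log(p.psi) + (b0 - 1.0) * np.log1p(-p.psi)
        elif a0 != 1.0 or b0 != 1.0:
            return -np.inf
    # hyperpriors
    sh, rt = config.sigma_prior_shape, config.sigma_prior_rate
    for h in hyperparams.values():
        for cname in COEF_NAMES:
            mu, sd = h.mu[cname], h.sigma[cname]
            if sd <= 0:
                return -np.inf
            total += -0.5 * (mu / config.mu_prior_sd) ** 2 \
                - np.log(config.mu_prior_sd) - 0.5 * np.log(2.0 * np.pi)
            log_gamma_norm = sh * np.log(rt) - gammaln(sh)
            if config.sigma_prior_parameterization == "precision":
                tau = sd ** -2.0
                # Gamma density of tau times |d tau / d sigma| = 2 sigma^-3
                total += log_gamma_norm + (sh - 1.0) * np.log(tau) - rt * tau \
                    + np.log(2.0) - 3.0 * np.log(sd)
            else:
                total += log_gamma_norm + (sh - 1.0) * np.log(sd) - rt * sd
    return float(total)
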