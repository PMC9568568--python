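"""Bayesian inference of binding probabilities and the shared saturation count.

The joint model for m scored samples has parameters
``theta = (p_1, ..., p_m, n_sat)``: a Beta(1,1) prior on each binding
probability and a discrete-uniform prior on the integer saturation count
``n_sat`` shared across samples.  Sampling is Metropolis-within-Gibbs:

* each ``p_j`` moves by a Gaussian random walk on the logit scale
  (accept/reject on the joint posterior; given ``n_sat`` the full
  conditional factorises over j, so all components update in parallel);
* ``n_sat`` moves by a symmetric integer random walk, with proposals
  outside the prior support rejected.

Runs are deterministic given the sampler seed: chain c draws its entire
random stream from a generator seeded ``seed + c``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit, logit

from .model import BinaryScoreSet, bernoulli_log_likelihood

__all__ = [
    "PriorSpec",
    "SamplerConfig",
    "PosteriorResult",
    "fit_joint",
    "fit_single",
    "map_estimate",
    "credible_interval",
    "gelman_rubin",
]


@dataclass(frozen=True)
class PriorSpec:
    """Priors: Beta(p_alpha, p_beta) on every p_j; integer-uniform
    [n_sat_lower, n_sat_upper] on n_sat."""

    p_alpha: float = 1.0
    p_beta: float = 1.0
    n_sat_lower: int = 0
    n_sat_upper: int = 1000

    def __post_init__(self) -> None:
        if self.p_alpha <= 0 or self.p_beta <= 0:
            raise ValueError("Beta prior parameters must be positive")
        if not (0 <= self.n_sat_lower < self.n_sat_upper):
            raise ValueError("need 0 <= n_sat_lower < n_sat_upper")


@dataclass(frozen=True)
class SamplerConfig:
    """Metropolis-within-Gibbs settings.

    ``p_proposal_sd`` is the random-walk step on the logit scale;
    ``nsat_step_max`` is the maximum magnitude of the uniform integer step
    (proposal = current ± Uniform{1..nsat_step_max}).  ``continuous_nsat``
    relaxes n_sat to a real parameter in the closed form (Gaussian random
    walk with sd ``nsat_proposal_sd``), for comparison with the default
    integer treatment.
    """

    n_chains: int = 4
    n_draws: int = 20000
    n_burnin: int = 5000
    seed: int = 0
    p_proposal_sd: float = 0.2
    nsat_step_max: int = 10
    nsat_proposal_sd: float = 5.0
    continuous_nsat: bool = False
    max_init_retries: int = 100

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("n_chains must be >= 2 (Gelman-Rubin needs multiple chains)")
        if self.n_draws <= 0 or self.n_burnin < 0:
            raise ValueError("n_draws must be > 0 and n_burnin >= 0")


@dataclass
class PosteriorResult:
    """Posterior draws plus point/interval summaries and diagnostics.

    ``draws[name]`` has shape (n_chains, n_draws), post-burn-in.  Parameter
    names are ``"p[j]"`` for sample j (input order) and ``"n_sat"``.
    """

    draws: dict[str, np.ndarray]
    map: dict[str, float] = field(default_factory=dict)
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    rhat: dict[str, float] = field(default_factory=dict)
    autocorr: dict[str, float] = field(default_factory=dict)
    accept_rates: dict[str, float] = field(default_factory=dict)

    @property
    def parameters(self) -> list[str]:
        return list(self.draws)

    def converged(self, threshold: float = 1.1) -> bool:
        """Quantitative convergence gate: every parameter's R-hat below threshold."""
        return all(r < threshold for r in self.rhat.values())


# ---------------------------------------------------------------------------
# summaries


def map_estimate(draws: np.ndarray, integer: bool = False) -> float:
    """MAP estimate from posterior samples.

    Integer parameters: the most frequent value (ties broken toward the
    smallest).  Real parameters: the midpoint of the tallest bin of a
    200-bin histogram spanning the sample range.
    """
    x = np.asarray(draws).ravel()
    if x.size < 1:
        raise ValueError("no draws")
    if integer:
        vals, counts = np.unique(x.astype(np.int64), return_counts=True)
        return float(vals[np.argmax(counts)])  # unique() sorts, argmax takes first
    lo, hi = float(x.min()), float(x.max())
    if lo == hi:
        return lo
    counts, edges = np.histogram(x, bins=200, range=(lo, hi))
    i = int(np.argmax(counts))
    return float(0.5 * (edges[i] + edges[i + 1]))


def credible_interval(draws: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Central equal-tailed credible interval from pooled samples."""
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    x = np.asarray(draws).ravel()
    if x.size < 1:
        raise ValueError("no draws")
    a = (1.0 - level) / 2.0
    lo, hi = np.quantile(x, [a, 1.0 - a])
    return float(lo), float(hi)


def gelman_rubin(draws: np.ndarray) -> float:
    """Potential scale reduction factor R-hat over chains.

    ``draws`` has shape (n_chains, n_draws).  Uses the standard formula
    ``sqrt(V_hat / W)`` with ``V_hat = (n-1)/n * W + (1 + 1/m) * B/n``.
    Degenerate chains (zero within-chain variance) return 1.0.
    """
    x = np.atleast_2d(np.asarray(draws, dtype=float))
    m, n = x.shape
    if m < 2:
        raise ValueError("gelman_rubin needs at least 2 chains")
    if n < 2:
        raise ValueError("gelman_rubin needs at least 2 draws per chain")
    chain_means = x.mean(axis=1)
    W = x.var(axis=1, ddof=1).mean()
    B_over_n = chain_means.var(ddof=1)  # = B / n
    if W == 0.0:
        return 1.0
    v_hat = (n - 1) / n * W + (1.0 + 1.0 / m) * B_over_n
    return float(np.sqrt(v_hat / W))


def _lag1_autocorr(draws: np.ndarray) -> float:
    """Mean lag-1 autocorrelation across chains (mixing summary)."""
    x = np.atleast_2d(np.asarray(draws, dtype=float))
    acs = []
    for row in x:
        r = row - row.mean()
        denom = float(r @ r)
        if denom == 0.0:
            acs.append(0.0)
        else:
            acs.append(float(r[:-1] @ r[1:]) / denom)
    return float(np.mean(acs))


# ---------------------------------------------------------------------------
# sampler internals


def _q_of(p: np.ndarray, f_l: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Closed-form q for array p (chains, m), f_l (m,), n (chains, 1) or scalar.

    Evaluated in log space; accepts real n so the continuous relaxation can
    reuse it.
    """
    pf = p * f_l
    with np.errstate(divide="ignore", invalid="ignore"):
        log_neg = n * np.log1p(-pf)
    log_neg = np.where((pf == 1.0) & (n == 0), 0.0, log_neg)
    return np.clip(-np.expm1(log_neg), 0.0, 1.0)


def _loglik_terms(p, f_l, n, V, V_plus) -> np.ndarray:
    """Per-sample Bernoulli log-likelihood terms, shape (chains, m)."""
    q = _q_of(p, f_l, n)
    return bernoulli_log_likelihood(V, V_plus, q)


def _run_mwg(
    f_l: np.ndarray,
    V: np.ndarray,
    V_plus: np.ndarray,
    priors: PriorSpec,
    config: SamplerConfig,
    n_sat_fixed: int | None = None,
) -> PosteriorResult:
    m = f_l.size
    C = config.n_chains
    n_iter = config.n_burnin + config.n_draws
    sample_nsat = n_sat_fixed is None
    rngs = [np.random.default_rng(config.seed + c) for c in range(C)]

    # pre-drawn per-chain streams, stacked chain-major so each chain's
    # stream depends only on its own seed
    eps = np.stack([r.normal(0.0, config.p_proposal_sd, size=(n_iter, m)) for r in rngs])
    log_u_p = np.log(np.stack([r.random(size=(n_iter, m)) for r in rngs]))
    if sample_nsat:
        if config.continuous_nsat:
            n_steps = np.stack(
                [r.normal(0.0, config.nsat_proposal_sd, size=n_iter) for r in rngs]
            )
        else:
            mag = np.stack(
                [r.integers(1, config.nsat_step_max + 1, size=n_iter) for r in rngs]
            )
            sign = np.stack([r.choice([-1, 1], size=n_iter) for r in rngs])
            n_steps = (mag * sign).astype(float)
        log_u_n = np.log(np.stack([r.random(size=n_iter) for r in rngs]))

    # initialisation: p_j from the Beta prior, n_sat uniform over support,
    # retried until the joint log-posterior is finite
    p = np.empty((C, m))
    n = np.empty((C, 1))
    for c, r in enumerate(rngs):
        for attempt in range(config.max_init_retries + 1):
            p_c = r.beta(priors.p_alpha, priors.p_beta, size=m)
            if sample_nsat:
                n_c = float(r.integers(priors.n_sat_lower, priors.n_sat_upper + 1))
            else:
                n_c = float(n_sat_fixed)
            terms = _loglik_terms(p_c[None, :], f_l, np.array([[n_c]]), V, V_plus)
            if np.all(np.isfinite(terms)):
                p[c], n[c, 0] = p_c, n_c
                break
        else:
            raise RuntimeError(
                "could not find a finite-posterior initial state "
                f"after {config.max_init_retries} retries"
            )

    ll_terms = _loglik_terms(p, f_l, n, V, V_plus)  # (C, m), current state

    a, b = priors.p_alpha, priors.p_beta
    # Beta prior density on the logit scale includes the Jacobian p(1-p)
    log_prior_p = a * np.log(p) + b * np.log1p(-p)

    keep_p = np.empty((C, config.n_draws, m))
    keep_n = np.empty((C, config.n_draws)) if sample_nsat else None
    acc_p = 0.0
    acc_n = 0.0

    lo, hi = priors.n_sat_lower, priors.n_sat_upper
    for t in range(n_iter):
        # --- parallel logit-random-walk update of all p_j
        x_new = logit(p) + eps[:, t, :]
        p_new = expit(x_new)
        with np.errstate(divide="ignore"):
            lp_new = a * np.log(p_new) + b * np.log1p(-p_new)
        ll_new = _loglik_terms(p_new, f_l, n, V, V_plus)
        with np.errstate(invalid="ignore"):
            delta = (ll_new + lp_new) - (ll_terms + log_prior_p)
        accept = log_u_p[:, t, :] < delta
        p = np.where(accept, p_new, p)
        ll_terms = np.where(accept, ll_new, ll_terms)
        log_prior_p = np.where(accept, lp_new, log_prior_p)
        acc_p += accept.mean()

        # --- integer (or relaxed real) random-walk update of n_sat
        if sample_nsat:
            n_new = n + n_steps[:, t, None]
            in_support = (n_new[:, 0] >= lo) & (n_new[:, 0] <= hi)
            ll_new = _loglik_terms(p, f_l, n_new, V, V_plus)
            delta_n = ll_new.sum(axis=1) - ll_terms.sum(axis=1)
            accept_n = in_support & (log_u_n[:, t] < delta_n)
            n = np.where(accept_n[:, None], n_new, n)
            ll_terms = np.where(accept_n[:, None], ll_new, ll_terms)
            acc_n += accept_n.mean()

        k = t - config.n_burnin
        if k >= 0:
            keep_p[:, k, :] = p
            if sample_nsat:
                keep_n[:, k] = n[:, 0]

    draws: dict[str, np.ndarray] = {f"p[{j}]": keep_p[:, :, j] for j in range(m)}
    if sample_nsat:
        draws["n_sat"] = keep_n

    result = PosteriorResult(draws=draws)
    for name, arr in draws.items():
        is_int = name == "n_sat" and not config.continuous_nsat
        result.map[name] = map_estimate(arr, integer=is_int)
        result.ci[name] = credible_interval(arr)
        result.rhat[name] = gelman_rubin(arr)
        result.autocorr[name] = _lag1_autocorr(arr)
    result.accept_rates["p"] = acc_p / n_iter
    if sample_nsat:
        result.accept_rates["n_sat"] = acc_n / n_iter
    return result


# ---------------------------------------------------------------------------
# public fitting API


def _unpack(scores: Sequence[BinaryScoreSet]):
    if len(scores) == 0:
        raise ValueError("need at least one score set")
    f_l = np.array([s.condition.f_l for s in scores], dtype=float)
    V = np.array([s.V for s in scores], dtype=float)
    V_plus = np.array([s.V_plus for s in scores], dtype=float)
    return f_l, V, V_plus


def fit_joint(
    scores: Sequence[BinaryScoreSet],
    priors: PriorSpec | None = None,
    config: SamplerConfig | None = None,
    n_sat_fixed: int | None = None,
) -> PosteriorResult:
    """Fit the joint model: m binding probabilities plus one shared n_sat.

    All ``p_j`` are estimated simultaneously; a single ``n_sat`` is shared
    over all samples, so the m+1 parameters are coupled only through it.
    Identifiability of ``n_sat`` in practice rests on at least one sample
    being near saturation (p close to 1).  With ``n_sat_fixed`` the
    saturation count is held constant and only the m binding probabilities
    are sampled (their posteriors are then mutually independent).
    """
    priors = priors or PriorSpec()
    config = config or SamplerConfig()
    f_l, V, V_plus = _unpack(scores)
    if n_sat_fixed is not None and (n_sat_fixed < 1 or int(n_sat_fixed) != n_sat_fixed):
        raise ValueError(f"n_sat_fixed must be a positive integer, got {n_sat_fixed}")
    return _run_mwg(
        f_l, V, V_plus, priors, config,
        n_sat_fixed=None if n_sat_fixed is None else int(n_sat_fixed),
    )


def fit_single(
    score: BinaryScoreSet,
    n_sat_fixed: int,
    priors: PriorSpec | None = None,
    config: SamplerConfig | None = None,
) -> PosteriorResult:
    """Fit a single sample with the saturation count held fixed.

    The binding probability p is then the only parameter estimated; this is
    the configuration used throughout the design-verification simulations.
    """
    if n_sat_fixed < 1 or int(n_sat_fixed) != n_sat_fixed:
        raise ValueError(f"n_sat_fixed must be a positive integer, got {n_sat_fixed}")
    priors = priors or PriorSpec()
    config = config or SamplerConfig()
    f_l, V, V_plus = _unpack([score])
    return _run_mwg(f_l, V, V_plus, priors, config, n_sat_fixed=int(n_sat_fixed))


def grid_posterior_p(
    score: BinaryScoreSet,
    n_sat_fixed: int,
    priors: PriorSpec | None = None,
    n_points: int = 2001,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalised posterior density of p on a uniform grid (quadrature).

    Independent of the MCMC path; serves as an exact (to grid resolution)
    reference for the single-sample posterior.
    """
    priors = priors or PriorSpec()
    grid = np.linspace(0.0, 1.0, n_points)
    q = _q_of(grid[None, :], np.array([score.condition.f_l]), float(n_sat_fixed))[0]
    loglik = bernoulli_log_likelihood(score.V, score.V_plus, q)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_prior = (priors.p_alpha - 1.0) * np.log(grid) + (
            priors.p_beta - 1.0
        ) * np.log1p(-grid)
    log_prior[np.isnan(log_prior)] = 0.0  # 0 * log(0) at the edges under a flat prior
    log_post = np.asarray(loglik) + log_prior
    log_post -= np.max(log_post[np.isfinite(log_post)])
    dens = np.exp(log_post)
    dens[~np.isfinite(dens)] = 0.0
    dens /= np.trapezoid(dens, grid)
    return grid, dens
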