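"""Posterior computation for random-intercept Poisson models.

The random intercepts (one per grouping unit, here per trial) are
integrated out of the likelihood with adaptive Gauss-Hermite quadrature:
for each group the integrand is re-centered at its conditional mode
(found by a short Newton iteration — the integrand is log-concave) and
scaled by the conditional curvature, which keeps a modest node count
accurate even for large counts.  Sampling over the remaining low-
dimensional parameter vector (fixed effects + random-intercept SD) uses
random-walk Metropolis with a Laplace-approximation proposal covariance
and Robbins-Monro scale adaptation during warm-up, vectorised across
chains.  The SD is parameterised as tau = |s| with s unconstrained
(folded parameterisation), which turns a Normal prior on s into a
half-Normal prior on tau and avoids a hard boundary at zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import logsumexp

_LINPRED_CAP = 50.0  # exp cap: keeps bad proposals finite, posterior ~ -inf there
_TAU_FLOOR = 1e-6


@dataclass
class GroupedPoissonData:
    """Counts with offsets, fixed-effect design and group index."""

    y: np.ndarray  # (n,)
    offset: np.ndarray  # (n,) log scale
    X: np.ndarray  # (n, p)
    groups: np.ndarray  # (n,) int in [0, n_groups)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.offset = np.asarray(self.offset, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        self.groups = np.asarray(self.groups, dtype=int)
        self.n_groups = int(self.groups.max()) + 1 if len(self.groups) else 0


def _group_sum(values: np.ndarray, groups: np.ndarray, n_groups: int) -> np.ndarray:
    """Sum (n, c) rows into (n_groups, c) by group index."""
    out = np.zeros((n_groups, values.shape[1]))
    np.add.at(out, groups, values)
    return out


def log_marginal_likelihood(
    data: GroupedPoissonData,
    beta: np.ndarray,
    tau: np.ndarray,
    n_nodes: int = 20,
    newton_iter: int = 30,
) -> np.ndarray:
    """Log marginal Poisson-lognormal likelihood for a batch of parameter
    vectors.  ``beta`` is (c, p), ``tau`` is (c,); returns (c,).

    Constants (log y!) are dropped.
    """
    beta = np.atleast_2d(beta)
    tau = np.atleast_1d(np.asarray(tau, dtype=float))
    c = beta.shape[0]
    G = data.n_groups
    eta = data.offset[:, None] + data.X @ beta.T  # (n, c)
    y = data.y[:, None]

    tau_eff = np.maximum(np.abs(tau), _TAU_FLOOR)
    degenerate = np.abs(tau) < _TAU_FLOOR
    inv_tau2 = 1.0 / tau_eff**2  # (c,)

    # Newton for the conditional mode of u_g given (beta, tau)
    u = np.zeros((G, c))
    for _ in range(newton_iter):
        lin = np.clip(eta + u[data.groups], -_LINPRED_CAP, _LINPRED_CAP)
        mu = np.exp(lin)
        grad = _group_sum(y - mu, data.groups, G) - u * inv_tau2
        hess = -_group_sum(mu, data.groups, G) - inv_tau2
        step = grad / hess
        step = np.clip(step, -5.0, 5.0)
        u_new = u - step
        if np.max(np.abs(u_new - u)) < 1e-10:
            u = u_new
            break
        u = u_new

    lin = np.clip(eta + u[data.groups], -_LINPRED_CAP, _LINPRED_CAP)
    mu = np.exp(lin)
    hess = -_group_sum(mu, data.groups, G) - inv_tau2
    s = 1.0 / np.sqrt(-hess)  # (G, c) conditional SD at the mode

    z, w = np.polynomial.hermite.hermgauss(n_nodes)
    log_w = np.log(w)
    # adaptive nodes u_gk = mode + sqrt(2) s z_k
    u_nodes = u[..., None] + math.sqrt(2.0) * s[..., None] * z  # (G, c, K)
    lin_nodes = np.clip(
        eta[..., None] + u_nodes[data.groups], -_LINPRED_CAP, _LINPRED_CAP
    )  # (n, c, K)
    point = y[..., None] * lin_nodes - np.exp(lin_nodes)
    term = _group_sum(point.reshape(len(data.y), -1), data.groups, G).reshape(
        G, c, n_nodes
    )
    term = term - 0.5 * u_nodes**2 * inv_tau2[None, :, None]
    term = term - (np.log(tau_eff) + 0.5 * math.log(2.0 * math.pi))[None, :, None]
    log_int = (
        logsumexp(log_w + z**2 + term, axis=2)
        + 0.5 * math.log(2.0)
        + np.log(s)
    )  # (G, c)
    ll = log_int.sum(axis=0)

    if np.any(degenerate):
        # tau -> 0: plain Poisson likelihood at u = 0
        plain = (y * np.clip(eta, None, _LINPRED_CAP)
                 - np.exp(np.clip(eta, None, _LINPRED_CAP))).sum(axis=0)
        ll = np.where(degenerate, plain, ll)
    return ll


@dataclass
class PriorSpec:
    """Weakly informative default priors for the hierarchical models."""

    beta_scale: float = 2.5  # Normal(0, beta_scale) on non-intercept effects
    intercept_scale: float = 5.0  # Normal(0, intercept_scale) on the intercept
    tau_scale: float = 1.0  # half-Normal(0, tau_scale) on the intercept SD
    flat: bool = False  # improper flat priors (oracle comparisons only)


def make_log_posterior(
    data: GroupedPoissonData,
    prior: PriorSpec,
    tau_fixed: float | None = None,
    n_nodes: int = 20,
):
    """Vectorised log-posterior over theta = (beta, s) with tau = |s|.

    When ``tau_fixed`` is given, theta = beta only.
    """
    p = data.X.shape[1]

    def log_posterior(theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        beta = theta[:, :p]
        if tau_fixed is not None:
            tau = np.full(theta.shape[0], float(tau_fixed))
        else:
            tau = np.abs(theta[:, p])
        ll = log_marginal_likelihood(data, beta, tau, n_nodes=n_nodes)
        if prior.flat:
            return ll
        lp = -0.5 * (beta[:, 0] / prior.intercept_scale) ** 2
        if p > 1:
            lp = lp - 0.5 * np.sum((beta[:, 1:] / prior.beta_scale) ** 2, axis=1)
        if tau_fixed is None:
            lp = lp - 0.5 * (theta[:, p] / prior.tau_scale) ** 2
        return ll + lp

    return log_posterior


def find_map(
    log_posterior,
    x0: np.ndarray,
    maxiter: int = 500,
) -> tuple[np.ndarray, np.ndarray]:
    """MAP point and Laplace covariance (finite-difference Hessian)."""

    def neg(theta: np.ndarray) -> float:
        val = log_posterior(theta[None, :])[0]
        return -val if np.isfinite(val) else 1e12

    res = optimize.minimize(neg, x0, method="Nelder-Mead",
                            options={"maxiter": maxiter * 10, "xatol": 1e-6,
                                     "fatol": 1e-8})
    res = optimize.minimize(neg, res.x, method="BFGS",
                            options={"maxiter": maxiter, "gtol": 1e-6})
    x_map = res.x
    d = len(x_map)
    h = 1e-4 * np.maximum(1.0, np.abs(x_map))
    H = np.zeros((d, d))
    f0 = neg(x_map)
    for i in range(d):
        for j in range(i, d):
            ei = np.zeros(d); ei[i] = h[i]
            ej = np.zeros(d); ej[j] = h[j]
            if i == j:
                H[i, i] = (neg(x_map + ei) - 2 * f0 + neg(x_map - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    neg(x_map + ei + ej) - neg(x_map + ei) - neg(x_map + ej) + f0
                ) / (h[i] * h[j])
    # Laplace covariance; repair non-PD Hessians by eigenvalue flooring
    evals, evecs = np.linalg.eigh(H)
    evals = np.clip(evals, 1e-6, None)
    cov = (evecs / evals) @ evecs.T
    return x_map, cov


def adaptive_metropolis(
    log_posterior,
    x0: np.ndarray,
    cov0: np.ndarray,
    n_chains: int = 4,
    n_warmup: int = 1000,
    n_draws: int = 1000,
    seed: int | None = None,
    target_accept: float = 0.3,
) -> tuple[np.ndarray, float]:
    """Random-walk Metropolis, vectorised across chains.

    Warm-up adapts a per-chain proposal scale (Robbins-Monro towards
    ``target_accept``) and refreshes the proposal covariance from the
    first half of warm-up.  Returns draws of shape (n_chains, n_draws, d)
    and the post-warm-up acceptance rate.
    """
    rng = np.random.default_rng(seed)
    d = len(x0)
    chol = np.linalg.cholesky(cov0 + 1e-10 * np.eye(d))
    x = x0 + 0.5 * (rng.standard_normal((n_chains, d)) @ chol.T)
    lp = log_posterior(x)
    log_scale = np.full(n_chains, math.log(2.38 / math.sqrt(d)))

    draws = np.empty((n_chains, n_draws, d))
    history = np.empty((n_chains, n_warmup, d))
    n_accept = 0
    refresh_at = n_warmup // 2

    for t in range(n_warmup + n_draws):
        step = rng.standard_normal((n_chains, d)) @ chol.T
        prop = x + np.exp(log_scale)[:, None] * step
        lp_prop = log_posterior(prop)
        log_u = np.log(rng.random(n_chains))
        accept = log_u < (lp_prop - lp)
        x = np.where(accept[:, None], prop, x)
        lp = np.where(accept, lp_prop, lp)

        if t < n_warmup:
            history[:, t] = x
            gamma = (t + 1) ** -0.6
            log_scale += gamma * (accept.astype(float) - target_accept)
            if t == refresh_at and refresh_at >= 50:
                pooled = history[:, refresh_at // 2: refresh_at].reshape(-1, d)
                emp = np.cov(pooled.T)
                emp = np.atleast_2d(emp) + 1e-10 * np.eye(d)
                try:
                    chol = np.linalg.cholesky(emp)
                except np.linalg.LinAlgError:
                    pass
        else:
            draws[:, t - n_warmup] = x
            n_accept += int(accept.sum())

    accept_rate = n_accept / (n_chains * n_draws)
    return draws, accept_rate
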