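"""Posterior sampling for Bayesian logistic regression.

Model: y_i ~ Bernoulli(sigmoid(beta0 + x_i·beta)) with independent
Normal(0, prior_sd²) priors on the intercept and every coefficient.

Sampler: Hamiltonian Monte Carlo preconditioned by the Laplace
approximation.  The posterior mode is found with L-BFGS, the Hessian at the
mode is Cholesky-factored, and HMC runs in the whitened space where the
posterior is approximately standard normal — a log-concave posterior then
mixes in a handful of leapfrog steps.  Step size is tuned by dual averaging
during warmup; convergence is checked with the split-chain potential scale
reduction factor (R-hat).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.optimize import minimize
from scipy.special import expit, log_expit


class SamplingError(RuntimeError):
    pass


@dataclass(frozen=True)
class SamplerConfig:
    """HMC settings.  Defaults yield 1000 post-warmup draws (2 × 500)."""

    chains: int = 2
    warmup: int = 200
    draws: int = 500
    leapfrog: int = 6
    target_accept: float = 0.8
    seed: int = 0
    rhat_limit: float = 1.05


@dataclass
class PosteriorFit:
    """Posterior draws for (intercept, coefficients), stacked chains."""

    samples: np.ndarray       # (chains * draws, p + 1); column 0 = intercept
    chains: int
    map_estimate: np.ndarray  # (p + 1,)
    rhat: np.ndarray          # (p + 1,)
    accept_rate: float
    converged: bool

    @property
    def mean(self) -> np.ndarray:
        return self.samples.mean(axis=0)

    @property
    def sd(self) -> np.ndarray:
        return self.samples.std(axis=0, ddof=1)


def _neg_logpost_and_grad(theta, X, y, inv_var):
    z = X @ theta
    # log-likelihood: sum y*z - log(1 + e^z)  (log_expit is numerically safe)
    ll = float(np.dot(y, z) + log_expit(-z).sum())
    lp = ll - 0.5 * inv_var * float(theta @ theta)
    p = expit(z)
    grad = X.T @ (y - p) - inv_var * theta
    return -lp, -grad


def split_rhat(samples: np.ndarray, chains: int) -> np.ndarray:
    """Split-chain potential scale reduction factor, per dimension.

    ``samples`` is (chains*draws, dim) with chains stacked contiguously.
    Each chain is split in half, giving 2*chains segments.
    """
    total, dim = samples.shape
    draws = total // chains
    half = draws // 2
    segs = []
    for c in range(chains):
        block = samples[c * draws : (c + 1) * draws]
        segs.append(block[:half])
        segs.append(block[half : 2 * half])
    arr = np.stack(segs)  # (2*chains, half, dim)
    m, n = arr.shape[0], arr.shape[1]
    seg_means = arr.mean(axis=1)
    seg_vars = arr.var(axis=1, ddof=1)
    W = seg_vars.mean(axis=0)
    B = n * seg_means.var(axis=0, ddof=1)
    var_plus = (n - 1) / n * W + B / n
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_plus / W)
    return np.where(W > 0, rhat, 1.0)


def sample_logistic_posterior(
    X: np.ndarray,
    y: np.ndarray,
    prior_sd: float = 1.0,
    cfg: SamplerConfig = SamplerConfig(),
    add_intercept: bool = True,
) -> PosteriorFit:
    """Draw from the posterior of a Bayesian logistic regression.

    X is (n, p); an intercept column is prepended unless ``add_intercept``
    is false.  Returns stacked chains of (p+1)-dimensional draws.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise SamplingError("X must be (n, p) with one label per row")
    if not np.all(np.isfinite(X)):
        raise SamplingError("X contains non-finite values")
    classes = np.unique(y)
    if not np.all(np.isin(classes, (0.0, 1.0))) or len(classes) < 2:
        raise SamplingError("y must contain both classes, coded 0/1")
    if prior_sd <= 0:
        raise SamplingError("prior_sd must be positive")
    if add_intercept:
        X = np.hstack([np.ones((X.shape[0], 1)), X])
    dim = X.shape[1]
    inv_var = 1.0 / prior_sd**2

    # --- MAP and Laplace preconditioner -----------------------------------
    res = minimize(
        _neg_logpost_and_grad,
        np.zeros(dim),
        args=(X, y, inv_var),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 500, "gtol": 1e-6},
    )
    theta_map = res.x
    p_map = expit(X @ theta_map)
    w = p_map * (1.0 - p_map)
    H = (X.T * w) @ X
    H[np.diag_indices(dim)] += inv_var
    L = np.linalg.cholesky(H)  # H = L Lᵀ; whitening theta = map + L^{-T} z

    X32 = X.astype(np.float32)  # fast matvecs inside the trajectory loop
    y64 = y

    def logpost_grad_z(zvec):
        theta = theta_map + solve_triangular(L, zvec, lower=True, trans="T")
        lin = (X32 @ theta.astype(np.float32)).astype(np.float64)
        lp = float(np.dot(y64, lin) + log_expit(-lin).sum()) - 0.5 * inv_var * float(theta @ theta)
        grad_theta = (X32.T @ (y64 - expit(lin)).astype(np.float32)).astype(np.float64) - inv_var * theta
        grad_z = solve_triangular(L, grad_theta, lower=True)
        return lp, grad_z

    rng = np.random.default_rng(cfg.seed)
    all_draws = np.empty((cfg.chains * cfg.draws, dim))
    n_accept = 0
    n_prop = 0
    for chain in range(cfg.chains):
        z = rng.standard_normal(dim) * 0.1
        lp, grad = logpost_grad_z(z)
        # dual averaging (Nesterov) for the step size during warmup
        eps = 0.25
        mu = np.log(10 * eps)
        log_eps_bar, h_bar = 0.0, 0.0
        gamma, t0, kappa = 0.05, 10.0, 0.75
        for it in range(cfg.warmup + cfg.draws):
            r = rng.standard_normal(dim)
            # step-size jitter breaks trajectories that resonate with the
            # (near-Gaussian) whitened posterior
            eps_it = eps * (0.8 + 0.4 * rng.random())
            z_new, grad_new = z, grad
            lp_new = lp
            r_new = r + 0.5 * eps_it * grad_new
            for _step in range(cfg.leapfrog):
                z_new = z_new + eps_it * r_new
                lp_new, grad_new = logpost_grad_z(z_new)
                if _step < cfg.leapfrog - 1:
                    r_new = r_new + eps_it * grad_new
            r_new = r_new + 0.5 * eps_it * grad_new
            log_accept = (lp_new - 0.5 * r_new @ r_new) - (lp - 0.5 * r @ r)
            if not np.isfinite(log_accept):
                log_accept = -np.inf
            alpha = min(1.0, np.exp(min(0.0, log_accept)))
            if rng.random() < alpha:
                z, lp, grad = z_new, lp_new, grad_new
            if it < cfg.warmup:
                h_bar = (1 - 1 / (it + 1 + t0)) * h_bar + (cfg.target_accept - alpha) / (it + 1 + t0)
                log_eps = mu - np.sqrt(it + 1) / gamma * h_bar
                eta = (it + 1) ** (-kappa)
                log_eps_bar = eta * log_eps + (1 - eta) * log_eps_bar
                eps = float(np.exp(log_eps))
                if it == cfg.warmup - 1:
                    eps = float(np.exp(log_eps_bar))
            else:
                n_prop += 1
                n_accept += alpha
                theta = theta_map + solve_triangular(L, z, lower=True, trans="T")
                all_draws[chain * cfg.draws + (it - cfg.warmup)] = theta

    rhat = split_rhat(all_draws, cfg.chains)
    converged = bool(np.nanmax(rhat) < cfg.rhat_limit)
    if not converged:
        warnings.warn(
            f"posterior sampling may not have converged: max split R-hat "
            f"{np.nanmax(rhat):.3f} >= {cfg.rhat_limit}",
            RuntimeWarning,
            stacklevel=2,
        )
    return PosteriorFit(
        samples=all_draws,
        chains=cfg.chains,
        map_estimate=theta_map,
        rhat=rhat,
        accept_rate=float(n_accept / max(n_prop, 1)),
        converged=converged,
    )


def laplace_covariance(X: np.ndarray, theta: np.ndarray, prior_sd: float) -> np.ndarray:
    """Inverse Hessian of the negative log posterior at ``theta`` (with
    intercept column already present in X)."""
    p = expit(X @ theta)
    w = p * (1 - p)
    H = (X.T * w) @ X
    H[np.diag_indices(len(theta))] += 1.0 / prior_sd**2
    return cho_solve(cho_factor(H), np.eye(len(theta)))
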