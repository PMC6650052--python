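"""Empirical-Bayes Laplace inference for latent-Gaussian Poisson models.

The model class is

    y_i ~ Poisson(E_i * exp(eta_i)),
    eta = F b + sum_k Z_k u_k + eps + offset

with Gaussian fixed effects ``b`` (known small precision), Gaussian
Markov random-field blocks ``u_k`` (RW1 over years, intrinsic CAR over
counties) and iid overdispersion ``eps`` (one per observation). The
random-term precisions ``tau_k = exp(theta_k)`` carry logGamma(a, b)
hyperpriors on ``theta_k``. Inference:

1. for candidate hyperparameters, find the latent posterior mode by
   damped Newton iteration; the overdispersion coordinates are
   eliminated exactly at each step (their Hessian block is diagonal),
   leaving a small dense symmetric system over the structured effects;
2. maximise the Laplace approximation of the log marginal likelihood
   over the 2-4 log-precisions (Nelder-Mead);
3. report the Gaussian approximation at the optimum, with sum-to-zero
   (and orthogonality-to-trend) constraints applied by conditioning by
   kriging.

This is the latent-Gaussian-model strategy behind nested Laplace
approximation software, reduced to its empirical-Bayes core; posterior
hyperparameter uncertainty is not propagated into the latent marginals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

__all__ = ["LatentBlock", "LaplaceFitResult", "fit_latent_gaussian_poisson"]

_ETA_CLIP = 35.0  # log-rate clip guarding exp overflow far from the mode


@dataclass
class LatentBlock:
    """One Gaussian random-effect block of the latent field.

    Parameters
    ----------
    name : str
        Block label ("nu", "alpha", "beta", "eps").
    Z : scipy.sparse matrix, shape (n_obs, size) or None
        Incidence in the linear predictor; None marks the iid
        overdispersion block (implicit identity incidence).
    R : scipy.sparse matrix, shape (size, size)
        Prior structure; prior precision is ``exp(theta) * R``.
    rank : int
        Rank of ``R`` (generalised log-determinant bookkeeping).
    constraints : ndarray, shape (k, size), optional
        Rows c imposing ``c @ u = 0``.
    """

    name: str
    Z: sp.spmatrix | None
    R: sp.spmatrix
    rank: int
    constraints: np.ndarray | None = None

    @property
    def size(self) -> int:
        return self.R.shape[0]


@dataclass
class LaplaceFitResult:
    """Gaussian approximation to the latent posterior at the hyperparameter optimum.

    ``mean`` stacks [fixed effects, structured blocks..., eps];
    ``marginal_sd`` is exact for every structured coordinate and NaN for
    the overdispersion field (not needed downstream).
    """

    mean: np.ndarray
    fixed_names: list[str]
    slices: dict[str, slice]
    marginal_sd: np.ndarray
    log_precisions: dict[str, float]
    log_marginal_likelihood: float
    converged: bool
    message: str
    n_newton: int
    n_hyper_evals: int
    cov_structured: np.ndarray | None = field(repr=False, default=None)

    def marginal_variance(self, idx: int) -> float:
        """Constrained posterior variance of one structured coordinate."""
        if self.cov_structured is None or idx >= self.cov_structured.shape[0]:
            raise IndexError("variance available only for structured coordinates")
        return float(self.cov_structured[idx, idx])


def _mode_newton(y, log_e, F_s, Qp_s, tau_eps, has_eps, u0, eps0,
                 max_iter=60, tol=1e-9):
    """Damped Newton for the posterior mode.

    ``F_s`` is the sparse (n_obs x m) design of fixed + structured
    effects, ``Qp_s`` their prior precision (dense m x m), ``tau_eps``
    the overdispersion precision. Returns the mode, the reduced
    negative Hessian ``M`` (Cholesky factor), the diagonal ``D`` of the
    eps block, and bookkeeping.
    """
    u, eps = u0.copy(), eps0.copy()
    # dense BLAS beats sparse products when the structured dimension is
    # small (models without county fields)
    dense = F_s.shape[1] <= 64
    Fd = F_s.toarray() if dense else None
    Ft = None if dense else F_s.T.tocsr()

    def matvec(v):
        return Fd @ v if dense else F_s @ v

    def rmatvec(v):
        return Fd.T @ v if dense else Ft @ v

    def weighted_gram(w):
        if dense:
            return (Fd * w[:, None]).T @ Fd
        return (Ft @ sp.diags(w) @ F_s).toarray()

    def objective(u, eps):
        eta = np.clip(matvec(u) + eps + log_e, -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        ll = float(y @ eta - mu.sum())
        pen = 0.5 * float(u @ (Qp_s @ u))
        if has_eps:
            pen += 0.5 * tau_eps * float(eps @ eps)
        return ll - pen, mu

    obj, mu = objective(u, eps)
    ok = False
    cho_M = D = None
    it = 0
    for it in range(1, max_iter + 1):
        r = y - mu
        g_u = rmatvec(r) - Qp_s @ u
        if has_eps:
            g_e = r - tau_eps * eps
            D = mu + tau_eps
            w_t = mu * tau_eps / D
            M = Qp_s + weighted_gram(w_t)
            rhs = g_u - rmatvec(mu / D * g_e)
            cho_M = cho_factor(M)
            du = cho_solve(cho_M, rhs)
            de = (g_e - mu * matvec(du)) / D
        else:
            M = Qp_s + weighted_gram(mu)
            cho_M = cho_factor(M)
            du = cho_solve(cho_M, g_u)
            de = np.zeros_like(eps)
        t = 1.0
        for _ in range(40):
            obj_new, mu_new = objective(u + t * du, eps + t * de)
            if obj_new >= obj - 1e-10:
                break
            t *= 0.5
        u, eps = u + t * du, eps + t * de
        rel = abs(obj_new - obj) / (abs(obj) + 1.0)
        obj, mu = obj_new, mu_new
        gnorm = max(np.max(np.abs(g_u)), np.max(np.abs(g_e)) if has_eps else 0.0)
        if rel < tol and gnorm < 1e-5 * (1.0 + float(np.max(y))):
            ok = True
            break
    # refresh curvature at the mode
    if has_eps:
        D = mu + tau_eps
        w_t = mu * tau_eps / D
        M = Qp_s + weighted_gram(w_t)
    else:
        D = mu
        M = Qp_s + weighted_gram(mu)
    cho_M = cho_factor(M)
    eta = np.clip(matvec(u) + eps + log_e, -_ETA_CLIP, _ETA_CLIP)
    loglik = float(y @ eta - np.exp(eta).sum())
    if not ok:
        g_u = rmatvec(y - mu) - Qp_s @ u
        ok = np.max(np.abs(g_u)) < 1e-3 * (1.0 + float(np.max(y)))
    return u, eps, mu, cho_M, D, obj, loglik, ok, it


def fit_latent_gaussian_poisson(
    y: np.ndarray,
    exposure: np.ndarray,
    F: np.ndarray,
    fixed_names: list[str],
    blocks: list[LatentBlock],
    *,
    fe_prec: float = 0.001,
    hyper_a: float = 1.0,
    hyper_b: float = 0.001,
    init_log_precisions: np.ndarray | None = None,
    optimizer_maxiter: int = 80,
    optimizer_xatol: float = 0.05,
    newton_maxiter: int = 60,
    sd_for: str = "structured",
) -> LaplaceFitResult:
    """Fit the latent-Gaussian Poisson model by empirical-Bayes Laplace.

    Parameters
    ----------
    y, exposure : arrays, shape (n_obs,)
        Death counts and person-time offsets (offset enters as log).
    F : array, shape (n_obs, p)
        Fixed-effect design (intercept, year, PM, covariates).
    blocks : list of LatentBlock
        Structured random blocks plus at most one iid "eps" block
        (identified by ``Z is None``), one log-precision each.
    """
    y = np.asarray(y, dtype=float)
    exposure = np.asarray(exposure, dtype=float)
    if np.any(exposure <= 0):
        raise ValueError("non-positive exposure; merge small counties first")
    n = len(y)
    log_e = np.log(exposure)
    p = F.shape[1]

    structured = [b for b in blocks if b.Z is not None]
    eps_blocks = [b for b in blocks if b.Z is None]
    if len(eps_blocks) > 1:
        raise ValueError("at most one iid overdispersion block")
    has_eps = bool(eps_blocks)

    F_s = sp.hstack([sp.csr_matrix(F)] + [b.Z for b in structured], format="csr")
    m = F_s.shape[1]

    slices: dict[str, slice] = {"fixed": slice(0, p)}
    off = p
    for blk in structured:
        slices[blk.name] = slice(off, off + blk.size)
        off += blk.size
    if has_eps:
        slices[eps_blocks[0].name] = slice(off, off + n)

    # Constraint rows over the structured coordinates. A quadratic soft
    # penalty kappa*(c@u)^2 is added to the prior: it regularises the
    # otherwise near-flat intercept-vs-field directions, and because a
    # Gaussian conditioned on c@u = 0 is unchanged by extra prior mass
    # along c, the exact kriging correction applied at the end still
    # yields the hard-constrained posterior.
    con_rows = []
    for blk in structured:
        if blk.constraints is not None and blk.constraints.size:
            for c in np.atleast_2d(blk.constraints):
                full = np.zeros(m)
                full[slices[blk.name]] = c
                con_rows.append(full)
    penalty = np.zeros((m, m))
    for c in con_rows:
        kappa = (1.0 + float(y.sum())) / float(c @ c)
        penalty += kappa * np.outer(c, c)

    def prior_structured(theta_struct: np.ndarray) -> np.ndarray:
        Qp = penalty.copy()
        Qp[:p, :p] += fe_prec * np.eye(p)
        for blk, th in zip(structured, theta_struct):
            sl = slices[blk.name]
            Qp[sl, sl] += np.exp(th) * blk.R.toarray()
        return Qp

    # hyperparameter order: structured blocks, then eps
    order = structured + eps_blocks
    n_theta = len(order)
    theta0 = (np.full(n_theta, np.log(100.0))
              if init_log_precisions is None
              else np.asarray(init_log_precisions, dtype=float))
    if theta0.shape != (n_theta,):
        raise ValueError(f"expected {n_theta} initial log-precisions")

    state = {"u": np.zeros(m), "eps": np.zeros(n), "evals": 0}

    def split_theta(theta):
        th_s = theta[: len(structured)]
        tau_e = float(np.exp(theta[len(structured)])) if has_eps else 0.0
        return th_s, tau_e

    def neg_logml(theta):
        state["evals"] += 1
        th_s, tau_e = split_theta(theta)
        Qp_s = prior_structured(th_s)
        u, eps, mu, cho_M, D, obj, loglik, ok, _ = _mode_newton(
            y, log_e, F_s, Qp_s, tau_e, has_eps, state["u"], state["eps"],
            max_iter=newton_maxiter,
        )
        state["u"], state["eps"] = u, eps
        logdet_M = 2.0 * float(np.sum(np.log(np.diag(cho_M[0]))))
        logdet_H = logdet_M + (float(np.sum(np.log(D))) if has_eps else 0.0)
        logdet_Qp = float(sum(blk.rank * th for blk, th in zip(order, theta)))
        hyper = float(np.sum(hyper_a * theta - hyper_b * np.exp(theta)))
        return -(obj + 0.5 * logdet_Qp - 0.5 * logdet_H + hyper)

    if n_theta > 0:
        opt = minimize(
            neg_logml, theta0, method="Nelder-Mead",
            options={"maxiter": optimizer_maxiter, "xatol": optimizer_xatol,
                     "fatol": 0.05, "adaptive": True},
        )
        theta_opt = opt.x
        logml = -float(opt.fun)
    else:
        theta_opt = theta0
        logml = -neg_logml(theta_opt)

    th_s, tau_e = split_theta(theta_opt)
    Qp_s = prior_structured(th_s)
    u, eps, mu, cho_M, D, obj, loglik, newton_ok, n_it = _mode_newton(
        y, log_e, F_s, Qp_s, tau_e, has_eps, state["u"], state["eps"],
        max_iter=newton_maxiter, tol=1e-11,
    )

    # covariance of the structured coordinates: (H^-1)_ss = M^-1
    cov = cho_solve(cho_M, np.eye(m))
    cov = 0.5 * (cov + cov.T)

    # hard constraints on structured blocks by conditioning by kriging
    if con_rows:
        C = np.vstack(con_rows)
        V = cov @ C.T
        S = C @ V
        Sinv = np.linalg.inv(S)
        u = u - V @ (Sinv @ (C @ u))
        cov = cov - V @ Sinv @ V.T

    mean = np.concatenate([u, eps]) if has_eps else u
    sds = np.full(mean.shape, np.nan)
    if sd_for != "none":
        sds[:m] = np.sqrt(np.maximum(np.diag(cov), 0.0))

    return LaplaceFitResult(
        mean=mean,
        fixed_names=list(fixed_names),
        slices=slices,
        marginal_sd=sds,
        log_precisions={blk.name: float(th) for blk, th in zip(order, theta_opt)},
        log_marginal_likelihood=logml,
        converged=bool(newton_ok),
        message="ok" if newton_ok else "mode finding did not fully converge",
        n_newton=n_it,
        n_hyper_evals=state["evals"],
        cov_structured=cov,
    )
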