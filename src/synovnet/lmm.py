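"""Profiled-REML linear mixed models with low-rank random effects.

Fits ``y = X beta + sum_j Z_j u_j + e`` with ``u_j ~ N(0, tau_j^2 I)`` and
``e ~ N(0, sigma^2 I)``.  Writing ``lambda_j = tau_j^2 / sigma^2``, the
marginal covariance is ``sigma^2 H`` with ``H = I + sum_j lambda_j Z_j Z_j'``.
``H`` is never formed: every quadratic form is evaluated through the Woodbury
identity, so the cost scales with the number of random-effect *levels*
(persons, proteins) rather than with the number of observations.  ``sigma^2``
is profiled out analytically and the remaining 1- or 2-dimensional REML (or
ML) surface over ``log lambda`` is optimised numerically.

This is the estimation backend for the hierarchical differential-abundance
model: a random intercept per person, optionally a second random effect
(protein-specific group deviation) for the partially pooled variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize, minimize_scalar

__all__ = ["LMMFit", "fit_lmm", "ConvergenceError"]

_LOG_LAMBDA_BOUNDS = (-23.0, 18.0)  # lambda in [1e-10, 6.6e7]


class ConvergenceError(RuntimeError):
    """Raised when the variance-ratio optimisation fails; carries the trace."""


@dataclass
class LMMFit:
    """Result of a profiled-REML fit.

    ``beta``/``cov_beta`` are the GLS fixed effects and their covariance at
    the estimated variance ratios; ``tau2`` holds one variance per
    random-effect block; ``blups`` the empirical best linear unbiased
    predictors of each block's levels.  ``mme_cov`` (filled on request) is the
    joint covariance of ``(beta_hat, u_hat - u)`` from Henderson's
    mixed-model equations, needed for prediction intervals on
    fixed-plus-random contrasts.
    """

    beta: np.ndarray
    cov_beta: np.ndarray
    names: list[str]
    sigma2: float
    tau2: np.ndarray
    lambdas: np.ndarray
    reml: bool
    converged: bool
    n_obs: int
    n_fixed: int
    deviance: float
    blups: list[np.ndarray] = field(default_factory=list)
    block_names: list[str] = field(default_factory=list)
    mme_cov: np.ndarray | None = None
    n_levels: list[int] = field(default_factory=list)
    opt_trace: list[tuple[np.ndarray, float]] = field(default_factory=list)


def _indicator(codes: np.ndarray, n_levels: int) -> sp.csr_matrix:
    n = codes.shape[0]
    keep = codes >= 0
    rows = np.nonzero(keep)[0]
    return sp.csr_matrix(
        (np.ones(rows.size), (rows, codes[keep])), shape=(n, n_levels)
    )


def fit_lmm(
    X: np.ndarray,
    y: np.ndarray,
    blocks: list[np.ndarray],
    names: list[str] | None = None,
    block_names: list[str] | None = None,
    reml: bool = True,
    compute_mme: bool = False,
    fixed_lambdas: np.ndarray | None = None,
) -> LMMFit:
    """Fit the mixed model by profiled (RE)ML.

    Parameters
    ----------
    X : (n, p) fixed-effect design, full rank.
    y : (n,) response.
    blocks : list of (n,) integer arrays; ``blocks[j][i]`` is the level of
        random-effect block ``j`` for observation ``i``, or ``-1`` when the
        observation does not load on that block (e.g. group-deviation effects
        that only apply to case samples).
    reml : profile the restricted likelihood (default) or the full ML.
    compute_mme : also build the mixed-model-equation covariance used for
        contrasts that mix fixed effects and BLUPs.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise np.linalg.LinAlgError("fixed-effect design matrix is rank deficient")

    levels = [int(b.max()) + 1 for b in blocks]
    Zs = [_indicator(np.asarray(b), q) for b, q in zip(blocks, levels)]
    Z = sp.hstack(Zs).tocsr() if Zs else sp.csr_matrix((n, 0))
    q = Z.shape[1]
    # block index of each Z column, to expand per-block lambdas
    col_block = np.concatenate(
        [np.full(qj, j) for j, qj in enumerate(levels)]
    ) if levels else np.zeros(0, dtype=int)

    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    ZtZ = (Z.T @ Z).toarray()
    ZtX = Z.T @ X
    Zty = Z.T @ y
    dof = n - p if reml else n

    def profile(log_lam: np.ndarray):
        lam = np.exp(np.clip(log_lam, *_LOG_LAMBDA_BOUNDS))
        dh = np.sqrt(lam[col_block]) if q else np.zeros(0)
        W = np.eye(q) + (dh[:, None] * ZtZ) * dh[None, :]
        cW = cho_factor(W, lower=True)
        logdet_w = 2.0 * float(np.sum(np.log(np.diag(cW[0]))))
        XtZD = (ZtX * dh[:, None]).T           # p x q
        ytZD = Zty * dh                        # q
        XtHX = XtX - XtZD @ cho_solve(cW, XtZD.T)
        XtHy = Xty - XtZD @ cho_solve(cW, ytZD)
        ytHy = yty - float(ytZD @ cho_solve(cW, ytZD))
        cX = cho_factor(XtHX, lower=True)
        beta = cho_solve(cX, XtHy)
        rss = max(ytHy - float(beta @ XtHy), 1e-300)
        sigma2 = rss / dof
        neg2 = dof * np.log(sigma2) + logdet_w
        if reml:
            neg2 += 2.0 * float(np.sum(np.log(np.diag(cX[0]))))
        return neg2, lam, beta, sigma2, XtHX, cW, dh

    trace: list[tuple[np.ndarray, float]] = []

    def objective(log_lam):
        val = profile(np.atleast_1d(np.asarray(log_lam, dtype=float)))[0]
        trace.append((np.atleast_1d(np.asarray(log_lam, float)).copy(), val))
        return val

    k = len(blocks)
    if fixed_lambdas is not None:
        # variance ratios held fixed (e.g. person variance pinned at 0 for
        # the OLS degenerate limit); no optimisation
        lam_fixed = np.clip(np.asarray(fixed_lambdas, float), 1e-300, None)
        log_opt = np.clip(np.log(lam_fixed), *_LOG_LAMBDA_BOUNDS)
        converged = True
    elif k == 0:
        log_opt = np.zeros(0)
        converged = True
    elif k == 1:
        res = minimize_scalar(
            lambda t: objective([t]), bounds=_LOG_LAMBDA_BOUNDS, method="bounded",
            options={"xatol": 1e-8},
        )
        log_opt = np.array([res.x])
        converged = bool(res.success)
    else:
        res = minimize(
            objective, np.zeros(k), method="Nelder-Mead",
            options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 2000},
        )
        log_opt = np.clip(res.x, *_LOG_LAMBDA_BOUNDS)
        converged = bool(res.success)
    if not converged:
        raise ConvergenceError(
            f"variance-ratio optimisation did not converge; trace: "
            f"{[(lv.tolist(), float(v)) for lv, v in trace[-5:]]}"
        )

    neg2, lam, beta, sigma2, XtHX, cW, dh = profile(log_opt)
    cov_beta = sigma2 * np.linalg.inv(XtHX)
    # BLUPs: u = D Z' H^{-1} r with r = y - X beta
    Ztr = Zty - ZtX @ beta
    if q:
        ZtHr = Ztr - ZtZ @ (dh * cho_solve(cW, dh * Ztr))
        u_all = lam[col_block] * ZtHr
    else:
        u_all = np.zeros(0)
    blups, start = [], 0
    for qj in levels:
        blups.append(u_all[start : start + qj])
        start += qj

    mme_cov = None
    if compute_mme and q:
        lam_floor = np.maximum(lam, 1e-10)
        Dinv = np.diag(1.0 / lam_floor[col_block])
        C = np.block([[XtX, ZtX.T], [ZtX, ZtZ + Dinv]])
        mme_cov = sigma2 * np.linalg.inv(C)

    return LMMFit(
        beta=beta,
        cov_beta=cov_beta,
        names=list(names) if names is not None else [f"x{i}" for i in range(p)],
        sigma2=float(sigma2),
        tau2=lam * sigma2,
        lambdas=lam,
        reml=reml,
        converged=converged,
        n_obs=n,
        n_fixed=p,
        deviance=float(neg2),
        blups=blups,
        block_names=list(block_names) if block_names else [f"z{j}" for j in range(k)],
        mme_cov=mme_cov,
        n_levels=levels,
        opt_trace=trace,
    )
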