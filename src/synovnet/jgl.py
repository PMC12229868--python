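"""Fused joint graphical lasso for group-specific precision matrices.

Estimates sparse Gaussian-graphical-model precision matrices Theta_k for
the two groups jointly by minimising

    sum_k n_k ( tr(S_k Theta_k) - log det Theta_k )
        + lambda1 * sum_k sum_{i != j} |Theta_k[i, j]|
        + lambda2 * sum_{i, j} |Theta_1[i, j] - Theta_2[i, j]|

via ADMM.  lambda1 controls within-group sparsity (the diagonal is never
penalised); the fused penalty lambda2 controls between-group similarity —
as lambda2 grows the two precision matrices are forced equal.  The primal
step is an eigen-decomposition; the auxiliary step is the closed-form
fused-lasso + soft-threshold proximal operator applied elementwise.

Model selection scans a (lambda1, lambda2) grid and scores each fit with
AIC_k = n_k tr(S_k Theta_k) - n_k log det Theta_k + 2 E_k (BIC with
log(n_k) E_k), E_k = nonzero off-diagonal entries in the upper triangle.
Zeros of Theta_k encode conditional independence, so the per-group edge
sets and their group-distinct connected components ("differential
clusters") are the interpretable output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "JGLConfig",
    "PrecisionEstimate",
    "joint_graphical_lasso",
    "model_selection",
    "differential_clusters",
    "group_covariances",
    "nearest_psd",
]


@dataclass
class JGLConfig:
    lambda1: float = 2.0
    lambda2: float = 0.5
    admm_rho: float = 10.0
    tol_primal: float = 1e-5
    tol_dual: float = 1e-5
    max_iter: int = 2000
    edge_tol: float = 1e-5

    def validate(self) -> None:
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("penalties must be non-negative")
        if self.admm_rho <= 0:
            raise ValueError("admm_rho must be positive")
        if self.tol_primal <= 0 or self.tol_dual <= 0:
            raise ValueError("tolerances must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class PrecisionEstimate:
    theta: list[np.ndarray]
    adjacency: list[np.ndarray]
    iterations: int
    primal_residual: float
    dual_residual: float
    converged: bool
    n_list: list[int]
    S_list: list[np.ndarray]
    config: JGLConfig
    objective_trace: list[float] = field(default_factory=list)

    def edge_count(self, k: int) -> int:
        return int(np.triu(self.adjacency[k], 1).sum())

    def shared_edge_count(self) -> int:
        shared = np.logical_and.reduce([a for a in self.adjacency])
        return int(np.triu(shared, 1).sum())


def _check_covariances(S_list):
    out = []
    dim = None
    for k, S in enumerate(S_list):
        S = np.asarray(S, float)
        if S.ndim != 2 or S.shape[0] != S.shape[1]:
            raise ValueError(f"covariance {k} is not square")
        if not np.allclose(S, S.T, atol=1e-8):
            raise ValueError(f"covariance {k} is not symmetric")
        if dim is None:
            dim = S.shape[0]
        elif S.shape[0] != dim:
            raise ValueError("covariances differ in dimension")
        out.append((S + S.T) / 2.0)
    return out


def _objective(theta_list, S_list, n_list, lambda1, lambda2):
    val = 0.0
    for theta, S, n in zip(theta_list, S_list, n_list):
        sign, logdet = np.linalg.slogdet(theta)
        if sign <= 0:
            return np.inf
        val += n * (float(np.sum(S * theta)) - logdet)
    off = ~np.eye(theta_list[0].shape[0], dtype=bool)
    val += lambda1 * sum(float(np.abs(th[off]).sum()) for th in theta_list)
    if len(theta_list) == 2:
        val += lambda2 * float(np.abs(theta_list[0] - theta_list[1]).sum())
    return val


def _theta_update(S, A, rho_eff):
    """argmin tr(S Theta) - log det Theta + (rho_eff/2)||Theta - A||_F^2."""
    vals, vecs = np.linalg.eigh(rho_eff * (A + A.T) / 2.0 - S)
    new = (vals + np.sqrt(vals**2 + 4.0 * rho_eff)) / (2.0 * rho_eff)
    return (vecs * new) @ vecs.T


def _fused_prox(a1, a2, lam2):
    """Prox of lam2 |z1 - z2| at (a1, a2) with unit quadratic weight."""
    mid = (a1 + a2) / 2.0
    half_gap = (a1 - a2) / 2.0
    shrink = np.sign(half_gap) * np.maximum(np.abs(half_gap) - lam2, 0.0)
    return mid + shrink, mid - shrink


def _soft(a, lam):
    return np.sign(a) * np.maximum(np.abs(a) - lam, 0.0)


def joint_graphical_lasso(
    S_list, n_list, config: JGLConfig | None = None
) -> PrecisionEstimate:
    """Solve the fused joint graphical lasso by ADMM.

    ``S_list`` holds per-group sample covariances (symmetric PSD, same
    dimension), ``n_list`` the per-group sample sizes.  With a single group
    this reduces to the ordinary graphical lasso; with
    lambda1 = lambda2 = 0 the unpenalised MLE S_k^{-1} is recovered.
    """
    config = config or JGLConfig()
    config.validate()
    S_list = _check_covariances(S_list)
    K = len(S_list)
    if K not in (1, 2):
        raise ValueError("one or two groups supported")
    n_list = [int(n) for n in n_list]
    p = S_list[0].shape[0]
    rho = config.admm_rho
    off_mask = ~np.eye(p, dtype=bool)

    theta = [np.eye(p) for _ in range(K)]
    Z = [np.eye(p) for _ in range(K)]
    U = [np.zeros((p, p)) for _ in range(K)]
    trace: list[float] = []
    primal = dual = np.inf
    it = 0
    for it in range(1, config.max_iter + 1):
        for k in range(K):
            theta[k] = _theta_update(S_list[k], Z[k] - U[k], rho / n_list[k])
        trace.append(
            _objective(theta, S_list, n_list, config.lambda1, config.lambda2)
        )
        Z_old = [z.copy() for z in Z]
        A = [theta[k] + U[k] for k in range(K)]
        if K == 2 and config.lambda2 > 0:
            z1, z2 = _fused_prox(A[0], A[1], config.lambda2 / rho)
        else:
            z1 = A[0]
            z2 = A[1] if K == 2 else None
        new_Z = []
        for zk in ([z1] if K == 1 else [z1, z2]):
            zs = zk.copy()
            zs[off_mask] = _soft(zk[off_mask], config.lambda1 / rho)
            new_Z.append((zs + zs.T) / 2.0)
        Z = new_Z
        for k in range(K):
            U[k] = U[k] + theta[k] - Z[k]
        primal = max(
            float(np.linalg.norm(theta[k] - Z[k], "fro")) for k in range(K)
        )
        dual = max(
            rho * float(np.linalg.norm(Z[k] - Z_old[k], "fro")) for k in range(K)
        )
        if primal < config.tol_primal and dual < config.tol_dual:
            break
    converged = primal < config.tol_primal and dual < config.tol_dual

    # report Theta from the sparse iterate when it is PD (exact zeros),
    # falling back to the primal iterate otherwise
    theta_out = []
    for k in range(K):
        cand = Z[k]
        if np.linalg.eigvalsh((cand + cand.T) / 2.0).min() > 1e-10:
            theta_out.append((cand + cand.T) / 2.0)
        else:
            theta_out.append((theta[k] + theta[k].T) / 2.0)
    adjacency = [
        (np.abs(th) > config.edge_tol) & off_mask for th in theta_out
    ]
    return PrecisionEstimate(
        theta=theta_out,
        adjacency=adjacency,
        iterations=it,
        primal_residual=float(primal),
        dual_residual=float(dual),
        converged=converged,
        n_list=n_list,
        S_list=S_list,
        config=config,
        objective_trace=trace,
    )


def _information_criteria(est: PrecisionEstimate) -> tuple[float, float]:
    aic = bic = 0.0
    for th, S, n, adj in zip(est.theta, est.S_list, est.n_list, est.adjacency):
        sign, logdet = np.linalg.slogdet(th)
        fit = n * float(np.sum(S * th)) - n * logdet
        e_k = int(np.triu(adj, 1).sum())
        aic += fit + 2.0 * e_k
        bic += fit + np.log(n) * e_k
    return aic, bic


def model_selection(
    S_list, n_list, lambda1_grid, lambda2_grid, config: JGLConfig | None = None
) -> tuple[pd.DataFrame, dict[str, PrecisionEstimate]]:
    """Fit the whole (lambda1, lambda2) grid and mark three models of
    increasing complexity: the BIC optimum, the AIC optimum, and the densest
    converged fit (the documented "denser alternative").

    Non-converged grid points are reported but excluded from the optima.
    Returns the selection table and the three marked estimates keyed
    'bic' / 'aic' / 'dense'.
    """
    lambda1_grid = list(lambda1_grid)
    lambda2_grid = list(lambda2_grid)
    if not lambda1_grid or not lambda2_grid:
        raise ValueError("grids must be non-empty")
    base = config or JGLConfig()
    rows = []
    fits = {}
    for l1 in lambda1_grid:
        for l2 in lambda2_grid:
            cfg = JGLConfig(
                lambda1=l1, lambda2=l2, admm_rho=base.admm_rho,
                tol_primal=base.tol_primal, tol_dual=base.tol_dual,
                max_iter=base.max_iter, edge_tol=base.edge_tol,
            )
            est = joint_graphical_lasso(S_list, n_list, cfg)
            aic, bic = _information_criteria(est)
            rows.append(
                {
                    "lambda1": l1, "lambda2": l2, "aic": aic, "bic": bic,
                    "edges_per_group": [est.edge_count(k) for k in range(len(S_list))],
                    "shared_edges": est.shared_edge_count(),
                    "total_edges": sum(est.edge_count(k) for k in range(len(S_list))),
                    "converged": est.converged,
                }
            )
            fits[(l1, l2)] = est
    table = pd.DataFrame(rows)
    ok = table[table["converged"]]
    if ok.empty:
        raise RuntimeError("no grid point converged")
    sel_aic = ok.loc[ok["aic"].idxmin()]
    sel_bic = ok.loc[ok["bic"].idxmin()]
    dense = ok.sort_values(
        ["total_edges", "lambda1", "lambda2"], ascending=[False, True, True]
    ).iloc[0]
    table["selected"] = ""
    for label, row in (("bic", sel_bic), ("aic", sel_aic), ("dense", dense)):
        idx = table.index[
            (table["lambda1"] == row["lambda1"]) & (table["lambda2"] == row["lambda2"])
        ][0]
        table.loc[idx, "selected"] = (
            table.loc[idx, "selected"] + "+" + label
        ).strip("+")
    selected = {
        "bic": fits[(sel_bic["lambda1"], sel_bic["lambda2"])],
        "aic": fits[(sel_aic["lambda1"], sel_aic["lambda2"])],
        "dense": fits[(dense["lambda1"], dense["lambda2"])],
    }
    return table, selected


def differential_clusters(
    estimate: PrecisionEstimate, names: list[str] | None = None
) -> dict[str, list[list[str]]]:
    """Connected components of the group-distinct edge sets, largest first.

    An edge is group-distinct when present in exactly one group's adjacency;
    clusters of such edges highlight sub-networks whose conditional
    dependence structure differs between groups.
    """
    if len(estimate.adjacency) != 2:
        raise ValueError("differential clusters need two groups")
    p = estimate.adjacency[0].shape[0]
    if names is None:
        names = [f"V{i}" for i in range(p)]
    labels = ["control", "OA"]
    out: dict[str, list[list[str]]] = {}
    for k, label in enumerate(labels):
        other = estimate.adjacency[1 - k]
        distinct = estimate.adjacency[k] & ~other
        graph = nx.Graph()
        ii, jj = np.nonzero(np.triu(distinct, 1))
        graph.add_edges_from((names[i], names[j]) for i, j in zip(ii, jj))
        comps = [sorted(c) for c in nx.connected_components(graph)]
        comps.sort(key=lambda c: (-len(c), c))
        out[label] = comps
    return out


def nearest_psd(S: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """Eigenvalue-clipped nearest positive-semi-definite repair."""
    S = (S + S.T) / 2.0
    vals, vecs = np.linalg.eigh(S)
    if vals.min() >= floor:
        return S
    vals = np.maximum(vals, floor)
    return (vecs * vals) @ vecs.T


def group_covariances(
    matrix: pd.DataFrame, groups
) -> tuple[list[np.ndarray], list[int], list[str]]:
    """Per-group covariances for the graphical lasso.

    Pairwise-complete covariance with within-group means and denominator
    n_k, followed by a PSD repair (pairwise completion can break
    definiteness).  Returns (S_list, n_list, protein names) ordered
    [control, OA].
    """
    g = np.asarray([1 if v in ("OA", 1, True) else 0 for v in groups])
    names = list(matrix.columns)
    S_list, n_list = [], []
    for code in (0, 1):
        sub = matrix.to_numpy(float)[g == code]
        n_k = sub.shape[0]
        masked = np.ma.masked_invalid(sub)
        S = np.ma.cov(masked, rowvar=False, bias=True, allow_masked=True)
        S = nearest_psd(np.asarray(S.filled(0.0)))
        S_list.append(S)
        n_list.append(n_k)
    return S_list, n_list, names
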