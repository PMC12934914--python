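"""Joint network estimation across strata and between-group comparison.

The fused graphical lasso estimates one precision matrix per stratum
while penalizing both sparsity and between-group differences,

    sum_g n_g (-logdet T_g + tr(S_g T_g))
      + lambda1 sum_g sum_{i != j} |t^g_ij|
      + lambda2 sum_{i,j} |t^1_ij - t^2_ij|,

solved by ADMM with closed-form fusion/soft-threshold proximal steps
(two groups). The fusion term includes the diagonal so that in the
lambda2 -> infinity limit the groups share one network. Global
differences between two observed networks are tested with a
permutation-based network comparison test on global strength and
maximum edge difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pingouin import partial_corr as _pg_partial_corr
from scipy import stats

from .communities import CommunityPartition
from .catalog import ItemCatalog
from .ggm import (
    GGMNetwork,
    GlassoConfig,
    _batched_corr,
    _batched_glasso_path,
    correlation_matrix,
    lambda_grid,
)

__all__ = [
    "FusedConfig",
    "GroupNetworks",
    "NCTResult",
    "fused_glasso",
    "network_comparison_test",
    "within_cluster_connectivity",
    "cross_domain_association",
]


@dataclass
class FusedConfig:
    """Fused-lasso penalties on the scale of the joint objective
    (per-group effective per-observation sparsity is lambda1 / n_g).
    ``lambda1=None`` triggers joint EBIC grid selection."""

    lambda1: float | None = None
    lambda2: float | None = None
    admm_rho: float | None = None  # None: set to the mean group size
    tol: float = 1e-6
    max_iter: int = 4000
    gamma: float = 0.5

    def __post_init__(self) -> None:
        for name in ("lambda1", "lambda2"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")


@dataclass
class GroupNetworks:
    networks: dict[str, GGMNetwork]
    lambda1: float
    lambda2: float
    n_iter: int
    converged: bool

    def __getitem__(self, key: str) -> GGMNetwork:
        return self.networks[key]


@dataclass
class NCTResult:
    p_global_strength: float
    p_structure: float
    observed_strength_diff: float
    observed_structure_diff: float
    n_perm: int
    seed: int | None


def _fused_admm(
    S: list[np.ndarray],
    ns: list[int],
    lambda1: float,
    lambda2: float,
    rho: float,
    tol: float,
    max_iter: int,
) -> tuple[list[np.ndarray], int, bool]:
    p = S[0].shape[0]
    K = len(S)
    theta = [np.linalg.inv(Sk + 0.1 * np.eye(p)) for Sk in S]
    Z = [t.copy() for t in theta]
    U = [np.zeros((p, p)) for _ in range(K)]
    offdiag = ~np.eye(p, dtype=bool)
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        # theta step: per-group eigen update
        for g in range(K):
            M = rho * (Z[g] - U[g]) - ns[g] * S[g]
            M = (M + M.T) / 2
            vals, vecs = np.linalg.eigh(M)
            d = (vals + np.sqrt(vals**2 + 4 * rho * ns[g])) / (2 * rho)
            theta[g] = (vecs * d) @ vecs.T
        # Z step: fuse across the two groups, then soft-threshold off-diagonals
        Z_old = [z.copy() for z in Z]
        A = [theta[g] + U[g] for g in range(K)]
        a1, a2 = A[0], A[1]
        diff = a1 - a2
        fuse = np.abs(diff) <= 2 * lambda2 / rho
        mid = (a1 + a2) / 2
        y1 = np.where(fuse, mid, a1 - np.sign(diff) * lambda2 / rho)
        y2 = np.where(fuse, mid, a2 + np.sign(diff) * lambda2 / rho)
        thr = lambda1 / rho
        z1 = np.where(offdiag, np.sign(y1) * np.maximum(np.abs(y1) - thr, 0.0), y1)
        z2 = np.where(offdiag, np.sign(y2) * np.maximum(np.abs(y2) - thr, 0.0), y2)
        Z = [(z1 + z1.T) / 2, (z2 + z2.T) / 2]
        for g in range(K):
            U[g] = U[g] + theta[g] - Z[g]
        primal = np.sqrt(sum(np.sum((theta[g] - Z[g]) ** 2) for g in range(K)))
        dual = rho * np.sqrt(sum(np.sum((Z[g] - Z_old[g]) ** 2) for g in range(K)))
        scale = max(
            1.0,
            np.sqrt(sum(np.sum(t**2) for t in theta)),
            np.sqrt(sum(np.sum(z**2) for z in Z)),
        )
        if primal <= tol * scale and dual <= tol * scale:
            converged = True
            break
    return Z, n_iter, converged


def _partial_from_precision(theta: np.ndarray) -> np.ndarray:
    d = np.diag(theta).copy()
    d[d <= 0] = 1e-12
    w = -theta / np.sqrt(np.outer(d, d))
    np.fill_diagonal(w, 0.0)
    return np.clip((w + w.T) / 2, -0.999999, 0.999999)


def _joint_ebic(
    S: list[np.ndarray], ns: list[int], Z: list[np.ndarray], gamma: float
) -> float:
    total = 0.0
    p = S[0].shape[0]
    iu = np.triu_indices(p, k=1)
    for Sk, nk, Tk in zip(S, ns, Z):
        sign, logdet = np.linalg.slogdet(Tk)
        if sign <= 0:
            return np.inf
        loglik = 0.5 * nk * (logdet - np.trace(Sk @ Tk))
        E = int((np.abs(Tk[iu]) > 1e-8).sum())
        total += -2 * loglik + E * np.log(nk) + 4 * gamma * E * np.log(p)
    return float(total)


def fused_glasso(
    data_by_group: dict[str, pd.DataFrame],
    config: FusedConfig | None = None,
    correlation_kind: str = "pearson",
) -> GroupNetworks:
    """Jointly estimate one partial-correlation network per group.

    Exactly two groups are supported (the SA+/SA- design). When the
    penalties are unset they are chosen by a small joint grid search
    minimizing the group-size-weighted summed EBIC.
    """
    config = config or FusedConfig()
    if len(data_by_group) != 2:
        raise ValueError("fused_glasso supports exactly 2 groups")
    names = list(data_by_group)
    cols = list(data_by_group[names[0]].columns)
    for name in names[1:]:
        if list(data_by_group[name].columns) != cols:
            raise ValueError("groups must share an identical item set")
    S, ns = [], []
    for name in names:
        Sg, ng = correlation_matrix(data_by_group[name], correlation_kind)
        S.append(Sg.to_numpy())
        ns.append(ng)

    rho = config.admm_rho if config.admm_rho is not None else float(np.mean(ns))
    if config.lambda1 is None or config.lambda2 is None:
        n_scale = float(np.mean(ns))
        l1_grid = (
            [config.lambda1]
            if config.lambda1 is not None
            else [a * n_scale for a in (0.02, 0.04, 0.06, 0.09)]
        )
        l2_grid = (
            [config.lambda2]
            if config.lambda2 is not None
            else [a * n_scale for a in (0.0, 0.005, 0.02, 0.05)]
        )
        best = None
        for l1 in l1_grid:
            for l2 in l2_grid:
                Z, _, _ = _fused_admm(
                    S, ns, l1, l2, rho, max(config.tol, 1e-5),
                    min(config.max_iter, 1000),
                )
                score = _joint_ebic(S, ns, Z, config.gamma)
                if best is None or score < best[0]:
                    best = (score, l1, l2)
        _, lambda1, lambda2 = best
    else:
        lambda1, lambda2 = config.lambda1, config.lambda2

    Z, n_iter, converged = _fused_admm(
        S, ns, lambda1, lambda2, rho, config.tol, config.max_iter
    )
    if not converged:
        raise RuntimeError(
            f"fused-lasso ADMM did not converge in {config.max_iter} iterations "
            f"(lambda1={lambda1:.4g}, lambda2={lambda2:.4g})"
        )
    networks = {}
    for name, Tk, nk in zip(names, Z, ns):
        networks[name] = GGMNetwork(
            nodes=cols,
            weights=_partial_from_precision(Tk),
            lambda_selected=float(lambda1),
            ebic=_joint_ebic(S, ns, Z, config.gamma),
            n=nk,
            meta={"lambda2": float(lambda2), "fused": True},
        )
    return GroupNetworks(
        networks=networks,
        lambda1=float(lambda1),
        lambda2=float(lambda2),
        n_iter=n_iter,
        converged=converged,
    )


def network_comparison_test(
    dataA: pd.DataFrame,
    dataB: pd.DataFrame,
    n_perm: int = 1000,
    seed: int | None = None,
    config: GlassoConfig | None = None,
) -> NCTResult:
    """Permutation test for global network differences.

    Statistics: the absolute difference in global strength (sum of
    |w_ij| over the upper triangle) and the maximum absolute edge
    difference. Group labels are permuted and both networks re-estimated
    per permutation; p-values use the add-one convention.
    """
    if n_perm < 100:
        raise ValueError("n_perm < 100 cannot resolve conventional alpha levels")
    if list(dataA.columns) != list(dataB.columns):
        raise ValueError("datasets must share the same items")
    config = config or GlassoConfig()
    rng = np.random.default_rng(seed)
    pooled = pd.concat([dataA, dataB], ignore_index=True)
    nA = len(dataA)
    X = pooled.to_numpy(dtype=float)
    if config.correlation_kind == "spearman":
        X = np.apply_along_axis(stats.rankdata, 0, X)
    p = X.shape[1]
    S_pool, _ = correlation_matrix(pooled, config.correlation_kind)
    grid = lambda_grid(S_pool.to_numpy(), config)
    iu = np.triu_indices(p, k=1)

    def stats_for(idxA: np.ndarray, idxB: np.ndarray) -> tuple[float, float]:
        # observed and permuted statistics share one estimation path
        # (shared penalty grid), so the permutation null is exchangeable
        WA = _batched_glasso_path(
            _batched_corr(X, idxA[None, :]), nA, grid, config.gamma
        )[0]
        WB = _batched_glasso_path(
            _batched_corr(X, idxB[None, :]), len(pooled) - nA, grid, config.gamma
        )[0]
        return (
            float(abs(np.abs(WA[iu]).sum() - np.abs(WB[iu]).sum())),
            float(np.abs(WA - WB).max()),
        )

    obs_s, obs_m = stats_for(np.arange(nA), np.arange(nA, len(pooled)))
    # permutation null built on a canonically ordered pooled matrix, so
    # swapping the group labels leaves the null (and p) unchanged
    canon = np.lexsort(X.T[::-1])
    X = X[canon]
    count_s = count_m = 0
    # permutations are solved in batches: resampled correlation matrices
    # followed by the batched EBIC-glasso path, per group
    chunk = max(1, int(2e7 // (len(pooled) * p)))
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        orders = np.stack([rng.permutation(len(pooled)) for _ in range(b)])
        WA = _batched_glasso_path(
            _batched_corr(X, orders[:, :nA]), nA, grid, config.gamma
        )
        WB = _batched_glasso_path(
            _batched_corr(X, orders[:, nA:]), len(pooled) - nA, grid, config.gamma
        )
        s = np.abs(
            np.abs(WA[:, iu[0], iu[1]]).sum(axis=1)
            - np.abs(WB[:, iu[0], iu[1]]).sum(axis=1)
        )
        m = np.abs(WA - WB).reshape(b, -1).max(axis=1)
        count_s += int((s >= obs_s).sum())
        count_m += int((m >= obs_m).sum())
        done += b
    return NCTResult(
        p_global_strength=(1 + count_s) / (1 + n_perm),
        p_structure=(1 + count_m) / (1 + n_perm),
        observed_strength_diff=obs_s,
        observed_structure_diff=obs_m,
        n_perm=n_perm,
        seed=seed,
    )


def within_cluster_connectivity(
    net: GGMNetwork, partition: CommunityPartition | ItemCatalog
) -> pd.Series:
    """Average node strength within each domain, computed on the
    subgraph restricted to the domain's members. Singleton domains score
    0 with a warning."""
    if isinstance(partition, ItemCatalog):
        domain_map = dict(partition.domain_of)
    else:
        domain_map = partition.as_domain_map()
    missing = [x for x in net.nodes if x not in domain_map]
    if missing:
        raise ValueError(f"partition does not cover nodes: {missing}")
    out = {}
    for domain in sorted(set(domain_map[x] for x in net.nodes)):
        idx = [i for i, x in enumerate(net.nodes) if domain_map[x] == domain]
        if len(idx) < 2:
            warnings.warn(f"singleton domain {domain}: connectivity 0", stacklevel=2)
            out[domain] = 0.0
            continue
        sub = net.weights[np.ix_(idx, idx)]
        out[domain] = float(np.abs(sub).sum(axis=0).mean())
    return pd.Series(out, name="within_connectivity")


def cross_domain_association(
    cluster_scores: pd.DataFrame,
    domain_a: str,
    domain_b: str,
    control: str | None = None,
) -> tuple[float, float]:
    """Spearman association between two domain scores, optionally the
    partial Spearman controlling for a third column (rank-based
    residualization)."""
    if len(cluster_scores) < 10:
        raise ValueError("n >= 10 required")
    for col in filter(None, (domain_a, domain_b, control)):
        if cluster_scores[col].nunique() < 2:
            raise ValueError(f"constant column: {col}")
    if control is None:
        rho, p = stats.spearmanr(cluster_scores[domain_a], cluster_scores[domain_b])
        return float(rho), float(p)
    res = _pg_partial_corr(
        data=cluster_scores, x=domain_a, y=domain_b, covar=control, method="spearman"
    )
    return float(res["r"].iloc[0]), float(res["p_val"].iloc[0])
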