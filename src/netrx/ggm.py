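"""Regularized partial-correlation network estimation.

The estimator is the graphical lasso (an L1-penalized Gaussian
log-likelihood over the precision matrix) with the penalty selected by
the extended BIC,

    EBIC(lambda) = -2 loglik + E log n + 4 gamma E log p,

where E is the number of nonzero upper-triangle edges and gamma the
EBIC hyperparameter (0.5 by default). Edge weights are the partial
correlations w_ij = -theta_ij / sqrt(theta_ii theta_jj). Edge
uncertainty comes from nonparametric case-resampling bootstraps, and
estimation stability from case-dropping subsample bootstraps summarized
as correlation-stability (CS) coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GlassoConfig",
    "GGMNetwork",
    "EdgeInference",
    "StabilityResult",
    "correlation_matrix",
    "glasso_ebic",
    "bootstrap_edge_ci",
    "case_dropping_cs",
]

_ZERO_TOL = 1e-8


@dataclass
class GlassoConfig:
    gamma: float = 0.5
    n_lambdas: int = 100
    lambda_min_ratio: float = 0.01
    correlation_kind: str = "pearson"

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.n_lambdas < 2:
            raise ValueError("n_lambdas must be >= 2")
        if not 0 < self.lambda_min_ratio < 1:
            raise ValueError("lambda_min_ratio must lie in (0, 1)")
        if self.correlation_kind not in ("pearson", "spearman"):
            raise ValueError("correlation_kind must be 'pearson' or 'spearman'")


@dataclass
class GGMNetwork:
    """A partial-correlation network: symmetric weights, zero diagonal."""

    nodes: list[str]
    weights: np.ndarray
    lambda_selected: float
    ebic: float
    n: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (len(self.nodes), len(self.nodes)):
            raise ValueError("weight matrix shape does not match node list")
        if not np.allclose(w, w.T, atol=1e-10):
            raise ValueError("weight matrix must be symmetric")
        if np.abs(np.diag(w)).max(initial=0.0) > 1e-10:
            raise ValueError("weight matrix must have a zero diagonal")
        if np.abs(w).max(initial=0.0) >= 1.0:
            raise ValueError("partial correlations must satisfy |w| < 1")
        self.weights = w

    @property
    def p(self) -> int:
        return len(self.nodes)

    def edge(self, a: str, b: str) -> float:
        return float(self.weights[self.nodes.index(a), self.nodes.index(b)])

    def n_edges(self) -> int:
        iu = np.triu_indices(self.p, k=1)
        return int((np.abs(self.weights[iu]) > _ZERO_TOL).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=self.nodes, columns=self.nodes)


@dataclass
class EdgeInference:
    """Bootstrap edge estimates: point estimate, percentile 95% CI
    (widened to contain the point estimate), raw and BH-adjusted
    sign-crossing p-values. One row per upper-triangle edge."""

    table: pd.DataFrame  # columns: node_a, node_b, estimate, lower, upper, p_raw, p_fdr

    def lookup(self, a: str, b: str) -> pd.Series:
        t = self.table
        hit = t[((t.node_a == a) & (t.node_b == b)) | ((t.node_a == b) & (t.node_b == a))]
        if hit.empty:
            raise KeyError(f"no edge ({a}, {b}) in inference table")
        return hit.iloc[0]


@dataclass
class StabilityResult:
    cs: float
    target: str
    drop_fractions: list[float]
    quantile05: list[float]
    correlation_threshold: float = 0.7


def correlation_matrix(
    items: pd.DataFrame, kind: str = "pearson"
) -> tuple[pd.DataFrame, int]:
    """Pearson or Spearman correlation matrix, repaired to the nearest
    positive semi-definite correlation matrix (negative eigenvalues
    clipped, diagonal renormalized to 1)."""
    X = items.to_numpy(dtype=float)
    n, p = X.shape
    nunique = items.nunique()
    constant = nunique[nunique < 2]
    if len(constant):
        raise ValueError(f"constant column(s): {list(constant.index)}")
    if np.isnan(X).any():
        raise ValueError("missing values are not supported")
    if kind == "spearman":
        X = np.apply_along_axis(stats.rankdata, 0, X)
    elif kind != "pearson":
        raise ValueError("kind must be 'pearson' or 'spearman'")
    R = np.corrcoef(X, rowvar=False)
    # nearest-PSD repair
    vals, vecs = np.linalg.eigh(R)
    if vals[0] < 0:
        vals = np.clip(vals, 0.0, None)
        R = (vecs * vals) @ vecs.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
    R = (R + R.T) / 2
    np.fill_diagonal(R, 1.0)
    return pd.DataFrame(R, index=items.columns, columns=items.columns), n


def _partial_corr(precision: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(precision))
    w = -precision / np.outer(d, d)
    np.fill_diagonal(w, 0.0)
    return (w + w.T) / 2


def _ebic_score(S: np.ndarray, precision: np.ndarray, n: int, gamma: float) -> float:
    p = S.shape[0]
    sign, logdet = np.linalg.slogdet(precision)
    if sign <= 0:
        return np.inf
    loglik = 0.5 * n * (logdet - np.trace(S @ precision))
    w = _partial_corr(precision)
    iu = np.triu_indices(p, k=1)
    E = int((np.abs(w[iu]) > _ZERO_TOL).sum())
    return float(-2 * loglik + E * np.log(n) + 4 * gamma * E * np.log(p))


def lambda_grid(S: np.ndarray, config: GlassoConfig) -> np.ndarray:
    """Log-spaced penalty grid from max |off-diagonal| of S downward."""
    p = S.shape[0]
    off = np.abs(S[~np.eye(p, dtype=bool)])
    lam_max = max(off.max(initial=0.0), 1e-8)
    return np.geomspace(lam_max, lam_max * config.lambda_min_ratio, config.n_lambdas)


def glasso_at(
    S: np.ndarray,
    lam: float,
    tol: float = 1e-5,
    max_iter: int = 1000,
    rho: float = 1.0,
    warm: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Single graphical-lasso solve at penalty ``lam``.

    Minimizes -logdet(T) + tr(S T) + lam * sum_{i!=j} |t_ij| by ADMM:
    the T-step is a closed-form eigenvalue update, the Z-step
    soft-thresholds the off-diagonal, giving exact zeros. ``warm``
    carries (Z, U) from a previous penalty for warm starts along a
    path. Returns (precision, Z, U).
    """
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    Z = np.eye(p) if warm is None else warm[0].copy()
    U = np.zeros((p, p)) if warm is None else warm[1].copy()
    off = ~np.eye(p, dtype=bool)
    for _ in range(max_iter):
        M = rho * (Z - U) - S
        M = (M + M.T) / 2
        vals, vecs = np.linalg.eigh(M)
        d = (vals + np.sqrt(vals**2 + 4 * rho)) / (2 * rho)
        T = (vecs * d) @ vecs.T
        Z_old = Z
        A = T + U
        Z = np.where(off, np.sign(A) * np.maximum(np.abs(A) - lam / rho, 0.0), A)
        Z = (Z + Z.T) / 2
        U = U + T - Z
        primal = np.linalg.norm(T - Z)
        dual = rho * np.linalg.norm(Z - Z_old)
        scale = max(1.0, np.linalg.norm(T))
        if primal <= tol * scale and dual <= tol * scale:
            break
    else:
        raise RuntimeError(
            f"graphical lasso ADMM did not converge at lambda={lam:.3g} "
            f"(primal {primal:.2e}, dual {dual:.2e})"
        )
    return Z, Z, U


def glasso_ebic(
    S: pd.DataFrame | np.ndarray,
    n: int,
    config: GlassoConfig | None = None,
    nodes: list[str] | None = None,
) -> GGMNetwork:
    """Graphical lasso over a log-spaced penalty grid; the returned
    network is the EBIC-minimizing solution."""
    config = config or GlassoConfig()
    if isinstance(S, pd.DataFrame):
        nodes = list(S.columns)
        S = S.to_numpy(dtype=float)
    elif nodes is None:
        nodes = [f"V{i}" for i in range(S.shape[0])]
    if np.linalg.eigvalsh(S)[0] < -1e-8:
        raise ValueError("correlation input must be positive semi-definite")

    grid = lambda_grid(S, config)
    best = None
    errors = []
    rising = 0
    warm = None
    # The EBIC path falls then rises as lambda decreases; once it has
    # risen for several consecutive penalties past the minimum, the
    # (slow) small-penalty tail of the grid cannot win and is skipped.
    patience = 10
    for lam in grid:
        try:
            precision, Zw, Uw = glasso_at(S, lam, warm=warm)
            warm = (Zw, Uw)
        except RuntimeError as exc:
            errors.append(str(exc))
            continue
        score = _ebic_score(S, precision, n, config.gamma)
        if best is None or score < best[0]:
            best = (score, lam, precision)
            rising = 0
        else:
            rising += 1
            if rising >= patience:
                break
    if best is None:
        raise RuntimeError("no lambda converged; diagnostics: " + "; ".join(errors))
    score, lam, precision = best
    return GGMNetwork(
        nodes=nodes,
        weights=_partial_corr(precision),
        lambda_selected=float(lam),
        ebic=score,
        n=n,
        meta={"gamma": config.gamma, "correlation_kind": config.correlation_kind},
    )


def estimate_network(
    items: pd.DataFrame, config: GlassoConfig | None = None
) -> GGMNetwork:
    """Convenience: correlation matrix + EBIC graphical lasso."""
    config = config or GlassoConfig()
    S, n = correlation_matrix(items, config.correlation_kind)
    return glasso_ebic(S, n, config)


def _batched_corr(X: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Correlation matrices of ``X[idx[b]]`` for every resample row b."""
    Xb = X[idx]  # (B, n, p)
    Xb = Xb - Xb.mean(axis=1, keepdims=True)
    cov = np.einsum("bni,bnj->bij", Xb, Xb) / (Xb.shape[1] - 1)
    sd = np.sqrt(np.diagonal(cov, axis1=1, axis2=2))
    sd = np.where(sd <= 0, 1.0, sd)
    R = cov / (sd[:, :, None] * sd[:, None, :])
    R = np.clip(R, -1.0, 1.0)
    p = R.shape[1]
    R[:, np.arange(p), np.arange(p)] = 1.0
    return R


def _batched_glasso_path(
    S: np.ndarray,
    ns: int,
    grid: np.ndarray,
    gamma: float,
    tol: float = 1e-4,
    max_iter: int = 500,
    rho: float = 1.0,
) -> np.ndarray:
    """EBIC-selected partial correlations for a batch of correlation
    matrices sharing one penalty grid. Returns (B, p, p) weights.

    The ADMM recursion of :func:`glasso_at` is applied to all batch
    members at once (batched eigendecompositions), warm-started along
    the path.
    """
    B, p, _ = S.shape
    eye = np.eye(p)
    off = ~np.eye(p, dtype=bool)
    Z = np.broadcast_to(eye, (B, p, p)).copy()
    U = np.zeros((B, p, p))
    best_score = np.full(B, np.inf)
    best_W = np.zeros((B, p, p))
    iu = np.triu_indices(p, k=1)
    for lam in grid:
        for _ in range(max_iter):
            M = rho * (Z - U) - S
            M = (M + M.transpose(0, 2, 1)) / 2
            vals, vecs = np.linalg.eigh(M)
            d = (vals + np.sqrt(vals**2 + 4 * rho)) / (2 * rho)
            T = np.einsum("bik,bk,bjk->bij", vecs, d, vecs)
            Z_old = Z
            A = T + U
            Z = np.where(off, np.sign(A) * np.maximum(np.abs(A) - lam / rho, 0.0), A)
            Z = (Z + Z.transpose(0, 2, 1)) / 2
            U = U + T - Z
            primal = np.linalg.norm((T - Z).reshape(B, -1), axis=1)
            dual = rho * np.linalg.norm((Z - Z_old).reshape(B, -1), axis=1)
            scale = np.maximum(1.0, np.linalg.norm(T.reshape(B, -1), axis=1))
            if np.all(primal <= tol * scale) and np.all(dual <= tol * scale):
                break
        # EBIC per batch member
        sign, logdet = np.linalg.slogdet(Z)
        tr = np.einsum("bij,bji->b", S, Z)
        loglik = 0.5 * ns * (logdet - tr)
        E = (np.abs(Z[:, iu[0], iu[1]]) > _ZERO_TOL).sum(axis=1)
        score = np.where(
            sign > 0, -2 * loglik + E * np.log(ns) + 4 * gamma * E * np.log(p), np.inf
        )
        better = score < best_score
        if better.any():
            dz = np.sqrt(np.diagonal(Z, axis1=1, axis2=2))
            W = -Z / (dz[:, :, None] * dz[:, None, :])
            W[:, np.arange(p), np.arange(p)] = 0.0
            W = (W + W.transpose(0, 2, 1)) / 2
            best_W[better] = W[better]
            best_score[better] = score[better]
    return best_W


def bootstrap_edge_ci(
    items: pd.DataFrame,
    B: int = 500,
    config: GlassoConfig | None = None,
    seed: int | None = None,
) -> EdgeInference:
    """Nonparametric case-resampling bootstrap of edge weights.

    Per edge: percentile 2.5/97.5 CI (widened to include the full-sample
    point estimate so lower <= estimate <= upper always holds), raw
    p-value twice the smaller add-one-smoothed sign-crossing fraction,
    and Benjamini-Hochberg adjustment across the upper triangle.
    """
    if B < 200:
        raise ValueError("B < 200 gives unstable percentile CIs; refuse")
    config = config or GlassoConfig()
    rng = np.random.default_rng(seed)
    net = estimate_network(items, config)
    p = net.p
    iu = np.triu_indices(p, k=1)
    n = len(items)
    X = items.to_numpy(dtype=float)
    S_full, _ = correlation_matrix(items, config.correlation_kind)
    grid = lambda_grid(S_full.to_numpy(), config)
    if config.correlation_kind == "spearman":
        X = np.apply_along_axis(stats.rankdata, 0, X)
    boot = np.empty((B, len(iu[0])))
    chunk = max(1, int(2e7 // (n * p)))  # cap resample memory
    done = 0
    while done < B:
        b = min(chunk, B - done)
        idx = rng.integers(0, n, size=(b, n))
        Sb = _batched_corr(X, idx)
        Wb = _batched_glasso_path(Sb, n, grid, config.gamma)
        boot[done : done + b] = Wb[:, iu[0], iu[1]]
        done += b
    est = net.weights[iu]
    lower = np.minimum(np.percentile(boot, 2.5, axis=0), est)
    upper = np.maximum(np.percentile(boot, 97.5, axis=0), est)
    frac_le = (1 + (boot <= 0).sum(axis=0)) / (B + 1)
    frac_ge = (1 + (boot >= 0).sum(axis=0)) / (B + 1)
    p_raw = np.minimum(1.0, 2 * np.minimum(frac_le, frac_ge))
    p_fdr = multipletests(p_raw, method="fdr_bh")[1]
    p_fdr = np.maximum(p_fdr, p_raw)
    table = pd.DataFrame(
        {
            "node_a": [net.nodes[i] for i in iu[0]],
            "node_b": [net.nodes[j] for j in iu[1]],
            "estimate": est,
            "lower": lower,
            "upper": upper,
            "p_raw": p_raw,
            "p_fdr": p_fdr,
        }
    )
    return EdgeInference(table=table)


def _strengths(weights: np.ndarray) -> np.ndarray:
    return np.abs(weights).sum(axis=0)


def case_dropping_cs(
    items: pd.DataFrame,
    target: str = "structure",
    drop_grid: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7),
    B: int = 500,
    config: GlassoConfig | None = None,
    correlation_threshold: float = 0.7,
    probability: float = 0.95,
    seed: int | None = None,
) -> StabilityResult:
    """Case-dropping bootstrap stability.

    For each drop fraction, networks are re-estimated on random
    subsamples and correlated (edge weights for ``structure``, node
    strengths for ``strength``) with the full-sample network. The CS
    coefficient is the largest drop fraction whose 5th-percentile
    correlation still reaches the threshold (0.7 by default).
    ``B`` is the total number of subsamples, split evenly over the grid.
    """
    if target not in ("structure", "strength"):
        raise ValueError("target must be 'structure' or 'strength'")
    if not all(0 < f <= 0.75 for f in drop_grid):
        raise ValueError("drop_grid fractions must lie in (0, 0.75]")
    config = config or GlassoConfig()
    rng = np.random.default_rng(seed)
    full = estimate_network(items, config)
    iu = np.triu_indices(full.p, k=1)
    ref = full.weights[iu] if target == "structure" else _strengths(full.weights)
    n = len(items)
    X = items.to_numpy(dtype=float)
    if config.correlation_kind == "spearman":
        X = np.apply_along_axis(stats.rankdata, 0, X)
    S_full, _ = correlation_matrix(items, config.correlation_kind)
    grid = lambda_grid(S_full.to_numpy(), config)
    per_frac = max(10, B // len(drop_grid))
    fractions, q05 = [], []
    lo_q = 100 * (1 - probability)
    for frac in drop_grid:
        m = int(round(n * (1 - frac)))
        if m < 3 * full.p:
            warnings.warn(
                f"drop fraction {frac}: subsample {m} < 3p; skipped", stacklevel=2
            )
            continue
        cors = []
        chunk = max(1, int(2e7 // (m * full.p)))
        done = 0
        while done < per_frac:
            b = min(chunk, per_frac - done)
            idx = np.stack(
                [rng.choice(n, size=m, replace=False) for _ in range(b)]
            )
            Sb = _batched_corr(X, idx)
            Wb = _batched_glasso_path(Sb, m, grid, config.gamma)
            for W in Wb:
                vec = W[iu] if target == "structure" else _strengths(W)
                if np.std(vec) == 0 or np.std(ref) == 0:
                    cors.append(0.0)
                else:
                    cors.append(float(np.corrcoef(ref, vec)[0, 1]))
            done += b
        fractions.append(float(frac))
        q05.append(float(np.percentile(cors, lo_q)))
    cs = 0.0
    for frac, q in zip(fractions, q05):
        if q >= correlation_threshold and frac > cs:
            cs = frac
    return StabilityResult(
        cs=cs,
        target=target,
        drop_fractions=fractions,
        quantile05=q05,
        correlation_threshold=correlation_threshold,
    )
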