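"""Emulated stratified randomized trial on symptom profiles.

Participants are randomized 1:1 within suicide-attempt strata. The
intervention arm receives a simulated "deactivation" of one target
symptom domain: each member item is reduced toward the scale floor (1,
"absent") in proportion to its normalized expected-influence
centrality, so the most network-influential symptom receives the full
dose alpha. The control arm receives synthetic post profiles resampled
from a Gaussian copula fitted to the arm's baseline profiles, which
preserves both the ordinal marginals and the rank dependence of the
untreated joint distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .catalog import ItemCatalog
from .centrality import CentralityTable

__all__ = [
    "DeactivationConfig",
    "CopulaModel",
    "TrialState",
    "stratified_randomize",
    "deactivate",
    "fit_copula",
    "sample_controls",
    "run_trial",
]

LEVELS = np.arange(1, 8)


@dataclass
class DeactivationConfig:
    target_domain: str = "DST"
    alpha: float = 0.5
    normalization: str = "max"  # or "sum"
    rounding: str = "continuous"  # or "integer" (round-half-up)

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.normalization not in ("max", "sum"):
            raise ValueError("normalization must be 'max' or 'sum'")
        if self.rounding not in ("continuous", "integer"):
            raise ValueError("rounding must be 'continuous' or 'integer'")


@dataclass
class CopulaModel:
    """Gaussian copula of ordinal item profiles: per-item empirical CDF
    tables over levels 1..7 plus the latent normal-scores correlation."""

    columns: list[str]
    cdf: np.ndarray  # (p, 7) monotone per row, last entry 1
    latent_corr: np.ndarray
    point_mass: np.ndarray  # bool per item

    def __post_init__(self) -> None:
        if not np.allclose(self.cdf[:, -1], 1.0):
            raise ValueError("CDF tables must end at 1")
        if np.any(np.diff(self.cdf, axis=1) < -1e-12):
            raise ValueError("CDF tables must be monotone")


@dataclass
class TrialState:
    """Paired baseline/post profiles with arm and stratum labels."""

    t0: pd.DataFrame
    t1: pd.DataFrame
    arm: np.ndarray  # "intervention" | "control"
    stratum: np.ndarray  # "SA+" | "SA-"
    covariates: pd.DataFrame
    config: DeactivationConfig = field(default_factory=DeactivationConfig)

    def mask(self, arm: str | None = None, stratum: str | None = None) -> np.ndarray:
        m = np.ones(len(self.t0), dtype=bool)
        if arm is not None:
            m &= self.arm == arm
        if stratum is not None:
            m &= self.stratum == stratum
        return m

    def long_frame(self) -> pd.DataFrame:
        rows = []
        for time, prof in (("T0", self.t0), ("T1", self.t1)):
            block = prof.copy()
            block.insert(0, "participant", np.arange(len(prof)))
            block.insert(1, "stratum", self.stratum)
            block.insert(2, "arm", self.arm)
            block.insert(3, "time", time)
            rows.append(block)
        return pd.concat(rows, ignore_index=True)


def stratified_randomize(
    n: int, stratum_labels: np.ndarray, seed: int | None = None
) -> np.ndarray:
    """1:1 randomization within each stratum (odd counts: the
    intervention arm receives the extra participant)."""
    stratum_labels = np.asarray(stratum_labels)
    if len(stratum_labels) != n:
        raise ValueError("stratum label required for every participant")
    rng = np.random.default_rng(seed)
    arm = np.empty(n, dtype=object)
    for s in pd.unique(stratum_labels):
        idx = np.nonzero(stratum_labels == s)[0]
        if len(idx) < 2:
            raise ValueError(f"stratum {s!r} has fewer than 2 participants")
        order = rng.permutation(idx)
        k = (len(idx) + 1) // 2
        arm[order[:k]] = "intervention"
        arm[order[k:]] = "control"
    return arm


def normalized_influence(
    ei: CentralityTable, members: list[str], normalization: str = "max"
) -> pd.Series:
    """Nonnegative expected influence of the member items, scaled so the
    most influential member is 1 ('max') or the values sum to 1 ('sum').
    Negative expected influence is clipped to zero."""
    vals = ei.metric("expected_influence").reindex(members)
    if vals.isna().any():
        missing = list(vals.index[vals.isna()])
        raise ValueError(f"centrality table lacks target items: {missing}")
    clipped = vals.clip(lower=0.0)
    denom = clipped.max() if normalization == "max" else clipped.sum()
    if denom <= 0:
        raise ValueError(
            "all member expected influences are <= 0; no influence signal"
        )
    return clipped / denom


def deactivate(
    profiles_t0: pd.DataFrame,
    config: DeactivationConfig,
    ei: CentralityTable,
    catalog: ItemCatalog,
) -> pd.DataFrame:
    """Centrality-proportional symptom reduction.

    For target-domain item j with normalized influence e_j, the post
    score is x' = x - alpha * e_j * (x - 1): reductions scale the
    distance to the scale floor so profiles stay within 1..7. Non-target
    items are returned unchanged.
    """
    members = catalog.members(config.target_domain)
    if not members:
        raise ValueError(f"unknown target domain {config.target_domain!r}")
    e = normalized_influence(ei, members, config.normalization)
    out = profiles_t0.astype(float).copy()
    for item in members:
        x = out[item].to_numpy()
        x1 = x - config.alpha * float(e[item]) * (x - 1.0)
        if config.rounding == "integer":
            x1 = np.floor(x1 + 0.5)
        out[item] = np.clip(x1, 1.0, 7.0)
    return out


_MC_DRAWS = 4000


def _calibrate_latent(
    R0: np.ndarray,
    S_target: np.ndarray,
    cdf: np.ndarray,
    mid: np.ndarray,
    live: np.ndarray,
) -> np.ndarray:
    """Adjust pairwise latent correlations so that the copula's implied
    mid-rank (Spearman-style) correlation reproduces the observed one.

    The normal-scores Pearson start value is strongly attenuated for
    items with extreme floor mass; a monotone bisection against a fixed
    Monte-Carlo latent sample removes that bias pair by pair.
    """
    p = R0.shape[0]
    rng = np.random.default_rng(1234567)
    z1 = rng.standard_normal(_MC_DRAWS)
    z2 = rng.standard_normal(_MC_DRAWS)
    cuts = ndtri(np.clip(cdf[:, :-1], 1e-12, 1 - 1e-12))  # (p, 6)
    # mid-rank value of each item under the fixed z1 stream
    lev1 = (z1[None, :, None] > cuts[:, None, :]).sum(axis=2)  # (p, m)
    a = np.take_along_axis(mid, lev1, axis=1)  # (p, m)

    pairs = [
        (i, j)
        for i in range(p)
        for j in range(i + 1, p)
        if live[i] and live[j] and abs(S_target[i, j]) > 0.03
    ]
    if not pairs:
        return R0
    I = np.array([ij[0] for ij in pairs])
    J = np.array([ij[1] for ij in pairs])
    target = S_target[I, J]
    lo = np.full(len(pairs), -0.999)
    hi = np.full(len(pairs), 0.999)
    aI = a[I].astype(float)  # (P, m)
    aI_c = aI - aI.mean(axis=1, keepdims=True)
    aI_sd = np.sqrt((aI_c**2).sum(axis=1))
    cutsJ = cuts[J]  # (P, 6)
    midJ = mid[J]  # (P, 7)
    for _ in range(16):
        rho = (lo + hi) / 2
        y = rho[:, None] * z1[None, :] + np.sqrt(1 - rho**2)[:, None] * z2[None, :]
        lev = (y[:, :, None] > cutsJ[:, None, :]).sum(axis=2)
        b = np.take_along_axis(midJ, lev, axis=1).astype(float)
        b_c = b - b.mean(axis=1, keepdims=True)
        b_sd = np.sqrt((b_c**2).sum(axis=1))
        denom = aI_sd * b_sd
        implied = np.where(denom > 0, (aI_c * b_c).sum(axis=1) / np.where(denom > 0, denom, 1.0), 0.0)
        too_low = implied < target
        lo = np.where(too_low, rho, lo)
        hi = np.where(too_low, hi, rho)
    R = R0.copy()
    R[I, J] = R[J, I] = (lo + hi) / 2
    return R


def fit_copula(profiles: pd.DataFrame) -> CopulaModel:
    """Fit a Gaussian copula to ordinal profiles.

    Per item the empirical CDF is stored with mid-rank treatment of
    ties; the latent correlation starts from the Pearson correlation of
    the normal scores and is then calibrated pair by pair so the
    implied rank dependence matches the observed one (the raw
    normal-scores estimate is attenuated for heavily floored items).
    The matrix is PSD-repaired. Constant items are modeled as point
    masses (with a warning)."""
    n, p = profiles.shape
    if n < 50:
        raise ValueError("n >= 50 required to fit the copula")
    X = profiles.to_numpy(dtype=float)
    cdf = np.empty((p, 7))
    mid_table = np.empty((p, 7))
    scores = np.empty_like(X)
    midvals = np.empty_like(X)
    point_mass = np.zeros(p, dtype=bool)
    for j in range(p):
        counts = np.array([(X[:, j] == lv).sum() for lv in LEVELS], dtype=float)
        cum = np.cumsum(counts) / n
        cdf[j] = cum
        mid = cum - counts / (2 * n)  # mid-rank CDF value per level
        mid_table[j] = mid
        if (counts > 0).sum() < 2:
            point_mass[j] = True
            warnings.warn(
                f"item {profiles.columns[j]} is constant; modeled as point mass",
                stacklevel=2,
            )
            scores[:, j] = 0.0
            midvals[:, j] = 0.5
            continue
        level_idx = (X[:, j][:, None] == LEVELS[None, :]).argmax(axis=1)
        u = np.clip(mid[level_idx], 1e-10, 1 - 1e-10)
        midvals[:, j] = mid[level_idx]
        scores[:, j] = ndtri(u)
    latent = np.eye(p)
    live = ~point_mass
    if live.sum() >= 2:
        R0 = np.corrcoef(scores[:, live], rowvar=False)
        S_target = np.corrcoef(midvals[:, live], rowvar=False)
        R = _calibrate_latent(
            R0, S_target, cdf[live], mid_table[live], np.ones(live.sum(), bool)
        )
        vals, vecs = np.linalg.eigh(R)
        if vals[0] < 1e-10:
            vals = np.clip(vals, 1e-10, None)
            R = (vecs * vals) @ vecs.T
            d = np.sqrt(np.diag(R))
            R = R / np.outer(d, d)
        latent[np.ix_(live, live)] = (R + R.T) / 2
        np.fill_diagonal(latent, 1.0)
    return CopulaModel(
        columns=list(profiles.columns),
        cdf=cdf,
        latent_corr=latent,
        point_mass=point_mass,
    )


def sample_controls(
    model: CopulaModel, n: int, seed: int | None = None
) -> pd.DataFrame:
    """Draw synthetic profiles: latent multivariate normal -> uniform
    through the normal CDF -> levels through the right-continuous
    inverse of each item's empirical CDF."""
    rng = np.random.default_rng(seed)
    p = len(model.columns)
    corr = model.latent_corr + 1e-10 * np.eye(p)
    L = np.linalg.cholesky(corr)
    z = rng.standard_normal((n, p)) @ L.T
    u = ndtr(z)
    out = np.empty((n, p), dtype=int)
    for j in range(p):
        if model.point_mass[j]:
            level = int(LEVELS[np.argmax(model.cdf[j] >= 1.0 - 1e-12)])
            out[:, j] = level
        else:
            out[:, j] = LEVELS[np.searchsorted(model.cdf[j], u[:, j], side="left")]
    return pd.DataFrame(out, columns=model.columns)


def run_trial(
    items: pd.DataFrame,
    stratum: np.ndarray,
    ei: CentralityTable,
    catalog: ItemCatalog,
    config: DeactivationConfig | None = None,
    covariates: pd.DataFrame | None = None,
    seed: int | None = None,
) -> TrialState:
    """Full trial emulation: stratified 1:1 randomization, deactivation
    of the intervention arm, copula-resampled controls fitted per
    stratum on the control arm's baseline profiles."""
    config = config or DeactivationConfig()
    stratum = np.asarray(stratum)
    arm = stratified_randomize(len(items), stratum, seed=seed)
    t1 = items.astype(float).copy()
    imask = arm == "intervention"
    t1.loc[imask] = deactivate(items.loc[imask], config, ei, catalog)
    rng = np.random.default_rng(None if seed is None else seed + 1)
    for s in pd.unique(stratum):
        cmask = (arm == "control") & (stratum == s)
        if cmask.sum() == 0:
            continue
        # Fit on the control arm's baseline profiles; small strata fall
        # back to the whole stratum at T0 (still untreated data).
        fit_mask = cmask if cmask.sum() >= 50 else stratum == s
        model = fit_copula(items.loc[fit_mask])
        draw = sample_controls(
            model, int(cmask.sum()), seed=int(rng.integers(2**31 - 1))
        )
        t1.loc[cmask, model.columns] = draw.to_numpy(dtype=float)
    if covariates is None:
        covariates = pd.DataFrame(index=items.index)
    return TrialState(
        t0=items.copy(),
        t1=t1,
        arm=arm,
        stratum=stratum,
        covariates=covariates,
        config=config,
    )
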