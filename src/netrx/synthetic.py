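"""Synthetic cohort generator for ordinal symptom-network studies.

Emulates a clinical psychosis cohort rated on the 30-item PANSS plus a
single ordinal suicidal-ideation item (0-5) and a binary lifetime
suicide-attempt (SA) stratum. Generation is latent-then-threshold
(graded-response style): a multivariate normal latent vector with a
planted sparse partial-correlation structure is discretized through
per-item cut points calibrated to right-skewed clinical marginals;
ideation is drawn from an ordered-logit model on the mean of the four
Distress items with an SA main effect.

The two strata share all network structure except for configurable
stratum-specific mean shifts (higher Distress, lower Negative severity
in SA+) and an extra planted Negative-Distress cross-domain edge present
only in SA+.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr, ndtri

from .catalog import SUICIDE_NODE, ItemCatalog, default_catalog

__all__ = [
    "CohortConfig",
    "SyntheticCohort",
    "build_planted_network",
    "sample_cohort",
    "write_cohort",
    "read_cohort",
]

# Within-domain latent partial-correlation magnitudes. Each block must
# satisfy rho < 1/(m-1) for an equicorrelated precision block of size m
# to stay positive definite; values sit well inside that bound.
DEFAULT_WITHIN: dict[str, float] = {
    "POS": 0.12,
    "COG": 0.11,
    "HOS": 0.30,
    "DST": 0.25,
    "NEG": 0.17,
}

# Cross-domain / ideation bridges planted in every stratum.
DEFAULT_BRIDGES: tuple[tuple[str, str, float], ...] = (("G6", SUICIDE_NODE, 0.30),)

# Extra edges present only in the SA+ generator variant: the
# Negative-Distress cross-domain bridge.
DEFAULT_SA_BRIDGES: tuple[tuple[str, str, float], ...] = (("N2", "G6", 0.237),)

# Latent mean shifts (SD units) applied to SA+ participants, calibrated
# so the SA+ / SA- Distress domain-score medians land near 2.5 / 2.0 and
# the Negative medians near 1.67 / 2.0.
DEFAULT_SA_SHIFT: dict[str, float] = {"DST": 0.32, "NEG": -0.27}

# Per-domain latent severity offsets used to build the default per-item
# thresholds; calibrated so SA- domain-score medians land near the
# POS/COG/HOS/DST/NEG quartile profile of a chronic-psychosis sample
# (POS most severe, HOS floored near "absent").
DOMAIN_SEVERITY_OFFSET: dict[str, float] = {
    "POS": 0.08,
    "COG": -0.32,
    "HOS": -1.56,
    "DST": -0.35,
    "NEG": -0.30,
}

# Baseline marginal for a domain at offset 0: ~55% of the mass on levels
# 1-2 and a right tail that keeps domain-score interquartile ranges near
# the clinical quartile profile (extreme levels 6-7 are rare).
_BASE_LEVEL_PROBS = np.array([0.30, 0.25, 0.20, 0.12, 0.07, 0.04, 0.02])

# Ordered-logit defaults for ideation: P(SI <= k) = expit(tau_k - eta),
# eta = slope * (mean DST score - center) + sa_effect * SA. The slope
# makes ideation strongly (though not deterministically) driven by
# Distress, so that a classifier on the items can reach the mid-0.80s
# accuracy reported for real cohorts; thresholds give the floor-heavy
# per-stratum level distributions seen clinically (~84% of SA- and
# ~60% of SA+ at level 0) and zero mass at the instrument's top level 6.
DEFAULT_IDEATION: dict[str, object] = {
    "thresholds": (5.88, 9.10, 11.86, 15.32, 19.93),
    "slope": 5.0,
    "sa_effect": 1.05,
    "center": 2.0,
}

DEFAULT_AGE_DIST: dict[str, float] = {
    "median_sa_minus": 23.0,
    "median_sa_plus": 32.0,
    "min": 18.0,
    "max": 65.0,
}
DEFAULT_SEX_DIST: dict[str, float] = {
    "p_female_sa_minus": 0.25,
    "p_female_sa_plus": 0.39,
}

_RIDGE_FLOOR = 1e-6
_MAX_RIDGE_STEPS = 100
# Fixed per-participant draw budget: 30 latent + SA + ideation + age + sex.
_DRAWS_PER_PARTICIPANT = 34


def default_marginal_thresholds(
    catalog: ItemCatalog | None = None,
    level_probs: np.ndarray = _BASE_LEVEL_PROBS,
    severity_offset: Mapping[str, float] = DOMAIN_SEVERITY_OFFSET,
) -> dict[str, tuple[float, ...]]:
    """Per-item latent cut points implied by a target marginal.

    The baseline marginal is shared across items; per-domain severity
    offsets shift the cut points so that more severe domains put more
    mass on high levels.
    """
    catalog = catalog or default_catalog()
    cum = np.cumsum(level_probs)[:-1]
    base = ndtri(cum)
    return {
        code: tuple(base - severity_offset[catalog.domain_of[code]])
        for code in catalog.codes
    }


@dataclass
class CohortConfig:
    """Parameters of the planted generative model.

    All partial-correlation magnitudes refer to the latent Gaussian
    layer; item scores are the thresholded levels 1-7.
    """

    n: int = 313
    partial_corr_within: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_WITHIN)
    )
    bridge_edges: tuple[tuple[str, str, float], ...] = DEFAULT_BRIDGES
    sa_bridge_edges: tuple[tuple[str, str, float], ...] = DEFAULT_SA_BRIDGES
    sa_plus_fraction: float = 0.344
    sa_shift: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SA_SHIFT))
    ideation_coeffs: dict[str, object] = field(
        default_factory=lambda: dict(DEFAULT_IDEATION)
    )
    marginal_thresholds: dict[str, tuple[float, ...]] | None = None
    age_dist: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_AGE_DIST))
    sex_dist: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SEX_DIST))
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.sa_plus_fraction < 1.0:
            raise ValueError("sa_plus_fraction must lie in (0, 1)")
        thr = np.asarray(self.ideation_coeffs["thresholds"], dtype=float)
        if thr.shape != (5,):
            raise ValueError("ideation_coeffs must provide exactly 5 thresholds")
        if not np.all(np.diff(thr) > 0):
            raise ValueError("ideation thresholds must be strictly increasing")
        for dom, rho in self.partial_corr_within.items():
            if not 0.0 <= rho < 1.0:
                raise ValueError(f"partial_corr_within[{dom}] outside [0, 1)")
        if self.marginal_thresholds is not None:
            for code, cuts in self.marginal_thresholds.items():
                if not np.all(np.diff(cuts) > 0):
                    raise ValueError(
                        f"marginal thresholds for {code} not strictly increasing"
                    )

    def thresholds(self, catalog: ItemCatalog) -> dict[str, tuple[float, ...]]:
        if self.marginal_thresholds is not None:
            return self.marginal_thresholds
        return default_marginal_thresholds(catalog)

    def hash(self) -> str:
        payload = json.dumps(
            {
                k: (sorted(v.items()) if isinstance(v, dict) else v)
                for k, v in self.__dict__.items()
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.blake2s(payload.encode()).hexdigest()[:16]


@dataclass
class SyntheticCohort:
    """A sampled cohort: items (n x 30, levels 1-7), ideation (0-5),
    SA stratum, age and sex, plus a provenance hash of the config."""

    items: pd.DataFrame
    ideation: np.ndarray
    sa: np.ndarray
    age: np.ndarray
    sex: np.ndarray
    config_hash: str = ""

    def __post_init__(self) -> None:
        vals = self.items.to_numpy()
        if not np.isin(vals, np.arange(1, 8)).all():
            raise ValueError("item scores must be integers in 1..7")
        if not np.isin(self.ideation, np.arange(6)).all():
            raise ValueError("ideation must be integers in 0..5")

    @property
    def n(self) -> int:
        return len(self.items)

    def frame(self) -> pd.DataFrame:
        out = self.items.copy()
        out["SI"] = self.ideation
        out["SA"] = self.sa
        out["AGE"] = self.age
        out["SEX"] = self.sex
        return out


def _edge_entries(
    edges: Iterable[tuple[str, str, float]], labels: Sequence[str]
) -> list[tuple[int, int, float]]:
    index = {lab: i for i, lab in enumerate(labels)}
    out = []
    for a, b, w in edges:
        if a not in index or b not in index:
            raise ValueError(f"bridge edge ({a}, {b}) names an unknown node")
        if a == b:
            raise ValueError(f"bridge edge ({a}, {b}) is a self loop")
        out.append((index[a], index[b], float(w)))
    return out


def build_planted_network(
    config: CohortConfig,
    catalog: ItemCatalog | None = None,
    stratum: str = "SA-",
) -> pd.DataFrame:
    """Latent partial-correlation matrix over the 30 items + ideation node.

    Within-domain entries take the per-domain magnitude, planted bridges
    their configured weights, all else zero. The implied precision matrix
    (unit diagonal, negated off-diagonal) is ridge-adjusted on the
    diagonal until its smallest eigenvalue reaches 1e-6 and the partial
    correlations are re-derived, so the result is always a valid model.

    ``stratum="SA+"`` additionally plants the SA-only bridge edges.
    """
    catalog = catalog or default_catalog()
    labels = list(catalog.codes) + [SUICIDE_NODE]
    p = len(labels)
    P = np.zeros((p, p))
    for dom, rho in config.partial_corr_within.items():
        idx = [catalog.index_of(c) for c in catalog.members(dom)]
        for i in idx:
            for j in idx:
                if i != j:
                    P[i, j] = rho
    edges = list(config.bridge_edges)
    if stratum == "SA+":
        edges += list(config.sa_bridge_edges)
    elif stratum != "SA-":
        raise ValueError("stratum must be 'SA+' or 'SA-'")
    for i, j, w in _edge_entries(edges, labels):
        P[i, j] = P[j, i] = w

    theta = np.eye(p) - P
    for _ in range(_MAX_RIDGE_STEPS):
        smallest = np.linalg.eigvalsh(theta)[0]
        if smallest >= _RIDGE_FLOOR:
            break
        theta = theta + (_RIDGE_FLOOR - smallest) * np.eye(p)
    else:
        raise ValueError(
            "planted precision not positive definite after ridge adjustment; "
            f"offending weights: within={config.partial_corr_within}, "
            f"bridges={edges}"
        )
    d = np.sqrt(np.diag(theta))
    out = -theta / np.outer(d, d)
    np.fill_diagonal(out, 0.0)
    return pd.DataFrame(out, index=labels, columns=labels)


def _item_correlation_from_partials(P_items: np.ndarray) -> np.ndarray:
    """Correlation matrix of the latent items implied by their partial
    correlations (unit-diagonal precision convention)."""
    theta = np.eye(P_items.shape[0]) - P_items
    sigma = np.linalg.inv(theta)
    d = np.sqrt(np.diag(sigma))
    return sigma / np.outer(d, d)


def sample_cohort(
    config: CohortConfig,
    catalog: ItemCatalog | None = None,
    return_latent: bool = False,
) -> SyntheticCohort | tuple[SyntheticCohort, np.ndarray]:
    """Draw a cohort from the planted model; deterministic given the seed.

    Randomness is consumed as one participant-major block of 34 standard
    normals per participant, so cohorts generated with the same seed but
    different ``n`` share their leading participants.
    ``return_latent`` additionally returns the pre-threshold latent item
    matrix (for parameter-recovery checks).
    """
    catalog = catalog or default_catalog()
    if config.n < 10:
        raise ValueError("n < 10: too small for any downstream estimator")
    n = config.n
    n_items = len(catalog.codes)

    chol = {}
    for stratum in ("SA-", "SA+"):
        planted = build_planted_network(config, catalog, stratum=stratum)
        corr = _item_correlation_from_partials(
            planted.to_numpy()[:n_items, :n_items]
        )
        chol[stratum] = np.linalg.cholesky(corr)

    rng = np.random.default_rng(config.seed)
    z = rng.standard_normal((n, _DRAWS_PER_PARTICIPANT))
    u_sa, z_si, z_age, z_sex = z[:, 30], z[:, 31], z[:, 32], z[:, 33]
    sa = (ndtr(u_sa) < config.sa_plus_fraction).astype(int)

    shift = np.zeros(n_items)
    for dom, s in config.sa_shift.items():
        for code in catalog.members(dom):
            shift[catalog.index_of(code)] = s
    latent = np.empty((n, n_items))
    for stratum, mask in (("SA-", sa == 0), ("SA+", sa == 1)):
        latent[mask] = z[mask, :n_items] @ chol[stratum].T
    latent[sa == 1] += shift

    cuts = np.array([config.thresholds(catalog)[c] for c in catalog.codes])
    items = (latent[:, :, None] > cuts[None, :, :]).sum(axis=2) + 1
    item_df = pd.DataFrame(items.astype(int), columns=list(catalog.codes))

    dst_cols = catalog.members("DST")
    dst_mean = item_df[dst_cols].to_numpy().mean(axis=1)
    ic = config.ideation_coeffs
    eta = float(ic["slope"]) * (dst_mean - float(ic["center"])) + float(
        ic["sa_effect"]
    ) * sa
    cum = expit(np.asarray(ic["thresholds"], dtype=float)[None, :] - eta[:, None])
    u_si = ndtr(z_si)
    ideation = (u_si[:, None] > cum).sum(axis=1)

    ad = config.age_dist
    scale_minus = (ad["median_sa_minus"] - ad["min"]) / np.log(2.0)
    scale_plus = (ad["median_sa_plus"] - ad["min"]) / np.log(2.0)
    scale = np.where(sa == 1, scale_plus, scale_minus)
    age = ad["min"] - scale * np.log1p(-ndtr(z_age))
    age = np.clip(np.round(age), ad["min"], ad["max"])

    sd = config.sex_dist
    p_female = np.where(sa == 1, sd["p_female_sa_plus"], sd["p_female_sa_minus"])
    sex = (ndtr(z_sex) < p_female).astype(int)

    cohort = SyntheticCohort(
        items=item_df,
        ideation=ideation.astype(int),
        sa=sa,
        age=age,
        sex=sex.astype(int),
        config_hash=config.hash(),
    )
    if return_latent:
        return cohort, latent
    return cohort


_EXPECTED_EXTRA = ["SI", "SA", "AGE", "SEX"]


def write_cohort(cohort: SyntheticCohort, path) -> None:
    """Write a cohort as CSV with columns P1..G16, SI, SA, AGE, SEX."""
    cohort.frame().to_csv(path, index=False)


def read_cohort(path, catalog: ItemCatalog | None = None) -> SyntheticCohort:
    """Read and validate a cohort CSV written by :func:`write_cohort`.

    Raises on missing columns, non-integer item values, and values
    outside the instrument ranges, naming the offending cell.
    """
    catalog = catalog or default_catalog()
    df = pd.read_csv(path)
    expected = list(catalog.codes) + _EXPECTED_EXTRA
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file missing columns: {missing}")

    def _check_int_range(col: str, lo: int, hi: int) -> np.ndarray:
        vals = df[col].to_numpy()
        as_int = np.asarray(vals, dtype=float)
        if not np.all(as_int == np.round(as_int)):
            row = int(np.nonzero(as_int != np.round(as_int))[0][0])
            raise ValueError(f"non-integer value in column {col}, row {row}")
        as_int = as_int.astype(int)
        bad = (as_int < lo) | (as_int > hi)
        if bad.any():
            row = int(np.nonzero(bad)[0][0])
            raise ValueError(
                f"value {as_int[row]} outside [{lo}, {hi}] in column {col}, row {row}"
            )
        return as_int

    items = pd.DataFrame(
        {c: _check_int_range(c, 1, 7) for c in catalog.codes},
        columns=list(catalog.codes),
    )
    ideation = _check_int_range("SI", 0, 5)
    sa = _check_int_range("SA", 0, 1)
    sex = _check_int_range("SEX", 0, 1)
    age = df["AGE"].to_numpy(dtype=float)
    if np.isnan(age).any():
        row = int(np.nonzero(np.isnan(age))[0][0])
        raise ValueError(f"missing AGE at row {row}")
    return SyntheticCohort(
        items=items, ideation=ideation, sa=sa, age=age, sex=sex
    )
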