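"""Evaluation of emulated-intervention effects on predicted ideation.

A small feed-forward multi-class classifier (two hidden layers,
logistic activations) is trained on baseline symptom profiles to
predict the ordinal ideation level, with accuracy reported both by
10-fold cross-validation on the 70% training portion and on the 30%
held-out split. The trained model scores post-intervention profiles in
both arms; arms are compared per stratum with the tie-corrected
Wilcoxon-Mann-Whitney test, covariate balance with standardized mean
differences, and robustness with a median-age-split sensitivity
analysis. A cluster-level suicide network re-estimated per arm at T1
(using predicted ideation as the suicide variable) summarizes the
post-intervention network contrast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import StratifiedKFold, cross_val_score, train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .catalog import SUICIDE_NODE, ItemCatalog
from .communities import aggregate_clusters, suicide_network
from .ggm import GGMNetwork, GlassoConfig, bootstrap_edge_ci
from .trial import TrialState

__all__ = [
    "ClassifierSpec",
    "TrainedClassifier",
    "PredictedIdeation",
    "ArmComparison",
    "train_classifier",
    "predict_ideation",
    "compare_arms",
    "covariate_balance",
    "age_stratified_sensitivity",
    "post_network_contrast",
]


@dataclass
class ClassifierSpec:
    """Two-hidden-layer feed-forward classifier configuration.

    ``l2`` is the weight penalty; the default (0.5) keeps the network
    from memorizing baseline profiles, which matters because the same
    profiles reappear at T1 in the intervention arm.
    """

    hidden_layers: tuple[int, int] = (16, 8)
    activation: str = "logistic"
    max_epochs: int = 800
    learning_rate_init: float = 0.01
    l2: float = 0.5
    train_fraction: float = 0.7
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.hidden_layers) != 2:
            raise ValueError("the classifier uses exactly two hidden layers")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")


@dataclass
class TrainedClassifier:
    model: object
    spec: ClassifierSpec
    cv_accuracy: float
    test_accuracy: float
    classes: np.ndarray


@dataclass
class PredictedIdeation:
    """Per-participant predicted ideation with arm/stratum labels."""

    table: pd.DataFrame  # columns: predicted, arm, stratum, time (+ optional extras)

    def frequencies(self) -> pd.DataFrame:
        """Level-frequency table per (arm, time); rows sum to 1."""
        out = (
            self.table.groupby(["arm", "time"])["predicted"]
            .value_counts(normalize=True)
            .unstack(fill_value=0.0)
        )
        return out.reindex(columns=range(6), fill_value=0.0)

    def levels(self, arm: str, time: str = "T1", stratum: str | None = None) -> np.ndarray:
        t = self.table
        m = (t.arm == arm) & (t.time == time)
        if stratum is not None:
            m &= t.stratum == stratum
        return t.loc[m, "predicted"].to_numpy()


@dataclass
class ArmComparison:
    u_statistic: float
    p_value: float
    rank_biserial: float
    n_intervention: int
    n_control: int
    level0_delta: dict = field(default_factory=dict)


def _build_mlp(spec: ClassifierSpec):
    return make_pipeline(
        StandardScaler(),
        MLPClassifier(
            hidden_layer_sizes=tuple(spec.hidden_layers),
            activation=spec.activation,
            max_iter=spec.max_epochs,
            learning_rate_init=spec.learning_rate_init,
            alpha=spec.l2,
            random_state=spec.seed,
        ),
    )


def _split_key(y: np.ndarray) -> np.ndarray:
    """Stratification key: ordinal classes too rare to stratify on
    (fewer than 2 members) are merged with the nearest lower level."""
    key = y.copy()
    classes, counts = np.unique(y, return_counts=True)
    rare = classes[counts < 2]
    for c in rare:
        lower = classes[(classes < c) & ~np.isin(classes, rare)]
        key[y == c] = lower.max() if len(lower) else classes[~np.isin(classes, rare)][0]
    return key


def train_classifier(
    items: pd.DataFrame, ideation: np.ndarray, spec: ClassifierSpec | None = None
) -> TrainedClassifier:
    """Train the ideation classifier on baseline profiles.

    Accuracy is evaluated with a 70/30 stratified split (10-fold CV on
    the training portion; held-out accuracy from a model fit on the
    training portion only), then the final model is trained on the full
    baseline sample. Deterministic given the spec seed.
    """
    spec = spec or ClassifierSpec()
    y = np.asarray(ideation)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("stratification error: at least 2 ideation classes required")
    X = items.to_numpy(dtype=float)
    key = _split_key(y)
    X_tr, X_te, y_tr, y_te = train_test_split(
        X,
        y,
        train_size=spec.train_fraction,
        stratify=key,
        random_state=spec.seed,
    )
    if len(np.unique(y_tr)) < 2:
        raise ValueError("stratification error: a class is absent from training")
    tr_counts = np.unique(_split_key(y_tr), return_counts=True)[1]
    folds = max(2, min(spec.cv_folds, int(tr_counts.min())))
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=spec.seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        cv_acc = cross_val_score(_build_mlp(spec), X_tr, _split_key(y_tr), cv=cv).mean()
        eval_model = _build_mlp(spec)
        eval_model.fit(X_tr, y_tr)
        test_acc = eval_model.score(X_te, y_te)
        model = _build_mlp(spec)
        model.fit(X, y)
    return TrainedClassifier(
        model=model,
        spec=spec,
        cv_accuracy=float(cv_acc),
        test_accuracy=float(test_acc),
        classes=classes,
    )


def predict_ideation(
    clf: TrainedClassifier,
    profiles: pd.DataFrame,
    arm: np.ndarray,
    stratum: np.ndarray,
    time: str = "T1",
) -> PredictedIdeation:
    """Argmax predicted ideation level per participant."""
    X = profiles.to_numpy(dtype=float)
    if X.min() < 1 or X.max() > 7:
        raise ValueError("item values outside the 1..7 range")
    pred = clf.model.predict(X)
    return PredictedIdeation(
        table=pd.DataFrame(
            {
                "predicted": pred.astype(int),
                "arm": np.asarray(arm),
                "stratum": np.asarray(stratum),
                "time": time,
            }
        )
    )


def _exact_wmw(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided WMW by enumerating every split of the pooled
    sample; U uses midranks so ties are handled exactly."""
    import itertools

    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    total = len(pooled)
    offset = n1 * (n1 + 1) / 2
    obs = ranks[:n1].sum() - offset
    mid = n1 * len(y) / 2
    count = denom = 0
    for combo in itertools.combinations(range(total), n1):
        u = ranks[list(combo)].sum() - offset
        count += abs(u - mid) >= abs(obs - mid) - 1e-12
        denom += 1
    return float(obs), count / denom


def compare_arms(
    pred_intervention: np.ndarray, pred_control: np.ndarray
) -> ArmComparison:
    """Two-sided Wilcoxon-Mann-Whitney comparison of predicted levels
    (tie-corrected normal approximation with continuity correction).
    The rank-biserial sign gives the effect direction: negative means
    the intervention arm sits at lower ideation levels."""
    x = np.asarray(pred_intervention, dtype=float)
    y = np.asarray(pred_control, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both arms must be non-empty")
    n1, n2 = len(x), len(y)
    if np.ptp(np.concatenate([x, y])) == 0:
        u, p = n1 * n2 / 2.0, 1.0
    elif n1 + n2 <= 18:
        # small arms: exact two-sided permutation p over all splits,
        # valid under ties (the asymptotic approximation is not reliable
        # at these sizes)
        u, p = _exact_wmw(x, y)
    else:
        u, p = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    rb = 2.0 * u / (n1 * n2) - 1.0
    return ArmComparison(
        u_statistic=float(u),
        p_value=float(min(max(p, np.nextafter(0, 1)), 1.0)),
        rank_biserial=float(rb),
        n_intervention=n1,
        n_control=n2,
    )


def covariate_balance(
    trial: TrialState, covariates: list[str] | None = None
) -> pd.DataFrame:
    """Standardized mean differences (intervention - control over the
    pooled SD) per covariate, within each stratum and in the full
    sample. Zero pooled SD yields SMD 0 with a warning."""
    cov = trial.covariates
    covariates = covariates or list(cov.columns)
    if not covariates:
        raise ValueError("no covariates available")
    rows = []
    strata = ["ALL"] + list(pd.unique(trial.stratum))
    for s in strata:
        smask = np.ones(len(cov), dtype=bool) if s == "ALL" else trial.stratum == s
        for c in covariates:
            a = cov.loc[smask & (trial.arm == "intervention"), c].to_numpy(float)
            b = cov.loc[smask & (trial.arm == "control"), c].to_numpy(float)
            pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
            if pooled == 0:
                warnings.warn(
                    f"zero pooled SD for {c} in stratum {s}; SMD set to 0",
                    stacklevel=2,
                )
                smd = 0.0
            else:
                smd = (a.mean() - b.mean()) / pooled
            rows.append({"stratum": s, "covariate": c, "smd": float(smd)})
    return pd.DataFrame(rows)


def age_stratified_sensitivity(
    trial: TrialState,
    pred_t0: PredictedIdeation,
    pred_t1: PredictedIdeation,
    age_column: str = "AGE",
) -> pd.DataFrame:
    """T0 -> T1 change in the no-ideation (level 0) proportion per
    (SA stratum x age half x arm) cell; the age split is at the stratum
    median with ties assigned to the younger half. Cells with < 5
    participants are flagged but still reported."""
    if age_column not in trial.covariates.columns:
        raise ValueError(f"covariate {age_column!r} not available")
    age = trial.covariates[age_column].to_numpy(float)
    t0 = pred_t0.table["predicted"].to_numpy()
    t1 = pred_t1.table["predicted"].to_numpy()
    rows = []
    for s in pd.unique(trial.stratum):
        smask = trial.stratum == s
        med = np.median(age[smask])
        for half, hmask in (
            ("younger", smask & (age <= med)),
            ("older", smask & (age > med)),
        ):
            for arm in ("intervention", "control"):
                m = hmask & (trial.arm == arm)
                n_cell = int(m.sum())
                p0_t0 = float((t0[m] == 0).mean()) if n_cell else np.nan
                p0_t1 = float((t1[m] == 0).mean()) if n_cell else np.nan
                rows.append(
                    {
                        "stratum": s,
                        "age_half": half,
                        "arm": arm,
                        "n": n_cell,
                        "p0_t0": p0_t0,
                        "p0_t1": p0_t1,
                        "p0_change": p0_t1 - p0_t0 if n_cell else np.nan,
                        "small_cell": n_cell < 5,
                    }
                )
    return pd.DataFrame(rows)


def post_network_contrast(
    trial: TrialState,
    pred_t0: PredictedIdeation,
    pred_t1: PredictedIdeation,
    catalog: ItemCatalog,
    config: GlassoConfig | None = None,
    bootstrap_B: int = 200,
    seed: int | None = None,
    target_domain: str = "DST",
) -> dict:
    """Cluster-level suicide networks at baseline and per arm at T1.

    At T1 the suicide variable is the predicted ideation level (no
    observed post-intervention ideation exists in an emulated trial).
    Returns the networks plus the target-domain/suicide edge with a
    bootstrap CI per arm.
    """
    config = config or GlassoConfig(n_lambdas=30)
    out: dict[str, object] = {}

    def _edge_with_ci(scores: pd.DataFrame, key: str) -> GGMNetwork:
        net = suicide_network(scores, config)
        inference = bootstrap_edge_ci(scores, B=bootstrap_B, config=config, seed=seed)
        rec = inference.lookup(target_domain, SUICIDE_NODE)
        out[f"{key}_edge"] = {
            "estimate": float(rec.estimate),
            "lower": float(rec.lower),
            "upper": float(rec.upper),
        }
        return net

    t0_scores = aggregate_clusters(
        trial.t0, catalog, ideation=pred_t0.table["predicted"].to_numpy()
    )
    out["t0"] = _edge_with_ci(t0_scores, "t0")
    for arm in ("intervention", "control"):
        m = trial.arm == arm
        scores = aggregate_clusters(
            trial.t1.loc[m],
            catalog,
            ideation=pred_t1.table.loc[m, "predicted"].to_numpy(),
        )
        out[arm] = _edge_with_ci(scores, arm)
    return out
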