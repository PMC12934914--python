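"""End-to-end pipeline orchestration.

Runs the full analysis — simulate, estimate, communities, centrality,
compare, trial, evaluate — writing one artifact per stage plus a
manifest of output hashes. Stage randomness comes from named substreams
(a hash of the stage name mixed with the global seed), so adding or
reordering stages never perturbs the draws of the others, and a rerun
with the same configuration reproduces identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import serialize
from .catalog import SUICIDE_NODE, default_catalog
from .centrality import bridge_report, centrality, select_targets
from .communities import (
    aggregate_clusters,
    detect_communities,
    label_partition,
    permanova_clusters,
    suicide_network,
)
from .evaluate import (
    ClassifierSpec,
    age_stratified_sensitivity,
    compare_arms,
    covariate_balance,
    post_network_contrast,
    predict_ideation,
    train_classifier,
)
from .ggm import GlassoConfig, bootstrap_edge_ci, correlation_matrix, estimate_network
from .stratified import (
    FusedConfig,
    cross_domain_association,
    fused_glasso,
    network_comparison_test,
    within_cluster_connectivity,
)
from .synthetic import CohortConfig, sample_cohort, write_cohort
from .trial import DeactivationConfig, run_trial

logger = logging.getLogger("netrx")

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "validate_config", "stage_seed"]


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class SimulateOptions(_Model):
    n: int = Field(313, ge=10)


class EstimateOptions(_Model):
    gamma: float = Field(0.5, ge=0)
    n_lambdas: int = Field(60, ge=2)
    lambda_min_ratio: float = Field(0.01, gt=0, lt=1)
    correlation_kind: str = "pearson"

    def glasso(self) -> GlassoConfig:
        return GlassoConfig(
            gamma=self.gamma,
            n_lambdas=self.n_lambdas,
            lambda_min_ratio=self.lambda_min_ratio,
            correlation_kind=self.correlation_kind,
        )


class CommunityOptions(_Model):
    steps: int = 4
    permanova_permutations: int = 999


class CentralityOptions(_Model):
    bootstrap_B: int = Field(500, ge=200)


class CompareOptions(_Model):
    nct_permutations: int = Field(200, ge=100)
    level: str = "cluster"  # cluster-level keeps the permutation loop tractable
    lambda1: float | None = None
    lambda2: float | None = None


class TrialOptions(_Model):
    target_domain: str = "DST"
    alpha: float = Field(0.5, ge=0, le=1)
    normalization: str = "max"
    rounding: str = "continuous"

    def deactivation(self) -> DeactivationConfig:
        return DeactivationConfig(
            target_domain=self.target_domain,
            alpha=self.alpha,
            normalization=self.normalization,
            rounding=self.rounding,
        )


class EvaluateOptions(_Model):
    hidden_layers: tuple[int, int] = (16, 8)
    max_epochs: int = 600
    bootstrap_B: int = 200


class RunConfig(_Model):
    seed: int = 0
    out_dir: str = "netrx_run"
    verbosity: int = 1
    simulate: SimulateOptions = SimulateOptions()
    estimate: EstimateOptions = EstimateOptions()
    communities: CommunityOptions = CommunityOptions()
    centrality: CentralityOptions = CentralityOptions()
    compare: CompareOptions = CompareOptions()
    trial: TrialOptions = TrialOptions()
    evaluate: EvaluateOptions = EvaluateOptions()


@dataclass
class RunManifest:
    stages: list[dict]
    seed: int
    config: dict

    def to_dict(self) -> dict:
        return {"seed": self.seed, "config": self.config, "stages": self.stages}


class ConfigError(ValueError):
    def __init__(self, errors: list[str]):
        super().__init__("; ".join(errors))
        self.errors = errors


def validate_config(path: str | Path) -> RunConfig:
    """Load, schema-check and default-fill a JSON run configuration.

    All violations (unknown keys, range errors) are collected and
    reported together; string-typed numbers are coerced with a warning.
    """
    text = Path(path).read_text().strip()
    raw = json.loads(text) if text else {}
    _warn_string_numbers(raw, [])
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        msgs = [
            f"{'.'.join(str(x) for x in err['loc'])}: {err['msg']}"
            for err in exc.errors()
        ]
        raise ConfigError(msgs) from exc


def _warn_string_numbers(node, path: list[str]) -> None:
    if isinstance(node, dict):
        for k, v in node.items():
            _warn_string_numbers(v, path + [str(k)])
    elif isinstance(node, str):
        try:
            float(node)
        except ValueError:
            return
        warnings.warn(
            f"config field {'.'.join(path)}: string {node!r} coerced to number",
            stacklevel=2,
        )


def stage_seed(global_seed: int, stage: str) -> int:
    """Named substream: hash of the stage name mixed with the seed."""
    digest = hashlib.blake2s(f"{stage}:{global_seed}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute all stages in order; returns the manifest (also written
    to ``out_dir/manifest.json``). A stage failure aborts with the stage
    name after writing the partial manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    catalog = default_catalog()
    stages: list[dict] = []
    manifest = RunManifest(stages=stages, seed=config.seed, config=config.model_dump())

    def record(stage: str, files: list[Path]) -> None:
        stages.append(
            {
                "stage": stage,
                "outputs": {str(f): _hash_file(f) for f in files},
                "seed": stage_seed(config.seed, stage),
                "timestamp": time.time(),
            }
        )
        if config.verbosity:
            logger.info("stage %s done: %s", stage, [str(f) for f in files])

    def fail(stage: str, exc: Exception) -> None:
        (out / "manifest.json").write_text(json.dumps(manifest.to_dict(), indent=1))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    try:  # ---- simulate
        cohort = sample_cohort(
            CohortConfig(n=config.simulate.n, seed=stage_seed(config.seed, "simulate")),
            catalog,
        )
        cohort_path = out / "cohort.csv"
        write_cohort(cohort, cohort_path)
        record("simulate", [cohort_path])
    except Exception as exc:
        fail("simulate", exc)

    glasso_cfg = config.estimate.glasso()
    try:  # ---- estimate
        net = estimate_network(cohort.items, glasso_cfg)
        net_path = out / "net.json"
        serialize.write_network(net, net_path)
        record("estimate", [net_path])
    except Exception as exc:
        fail("estimate", exc)

    try:  # ---- communities (+ PERMANOVA validation)
        partition = label_partition(
            detect_communities(net, steps=config.communities.steps), catalog
        )
        S, _ = correlation_matrix(cohort.items, glasso_cfg.correlation_kind)
        F, p_perm = permanova_clusters(
            S,
            partition,
            n_perm=config.communities.permanova_permutations,
            seed=stage_seed(config.seed, "permanova"),
        )
        part_path = out / "partition.json"
        payload = serialize.partition_to_dict(partition)
        payload["permanova"] = {"F": F, "p": p_perm}
        part_path.write_text(json.dumps(payload, indent=1))
        record("communities", [part_path])
    except Exception as exc:
        fail("communities", exc)

    try:  # ---- centrality, suicide network, bridges, target selection
        item_cent = centrality(net)
        scores = aggregate_clusters(cohort.items, partition, ideation=cohort.ideation)
        sui_net = suicide_network(scores, glasso_cfg)
        inference = bootstrap_edge_ci(
            scores,
            B=config.centrality.bootstrap_B,
            config=glasso_cfg,
            seed=stage_seed(config.seed, "bootstrap"),
        )
        bridges = bridge_report(sui_net, inference)
        cluster_cent = centrality(sui_net)
        targets = select_targets(item_cent, cluster_cent, bridges, catalog)
        cent_path = out / "centrality.tsv"
        item_cent.table.to_csv(cent_path, sep="\t")
        targets_path = out / "targets.json"
        targets_path.write_text(
            json.dumps(
                {
                    "ranking": targets.to_dict(orient="records"),
                    "bridges": bridges.edges.to_dict(orient="records"),
                },
                indent=1,
                default=float,
            )
        )
        record("centrality", [cent_path, targets_path])
    except Exception as exc:
        fail("centrality", exc)

    try:  # ---- stratified comparison
        sa_mask = cohort.sa == 1
        by_group_items = {
            "SA+": cohort.items.loc[sa_mask],
            "SA-": cohort.items.loc[~sa_mask],
        }
        fused = fused_glasso(
            by_group_items,
            FusedConfig(
                lambda1=config.compare.lambda1, lambda2=config.compare.lambda2
            ),
        )
        if config.compare.level == "cluster":
            nct_data = {
                g: aggregate_clusters(items_g, partition)
                for g, items_g in by_group_items.items()
            }
        else:
            nct_data = by_group_items
        nct = network_comparison_test(
            nct_data["SA+"],
            nct_data["SA-"],
            n_perm=config.compare.nct_permutations,
            seed=stage_seed(config.seed, "nct"),
            config=glasso_cfg,
        )
        comp = {
            "nct": {
                "p_global_strength": nct.p_global_strength,
                "p_structure": nct.p_structure,
                "observed_strength_diff": nct.observed_strength_diff,
                "observed_structure_diff": nct.observed_structure_diff,
            },
            "fused": {
                g: serialize.network_to_dict(fused[g]) for g in fused.networks
            },
            "within_cluster_connectivity": {
                g: within_cluster_connectivity(fused[g], partition).to_dict()
                for g in fused.networks
            },
            "cross_domain": {},
        }
        for g, items_g in by_group_items.items():
            sc = aggregate_clusters(
                items_g, partition, ideation=cohort.ideation[items_g.index]
            )
            rho, p_rho = cross_domain_association(sc, "NEG", "DST")
            prho, pp = cross_domain_association(sc, "NEG", "DST", control=SUICIDE_NODE)
            comp["cross_domain"][g] = {
                "neg_dst_rho": rho,
                "neg_dst_p": p_rho,
                "neg_dst_partial_rho": prho,
                "neg_dst_partial_p": pp,
            }
        nct_path = out / "nct.json"
        nct_path.write_text(json.dumps(comp, indent=1, default=float))
        record("compare", [nct_path])
    except Exception as exc:
        fail("compare", exc)

    try:  # ---- trial emulation
        stratum = np.where(cohort.sa == 1, "SA+", "SA-")
        covars = pd.DataFrame(
            {"AGE": cohort.age, "SEX": cohort.sex}, index=cohort.items.index
        )
        trial = run_trial(
            cohort.items,
            stratum,
            item_cent,
            catalog,
            config=config.trial.deactivation(),
            covariates=covars,
            seed=stage_seed(config.seed, "trial"),
        )
        trial_path = out / "trial.csv"
        trial.long_frame().to_csv(trial_path, index=False)
        record("trial", [trial_path])
    except Exception as exc:
        fail("trial", exc)

    try:  # ---- evaluate
        spec = ClassifierSpec(
            hidden_layers=tuple(config.evaluate.hidden_layers),
            max_epochs=config.evaluate.max_epochs,
            seed=stage_seed(config.seed, "classifier"),
        )
        clf = train_classifier(cohort.items, cohort.ideation, spec)
        pred_t0 = predict_ideation(clf, trial.t0, trial.arm, trial.stratum, time="T0")
        pred_t1 = predict_ideation(clf, trial.t1, trial.arm, trial.stratum, time="T1")
        wmw = {}
        for s in ("SA+", "SA-"):
            cmp_ = compare_arms(
                pred_t1.levels("intervention", stratum=s),
                pred_t1.levels("control", stratum=s),
            )
            wmw[s] = {
                "U": cmp_.u_statistic,
                "p": cmp_.p_value,
                "rank_biserial": cmp_.rank_biserial,
            }
        balance = covariate_balance(trial)
        age_cells = age_stratified_sensitivity(trial, pred_t0, pred_t1)
        contrast = post_network_contrast(
            trial,
            pred_t0,
            pred_t1,
            catalog,
            config=glasso_cfg,
            bootstrap_B=config.evaluate.bootstrap_B,
            seed=stage_seed(config.seed, "contrast"),
            target_domain=config.trial.target_domain,
        )
        freq = pred_t1.frequencies()
        freq_t0 = pred_t0.frequencies()
        report = {
            "classifier": {
                "cv_accuracy": clf.cv_accuracy,
                "test_accuracy": clf.test_accuracy,
                "hidden_layers": list(spec.hidden_layers),
            },
            "wmw": wmw,
            "frequencies_t0": {
                f"{a}_{t}": {str(k): v for k, v in row.items()}
                for (a, t), row in freq_t0.iterrows()
            },
            "frequencies_t1": {
                f"{a}_{t}": {str(k): v for k, v in row.items()}
                for (a, t), row in freq.iterrows()
            },
            "covariate_balance": balance.to_dict(orient="records"),
            "age_stratified": age_cells.to_dict(orient="records"),
            "post_network_edges": {
                k: v for k, v in contrast.items() if k.endswith("_edge")
            },
        }
        report_path = out / "report.json"
        report_path.write_text(json.dumps(report, indent=1, default=float))
        record("evaluate", [report_path])
    except Exception as exc:
        fail("evaluate", exc)

    (out / "manifest.json").write_text(json.dumps(manifest.to_dict(), indent=1))
    return manifest
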