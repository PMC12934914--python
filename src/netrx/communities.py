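"""Community structure of symptom networks.

Communities are detected with a random-walk (walktrap) algorithm on the
absolute-weight graph, mirroring exploratory graph analysis: the number
of communities is not fixed in advance but chosen by modularity along
the walktrap merge sequence. Cluster-level summaries average the member
items per participant, the ideation item can be appended as an extra
node to form a suicide-symptom network, and the item partition is
validated with a PERMANOVA on the 1 - |r| distance between items.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import igraph as ig
import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.stats.distance import permanova as _skbio_permanova

from .catalog import SUICIDE_NODE, ItemCatalog
from .ggm import GGMNetwork, GlassoConfig, glasso_ebic, correlation_matrix

__all__ = [
    "CommunityPartition",
    "detect_communities",
    "label_partition",
    "aggregate_clusters",
    "suicide_network",
    "permanova_clusters",
]


@dataclass
class CommunityPartition:
    assignment: dict[str, int]
    labels: dict[int, str]
    modularity: float

    def __post_init__(self) -> None:
        if len(set(self.labels.values())) != len(self.labels):
            raise ValueError("community labels must be unique")
        missing = set(self.assignment.values()) - set(self.labels)
        if missing:
            raise ValueError(f"communities without labels: {sorted(missing)}")

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values()))

    def members(self, community: int) -> list[str]:
        return [k for k, v in self.assignment.items() if v == community]

    def domain_of(self, item: str) -> str:
        return self.labels[self.assignment[item]]

    def as_domain_map(self) -> dict[str, str]:
        return {item: self.labels[c] for item, c in self.assignment.items()}


def detect_communities(net: GGMNetwork, steps: int = 4) -> CommunityPartition:
    """Walktrap community detection on the |w| graph.

    Isolated nodes become singleton communities; the community count is
    the modularity-optimal cut of the walktrap dendrogram. Deterministic
    (walktrap involves no randomness; merge ties resolved by node index).
    """
    W = np.abs(net.weights)
    if not (W > 0).any():
        raise ValueError("no edges; communities undefined")
    deg = W.sum(axis=0)
    connected = np.where(deg > 0)[0]
    isolated = np.where(deg == 0)[0]
    sub = W[np.ix_(connected, connected)]
    g = ig.Graph.Weighted_Adjacency(sub.tolist(), mode="undirected", attr="weight")
    dendro = g.community_walktrap(weights="weight", steps=steps)
    clusters = dendro.as_clustering()
    assignment: dict[str, int] = {}
    for local, node in enumerate(connected):
        assignment[net.nodes[node]] = clusters.membership[local]
    next_id = max(clusters.membership, default=-1) + 1
    for node in isolated:
        assignment[net.nodes[node]] = next_id
        next_id += 1
    labels = {c: f"C{c + 1}" for c in sorted(set(assignment.values()))}
    return CommunityPartition(
        assignment=assignment,
        labels=labels,
        modularity=_modularity(W, [assignment[x] for x in net.nodes]),
    )


def _modularity(W: np.ndarray, membership: list[int]) -> float:
    total = W.sum()
    if total == 0:
        return 0.0
    deg = W.sum(axis=0)
    m = np.asarray(membership)
    same = m[:, None] == m[None, :]
    return float(((W - np.outer(deg, deg) / total) * same).sum() / total)


def label_partition(
    partition: CommunityPartition, catalog: ItemCatalog
) -> CommunityPartition:
    """Relabel communities by the majority reference domain of their
    members (ties and repeats disambiguated with a numeric suffix)."""
    labels: dict[int, str] = {}
    used: set[str] = set()
    for c in sorted(set(partition.assignment.values())):
        members = partition.members(c)
        domains = [catalog.domain_of[m] for m in members if m in catalog.domain_of]
        if domains:
            counts = pd.Series(domains).value_counts()
            top = sorted(counts[counts == counts.max()].index)[0]
        else:
            top = SUICIDE_NODE
        label = top
        k = 2
        while label in used:
            label = f"{top}{k}"
            k += 1
        used.add(label)
        labels[c] = label
    return CommunityPartition(
        assignment=dict(partition.assignment),
        labels=labels,
        modularity=partition.modularity,
    )


def aggregate_clusters(
    items: pd.DataFrame,
    partition: CommunityPartition | ItemCatalog,
    ideation: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-participant domain scores: the mean of member items.

    ``partition`` may be a detected partition or an item catalog; an
    optional ideation vector is appended as a SUI column.
    """
    if isinstance(partition, ItemCatalog):
        domain_map = dict(partition.domain_of)
    else:
        domain_map = partition.as_domain_map()
    missing = [c for c in items.columns if c not in domain_map]
    if missing:
        raise ValueError(f"partition does not cover items: {missing}")
    out = {}
    for domain in sorted(set(domain_map.values())):
        cols = [c for c in items.columns if domain_map[c] == domain]
        out[domain] = items[cols].mean(axis=1)
    scores = pd.DataFrame(out, index=items.index)
    if ideation is not None:
        scores[SUICIDE_NODE] = np.asarray(ideation, dtype=float)
    return scores


def suicide_network(
    cluster_scores: pd.DataFrame, config: GlassoConfig | None = None
) -> GGMNetwork:
    """EBIC-glasso network over domain scores plus the ideation column,
    which must be present (as SUI) and is treated as numeric. The SUI
    node is kept last in the node order."""
    if SUICIDE_NODE not in cluster_scores.columns:
        raise ValueError("ideation column (SUI) required for the suicide network")
    cols = [c for c in cluster_scores.columns if c != SUICIDE_NODE] + [SUICIDE_NODE]
    config = config or GlassoConfig()
    S, n = correlation_matrix(cluster_scores[cols], config.correlation_kind)
    return glasso_ebic(S, n, config)


def permanova_clusters(
    correlation: pd.DataFrame,
    partition: CommunityPartition | ItemCatalog,
    n_perm: int = 9999,
    seed: int | None = None,
) -> tuple[float, float]:
    """PERMANOVA of the item partition on d_ij = 1 - |r_ij|.

    Items are the observations and communities the groups; the pseudo-F
    compares among- to within-community squared distances, with the
    permutation p-value using the add-one convention. Communities of
    size 1 are excluded with a warning.
    """
    if isinstance(partition, ItemCatalog):
        domain_map = dict(partition.domain_of)
    else:
        domain_map = partition.as_domain_map()
    items = [c for c in correlation.columns if c in domain_map]
    groups = pd.Series({c: domain_map[c] for c in items})
    sizes = groups.value_counts()
    small = sizes[sizes < 2]
    if len(small):
        warnings.warn(
            f"singleton communities excluded from PERMANOVA: {list(small.index)}",
            stacklevel=2,
        )
        items = [c for c in items if sizes[groups[c]] >= 2]
        groups = groups[items]
    if groups.nunique() < 2:
        raise ValueError("PERMANOVA needs >= 2 communities with >= 2 members")
    R = correlation.loc[items, items].to_numpy(dtype=float)
    D = 1.0 - np.abs(R)
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2
    dm = DistanceMatrix(D, ids=items)
    res = _skbio_permanova(dm, groups.tolist(), permutations=n_perm, seed=seed)
    return float(res["test statistic"]), float(res["p-value"])
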