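"""Node centrality, bridge edges to the ideation node, and convergent
target selection.

Four centrality metrics are computed on partial-correlation networks:
strength (sum of absolute edge weights), expected influence (sum of
signed weights), harmonic closeness and betweenness, the latter two on
shortest paths under the distance transform d_ij = 1/|w_ij|. Metrics are
standardized as proportional deviations (%) from the network mean so
nodes can be described as e.g. "+22% above the network average".
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .catalog import SUICIDE_NODE, ItemCatalog
from statsmodels.stats.multitest import multipletests

from .ggm import EdgeInference, GGMNetwork

__all__ = [
    "CentralityTable",
    "BridgeReport",
    "centrality",
    "proportional_deviation",
    "bridge_report",
    "select_targets",
]

METRICS = ("strength", "expected_influence", "closeness", "betweenness")


@dataclass
class CentralityTable:
    """Per-node metrics plus their % deviations from the network mean
    (columns ``<metric>_dev``; deviation is NaN when a metric's mean is
    zero, e.g. the empty network)."""

    table: pd.DataFrame

    def metric(self, name: str) -> pd.Series:
        return self.table[name]

    def deviation(self, name: str) -> pd.Series:
        return self.table[f"{name}_dev"]


@dataclass
class BridgeReport:
    """Edges incident to the ideation node, with CIs and FDR-adjusted
    p-values when bootstrap inference is available."""

    edges: pd.DataFrame  # columns: target, weight, lower, upper, p_fdr, significant

    def significant_targets(self) -> list[str]:
        return list(self.edges.loc[self.edges.significant, "target"])


def _graph(net: GGMNetwork) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(net.p))
    for i in range(net.p):
        for j in range(i + 1, net.p):
            w = net.weights[i, j]
            if w != 0:
                g.add_edge(i, j, length=1.0 / abs(w))
    return g


def centrality(net: GGMNetwork) -> CentralityTable:
    """The four centrality metrics for every node.

    Closeness is harmonic (sum of reciprocal shortest-path distances),
    so isolated nodes score 0 and disconnected networks are
    well-defined; betweenness gives fractional credit to tied shortest
    paths. An all-zero network yields all-zero metrics.
    """
    if net.p < 2:
        raise ValueError("centrality needs >= 2 nodes")
    strength = np.abs(net.weights).sum(axis=0)
    ei = net.weights.sum(axis=0)
    g = _graph(net)
    harm = nx.harmonic_centrality(g, distance="length")
    betw = nx.betweenness_centrality(g, weight="length", normalized=False)
    table = pd.DataFrame(
        {
            "strength": strength,
            "expected_influence": ei,
            "closeness": [harm[i] for i in range(net.p)],
            "betweenness": [betw[i] for i in range(net.p)],
        },
        index=net.nodes,
    )
    for m in METRICS:
        mean = table[m].mean()
        if mean == 0:
            table[f"{m}_dev"] = np.nan
        else:
            table[f"{m}_dev"] = proportional_deviation(table[m].to_numpy())
    return CentralityTable(table=table)


def proportional_deviation(values: np.ndarray) -> np.ndarray:
    """Percent deviation from the mean: 100 (v - mean) / mean."""
    values = np.asarray(values, dtype=float)
    mean = values.mean()
    if mean == 0:
        raise ValueError("proportional deviation undefined for zero-mean values")
    return 100.0 * (values - mean) / mean


def bridge_report(
    net: GGMNetwork,
    inference: EdgeInference | None = None,
    alpha: float = 0.05,
) -> BridgeReport:
    """Extract the edges linking the ideation node to every other node,
    flagging those that survive FDR correction.

    FDR (Benjamini-Hochberg) is applied across the family of
    suicide-incident edges — the set of hypotheses this analysis
    evaluates — rather than across every edge of the network.
    """
    if SUICIDE_NODE not in net.nodes:
        raise ValueError("network has no suicide node")
    rows = []
    for node in net.nodes:
        if node == SUICIDE_NODE:
            continue
        w = net.edge(node, SUICIDE_NODE)
        lower = upper = p_raw = np.nan
        if inference is not None:
            rec = inference.lookup(node, SUICIDE_NODE)
            lower, upper, p_raw = rec.lower, rec.upper, rec.p_raw
        rows.append(
            {
                "target": node,
                "weight": w,
                "lower": lower,
                "upper": upper,
                "p_raw": p_raw,
            }
        )
    table = pd.DataFrame(rows)
    if inference is not None and table["p_raw"].notna().all():
        table["p_fdr"] = multipletests(table["p_raw"], method="fdr_bh")[1]
        table["significant"] = table["p_fdr"] < alpha
    else:
        table["p_fdr"] = np.nan
        table["significant"] = False
    return BridgeReport(edges=table)


def select_targets(
    item_centrality: CentralityTable,
    cluster_centrality: CentralityTable,
    bridge: BridgeReport,
    catalog: ItemCatalog,
) -> pd.DataFrame:
    """Convergent-evidence ranking of candidate target domains.

    Score per domain = (# member items whose strength or expected
    influence sits above the network average) + 2 x (domain has an
    FDR-significant bridge to the ideation node) + 1 x (its bridge edge
    is positive). Ties break alphabetically. The full evidence vector is
    returned for audit.
    """
    bridges = bridge.edges.set_index("target")
    rows = []
    for domain in catalog.domains:
        members = catalog.members(domain)
        above = 0
        for m in members:
            if m in item_centrality.table.index:
                row = item_centrality.table.loc[m]
                if row["strength_dev"] > 0 or row["expected_influence_dev"] > 0:
                    above += 1
        sig = bool(bridges.loc[domain, "significant"]) if domain in bridges.index else False
        pos = bool(bridges.loc[domain, "weight"] > 0) if domain in bridges.index else False
        cluster_dev = (
            float(cluster_centrality.table.loc[domain, "expected_influence_dev"])
            if domain in cluster_centrality.table.index
            else np.nan
        )
        rows.append(
            {
                "domain": domain,
                "score": above + 2 * sig + pos,
                "items_above_average": above,
                "fdr_significant_bridge": sig,
                "positive_bridge": pos,
                "cluster_ei_deviation": cluster_dev,
            }
        )
    out = pd.DataFrame(rows).sort_values(
        ["score", "domain"], ascending=[False, True], kind="mergesort"
    )
    return out.reset_index(drop=True)
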