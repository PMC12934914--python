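"""Centrality metrics against brute-force graph oracles; target selection."""

import itertools

import numpy as np
import pandas as pd
import pytest

from netrx.catalog import SUICIDE_NODE
from netrx.centrality import (
    BridgeReport,
    bridge_report,
    centrality,
    proportional_deviation,
    select_targets,
)
from netrx.ggm import GGMNetwork


def _net(weights, nodes=None):
    p = len(weights)
    nodes = nodes or [f"v{i}" for i in range(p)]
    return GGMNetwork(
        nodes=nodes, weights=np.asarray(weights, float), lambda_selected=0.1,
        ebic=0.0, n=100,
    )


def _brute_force_paths(W):
    """Floyd-Warshall distances and all-shortest-path counts on 1/|w|."""
    p = W.shape[0]
    dist = np.full((p, p), np.inf)
    np.fill_diagonal(dist, 0.0)
    for i in range(p):
        for j in range(p):
            if i != j and W[i, j] != 0:
                dist[i, j] = 1.0 / abs(W[i, j])
    for k in range(p):
        dist = np.minimum(dist, dist[:, [k]] + dist[[k], :])
    return dist


def _brute_betweenness(W):
    """Betweenness by exhaustive enumeration of simple paths."""
    p = W.shape[0]
    dist = _brute_force_paths(W)
    between = np.zeros(p)
    for s, t in itertools.combinations(range(p), 2):
        if not np.isfinite(dist[s, t]):
            continue
        # enumerate all shortest s-t paths by DFS over the graph
        paths = []
        stack = [(s, [s], 0.0)]
        while stack:
            node, path, length = stack.pop()
            if length - 1e-9 > dist[s, t]:
                continue
            if node == t:
                if abs(length - dist[s, t]) < 1e-9:
                    paths.append(path)
                continue
            for nxt in range(p):
                if W[node, nxt] != 0 and nxt not in path:
                    stack.append((nxt, path + [nxt], length + 1.0 / abs(W[node, nxt])))
        for path in paths:
            for mid in path[1:-1]:
                between[mid] += 1.0 / len(paths)
    return between


class TestCentrality:
    def test_three_node_path_hand_values(self):
        W = [[0, 0.5, 0], [0.5, 0, 0.5], [0, 0.5, 0]]
        table = centrality(_net(W)).table
        assert table.betweenness.tolist() == [0.0, 1.0, 0.0]
        assert table.strength.iloc[1] == pytest.approx(1.0)

    def test_sign_cancellation_in_expected_influence(self):
        W = [[0, 0.2, -0.2], [0.2, 0, 0], [-0.2, 0, 0]]
        table = centrality(_net(W)).table
        assert table.strength.iloc[0] == pytest.approx(0.4)
        assert table.expected_influence.iloc[0] == pytest.approx(0.0)

    def test_all_zero_network_scores_zero_without_error(self):
        table = centrality(_net(np.zeros((4, 4)))).table
        assert (table[["strength", "expected_influence", "closeness",
                       "betweenness"]].to_numpy() == 0).all()

    @pytest.mark.parametrize("seed", range(20))
    def test_path_metrics_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        p = int(rng.integers(4, 11))
        W = np.zeros((p, p))
        iu = np.triu_indices(p, 1)
        vals = rng.uniform(-0.6, 0.6, len(iu[0]))
        vals[rng.random(len(vals)) < 0.5] = 0.0
        W[iu] = vals
        W = W + W.T
        table = centrality(_net(W)).table
        dist = _brute_force_paths(W)
        with np.errstate(divide="ignore"):
            inv = np.where(dist > 0, 1.0 / dist, 0.0)
        np.fill_diagonal(inv, 0.0)
        harmonic = inv.sum(axis=1)
        assert np.allclose(table.closeness.to_numpy(), harmonic, atol=1e-8)
        assert np.allclose(
            table.betweenness.to_numpy(), _brute_betweenness(W), atol=1e-6
        )

    def test_adding_edge_never_decreases_strength(self):
        rng = np.random.default_rng(5)
        W = np.zeros((5, 5))
        W[0, 1] = W[1, 0] = 0.3
        base = centrality(_net(W)).table.strength
        W2 = W.copy()
        W2[0, 2] = W2[2, 0] = 0.1
        grown = centrality(_net(W2)).table.strength
        assert (grown >= base - 1e-12).all()


class TestProportionalDeviation:
    def test_constant_values_have_zero_deviation(self):
        assert np.allclose(proportional_deviation(np.array([1.0, 1, 1])), 0.0)

    def test_hand_computed_percentages(self):
        dev = proportional_deviation(np.array([1.22, 1.0, 0.78]))
        assert np.allclose(dev, [22.0, 0.0, -22.0])

    def test_deviations_average_to_zero(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0.5, 3.0, 50)
        assert proportional_deviation(vals).mean() == pytest.approx(0.0, abs=1e-10)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError, match="zero-mean"):
            proportional_deviation(np.array([-1.0, 1.0]))


class TestBridgesAndTargets:
    def test_network_without_suicide_node_rejected(self):
        with pytest.raises(ValueError, match="no suicide node"):
            bridge_report(_net(np.zeros((3, 3))))

    def test_flat_evidence_ties_break_alphabetically(self, catalog):
        domains = list(catalog.domains)
        item_tab = centrality(_net(np.zeros((30, 30)), list(catalog.codes)))
        cluster_tab = centrality(
            _net(np.zeros((6, 6)), domains + [SUICIDE_NODE])
        )
        bridge = BridgeReport(
            edges=pd.DataFrame(
                {
                    "target": domains,
                    "weight": 0.0,
                    "lower": np.nan,
                    "upper": np.nan,
                    "p_raw": 1.0,
                    "p_fdr": 1.0,
                    "significant": False,
                }
            )
        )
        ranked = select_targets(item_tab, cluster_tab, bridge, catalog)
        assert ranked.domain.tolist() == sorted(domains)
        assert (ranked.score == 0).all()

    def test_significant_bridge_outranks_centrality_poor_domain(self, catalog):
        item_tab = centrality(_net(np.zeros((30, 30)), list(catalog.codes)))
        cluster_tab = centrality(_net(np.zeros((6, 6)), list(catalog.domains) + [SUICIDE_NODE]))
        rows = []
        for d in catalog.domains:
            rows.append(
                {
                    "target": d,
                    "weight": 0.3 if d == "DST" else 0.0,
                    "lower": np.nan,
                    "upper": np.nan,
                    "p_raw": 0.004 if d == "DST" else 1.0,
                    "p_fdr": 0.02 if d == "DST" else 1.0,
                    "significant": d == "DST",
                }
            )
        ranked = select_targets(
            item_tab, cluster_tab, BridgeReport(edges=pd.DataFrame(rows)), catalog
        )
        assert ranked.domain.iloc[0] == "DST"
        assert ranked.score.iloc[0] == 3  # 2 for significance + 1 for positive sign

    def test_ranking_invariant_to_node_order(self, catalog, item_network):
        item_tab = centrality(item_network)
        perm = np.random.default_rng(1).permutation(30)
        shuffled = GGMNetwork(
            nodes=[item_network.nodes[i] for i in perm],
            weights=item_network.weights[np.ix_(perm, perm)],
            lambda_selected=item_network.lambda_selected,
            ebic=item_network.ebic,
            n=item_network.n,
        )
        item_tab_shuffled = centrality(shuffled)
        cluster_tab = centrality(_net(np.zeros((6, 6)), list(catalog.domains) + [SUICIDE_NODE]))
        bridge = BridgeReport(
            edges=pd.DataFrame(
                {
                    "target": list(catalog.domains),
                    "weight": [0.0, 0.3, 0.0, 0.0, 0.0],
                    "lower": np.nan,
                    "upper": np.nan,
                    "p_raw": [1.0, 0.004, 1.0, 1.0, 1.0],
                    "p_fdr": [1.0, 0.02, 1.0, 1.0, 1.0],
                    "significant": [False, True, False, False, False],
                }
            )
        )
        a = select_targets(item_tab, cluster_tab, bridge, catalog)
        b = select_targets(item_tab_shuffled, cluster_tab, bridge, catalog)
        pd.testing.assert_frame_equal(a, b)
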