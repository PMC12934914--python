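"""JSON serialization of networks and partitions."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .communities import CommunityPartition
from .ggm import GGMNetwork


def network_to_dict(net: GGMNetwork) -> dict:
    return {
        "nodes": list(net.nodes),
        "weights": [float(x) for x in net.weights.ravel()],  # row-major
        "lambda": net.lambda_selected,
        "ebic": net.ebic,
        "n": net.n,
        "meta": net.meta,
    }


def network_from_dict(d: dict) -> GGMNetwork:
    p = len(d["nodes"])
    return GGMNetwork(
        nodes=list(d["nodes"]),
        weights=np.asarray(d["weights"], dtype=float).reshape(p, p),
        lambda_selected=float(d["lambda"]),
        ebic=float(d["ebic"]),
        n=int(d["n"]),
        meta=d.get("meta", {}),
    )


def write_network(net: GGMNetwork, path: str | Path) -> None:
    Path(path).write_text(json.dumps(network_to_dict(net), indent=1))


def read_network(path: str | Path) -> GGMNetwork:
    return network_from_dict(json.loads(Path(path).read_text()))


def partition_to_dict(part: CommunityPartition) -> dict:
    return {
        "assignment": dict(part.assignment),
        "labels": {str(k): v for k, v in part.labels.items()},
        "modularity": part.modularity,
    }


def write_partition(part: CommunityPartition, path: str | Path) -> None:
    Path(path).write_text(json.dumps(partition_to_dict(part), indent=1))


def read_partition(path: str | Path) -> CommunityPartition:
    d = json.loads(Path(path).read_text())
    return CommunityPartition(
        assignment={k: int(v) for k, v in d["assignment"].items()},
        labels={int(k): v for k, v in d["labels"].items()},
        modularity=float(d["modularity"]),
    )


def edge_list_tsv(net: GGMNetwork, path: str | Path) -> None:
    lines = ["node_a\tnode_b\tweight"]
    for i in range(net.p):
        for j in range(i + 1, net.p):
            w = net.weights[i, j]
            if w != 0:
                lines.append(f"{net.nodes[i]}\t{net.nodes[j]}\t{w:.6g}")
    Path(path).write_text("\n".join(lines) + "\n")
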