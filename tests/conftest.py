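import numpy as np
import pandas as pd
import pytest

from netomics import EdgeRecord, MultiOmicsNetwork, NodeRecord


def make_net(nodes, edges=(), name="net"):
    """nodes: iterable of ids or NodeRecords; edges: (u, v[, provenance]) tuples."""
    net = MultiOmicsNetwork(name)
    for n in nodes:
        if isinstance(n, NodeRecord):
            net.add_node(n)
        else:
            net.add_node(NodeRecord(id=n, layer="gene", measured=True))
    for e in edges:
        if isinstance(e, EdgeRecord):
            net.add_edge(e)
        else:
            u, v, *rest = e
            net.add_edge(EdgeRecord(u=u, v=v, provenance=rest[0] if rest else "inferred_mi"))
    return net


@pytest.fixture
def path_net():
    return make_net("abc", [("a", "b"), ("b", "c")])


@pytest.fixture
def triangle_net():
    return make_net("abc", [("a", "b"), ("b", "c"), ("a", "c")])


def random_net(rng, n_nodes=8, p_edge=0.3):
    ids = [f"n{i}" for i in range(n_nodes)]
    net = MultiOmicsNetwork("random")
    for i, nid in enumerate(ids):
        net.add_node(
            NodeRecord(
                id=nid,
                layer="gene",
                measured=bool(rng.random() < 0.7),
                cluster=int(rng.integers(1, 4)) if rng.random() < 0.5 else None,
            )
        )
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p_edge:
                net.add_edge(
                    EdgeRecord(
                        u=ids[i], v=ids[j], provenance="inferred_mi",
                        weight=float(np.round(rng.uniform(0.1, 1.0), 6)),
                    )
                )
    return net


def map_clusters(truth_labels: dict, pred_labels: dict) -> dict:
    """Map predicted cluster ids to the truth cluster they overlap most."""
    pred_to_truth = {}
    for p in set(pred_labels.values()):
        members = [f for f, c in pred_labels.items() if c == p]
        counts = {}
        for f in members:
            if f in truth_labels:
                counts[truth_labels[f]] = counts.get(truth_labels[f], 0) + 1
        if counts:
            pred_to_truth[p] = max(sorted(counts), key=counts.get)
    return pred_to_truth
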