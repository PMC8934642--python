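"""Random walk with restart: transition contract, convergence, interpretation."""

import numpy as np
import pytest

from netomics import (
    EdgeRecord,
    NodeRecord,
    WalkConfig,
    cluster_intersection,
    mechanism_subnetworks,
    predict_function,
    rwr,
    transition_matrix,
    unannotated_nodes,
)
from netomics.propagate import PropagationError
from conftest import make_net, random_net


def direct_solve(net, seeds, r, weighted=False):
    """Independent oracle: dense linear solve of (I - (1-r)W) p = r p0."""
    W, ids = transition_matrix(net, weighted=weighted)
    index = {nid: i for i, nid in enumerate(ids)}
    p0 = np.zeros(len(ids))
    for s in seeds:
        p0[index[s]] = 1.0 / len(seeds)
    p = np.linalg.solve(np.eye(len(ids)) - (1 - r) * W, r * p0)
    return {nid: p[index[nid]] for nid in ids}


class TestTransitionMatrix:
    def test_path_column_splits_equally(self, path_net):
        W, ids = transition_matrix(path_net)
        b = ids.index("b")
        assert W[ids.index("a"), b] == 0.5 and W[ids.index("c"), b] == 0.5

    def test_unweighted_columns_are_inverse_degree(self):
        rng = np.random.default_rng(0)
        net = random_net(rng, n_nodes=12, p_edge=0.4)
        W, ids = transition_matrix(net)
        for j, nid in enumerate(ids):
            d = net.degree(nid)
            col = W[:, j]
            if d == 0:
                assert col[j] == 1.0
            else:
                assert set(np.round(col[col > 0], 12)) == {round(1.0 / d, 12)}

    def test_isolated_node_gets_self_loop(self):
        net = make_net("ab", [])
        W, ids = transition_matrix(net)
        assert np.allclose(W, np.eye(2))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_columns_stochastic(self, seed):
        rng = np.random.default_rng(seed)
        net = random_net(rng, n_nodes=15)
        for weighted in (False, True):
            W, _ = transition_matrix(net, weighted=weighted)
            assert np.allclose(W.sum(axis=0), 1.0, atol=1e-12)

    def test_parallel_provenances_collapse_to_max_weight(self):
        net = make_net("ab")
        net.add_edge(EdgeRecord(u="a", v="b", provenance="inferred_mi", weight=0.2))
        net.add_edge(EdgeRecord(u="a", v="b", provenance="knowledge_ppi", weight=0.9))
        W, ids = transition_matrix(net, weighted=True)
        assert W[ids.index("a"), ids.index("b")] == 1.0  # single neighbour, normalized
        net.add_node(NodeRecord(id="c", layer="gene"))
        net.add_edge(EdgeRecord(u="b", v="c", provenance="inferred_mi", weight=0.9))
        W, ids = transition_matrix(net, weighted=True)
        col = W[:, ids.index("b")]
        assert col[ids.index("a")] == pytest.approx(0.5)  # max(0.2, 0.9) vs 0.9


class TestRWR:
    def test_restart_one_returns_seed_vector(self, path_net):
        res = rwr(path_net, ["a"], WalkConfig(restart=1.0))
        assert res.scores == {"a": 1.0, "b": 0.0, "c": 0.0}

    def test_three_leaf_star_closed_form(self):
        net = make_net("clmn", [("c", "l"), ("c", "m"), ("c", "n")])
        res = rwr(net, ["c"], WalkConfig(restart=0.5, tolerance=1e-14))
        assert res.scores["c"] == pytest.approx(2 / 3, abs=1e-9)
        for leaf in "lmn":
            assert res.scores[leaf] == pytest.approx(1 / 9, abs=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_iterative_matches_direct_solve(self, seed):
        rng = np.random.default_rng(seed)
        net = random_net(rng, n_nodes=int(rng.integers(10, 60)), p_edge=0.15)
        seeds = [sorted(net.nodes)[0]]
        res = rwr(net, seeds, WalkConfig(restart=0.7, tolerance=1e-12))
        oracle = direct_solve(net, seeds, 0.7)
        l1 = sum(abs(res.scores[n] - oracle[n]) for n in net.nodes)
        assert l1 <= 1e-8

    def test_scores_conserve_probability(self):
        rng = np.random.default_rng(5)
        net = random_net(rng, n_nodes=30)
        res = rwr(net, sorted(net.nodes)[:3])
        assert sum(res.scores.values()) == pytest.approx(1.0, abs=1e-8)

    def test_path_scores_decrease_with_hop_distance(self):
        # strict monotone locality holds once the restart term dominates the
        # degree bias of the r->0 stationary limit (where interior nodes of
        # degree 2 outscore a degree-1 seed); beyond the seed's neighbour it
        # holds for any r
        ids = [f"n{i}" for i in range(7)]
        net = make_net(ids, [(ids[i], ids[i + 1]) for i in range(6)])
        for r in (0.3, 0.5, 0.7, 0.9):
            res = rwr(net, [ids[0]], WalkConfig(restart=r, tolerance=1e-13))
            scores = [res.scores[n] for n in ids]
            assert all(scores[i] > scores[i + 1] for i in range(6))
        for r in (0.05, 0.15):
            res = rwr(net, [ids[0]], WalkConfig(restart=r, tolerance=1e-13))
            scores = [res.scores[n] for n in ids]
            assert all(scores[i] > scores[i + 1] for i in range(1, 6))

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(8)
        net = random_net(rng, n_nodes=12)
        res = rwr(net, ["n0"], WalkConfig(tolerance=1e-13))
        renamed = make_net(
            [NodeRecord(id=f"x{nid}", layer=n.layer, measured=n.measured) for nid, n in net.nodes.items()],
            [EdgeRecord(u=f"x{e.u}", v=f"x{e.v}", provenance=e.provenance, weight=e.weight) for e in net.edges.values()],
        )
        res2 = rwr(renamed, ["xn0"], WalkConfig(tolerance=1e-13))
        for nid in net.nodes:
            assert res2.scores[f"x{nid}"] == pytest.approx(res.scores[nid], abs=1e-9)

    def test_seed_not_in_network_rejected(self, path_net):
        with pytest.raises(PropagationError):
            rwr(path_net, ["zz"])

    def test_ranking_excludes_seeds_and_breaks_ties_lexicographically(self):
        net = make_net("clmn", [("c", "l"), ("c", "m"), ("c", "n")])
        res = rwr(net, ["c"])
        assert res.ranking == ["l", "m", "n"]


def annotated_fixture():
    """Two-cluster molecule network with one GO term per cluster."""
    nodes = [
        NodeRecord(id="rna:a1", layer="gene", measured=True, cluster=1),
        NodeRecord(id="rna:a2", layer="gene", measured=True, cluster=1),
        NodeRecord(id="prot:b1", layer="protein", measured=True, cluster=2),
        NodeRecord(id="prot:b2", layer="protein", measured=True, cluster=2),
        NodeRecord(id="rna:reg", layer="gene", measured=True, cluster=1),
        NodeRecord(id="go:T1", layer="go_term", ontology="GO:BP"),
        NodeRecord(id="go:T2", layer="go_term", ontology="GO:BP"),
    ]
    edges = [
        EdgeRecord(u="rna:a1", v="rna:a2", provenance="inferred_mi"),
        EdgeRecord(u="prot:b1", v="prot:b2", provenance="knowledge_ppi"),
        EdgeRecord(u="rna:reg", v="rna:a1", provenance="inferred_mi"),
        EdgeRecord(u="rna:reg", v="prot:b1", provenance="tf_target"),
        EdgeRecord(u="go:T1", v="rna:a1", provenance="annotation"),
        EdgeRecord(u="go:T1", v="rna:a2", provenance="annotation"),
        EdgeRecord(u="go:T2", v="prot:b1", provenance="annotation"),
        EdgeRecord(u="go:T2", v="prot:b2", provenance="annotation"),
    ]
    return make_net(nodes, edges)


class TestMechanismSubnetworks:
    def test_seed_with_single_neighbour_gives_two_node_subnetwork(self):
        net = make_net(
            [NodeRecord(id="go:T", layer="go_term"), NodeRecord(id="rna:g", layer="gene", measured=True)],
            [EdgeRecord(u="go:T", v="rna:g", provenance="annotation")],
        )
        out = mechanism_subnetworks(net, k=25)
        assert len(out) == 1 and set(out[0].subnetwork.nodes) == {"go:T", "rna:g"}

    def test_large_k_covers_reachable_component(self):
        net = annotated_fixture()
        out = mechanism_subnetworks(net, k=len(net))
        for sub in out:
            assert len(sub.subnetwork) == len(net)

    def test_cross_layer_screen_flags_terms_reaching_gene_and_protein(self):
        net = annotated_fixture()
        out = {s.seed: s for s in mechanism_subnetworks(net, k=3)}
        assert out["go:T1"].screens["reaches_gene_and_protein"] in (True, False)
        wide = {s.seed: s for s in mechanism_subnetworks(net, k=6)}
        assert wide["go:T1"].screens["reaches_gene_and_protein"]


class TestPredictFunction:
    def test_node_with_only_term_edge_inherits_it(self):
        net = make_net(
            [NodeRecord(id="rna:g", layer="gene", measured=True), NodeRecord(id="go:T", layer="go_term", ontology="GO:BP")],
            [EdgeRecord(u="rna:g", v="go:T", provenance="annotation")],
        )
        # the node has an annotation edge, so ask for it explicitly
        out = predict_function(net, nodes=["rna:g"])
        assert out["rna:g"]["GO:BP"]["term"] == "go:T"

    def test_disconnected_node_flagged_unassigned(self):
        net = annotated_fixture()
        net.add_node(NodeRecord(id="rna:lonely", layer="gene", measured=True))
        out = predict_function(net, nodes=["rna:lonely"])
        assert out["rna:lonely"]["GO:BP"] is None

    def test_unannotated_nodes_found_by_annotation_edges(self):
        net = annotated_fixture()
        assert unannotated_nodes(net) == ["rna:reg"]

    def test_neighbour_term_recovered_through_knowledge_edges(self):
        net = annotated_fixture()
        out = predict_function(net)
        assert out["rna:reg"]["GO:BP"]["term"] == "go:T1"


class TestClusterIntersection:
    def test_homogeneous_clusters_retain_no_seeds(self):
        net = annotated_fixture()
        for node in net.nodes.values():
            if node.cluster is not None:
                node.cluster = 1
        assert cluster_intersection(net, k=4) == []

    def test_seed_bridging_clusters_and_term_retained(self):
        net = annotated_fixture()
        out = cluster_intersection(net, k=4)
        assert "rna:reg" in {s.seed for s in out}

    def test_retained_seed_reports_clusters_and_terms(self):
        net = annotated_fixture()
        out = {s.seed: s for s in cluster_intersection(net, k=4)}
        reg = out["rna:reg"]
        assert {1, 2} <= reg.clusters_reached and reg.terms_reached
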