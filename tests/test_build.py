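"""Layer construction: MI/DPI inference, knowledge layers, correlation layers,
compositional correlation, and assembly."""

import math

import numpy as np
import pandas as pd
import pytest

from netomics import (
    KnowledgeTable,
    NodeRecord,
    assemble,
    correlation_link,
    cross_link_ids,
    dpi_prune,
    estimate_mi,
    gen_chain,
    gen_compositional,
    knowledge_layer,
    mi_network,
    mi_permutation_floor,
    reaction_layer,
    sparcc_correlation,
    substream,
)
from netomics.build import BuildError, MIMatrix


def brute_mi(x, y, bins, base=2.0):
    """Contingency-table MI from explicit probability sums."""
    def binned(v):
        order = np.argsort(v, kind="mergesort")
        ranks = np.empty(len(v), dtype=int)
        ranks[order] = np.arange(len(v))
        return (ranks * bins) // len(v)

    bx, by = binned(np.asarray(x)), binned(np.asarray(y))
    n = len(bx)
    total = 0.0
    for i in range(bins):
        for j in range(bins):
            pxy = np.sum((bx == i) & (by == j)) / n
            if pxy == 0:
                continue
            px = np.sum(bx == i) / n
            py = np.sum(by == j) / n
            total += pxy * math.log(pxy / (px * py), base)
    return total


class TestEstimateMI:
    def test_identical_features_give_marginal_entropy(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=400)
        expr = pd.DataFrame([x, x], index=["a", "b"])
        mi = estimate_mi(expr, bins=4)
        assert mi.values.loc["a", "b"] == pytest.approx(2.0, abs=1e-12)

    def test_independent_features_near_zero(self):
        low = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            expr = pd.DataFrame(rng.uniform(size=(2, 1000)), index=["x", "y"])
            mi = estimate_mi(expr, bins=4)
            low += mi.values.loc["x", "y"] <= 0.05
        assert low >= 19

    @pytest.mark.parametrize("seed,bins", [(0, 2), (1, 3), (2, 5)])
    def test_matches_brute_force_contingency(self, seed, bins):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=60)
        y = 0.5 * x + rng.normal(size=60)
        expr = pd.DataFrame([x, y], index=["x", "y"])
        mi = estimate_mi(expr, bins=bins)
        assert mi.values.loc["x", "y"] == pytest.approx(brute_mi(x, y, bins), abs=1e-12)

    def test_constant_feature_warns_and_scores_zero(self):
        expr = pd.DataFrame([[1.0] * 10, np.arange(10.0)], index=["c", "x"])
        with pytest.warns(UserWarning, match="constant"):
            mi = estimate_mi(expr, bins=2)
        assert mi.values.loc["c", "x"] == 0.0

    def test_symmetric_nonnegative(self):
        rng = np.random.default_rng(9)
        expr = pd.DataFrame(rng.normal(size=(5, 80)))
        mi = estimate_mi(expr)
        M = mi.values.to_numpy()
        iu = np.triu_indices(5, 1)
        assert np.allclose(M[iu], M.T[iu]) and (M[iu] >= 0).all()


def mimatrix(entries, ids=("a", "b", "c")):
    M = np.full((len(ids), len(ids)), np.nan)
    for (i, j), v in entries.items():
        M[i, j] = M[j, i] = v
    return MIMatrix(values=pd.DataFrame(M, index=ids, columns=ids), bins=4, base=2.0, n_samples=100)


class TestDPI:
    def test_weakest_triangle_edge_removed_at_epsilon_zero(self):
        mi = mimatrix({(0, 1): 0.5, (1, 2): 0.4, (0, 2): 0.1})
        edges = {frozenset({a, b}) for a, b, _ in dpi_prune(mi, 0.0, epsilon=0.0)}
        assert edges == {frozenset("ab"), frozenset("bc")}

    def test_large_epsilon_keeps_the_weak_edge(self):
        mi = mimatrix({(0, 1): 0.5, (1, 2): 0.4, (0, 2): 0.1})
        edges = {frozenset({a, b}) for a, b, _ in dpi_prune(mi, 0.0, epsilon=0.8)}
        assert frozenset("ac") in edges  # 0.1 >= 0.2 * 0.4

    def test_floor_applies_before_pruning(self):
        mi = mimatrix({(0, 1): 0.5, (1, 2): 0.4, (0, 2): 0.1})
        edges = {frozenset({a, b}) for a, b, _ in dpi_prune(mi, 0.45, epsilon=0.0)}
        assert edges == {frozenset("ab")}

    def test_output_subset_of_thresholded_graph(self):
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(rng.normal(size=(8, 100)))
        mi = estimate_mi(expr)
        floor = 0.05
        pruned = {frozenset({a, b}) for a, b, _ in dpi_prune(mi, floor)}
        thresholded = {
            frozenset({mi.feature_ids[i], mi.feature_ids[j]})
            for i in range(8)
            for j in range(i + 1, 8)
            if mi.values.iloc[i, j] >= floor
        }
        assert pruned <= thresholded

    def test_chain_fixture_indirect_edge_pruned(self):
        hits = 0
        for seed in range(10):
            expr, direct, indirect = gen_chain(seed=seed)
            mi = estimate_mi(expr)
            floor = mi_permutation_floor(expr, rng=substream(seed, "floor"))
            edges = {frozenset({a, b}) for a, b, _ in dpi_prune(mi, floor)}
            hits += (set(direct) <= edges) and not (set(indirect) & edges)
        assert hits >= 9


class TestKnowledgeLayer:
    def table(self, rows, scores=None):
        df = pd.DataFrame(rows, columns=["id_a", "id_b"])
        if scores is not None:
            df["score"] = scores
        return KnowledgeTable(rows=df, source="test")

    def test_first_degree_extension_only(self):
        net = knowledge_layer(
            {"A", "B"}, self.table([("A", "C"), ("C", "D"), ("B", "A")]), extend=True
        )
        assert set(net.nodes) == {"A", "B", "C"}
        assert {frozenset({e.u, e.v}) for e in net.edges.values()} == {
            frozenset("AB"), frozenset("AC")
        }
        assert not net.nodes["C"].measured

    def test_no_extension_restricts_to_measured(self):
        net = knowledge_layer(
            {"A", "B"}, self.table([("A", "C"), ("C", "D"), ("B", "A")]), extend=False
        )
        assert set(net.nodes) == {"A", "B"} and len(net.edges) == 1

    def test_score_filter_drops_low_confidence_rows(self):
        net = knowledge_layer(
            {"A", "B", "C"},
            self.table([("A", "B"), ("B", "C")], scores=[0.9, 0.1]),
            score_min=0.5,
            extend=False,
        )
        assert {frozenset({e.u, e.v}) for e in net.edges.values()} == {frozenset("AB")}

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_extension_never_exceeds_distance_one(self, seed):
        from netomics import gen_knowledge

        measured = [f"prot:m{i}" for i in range(12)]
        table, _ = gen_knowledge(measured, extra_unmeasured_per_node=2, seed=seed)
        net = knowledge_layer(measured, table, extend=True)
        measured_set = set(measured)
        for nid, node in net.nodes.items():
            if not node.measured:
                assert net.neighbors(nid) & measured_set, nid


class TestReactionLayer:
    def test_clique_and_enzyme_edges(self):
        reactions = pd.DataFrame(
            [{"reaction_id": "r1", "compounds": "C1;C2", "enzymes": "E1"}]
        )
        net = reaction_layer({"C1", "C2"}, reactions)
        pairs = {frozenset({e.u, e.v}) for e in net.edges.values()}
        assert pairs == {frozenset({"C1", "C2"}), frozenset({"E1", "C1"}), frozenset({"E1", "C2"})}

    def test_disjoint_reactions_do_not_cross(self):
        reactions = pd.DataFrame(
            [
                {"reaction_id": "r1", "compounds": "C1;C2", "enzymes": ""},
                {"reaction_id": "r2", "compounds": "C3;C4", "enzymes": ""},
            ]
        )
        net = reaction_layer({"C1", "C2", "C3", "C4"}, reactions)
        pairs = {frozenset({e.u, e.v}) for e in net.edges.values()}
        assert frozenset({"C1", "C3"}) not in pairs and len(pairs) == 2

    def test_unmeasured_partner_compound_included(self):
        reactions = pd.DataFrame([{"reaction_id": "r1", "compounds": "C1;C2", "enzymes": ""}])
        net = reaction_layer({"C1"}, reactions)
        assert "C2" in net.nodes and not net.nodes["C2"].measured

    def test_fully_unmeasured_reaction_skipped(self):
        reactions = pd.DataFrame([{"reaction_id": "r1", "compounds": "C8;C9", "enzymes": "E1"}])
        net = reaction_layer({"C1"}, reactions)
        assert len(net) == 0


class TestCrossLinks:
    def test_coding_row_yields_edge(self):
        edges = cross_link_ids(
            pd.DataFrame([{"id_a": "prot:TP53", "id_b": "rna:TP53", "relation": "coding"}])
        )
        assert len(edges) == 1 and edges[0].provenance == "coding"

    def test_empty_table_no_edges(self):
        assert cross_link_ids(pd.DataFrame(columns=["id_a", "id_b", "relation"])) == []

    def test_duplicates_deduplicated(self):
        row = {"id_a": "a", "id_b": "b", "relation": "tf_target"}
        edges = cross_link_ids(pd.DataFrame([row, row]))
        assert len(edges) == 1

    def test_unknown_relation_rejected(self):
        with pytest.raises(BuildError):
            cross_link_ids(pd.DataFrame([{"id_a": "a", "id_b": "b", "relation": "foo"}]))


class TestCorrelationLink:
    def test_monotone_pair_links_at_rho_one(self):
        a = pd.DataFrame([[1, 2, 3, 4, 5.0]], index=["x"])
        b = pd.DataFrame([[2, 4, 8, 16, 32.0]], index=["y"])
        edges = correlation_link(a, b, rho_min=0.99)
        assert len(edges) == 1 and edges[0].weight == pytest.approx(1.0)

    def test_threshold_excludes_rho_below(self):
        rng = np.random.default_rng(0)
        base = np.arange(10.0)
        noisy = base.copy()
        noisy[0], noisy[1] = noisy[1], noisy[0]  # one swap: rho < 0.99
        a = pd.DataFrame([base], index=["x"])
        b = pd.DataFrame([noisy], index=["y"])
        assert correlation_link(a, b, rho_min=0.99) == []

    def test_antimonotone_pair_weight_is_abs_rho(self):
        a = pd.DataFrame([[1, 2, 3, 4.0]], index=["x"])
        b = pd.DataFrame([[9, 7, 5, 3.0]], index=["y"])
        edges = correlation_link(a, b, rho_min=0.99)
        assert len(edges) == 1 and edges[0].weight == pytest.approx(1.0)


class TestSparCC:
    def test_identical_trajectories_give_rho_one(self):
        rng = np.random.default_rng(0)
        base = rng.lognormal(2, 1, size=(50, 4))
        counts = pd.DataFrame(np.hstack([base[:, :1], base]), columns=list("abcde"))
        rho, _ = sparcc_correlation(counts, pseudocount=0.0)
        assert rho.loc["a", "b"] == pytest.approx(1.0)

    def test_independent_basis_low_background(self):
        counts, _ = gen_compositional(planted_pairs=(), n_samples=500, seed=1)
        rho, _ = sparcc_correlation(counts)
        off = rho.to_numpy()[np.triu_indices(len(rho), 1)]
        assert float(np.abs(off).mean()) <= 0.1

    def test_planted_correlation_recovered(self):
        counts, truth = gen_compositional(seed=2)
        rho, _ = sparcc_correlation(counts)
        a, b, target = truth.basis_correlations[0]
        assert abs(float(rho.loc[a, b]) - target) <= 0.15

    def test_too_few_taxa_rejected(self):
        counts = pd.DataFrame(np.ones((10, 3)), columns=list("abc"))
        with pytest.raises(BuildError):
            sparcc_correlation(counts)


class TestAssemble:
    @staticmethod
    def builders_and_labels():
        def builder(ids):
            from netomics import MultiOmicsNetwork

            net = MultiOmicsNetwork("measured")
            for i in sorted(ids):
                net.add_node(NodeRecord(id=i, layer="gene", measured=True))
            return net

        table = KnowledgeTable(
            rows=pd.DataFrame(
                [("rna:a", "ext:hub"), ("rna:c", "ext:hub"), ("rna:a", "rna:b")],
                columns=["id_a", "id_b"],
            ),
            source="t",
        )

        def knowledge_builder(ids):
            return knowledge_layer(ids, table, layer="gene", extend=True)

        labels = {"rna:a": 1, "rna:b": 1, "rna:c": 2, "rna:d": 2}
        return [builder, knowledge_builder], labels

    def test_per_cluster_measured_sets_partition_entire(self):
        builders, labels = self.builders_and_labels()
        out = assemble(builders, list(labels), labels)
        entire_measured = {n.id for n in out.entire.nodes.values() if n.measured}
        union = set()
        for net in out.per_cluster.values():
            union |= {n.id for n in net.nodes.values() if n.measured}
        assert union == entire_measured

    def test_single_cluster_equals_entire(self):
        builders, labels = self.builders_and_labels()
        labels = {k: 1 for k in labels}
        out = assemble(builders, list(labels), labels)
        assert out.per_cluster[1] == out.entire

    def test_knowledge_hub_shared_across_cluster_networks(self):
        builders, labels = self.builders_and_labels()
        out = assemble(builders, list(labels), labels)
        present = [c for c, net in out.per_cluster.items() if "ext:hub" in net]
        assert len(present) >= 2

    def test_unlabeled_feature_only_in_entire_with_warning(self):
        builders, labels = self.builders_and_labels()
        out = assemble(builders, list(labels) + ["rna:zz"], labels)
        assert "rna:zz" in out.entire
        assert all("rna:zz" not in net for net in out.per_cluster.values())
        assert out.warnings


class TestMINetwork:
    def test_planted_edges_recovered_with_high_f1(self):
        from netomics import gen_regulatory

        expr, truth = gen_regulatory(seed=3)
        net = mi_network(expr, rng=substream(3, "mi"))
        pred = {frozenset({e.u, e.v}) for e in net.edges.values()}
        true = set(truth.regulatory_edges)
        tp = len(pred & true)
        prec = tp / max(len(pred), 1)
        rec = tp / len(true)
        f1 = 2 * prec * rec / max(prec + rec, 1e-12)
        assert f1 >= 0.7
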