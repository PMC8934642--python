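"""Layer construction and multi-layer network assembly.

Data-driven layers come from pairwise mutual information with
data-processing-inequality (DPI) pruning — the co-expression inference
strategy popularized by ARACNe — from compositionality-aware log-ratio
correlation for count tables (SparCC-style), and from cross-layer Spearman
screens at a high threshold.  Knowledge-driven layers are read from edge
tables emulating interaction-database exports (protein-protein interactions,
biochemical reactions, TF-target and protein-coding links), optionally
extended by first-degree unmeasured neighbours.  The assembler merges the
layers into one network and additionally rebuilds every layer per kinetic
cluster, so that each cluster gets its own sub-network reconstructed from
scratch on its members.
"""

from __future__ import annotations

import math
import warnings as _warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .graph_core import (
    EdgeRecord,
    GraphError,
    MultiOmicsNetwork,
    NodeRecord,
    layer_for_id,
    merge_networks,
)

#: DPI tolerance (fraction of the min adjacent MI an edge may fall short by).
DEFAULT_DPI_EPSILON = 0.15
#: Family-wise false-edge rate the default permutation-null MI floor controls.
DEFAULT_MI_NULL_ALPHA = 0.05
DEFAULT_MI_PERMUTATIONS = 20


class BuildError(ValueError):
    pass


# -- mutual information -------------------------------------------------------


@dataclass
class MIMatrix:
    """Symmetric pairwise mutual-information estimates with estimator settings."""

    values: pd.DataFrame  # features x features, diagonal NaN
    bins: int
    base: float  # log base: 2 -> bits, e -> nats
    n_samples: int

    @property
    def feature_ids(self) -> list:
        return list(self.values.index)


def _equal_frequency_bins(x: np.ndarray, bins: int) -> np.ndarray:
    """Rank-based discretization into ``bins`` near-equal-count bins."""
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x), dtype=np.int64)
    ranks[order] = np.arange(len(x))
    return (ranks * bins) // len(x)


def _pair_mi(bx: np.ndarray, by: np.ndarray, bins: int, base: float) -> float:
    joint = np.zeros((bins, bins), dtype=np.float64)
    np.add.at(joint, (bx, by), 1.0)
    n = len(bx)
    pxy = joint / n
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)
    mask = pxy > 0
    outer = np.outer(px, py)
    mi = float(np.sum(pxy[mask] * np.log(pxy[mask] / outer[mask])))
    return max(mi, 0.0) / math.log(base)


def estimate_mi(
    expr: pd.DataFrame,
    bins: Optional[int] = None,
    base: float = 2.0,
) -> MIMatrix:
    """Pairwise mutual information between feature rows of ``expr``.

    Each feature is discretized into ``bins`` equal-frequency bins (default
    floor(cbrt(n_samples)): the plug-in estimator's upward bias grows with
    bins^2 / n, and cube-root binning keeps it well below the MI scale of
    interest at desk-scale sample sizes) and MI is the plug-in estimate
    sum p(x, y) log[p(x, y) / (p(x) p(y))] in base ``base``.  Constant
    features get MI 0 against everything, with a warning.
    """
    X = expr.to_numpy(dtype=float)
    p, n = X.shape
    if n < 2:
        raise BuildError("need >=2 samples for MI estimation")
    if bins is None:
        bins = max(2, int(math.floor(n ** (1.0 / 3.0))))
    if bins < 2:
        raise BuildError("bins must be >= 2")
    constant = np.array([np.nanstd(X[i]) == 0 for i in range(p)])
    if constant.any():
        _warnings.warn(
            f"{int(constant.sum())} constant feature(s); their MI is defined as 0",
            stacklevel=2,
        )
    binned = np.stack([_equal_frequency_bins(X[i], bins) for i in range(p)])
    M = np.full((p, p), np.nan)
    for i in range(p):
        for j in range(i + 1, p):
            mi = 0.0 if (constant[i] or constant[j]) else _pair_mi(binned[i], binned[j], bins, base)
            M[i, j] = M[j, i] = mi
    return MIMatrix(
        values=pd.DataFrame(M, index=expr.index, columns=expr.index),
        bins=bins,
        base=base,
        n_samples=n,
    )


def mi_permutation_floor(
    expr: pd.DataFrame,
    bins: Optional[int] = None,
    base: float = 2.0,
    n_permutations: int = DEFAULT_MI_PERMUTATIONS,
    quantile: Optional[float] = None,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """MI floor from a permutation null: shuffle samples independently per
    feature, recompute all pairwise MIs, take the ``quantile`` of the pool.

    The default quantile is Bonferroni-style, 1 - alpha / n_pairs with
    alpha = 0.05, so that on independent data the *network* carries about
    alpha false edges rather than alpha false edges per pair."""
    rng = rng or np.random.default_rng(0)
    if quantile is None:
        n_pairs = expr.shape[0] * (expr.shape[0] - 1) // 2
        quantile = 1.0 - DEFAULT_MI_NULL_ALPHA / max(n_pairs, 1)
    null = []
    for _ in range(n_permutations):
        perm = expr.to_numpy(dtype=float).copy()
        for i in range(perm.shape[0]):
            rng.shuffle(perm[i])
        m = estimate_mi(pd.DataFrame(perm, index=expr.index), bins=bins, base=base)
        vals = m.values.to_numpy()
        null.append(vals[np.triu_indices_from(vals, k=1)])
    return float(np.quantile(np.concatenate(null), quantile))


def dpi_prune(
    mi: MIMatrix,
    mi_floor: float,
    epsilon: float = DEFAULT_DPI_EPSILON,
) -> list:
    """Threshold the MI matrix and prune likely-indirect edges by the data
    processing inequality.

    Starting from edges with MI >= ``mi_floor``, every triangle (i, j, k)
    marks edge (i, j) for removal when
    MI(i, j) < (1 - epsilon) * min(MI(i, k), MI(j, k)); all marked edges are
    removed simultaneously.  Returns ``[(id_a, id_b, mi), ...]``.
    """
    if not (0 <= epsilon < 1):
        raise BuildError("epsilon must satisfy 0 <= epsilon < 1")
    ids = mi.feature_ids
    M = mi.values.to_numpy(dtype=float)
    p = len(ids)
    adj = np.zeros((p, p), dtype=bool)
    iu = np.triu_indices(p, k=1)
    keep = M[iu] >= mi_floor
    adj[iu[0][keep], iu[1][keep]] = True
    adj |= adj.T
    marked = np.zeros((p, p), dtype=bool)
    for i in range(p):
        for j in range(i + 1, p):
            if not adj[i, j]:
                continue
            ks = np.where(adj[i] & adj[j])[0]
            for k in ks:
                if M[i, j] < (1 - epsilon) * min(M[i, k], M[j, k]):
                    marked[i, j] = True
                    break
    edges = []
    for i in range(p):
        for j in range(i + 1, p):
            if adj[i, j] and not marked[i, j]:
                edges.append((ids[i], ids[j], float(M[i, j])))
    return edges


def mi_network(
    expr: pd.DataFrame,
    layer: str = "gene",
    bins: Optional[int] = None,
    base: float = 2.0,
    mi_floor: Optional[float] = None,
    epsilon: float = DEFAULT_DPI_EPSILON,
    rng: Optional[np.random.Generator] = None,
    name: str = "mi",
) -> MultiOmicsNetwork:
    """Full inference route: MI estimation, permutation-null floor, DPI prune,
    assembled into a measured-node network with ``inferred_mi`` provenance."""
    mi = estimate_mi(expr, bins=bins, base=base)
    if mi_floor is None:
        mi_floor = mi_permutation_floor(expr, bins=bins, base=base, rng=rng)
    edges = dpi_prune(mi, mi_floor, epsilon)
    net = MultiOmicsNetwork(name)
    for feat in expr.index:
        net.add_node(NodeRecord(id=feat, layer=layer_for_id(feat, layer), measured=True))
    for a, b, w in edges:
        net.add_edge(EdgeRecord(u=a, v=b, provenance="inferred_mi", weight=w))
    return net


# -- knowledge layers ---------------------------------------------------------


@dataclass
class KnowledgeTable:
    """Interaction rows from a database export: (id_a, id_b, type, score)."""

    rows: pd.DataFrame  # columns id_a, id_b, [interaction], [score]
    source: str = "knowledge"

    def __post_init__(self) -> None:
        for col in ("id_a", "id_b"):
            if col not in self.rows.columns:
                raise BuildError(f"knowledge table lacks column {col!r}")
            if (self.rows[col].astype(str).str.len() == 0).any():
                raise BuildError("empty ids in knowledge table")
        if "score" in self.rows.columns:
            scores = pd.to_numeric(self.rows["score"], errors="coerce")
            if self.rows["score"].notna().any() and scores.isna().any():
                raise BuildError("non-numeric scores in knowledge table")

    @classmethod
    def read_tsv(cls, path: Union[str, Path], source: str = "") -> "KnowledgeTable":
        rows = pd.read_csv(path, sep="\t")
        return cls(rows=rows, source=source or Path(str(path)).stem)


def knowledge_layer(
    measured_ids: Iterable[str],
    table: KnowledgeTable,
    score_min: Optional[float] = None,
    extend: bool = True,
    layer: str = "protein",
    provenance: str = "knowledge_ppi",
    name: str = "knowledge",
) -> MultiOmicsNetwork:
    """Knowledge sub-network on measured molecules, optionally extended by
    their first-degree database neighbours (flagged unmeasured).

    Rows with a score below ``score_min`` are discarded first (unscored rows
    always pass).  Nodes are the measured ids present in the table, plus
    (when ``extend``) their direct interactors; edges are the surviving rows
    with both endpoints in that node set.
    """
    measured = set(measured_ids)
    rows = table.rows
    if score_min is not None and "score" in rows.columns:
        scores = pd.to_numeric(rows["score"], errors="coerce")
        rows = rows[scores.isna() | (scores >= score_min)]
    pairs = list(zip(rows["id_a"].astype(str), rows["id_b"].astype(str)))
    weights = (
        pd.to_numeric(rows["score"], errors="coerce").fillna(1.0).to_numpy()
        if "score" in rows.columns
        else np.ones(len(rows))
    )
    in_table = {a for a, _ in pairs} | {b for _, b in pairs}
    nodes = measured & in_table
    if extend:
        for a, b in pairs:
            if a in measured and b not in measured:
                nodes.add(b)
            if b in measured and a not in measured:
                nodes.add(a)
    net = MultiOmicsNetwork(name)
    for nid in sorted(nodes):
        net.add_node(
            NodeRecord(id=nid, layer=layer_for_id(nid, layer), measured=nid in measured)
        )
    for (a, b), w in zip(pairs, weights):
        if a in nodes and b in nodes and a != b:
            net.add_edge(EdgeRecord(u=a, v=b, provenance=provenance, weight=float(w)))
    return net


def reaction_layer(
    measured_metabolites: Iterable[str],
    reactions: pd.DataFrame,
    name: str = "reactions",
) -> MultiOmicsNetwork:
    """Biochemical-reaction layer: clique edges among compounds sharing a
    reaction plus enzyme-compound edges for co-occurrence in a reaction.

    ``reactions`` columns: reaction_id, compounds (``;``-separated ids),
    enzymes (``;``-separated ids, may be empty).  Non-measured compounds are
    included only when a reaction also involves a measured one (first degree).
    """
    measured = set(measured_metabolites)
    net = MultiOmicsNetwork(name)

    def split(cell) -> list:
        if pd.isna(cell) or not str(cell):
            return []
        return [x for x in str(cell).split(";") if x]

    for _, row in reactions.iterrows():
        compounds = split(row.get("compounds"))
        enzymes = split(row.get("enzymes"))
        if not any(c in measured for c in compounds):
            continue
        for c in compounds:
            net.add_node(
                NodeRecord(id=c, layer=layer_for_id(c, "metabolite"), measured=c in measured),
                merge=True,
            )
        for e in enzymes:
            net.add_node(
                NodeRecord(id=e, layer=layer_for_id(e, "protein"), measured=e in measured),
                merge=True,
            )
        for i, c1 in enumerate(compounds):
            for c2 in compounds[i + 1 :]:
                if c1 != c2:
                    net.add_edge(
                        EdgeRecord(u=c1, v=c2, provenance="knowledge_reaction")
                    )
        for e in enzymes:
            for c in compounds:
                if e != c:
                    net.add_edge(
                        EdgeRecord(u=e, v=c, provenance="knowledge_reaction", source_role=e)
                    )
    return net


def cross_link_ids(map_table: pd.DataFrame) -> list:
    """Identifier cross-links between layers: one edge per (id_a, id_b,
    relation) row, relation in {coding, tf_target}; duplicates collapse."""
    edges = {}
    for _, row in map_table.iterrows():
        a, b, rel = str(row["id_a"]), str(row["id_b"]), str(row["relation"])
        if rel not in ("coding", "tf_target"):
            raise BuildError(f"unknown cross-link relation {rel!r}")
        edge = EdgeRecord(u=a, v=b, provenance=rel, source_role=a if rel == "tf_target" else None)
        edges[edge.key] = edge
    return [edges[k] for k in sorted(edges)]


# -- correlation layers -------------------------------------------------------


def correlation_link(
    block_a: pd.DataFrame,
    block_b: pd.DataFrame,
    rho_min: float,
    method: str = "spearman",
) -> list:
    """Cross-layer links: (a, b) edges for feature pairs across two blocks
    (features x shared grid) with |rank correlation| >= ``rho_min``."""
    if block_a.shape[1] != block_b.shape[1]:
        raise BuildError("blocks must share the sample/time grid")
    if method != "spearman":
        raise BuildError(f"unsupported correlation method {method!r}")
    A = stats.rankdata(block_a.to_numpy(dtype=float), axis=1)
    B = stats.rankdata(block_b.to_numpy(dtype=float), axis=1)
    A = (A - A.mean(axis=1, keepdims=True)) / np.maximum(A.std(axis=1, keepdims=True), 1e-300)
    B = (B - B.mean(axis=1, keepdims=True)) / np.maximum(B.std(axis=1, keepdims=True), 1e-300)
    rho = (A @ B.T) / block_a.shape[1]
    edges = []
    for i, a in enumerate(block_a.index):
        for j, b in enumerate(block_b.index):
            r = float(np.clip(rho[i, j], -1.0, 1.0))
            if abs(r) >= rho_min and a != b:
                edges.append(EdgeRecord(u=str(a), v=str(b), provenance="correlation", weight=abs(r)))
    return edges


def sparcc_correlation(
    counts: pd.DataFrame,
    rho_min: float = 0.3,
    pseudocount: float = 0.5,
) -> tuple:
    """Compositionality-aware correlation for count tables (samples x taxa).

    Single-pass log-ratio variance estimator: with fractions x_i,
    t_ij = var(log(x_i / x_j)); under sparsity the component variances w_i^2
    solve the linear system sum_j t_ij = (D - 1) w_i^2 + sum_{j != i} w_j^2,
    and rho_ij = (w_i^2 + w_j^2 - t_ij) / (2 w_i w_j), clipped to [-1, 1].
    Returns ``(rho DataFrame, edges with |rho| >= rho_min)``.  No iterative
    strong-pair exclusion is performed.
    """
    D = counts.shape[1]
    if D < 4:
        raise BuildError("SparCC needs >= 4 taxa (system underdetermined)")
    X = counts.to_numpy(dtype=float) + pseudocount
    if np.any(X <= 0):
        raise BuildError("counts must be positive after pseudocount")
    frac = X / X.sum(axis=1, keepdims=True)
    logf = np.log(frac)
    T = np.zeros((D, D))
    for i in range(D):
        diff = logf[:, i : i + 1] - logf
        T[i] = diff.var(axis=0)
    t_row = T.sum(axis=1)
    M = np.full((D, D), 1.0) + np.eye(D) * (D - 2)
    omega2 = np.linalg.solve(M, t_row)
    omega2 = np.maximum(omega2, 1e-12)
    omega = np.sqrt(omega2)
    rho = (omega2[:, None] + omega2[None, :] - T) / (2.0 * np.outer(omega, omega))
    rho = np.clip(rho, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    taxa = list(counts.columns)
    edges = []
    for i in range(D):
        for j in range(i + 1, D):
            if abs(rho[i, j]) >= rho_min:
                edges.append(
                    EdgeRecord(
                        u=str(taxa[i]),
                        v=str(taxa[j]),
                        provenance="correlation",
                        weight=abs(float(rho[i, j])),
                    )
                )
    return pd.DataFrame(rho, index=taxa, columns=taxa), edges


def sparcc_network(
    counts: pd.DataFrame,
    rho_min: float = 0.3,
    layer: str = "otu",
    name: str = "microbiome",
) -> MultiOmicsNetwork:
    """SparCC-style co-occurrence network over all taxa (measured nodes)."""
    _, edges = sparcc_correlation(counts, rho_min=rho_min)
    net = MultiOmicsNetwork(name)
    for taxon in counts.columns:
        net.add_node(NodeRecord(id=str(taxon), layer=layer_for_id(str(taxon), layer), measured=True))
    for e in edges:
        net.add_edge(e)
    return net


# -- assembly -----------------------------------------------------------------


@dataclass
class AssembledNetworks:
    entire: MultiOmicsNetwork
    per_cluster: dict  # cluster label -> MultiOmicsNetwork
    warnings: list = field(default_factory=list)


LayerBuilder = Callable[[Iterable[str]], MultiOmicsNetwork]


def assemble(
    layer_builders: Sequence[LayerBuilder],
    measured_ids: Iterable[str],
    cluster_labels: Mapping[str, int],
    cross_links: Sequence[EdgeRecord] = (),
    name: str = "multiomics",
) -> AssembledNetworks:
    """Build the entire network and one network per kinetic cluster.

    Each builder maps a set of measured feature ids to one layer.  The entire
    network is the merge of all layers built on all measured ids plus the
    cross-link edges, with nodes stamped by their cluster label.  Per-cluster
    networks are rebuilt from scratch on that cluster's measured features
    (inference re-run, knowledge extension re-applied), so unmeasured
    knowledge nodes may appear in several cluster networks.  Measured
    features without a cluster label go into the entire network only, with a
    warning.
    """
    measured_ids = sorted(set(measured_ids))
    warnings = []
    unlabeled = [m for m in measured_ids if m not in cluster_labels]
    if unlabeled:
        warnings.append(
            f"{len(unlabeled)} measured feature(s) without cluster label kept in entire network only"
        )

    def build_on(ids, net_name):
        nets = [builder(ids) for builder in layer_builders]
        merged = merge_networks(nets, name=net_name)
        present = set(merged.nodes)
        for edge in cross_links:
            for end in (edge.u, edge.v):
                if end not in present and (edge.u in present or edge.v in present):
                    merged.add_node(
                        NodeRecord(id=end, layer=layer_for_id(end), measured=False)
                    )
                    present.add(end)
            if edge.u in present and edge.v in present:
                merged.add_edge(
                    EdgeRecord(
                        u=edge.u,
                        v=edge.v,
                        provenance=edge.provenance,
                        weight=edge.weight,
                        source_role=edge.source_role,
                    )
                )
        return merged

    entire = build_on(measured_ids, name)
    _stamp_clusters(entire, cluster_labels)

    clusters = sorted(set(cluster_labels[m] for m in measured_ids if m in cluster_labels))
    per_cluster = {}
    for c in clusters:
        ids_c = [m for m in measured_ids if cluster_labels.get(m) == c]
        net_c = build_on(ids_c, f"{name}|cluster{c}")
        _stamp_clusters(net_c, cluster_labels)
        per_cluster[c] = net_c
    return AssembledNetworks(entire=entire, per_cluster=per_cluster, warnings=warnings)


def _stamp_clusters(net: MultiOmicsNetwork, cluster_labels: Mapping[str, int]) -> None:
    for nid, node in net.nodes.items():
        if node.measured and nid in cluster_labels:
            node.cluster = int(cluster_labels[nid])
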