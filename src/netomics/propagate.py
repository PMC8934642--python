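"""Random walk with restart (RWR) and its three interpretation procedures.

A particle moves on the merged (monoplex) network: from node x it steps to a
uniformly chosen neighbour (probability 1/d(x)), and at every step it
returns to the seed distribution p0 with probability r.  Iterating
p <- (1 - r) W p + r p0 to a steady state gives each node a probability
score measuring its proximity to the seed; this is the unique solution of
(I - (1 - r) W) p = r p0.  Parallel edges with different provenances are
collapsed to one adjacency entry before the walk; an optional weighted mode
normalizes edge weights per column instead of using 1/d(x).

Three interpretation procedures follow the scores:

* mechanism sub-networks — each enrichment-term node becomes a seed and the
  top-k closest nodes form a sub-network, screened for reaching several
  molecular layers at once;
* function prediction — unannotated molecules become seeds and inherit the
  closest term node per ontology (guilt by association);
* kinetic-cluster intersection — each measured molecule becomes a seed and
  sub-networks mixing cluster labels and containing a term node flag
  candidate cross-cluster regulators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .graph_core import (
    MOLECULE_LAYERS,
    TERM_LAYERS,
    GraphError,
    MultiOmicsNetwork,
    induced_subnetwork,
)

#: Default restart probability (the convention of monoplex RWR toolkits).
DEFAULT_RESTART = 0.7


class PropagationError(ValueError):
    pass


@dataclass
class WalkConfig:
    """Restart probability, convergence control, and edge-weight mode."""

    restart: float = DEFAULT_RESTART
    tolerance: float = 1e-10
    max_iterations: int = 10_000
    weighted: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.restart <= 1.0):
            raise PropagationError(f"restart must be in [0, 1], got {self.restart}")
        if self.tolerance <= 0:
            raise PropagationError("tolerance must be positive")


@dataclass
class PropagationResult:
    """Steady-state scores for one seed set."""

    seeds: frozenset
    scores: dict  # node id -> probability
    ranking: list  # non-seed node ids by descending score (ties: lexicographic)
    iterations: int

    def top(self, k: int) -> list:
        return self.ranking[:k]


def transition_matrix(net: MultiOmicsNetwork, weighted: bool = False):
    """Column-stochastic transition matrix over the collapsed simple graph.

    Unweighted: column x puts 1/d(x) on every neighbour of x.  Weighted:
    parallel provenance edges collapse to their maximum weight, normalized
    per column.  Isolated nodes get a self-loop of 1 so columns stay
    stochastic.  Returns ``(W, node_order)``.
    """
    ids = net.node_ids()
    if not ids:
        raise PropagationError("empty graph")
    index = {nid: i for i, nid in enumerate(ids)}
    n = len(ids)
    A = np.zeros((n, n))
    for edge in net.edges.values():
        i, j = index[edge.u], index[edge.v]
        w = edge.weight if weighted else 1.0
        A[i, j] = max(A[i, j], w)
        A[j, i] = A[i, j]
    col = A.sum(axis=0)
    isolated = col == 0
    A[np.where(isolated)[0], np.where(isolated)[0]] = 1.0
    col = A.sum(axis=0)
    return A / col, ids


def rwr(
    net: MultiOmicsNetwork,
    seeds: Iterable[str],
    config: Optional[WalkConfig] = None,
) -> PropagationResult:
    """Random walk with restart from a uniform distribution over ``seeds``.

    Iterates p <- (1 - r) W p + r p0 until the L1 change drops below the
    configured tolerance; the fixed point solves (I - (1 - r) W) p = r p0.
    """
    config = config or WalkConfig()
    seeds = sorted(set(seeds))
    if not seeds:
        raise PropagationError("empty seed set")
    missing = [s for s in seeds if s not in net]
    if missing:
        raise PropagationError(f"seeds not in network: {missing}")
    W, ids = transition_matrix(net, weighted=config.weighted)
    index = {nid: i for i, nid in enumerate(ids)}
    p0 = np.zeros(len(ids))
    for s in seeds:
        p0[index[s]] = 1.0 / len(seeds)
    r = config.restart
    p = p0.copy()
    if r == 1.0:
        iterations = 0
    else:
        for iterations in range(1, config.max_iterations + 1):
            p_next = (1.0 - r) * (W @ p) + r * p0
            delta = float(np.abs(p_next - p).sum())
            p = p_next
            if delta < config.tolerance:
                break
        else:
            raise PropagationError(
                f"no convergence in {config.max_iterations} iterations (residual {delta:.3e})"
            )
    scores = {nid: float(p[index[nid]]) for nid in ids}
    seed_set = set(seeds)
    ranking = sorted(
        (nid for nid in ids if nid not in seed_set),
        key=lambda nid: (-scores[nid], nid),
    )
    return PropagationResult(
        seeds=frozenset(seeds), scores=scores, ranking=ranking, iterations=iterations
    )


# -- interpretation -----------------------------------------------------------


@dataclass
class SeedSubnetwork:
    seed: str
    subnetwork: MultiOmicsNetwork
    reach: dict  # layer -> count among the top-k nodes
    screens: dict = field(default_factory=dict)
    clusters_reached: Optional[set] = None
    terms_reached: Optional[list] = None
    top_nodes: list = field(default_factory=list)


def _reach_profile(net: MultiOmicsNetwork, node_ids: Sequence[str]) -> dict:
    reach: dict = {}
    for nid in node_ids:
        layer = net.nodes[nid].layer
        reach[layer] = reach.get(layer, 0) + 1
    return reach


def mechanism_subnetworks(
    net: MultiOmicsNetwork,
    term_seeds: Optional[Iterable[str]] = None,
    k: int = 25,
    config: Optional[WalkConfig] = None,
) -> list:
    """Seed every enrichment-term node, keep its top-k closest nodes.

    For each seed the induced sub-network of {seed} + top-k and the per-layer
    reach profile are returned; the screens record whether the walk reached
    both genes and proteins, and genes + proteins + metabolites (genes count
    the ``gene`` and ``tf`` layers together)."""
    if term_seeds is None:
        term_seeds = [nid for nid, node in net.nodes.items() if node.layer in TERM_LAYERS]
    out = []
    for seed in sorted(term_seeds):
        result = rwr(net, [seed], config)
        top = result.top(k)
        reach = _reach_profile(net, top)
        genes = reach.get("gene", 0) + reach.get("tf", 0)
        screens = {
            "reaches_gene_and_protein": genes > 0 and reach.get("protein", 0) > 0,
            "reaches_gene_protein_metabolite": genes > 0
            and reach.get("protein", 0) > 0
            and reach.get("metabolite", 0) > 0,
        }
        sub = induced_subnetwork(net, [seed, *top], name=f"rwr:{seed}")
        out.append(
            SeedSubnetwork(seed=seed, subnetwork=sub, reach=reach, screens=screens, top_nodes=top)
        )
    return out


def unannotated_nodes(net: MultiOmicsNetwork) -> list:
    """Molecule nodes with no annotation-provenance edge."""
    annotated = set()
    for edge in net.edges.values():
        if edge.provenance == "annotation":
            annotated.add(edge.u)
            annotated.add(edge.v)
    return sorted(
        nid
        for nid, node in net.nodes.items()
        if node.layer in MOLECULE_LAYERS and nid not in annotated
    )


def predict_function(
    net: MultiOmicsNetwork,
    nodes: Optional[Iterable[str]] = None,
    ontologies: Optional[Sequence[str]] = None,
    config: Optional[WalkConfig] = None,
) -> dict:
    """Guilt-by-association function prediction.

    Each unannotated molecule becomes a seed; per ontology it is assigned
    the highest-scoring term node of that ontology (with its score), or
    ``None`` when no term node of the ontology is reachable.  Existing
    annotation edges are not masked during the walk."""
    if nodes is None:
        nodes = unannotated_nodes(net)
    term_nodes: dict = {}
    for nid, node in net.nodes.items():
        if node.layer in TERM_LAYERS:
            onto = node.ontology or node.layer
            term_nodes.setdefault(onto, []).append(nid)
    if ontologies is None:
        ontologies = sorted(term_nodes)
    assignments: dict = {}
    for seed in sorted(set(nodes)):
        result = rwr(net, [seed], config)
        per_onto = {}
        for onto in ontologies:
            best = None
            for tid in term_nodes.get(onto, []):
                score = result.scores[tid]
                if score > 0 and (best is None or score > best[1] or (score == best[1] and tid < best[0])):
                    best = (tid, score)
            per_onto[onto] = {"term": best[0], "score": best[1]} if best else None
        assignments[seed] = per_onto
    return assignments


def cluster_intersection(
    net: MultiOmicsNetwork,
    seeds: Optional[Iterable[str]] = None,
    k: int = 10,
    config: Optional[WalkConfig] = None,
) -> list:
    """Locate candidate cross-cluster regulators.

    Every measured molecule is seeded in turn; a seed is retained when its
    top-k sub-network contains at least one node carrying a kinetic-cluster
    label different from the seed's own, and at least one term node."""
    if seeds is None:
        seeds = [nid for nid, node in net.nodes.items() if node.measured]
    retained = []
    for seed in sorted(set(seeds)):
        if seed not in net:
            raise PropagationError(f"seed {seed!r} not in network")
        result = rwr(net, [seed], config)
        top = result.top(k)
        seed_clusters = _clusters_of(net, seed)
        other_clusters = set()
        terms = []
        for nid in top:
            node = net.nodes[nid]
            if node.layer in TERM_LAYERS:
                terms.append(nid)
            diff = _clusters_of(net, nid) - seed_clusters
            other_clusters |= diff
        if other_clusters and terms:
            sub = induced_subnetwork(net, [seed, *top], name=f"rwr:{seed}")
            retained.append(
                SeedSubnetwork(
                    seed=seed,
                    subnetwork=sub,
                    reach=_reach_profile(net, top),
                    clusters_reached=seed_clusters | other_clusters,
                    terms_reached=terms,
                    top_nodes=top,
                )
            )
    return retained


def _clusters_of(net: MultiOmicsNetwork, nid: str) -> set:
    c = net.nodes[nid].cluster
    if c is None:
        return set()
    if isinstance(c, frozenset):
        return set(c)
    return {c}
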