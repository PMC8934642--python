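"""Typed multi-layer graph model, invariants, and file I/O.

The central container is :class:`MultiOmicsNetwork`, an undirected graph whose
nodes belong to biological layers (gene, tf, protein, metabolite, otu,
clinical, go_term, disease) and whose edges carry a *provenance* tag saying
where the interaction came from (mutual-information inference, a knowledge
database, an identifier cross-link, a correlation screen, or an annotation).
Several edges may connect the same pair of nodes as long as their provenance
differs; propagation collapses them (see :mod:`netomics.propagate`).

Node identifiers live in a single flat namespace.  Callers disambiguate
colliding symbols across omics with prefixes (``rna:``, ``prot:``, ``met:``,
``otu:``, ``clin:``, ``go:``, ``dis:``, ``tf:``); the assembler applies these
by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence, Union

import networkx as nx

LAYERS = ("gene", "tf", "protein", "metabolite", "otu", "clinical", "go_term", "disease")
#: Layers holding enrichment-derived term nodes rather than molecules.
TERM_LAYERS = ("go_term", "disease")
MOLECULE_LAYERS = tuple(l for l in LAYERS if l not in TERM_LAYERS)

PROVENANCES = (
    "inferred_mi",
    "knowledge_ppi",
    "knowledge_reaction",
    "coding",
    "tf_target",
    "correlation",
    "annotation",
)

#: Default mapping from id prefix to layer, used when reading edge tables.
PREFIX_LAYERS = {
    "rna": "gene",
    "tf": "tf",
    "prot": "protein",
    "met": "metabolite",
    "otu": "otu",
    "clin": "clinical",
    "go": "go_term",
    "dis": "disease",
}


class GraphError(ValueError):
    """Raised on violations of the network data model."""


def layer_for_id(node_id: str, default: str = "gene") -> str:
    """Infer a node's layer from its ``prefix:`` if it carries one."""
    if ":" in node_id:
        prefix = node_id.split(":", 1)[0]
        if prefix in PREFIX_LAYERS:
            return PREFIX_LAYERS[prefix]
    return default


@dataclass
class NodeRecord:
    """A node: one molecule, clinical variable, or enrichment term.

    ``measured`` distinguishes profiled molecules from knowledge-database
    extensions; term nodes are never measured and never carry a kinetic
    cluster.  ``cluster`` is an ``int`` label, or a frozenset of labels when
    merging networks produced conflicting assignments.
    """

    id: str
    layer: str
    measured: bool = False
    cluster: Optional[Union[int, frozenset]] = None
    label: Optional[str] = None
    ontology: Optional[str] = None

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise GraphError(f"unknown layer {self.layer!r} for node {self.id!r}")
        if self.layer in TERM_LAYERS:
            if self.measured:
                raise GraphError(f"term node {self.id!r} cannot be measured")
            if self.cluster is not None:
                raise GraphError(f"term node {self.id!r} cannot carry a cluster label")


def _pair(a: str, b: str) -> tuple:
    return (a, b) if a <= b else (b, a)


@dataclass
class EdgeRecord:
    """An undirected edge with a provenance tag and a non-negative weight.

    TF->target and enzyme->compound inputs are stored undirected; the
    semantic direction, when present, survives in ``source_role`` (the id of
    the regulating/annotating endpoint).
    """

    u: str
    v: str
    provenance: str
    weight: float = 1.0
    source_role: Optional[str] = None

    def __post_init__(self) -> None:
        if self.u == self.v:
            raise GraphError(f"self-edge on {self.u!r}")
        if self.provenance not in PROVENANCES:
            raise GraphError(f"unknown provenance {self.provenance!r}")
        if not (self.weight >= 0.0):
            raise GraphError(f"negative weight on edge {self.u!r}-{self.v!r}")
        self.u, self.v = _pair(self.u, self.v)

    @property
    def key(self) -> tuple:
        return (self.u, self.v, self.provenance)


class MultiOmicsNetwork:
    """Undirected multi-layer graph G = (V, E).

    At most one edge exists per (node pair, provenance); every edge endpoint
    must be a known node.
    """

    def __init__(self, name: str = "network") -> None:
        self.name = name
        self._nodes: dict = {}
        self._edges: dict = {}
        self._adj: dict = {}

    # -- construction -----------------------------------------------------

    def add_node(self, node: NodeRecord, *, merge: bool = False) -> NodeRecord:
        existing = self._nodes.get(node.id)
        if existing is None:
            self._nodes[node.id] = node
            self._adj[node.id] = set()
            return node
        merged = _resolve_nodes(existing, node) if merge else existing
        self._nodes[node.id] = merged
        return merged

    def add_edge(self, edge: EdgeRecord) -> EdgeRecord:
        for end in (edge.u, edge.v):
            if end not in self._nodes:
                raise GraphError(f"edge endpoint {end!r} is not a node")
        self._edges[edge.key] = edge
        self._adj[edge.u].add(edge.v)
        self._adj[edge.v].add(edge.u)
        return edge

    # -- access -----------------------------------------------------------

    @property
    def nodes(self) -> Mapping[str, NodeRecord]:
        return self._nodes

    @property
    def edges(self) -> Mapping[tuple, EdgeRecord]:
        return self._edges

    def node_ids(self) -> list:
        return sorted(self._nodes)

    def neighbors(self, node_id: str) -> set:
        return set(self._adj[node_id])

    def degree(self, node_id: str) -> int:
        """Number of distinct neighbours (parallel provenances collapse)."""
        return len(self._adj[node_id])

    def __len__(self) -> int:
        return len(self._nodes)

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._nodes

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MultiOmicsNetwork):
            return NotImplemented
        return self._nodes == other._nodes and self._edges == other._edges

    def copy(self, name: Optional[str] = None) -> "MultiOmicsNetwork":
        out = MultiOmicsNetwork(name or self.name)
        for node in self._nodes.values():
            out.add_node(replace(node))
        for edge in self._edges.values():
            out.add_edge(replace(edge))
        return out

    def to_networkx(self) -> nx.MultiGraph:
        """Export as a networkx MultiGraph, edge key = provenance."""
        g = nx.MultiGraph(name=self.name)
        for node in self._nodes.values():
            attrs = {"layer": node.layer, "measured": node.measured}
            if node.cluster is not None:
                attrs["cluster"] = _cluster_str(node.cluster)
            if node.label is not None:
                attrs["label"] = node.label
            if node.ontology is not None:
                attrs["ontology"] = node.ontology
            g.add_node(node.id, **attrs)
        for edge in self._edges.values():
            attrs = {"provenance": edge.provenance, "weight": edge.weight}
            if edge.source_role is not None:
                attrs["source_role"] = edge.source_role
            g.add_edge(edge.u, edge.v, key=edge.provenance, **attrs)
        return g


def _cluster_str(cluster: Union[int, frozenset]) -> str:
    if isinstance(cluster, frozenset):
        return "|".join(str(c) for c in sorted(cluster))
    return str(cluster)


def _cluster_from_str(s: str) -> Union[int, frozenset]:
    parts = s.split("|")
    if len(parts) == 1:
        return int(parts[0])
    return frozenset(int(p) for p in parts)


def _cluster_set(c: Union[int, frozenset, None]) -> frozenset:
    if c is None:
        return frozenset()
    if isinstance(c, frozenset):
        return c
    return frozenset([c])


def _resolve_nodes(a: NodeRecord, b: NodeRecord) -> NodeRecord:
    """Attribute-resolution rule for shared nodes: measured=True wins,
    disagreeing cluster labels accumulate into a set."""
    if a.layer != b.layer:
        raise GraphError(f"node {a.id!r} has conflicting layers {a.layer!r} / {b.layer!r}")
    clusters = _cluster_set(a.cluster) | _cluster_set(b.cluster)
    if not clusters:
        cluster = None
    elif len(clusters) == 1:
        cluster = next(iter(clusters))
    else:
        cluster = clusters
    return NodeRecord(
        id=a.id,
        layer=a.layer,
        measured=a.measured or b.measured,
        cluster=cluster,
        label=a.label if a.label is not None else b.label,
        ontology=a.ontology if a.ontology is not None else b.ontology,
    )


# -- operations ---------------------------------------------------------------


def _resolve_edges(a: EdgeRecord, b: EdgeRecord) -> EdgeRecord:
    """Order-independent resolution of duplicate (pair, provenance) edges:
    the larger weight wins; on ties the smaller non-None source_role."""
    if a.weight != b.weight:
        return replace(a if a.weight > b.weight else b)
    roles = sorted(r for r in (a.source_role, b.source_role) if r is not None)
    return EdgeRecord(
        u=a.u, v=a.v, provenance=a.provenance, weight=a.weight,
        source_role=roles[0] if roles else None,
    )


def merge_networks(
    networks: Sequence[MultiOmicsNetwork], name: str = "merged"
) -> MultiOmicsNetwork:
    """Union of layers: node set union with attribute resolution, edge union
    keyed by (pair, provenance)."""
    out = MultiOmicsNetwork(name)
    for net in networks:
        for node in net.nodes.values():
            out.add_node(replace(node), merge=True)
    for net in networks:
        for edge in net.edges.values():
            existing = out.edges.get(edge.key)
            out.add_edge(replace(edge) if existing is None else _resolve_edges(existing, edge))
    return out


def induced_subnetwork(
    net: MultiOmicsNetwork, ids: Iterable[str], name: Optional[str] = None
) -> MultiOmicsNetwork:
    """Sub-network on exactly ``ids``, keeping edges with both endpoints inside."""
    ids = set(ids)
    unknown = ids - set(net.nodes)
    if unknown:
        raise GraphError(f"unknown node ids: {sorted(unknown)}")
    out = MultiOmicsNetwork(name or f"{net.name}|induced")
    for nid in ids:
        out.add_node(replace(net.nodes[nid]))
    for edge in net.edges.values():
        if edge.u in ids and edge.v in ids:
            out.add_edge(replace(edge))
    return out


def summarize(net: MultiOmicsNetwork) -> dict:
    """Basic network statistics: counts per layer and provenance, connected
    components, isolated nodes."""
    layer_counts = {layer: 0 for layer in LAYERS}
    for node in net.nodes.values():
        layer_counts[node.layer] += 1
    prov_counts = {prov: 0 for prov in PROVENANCES}
    for edge in net.edges.values():
        prov_counts[edge.provenance] += 1
    if len(net) == 0:
        n_components = 0
    else:
        g = nx.Graph()
        g.add_nodes_from(net.nodes)
        g.add_edges_from((e.u, e.v) for e in net.edges.values())
        n_components = nx.number_connected_components(g)
    isolated = sum(1 for nid in net.nodes if net.degree(nid) == 0)
    return {
        "n_nodes": len(net),
        "n_edges": len(net.edges),
        "nodes_by_layer": {k: v for k, v in layer_counts.items() if v},
        "edges_by_provenance": {k: v for k, v in prov_counts.items() if v},
        "n_components": n_components,
        "n_isolated": isolated,
        "n_measured": sum(1 for n in net.nodes.values() if n.measured),
    }


# -- annotation sets ----------------------------------------------------------


@dataclass
class TermRecord:
    members: tuple
    source: str = ""
    name: str = ""


@dataclass
class AnnotationSet:
    """Mapping term id -> member feature ids with ontology/source metadata."""

    terms: dict = field(default_factory=dict)

    def add(self, term_id: str, members: Iterable[str], source: str = "", name: str = "") -> None:
        members = tuple(members)
        if not members:
            raise GraphError(f"term {term_id!r} has no members")
        if term_id in self.terms:
            raise GraphError(f"duplicate term {term_id!r}")
        self.terms[term_id] = TermRecord(members=members, source=source, name=name)

    def members(self, term_id: str) -> tuple:
        return self.terms[term_id].members

    def sources(self) -> list:
        return sorted({t.source for t in self.terms.values()})

    def subset(self, source: str) -> "AnnotationSet":
        out = AnnotationSet()
        for tid, rec in self.terms.items():
            if rec.source == source:
                out.terms[tid] = rec
        return out

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self) -> Iterator[str]:
        return iter(self.terms)


# -- I/O ----------------------------------------------------------------------


@dataclass
class EdgeTableSchema:
    """How to interpret a headered TSV edge list.

    Unknown-prefix ids fall back to ``default_layer``; measured status of new
    nodes defaults to ``measured``.
    """

    default_provenance: str = "knowledge_ppi"
    default_layer: str = "protein"
    measured: bool = False


def read_edge_table(
    path: Union[str, Path], schema: Optional[EdgeTableSchema] = None
) -> MultiOmicsNetwork:
    """Read a TSV edge list (columns: source, target, [provenance], [weight],
    [score], [source_role]) into a network."""
    schema = schema or EdgeTableSchema()
    path = Path(path)
    net = MultiOmicsNetwork(path.stem)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        cols = {c: i for i, c in enumerate(header)}
        if "source" not in cols or "target" not in cols:
            raise GraphError(f"{path}: header must contain 'source' and 'target'")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < len(header):
                raise GraphError(f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}")
            try:
                u = fields[cols["source"]]
                v = fields[cols["target"]]
                prov = fields[cols["provenance"]] if "provenance" in cols else schema.default_provenance
                weight = float(fields[cols["weight"]]) if "weight" in cols else 1.0
                role = fields[cols["source_role"]] if "source_role" in cols and fields[cols["source_role"]] else None
                if not u or not v:
                    raise GraphError("empty node id")
                for nid in (u, v):
                    net.add_node(
                        NodeRecord(
                            id=nid,
                            layer=layer_for_id(nid, schema.default_layer),
                            measured=schema.measured,
                        ),
                        merge=True,
                    )
                net.add_edge(EdgeRecord(u=u, v=v, provenance=prov, weight=weight, source_role=role))
            except (GraphError, ValueError) as exc:
                raise GraphError(f"{path}:{lineno}: {exc}") from exc
    return net


def write_edge_table(net: MultiOmicsNetwork, path: Union[str, Path]) -> None:
    """Write a SIF-like TSV edge list (source, target, provenance, weight)."""
    with open(path, "w") as fh:
        fh.write("source\ttarget\tprovenance\tweight\tsource_role\n")
        for key in sorted(net.edges):
            e = net.edges[key]
            role = e.source_role or ""
            fh.write(f"{e.u}\t{e.v}\t{e.provenance}\t{e.weight!r}\t{role}\n")


def write_graphml(net: MultiOmicsNetwork, path: Union[str, Path]) -> None:
    nx.write_graphml(net.to_networkx(), str(path))


def read_graphml(path: Union[str, Path]) -> MultiOmicsNetwork:
    g = nx.read_graphml(str(path), force_multigraph=True)
    net = MultiOmicsNetwork(g.graph.get("name", Path(str(path)).stem))
    for nid, attrs in g.nodes(data=True):
        cluster = attrs.get("cluster")
        net.add_node(
            NodeRecord(
                id=nid,
                layer=attrs["layer"],
                measured=bool(attrs.get("measured", False)),
                cluster=_cluster_from_str(cluster) if cluster is not None else None,
                label=attrs.get("label"),
                ontology=attrs.get("ontology"),
            )
        )
    for u, v, attrs in g.edges(data=True):
        net.add_edge(
            EdgeRecord(
                u=u,
                v=v,
                provenance=attrs["provenance"],
                weight=float(attrs.get("weight", 1.0)),
                source_role=attrs.get("source_role"),
            )
        )
    return net


def read_gmt(path: Union[str, Path], source: str = "") -> AnnotationSet:
    """Read a GMT file: one term per line, ``term<TAB>description<TAB>member...``."""
    ann = AnnotationSet()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GraphError(f"{path}:{lineno}: GMT line needs term, description and >=1 member")
            term, desc, members = fields[0], fields[1], [m for m in fields[2:] if m]
            try:
                ann.add(term, members, source=source or desc.split(":")[0], name=desc)
            except GraphError as exc:
                raise GraphError(f"{path}:{lineno}: {exc}") from exc
    return ann


def write_gmt(ann: AnnotationSet, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for tid in sorted(ann.terms):
            rec = ann.terms[tid]
            fh.write("\t".join([tid, rec.name or rec.source or tid, *rec.members]) + "\n")
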