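"""Over-representation analysis and enrichment-term network layers.

ORA tests each annotation term for enrichment in a query set with the
upper-tail hypergeometric probability, adjusted per ontology by
Benjamini-Hochberg (a standard, well-defined FDR control used here in place
of web-service-specific corrections; the choice is recorded in the result
metadata).  P-values across omics can be pooled with Fisher's combined
probability test.  Significant terms become new network nodes (GO or
disease layer) connected by annotation edges to their member molecules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .graph_core import (
    AnnotationSet,
    EdgeRecord,
    MultiOmicsNetwork,
    NodeRecord,
)

DEFAULT_ALPHA = 0.05


class EnrichmentError(ValueError):
    pass


@dataclass
class EnrichmentResult:
    """Per-term ORA rows for one query, with the settings that produced them."""

    table: pd.DataFrame  # term, ontology, overlap, query_size, term_size, universe_size, p, adj_p, significant
    alpha: float
    universe_size: int
    query_name: str = "query"
    correction: str = "benjamini-hochberg"

    def significant_terms(self, ontology: Optional[str] = None) -> list:
        t = self.table[self.table["significant"]]
        if ontology is not None:
            t = t[t["ontology"] == ontology]
        return sorted(t["term"])


def hypergeom_tail(universe: int, term: int, query: int, overlap: int) -> float:
    """Upper-tail hypergeometric probability P(X >= overlap)."""
    if overlap == 0:
        return 1.0
    return float(stats.hypergeom.sf(overlap - 1, universe, term, query))


def ora(
    query: Iterable[str],
    ann: AnnotationSet,
    universe: Iterable[str],
    alpha: float = DEFAULT_ALPHA,
    query_name: str = "query",
) -> EnrichmentResult:
    """Over-representation analysis of ``query`` against every annotation term.

    Term memberships are intersected with the universe before testing;
    Benjamini-Hochberg adjustment runs separately within each ontology
    source, and a term is significant when its adjusted p-value is below
    ``alpha``.
    """
    universe = set(universe)
    query = set(query)
    if not query:
        raise EnrichmentError("empty query set")
    if not universe:
        raise EnrichmentError("empty universe")
    if not query <= universe:
        raise EnrichmentError(f"query not contained in universe: {sorted(query - universe)[:5]}")
    rows = []
    for tid in sorted(ann.terms):
        rec = ann.terms[tid]
        members = set(rec.members) & universe
        if not members:
            continue
        overlap = len(members & query)
        p = hypergeom_tail(len(universe), len(members), len(query), overlap)
        rows.append(
            {
                "term": tid,
                "ontology": rec.source,
                "name": rec.name,
                "overlap": overlap,
                "query_size": len(query),
                "term_size": len(members),
                "universe_size": len(universe),
                "p": p,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "term", "ontology", "name", "overlap", "query_size",
            "term_size", "universe_size", "p",
        ],
    )
    if len(table):
        adj = np.ones(len(table))
        for onto in table["ontology"].unique():
            mask = (table["ontology"] == onto).to_numpy()
            adj[mask] = multipletests(table.loc[mask, "p"], method="fdr_bh")[1]
        table["adj_p"] = adj
        table["significant"] = table["adj_p"] < alpha
    else:
        table["adj_p"] = pd.Series(dtype=float)
        table["significant"] = pd.Series(dtype=bool)
    return EnrichmentResult(
        table=table, alpha=alpha, universe_size=len(universe), query_name=query_name
    )


def fisher_combine(pvals: Sequence[float]) -> float:
    """Fisher's combined probability: X^2 = -2 sum ln p_i against chi-square
    with 2k degrees of freedom; p = 0 is rejected (caller clamps)."""
    pvals = [float(p) for p in pvals]
    if not pvals:
        raise EnrichmentError("no p-values to combine")
    for p in pvals:
        if not (0.0 < p <= 1.0):
            raise EnrichmentError(f"p-values must lie in (0, 1], got {p}")
    x2 = -2.0 * sum(math.log(p) for p in pvals)
    return float(stats.chi2.sf(x2, df=2 * len(pvals)))


def add_term_layer(
    net: MultiOmicsNetwork,
    result: EnrichmentResult,
    ann: AnnotationSet,
    layer: str = "go_term",
) -> MultiOmicsNetwork:
    """Inject significant terms as a new node layer.

    One node per significant term (layer ``go_term`` or ``disease``), with an
    annotation-provenance edge to every network node among its members —
    measured or knowledge-extended; members absent from the network are
    ignored."""
    if layer not in ("go_term", "disease"):
        raise EnrichmentError(f"term layer must be go_term or disease, got {layer!r}")
    out = net.copy()
    sig = result.table[result.table["significant"]]
    for _, row in sig.iterrows():
        tid = row["term"]
        members = [m for m in ann.members(tid) if m in out]
        if not members:
            continue
        out.add_node(
            NodeRecord(
                id=tid,
                layer=layer,
                measured=False,
                label=row.get("name") or None,
                ontology=row["ontology"] or None,
            ),
            merge=True,
        )
        for m in members:
            out.add_edge(EdgeRecord(u=tid, v=m, provenance="annotation", source_role=tid))
    return out


def compare_cluster_vs_entire(
    cluster_results: Mapping[int, EnrichmentResult],
    entire_result: EnrichmentResult,
) -> dict:
    """Compare enrichment with and without the clustering step.

    Per ontology: unique significant-term counts per cluster and for the
    entire feature set, pairwise cluster intersections, the union across
    clusters, and raw-p summaries."""
    ontologies = sorted(
        set(entire_result.table["ontology"]).union(
            *[set(r.table["ontology"]) for r in cluster_results.values()]
        )
        if len(entire_result.table) or cluster_results
        else []
    )
    out = {}
    for onto in ontologies:
        per_cluster = {
            c: set(r.significant_terms(onto)) for c, r in sorted(cluster_results.items())
        }
        entire = set(entire_result.significant_terms(onto))
        union = set().union(*per_cluster.values()) if per_cluster else set()
        pair_inter = {
            f"{a}&{b}": sorted(per_cluster[a] & per_cluster[b])
            for a, b in combinations(sorted(per_cluster), 2)
        }
        pvals = entire_result.table.loc[
            entire_result.table["ontology"] == onto, "p"
        ].to_numpy(dtype=float)
        out[onto] = {
            "n_terms_per_cluster": {c: len(s) for c, s in per_cluster.items()},
            "n_terms_entire": len(entire),
            "n_terms_cluster_union": len(union),
            "cluster_only": sorted(union - entire),
            "entire_only": sorted(entire - union),
            "pairwise_intersections": pair_inter,
            "p_summary": {
                "min": float(pvals.min()) if pvals.size else None,
                "median": float(np.median(pvals)) if pvals.size else None,
            },
        }
    return out
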