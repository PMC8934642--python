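"""Deterministic synthetic-data generation with stored ground truth.

Every input the pipeline consumes can be generated here: replicated
time-course omics blocks with planted archetype kinetics and per-subject
offsets, regulatory designs whose planted edges induce co-expression,
knowledge tables containing measured and unmeasured nodes, annotation sets
with one strongly enriched term per kinetic cluster, and compositional count
tables with planted basis correlations.  The ground truth (archetypes,
cluster labels, planted edges, planted terms, planted correlations) travels
with the data so recovery tests can score the pipeline against it.

All randomness flows from a single integer seed through named sub-streams
(:func:`substream`), so each generator is reproducible independently of the
others.  The default design mirrors a small replicated human time-course
study: three omics blocks (transcripts, proteins, metabolites), six
timepoints, three subjects, four kinetic clusters built from two
near-orthogonal archetype curves and their sign flips.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .build import KnowledgeTable
from .graph_core import AnnotationSet, write_gmt
from .profiles import OmicsBlock

DEFAULT_BLOCK_PREFIXES = ("rna", "prot", "met")
DEFAULT_BLOCK_LAYERS = {"rna": "gene", "prot": "protein", "met": "metabolite"}


def substream(seed: int, *keys) -> np.random.Generator:
    """Named, collision-resistant random sub-stream derived from one seed."""
    tokens = [int(seed) & 0x7FFFFFFF]
    for key in keys:
        tokens.append(zlib.crc32(str(key).encode()) & 0x7FFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(tokens))


@dataclass
class FixtureTruth:
    """Everything the generators planted, for recovery scoring."""

    seed: int
    grid: np.ndarray = field(default_factory=lambda: np.array([]))
    archetypes: Optional[pd.DataFrame] = None  # archetype x grid
    features: Optional[pd.DataFrame] = None  # feature -> block, archetype, sign, cluster, amplitude
    regulatory_edges: list = field(default_factory=list)  # frozenset pairs
    knowledge_unmeasured: list = field(default_factory=list)
    planted_terms: dict = field(default_factory=dict)  # cluster -> term id
    basis_correlations: list = field(default_factory=list)  # (taxon_a, taxon_b, rho)
    sigma: float = 0.0
    subject_sigma: float = 0.0

    def cluster_labels(self) -> dict:
        if self.features is None:
            return {}
        lab = self.features["cluster"]
        return {f: int(c) for f, c in lab.items() if c >= 0}

    def to_json(self) -> dict:
        return {
            "seed": self.seed,
            "grid": list(map(float, self.grid)),
            "archetypes": self.archetypes.to_dict() if self.archetypes is not None else None,
            "features": self.features.to_dict() if self.features is not None else None,
            "regulatory_edges": [sorted(e) for e in self.regulatory_edges],
            "knowledge_unmeasured": self.knowledge_unmeasured,
            "planted_terms": self.planted_terms,
            "basis_correlations": self.basis_correlations,
            "sigma": self.sigma,
            "subject_sigma": self.subject_sigma,
        }


# -- archetype time-course blocks ---------------------------------------------


def archetype_curves(n_clusters: int, grid: np.ndarray) -> pd.DataFrame:
    """ceil(n_clusters / 2) near-orthogonal smooth curves, unit-scaled on the grid."""
    n_arch = (n_clusters + 1) // 2
    s = (grid - grid.min()) / (grid.max() - grid.min())
    rows = {}
    for j in range(n_arch):
        curve = np.cos(np.pi * (j + 1) * s)
        curve = (curve - curve.mean()) / curve.std()
        rows[f"arch{j + 1}"] = curve
    return pd.DataFrame(rows, index=[f"{g:g}" for g in grid]).T


def gen_blocks(
    n_clusters: int = 4,
    features_per_block: int = 20,
    timepoints: int = 6,
    subjects: int = 3,
    sigma: float = 0.2,
    seed: int = 0,
    n_blocks: int = 3,
    subject_sigma: Optional[float] = None,
    noise_features: int = 2,
    baseline: float = 8.0,
    scale: str = "log",
) -> tuple:
    """Replicated time-course blocks with planted archetype kinetics.

    Each feature is sign x amplitude x archetype(t) + subject offset +
    Gaussian noise on top of a constant baseline (log2-abundance-like by
    default).  ``noise_features`` per block carry no time trend at all.
    ``subject_sigma`` defaults to sigma / 2, so sigma = 0 gives noiseless,
    offset-free profiles.  Returns ``(blocks, truth)``.
    """
    if subject_sigma is None:
        subject_sigma = 0.5 * sigma
    grid = np.arange(timepoints, dtype=float)
    arch = archetype_curves(n_clusters, grid)
    arch_mat = arch.to_numpy()
    combos = []  # (archetype index, sign) -> cluster 1..n_clusters
    for j in range(arch.shape[0]):
        for sign in (1.0, -1.0):
            if len(combos) < n_clusters:
                combos.append((j, sign))
    # skewed cluster sizes, as kinetic clusters show in practice; the skew also
    # separates the archetypes' variance shares
    weights = np.arange(n_clusters, 0, -1, dtype=float)
    counts = np.floor(weights / weights.sum() * features_per_block).astype(int)
    counts[counts == 0] = 1
    while counts.sum() < features_per_block:
        counts[int(np.argmin(counts / weights))] += 1
    while counts.sum() > features_per_block:
        counts[int(np.argmax(counts / weights))] -= 1
    cluster_of_index = np.repeat(np.arange(n_clusters), counts)

    prefixes = DEFAULT_BLOCK_PREFIXES[:n_blocks]
    sample_index = [f"s{s + 1}_t{ti}" for ti in range(timepoints) for s in range(subjects)]
    meta = pd.DataFrame(
        {
            "subject": [f"s{s + 1}" for _ in range(timepoints) for s in range(subjects)],
            "replicate": [f"s{s + 1}" for _ in range(timepoints) for s in range(subjects)],
            "time": [float(ti) for ti in range(timepoints) for _ in range(subjects)],
        },
        index=sample_index,
    )

    blocks = []
    feature_rows = []
    for prefix in prefixes:
        rng = substream(seed, "blocks", prefix)
        cols = {}
        for i in range(features_per_block):
            j, sign = combos[cluster_of_index[i]]
            fid = f"{prefix}:f{i + 1:03d}"
            amplitude = float(rng.uniform(0.7, 1.3))
            offsets = rng.normal(0.0, subject_sigma, size=subjects)
            vals = np.empty(len(sample_index))
            pos = 0
            for ti in range(timepoints):
                for s in range(subjects):
                    vals[pos] = (
                        baseline
                        + sign * amplitude * arch_mat[j, ti]
                        + offsets[s]
                        + rng.normal(0.0, sigma)
                    )
                    pos += 1
            cols[fid] = vals
            feature_rows.append(
                {
                    "feature": fid,
                    "block": prefix,
                    "archetype": j + 1,
                    "sign": int(sign),
                    "cluster": combos.index((j, sign)) + 1,
                    "amplitude": amplitude,
                }
            )
        for i in range(noise_features):
            fid = f"{prefix}:noise{i + 1:02d}"
            cols[fid] = baseline + rng.normal(0.0, max(sigma, 0.05), size=len(sample_index))
            feature_rows.append(
                {"feature": fid, "block": prefix, "archetype": 0, "sign": 0, "cluster": -1, "amplitude": 0.0}
            )
        blocks.append(
            OmicsBlock(
                values=pd.DataFrame(cols, index=sample_index),
                sample_meta=meta,
                name=prefix,
                scale=scale,
                log_base=2.0,
            )
        )
    truth = FixtureTruth(
        seed=seed,
        grid=grid,
        archetypes=arch,
        features=pd.DataFrame(feature_rows).set_index("feature"),
        sigma=sigma,
        subject_sigma=subject_sigma,
    )
    return blocks, truth


# -- regulatory designs -------------------------------------------------------


def gen_chain(n_samples: int = 200, noise: float = 0.75, seed: int = 0) -> tuple:
    """Three-gene chain X -> Y -> Z: Z depends on X only through Y.

    Returns ``(expr features x samples, direct_edges, indirect_edges)``."""
    rng = substream(seed, "chain")
    x = rng.normal(size=n_samples)
    y = x + rng.normal(0.0, noise, size=n_samples)
    z = y + rng.normal(0.0, noise, size=n_samples)
    expr = pd.DataFrame(
        np.vstack([x, y, z]), index=["rna:X", "rna:Y", "rna:Z"],
    )
    direct = [frozenset({"rna:X", "rna:Y"}), frozenset({"rna:Y", "rna:Z"})]
    indirect = [frozenset({"rna:X", "rna:Z"})]
    return expr, direct, indirect


def gen_regulatory(
    n_regulators: int = 10,
    targets_per_regulator: int = 4,
    n_samples: int = 200,
    noise: float = 0.75,
    seed: int = 0,
) -> tuple:
    """Forest-shaped regulatory design whose edges induce co-expression.

    Regulators are independent standard normals; each target equals its
    regulator plus Gaussian noise, so sibling targets correlate only through
    the shared parent (what DPI pruning should discard).  Returns
    ``(expr features x samples, truth)`` with planted edges in the truth."""
    rng = substream(seed, "regulatory")
    rows, ids, edges = [], [], []
    for ri in range(n_regulators):
        reg_id = f"rna:R{ri + 1:02d}"
        reg = rng.normal(size=n_samples)
        rows.append(reg)
        ids.append(reg_id)
        for ti in range(targets_per_regulator):
            tid = f"rna:R{ri + 1:02d}t{ti + 1}"
            rows.append(reg + rng.normal(0.0, noise, size=n_samples))
            ids.append(tid)
            edges.append(frozenset({reg_id, tid}))
    expr = pd.DataFrame(np.vstack(rows), index=ids)
    truth = FixtureTruth(seed=seed, regulatory_edges=edges)
    return expr, truth


# -- knowledge tables ---------------------------------------------------------


def gen_knowledge(
    measured_ids: Sequence[str],
    extra_unmeasured_per_node: int = 1,
    n_measured_edges: Optional[int] = None,
    seed: int = 0,
    source: str = "synthetic_ppi",
    scored: bool = True,
) -> tuple:
    """Knowledge interaction table over measured ids plus unmeasured extensions.

    Every unmeasured node gets at least one measured neighbour; a few
    unmeasured-unmeasured rows are included on purpose (a correct
    first-degree extension must not pull in their far endpoints).  Returns
    ``(KnowledgeTable, truth)``."""
    rng = substream(seed, "knowledge")
    measured = list(measured_ids)
    if n_measured_edges is None:
        n_measured_edges = max(1, int(1.5 * len(measured)))
    rows = []
    seen = set()
    attempts = 0
    while len(rows) < n_measured_edges and attempts < 50 * n_measured_edges:
        attempts += 1
        a, b = rng.choice(len(measured), size=2, replace=False)
        key = frozenset({measured[a], measured[b]})
        if key in seen:
            continue
        seen.add(key)
        rows.append((measured[a], measured[b]))
    unmeasured = []
    for i, m in enumerate(measured):
        for j in range(extra_unmeasured_per_node if rng.random() < 0.5 else 0):
            uid = f"ext:{m.split(':')[-1]}_{j + 1}"
            unmeasured.append(uid)
            rows.append((m, uid))
    # second-degree decoys: chains unmeasured -- far-unmeasured
    for i, uid in enumerate(unmeasured[: max(1, len(unmeasured) // 3)]):
        rows.append((uid, f"ext:far{i + 1}"))
    table = pd.DataFrame(rows, columns=["id_a", "id_b"])
    table["interaction"] = "physical"
    if scored:
        table["score"] = np.round(rng.uniform(0.5, 1.0, size=len(table)), 6)
    truth = FixtureTruth(seed=seed, knowledge_unmeasured=unmeasured)
    return KnowledgeTable(rows=table, source=source), truth


def gen_reactions(
    measured_metabolites: Sequence[str],
    enzymes: Sequence[str],
    n_reactions: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Reaction table linking compounds sharing a reaction and their enzymes;
    roughly one extra unmeasured compound appears per reaction."""
    rng = substream(seed, "reactions")
    mets = list(measured_metabolites)
    enz = list(enzymes)
    rows = []
    for ri in range(n_reactions):
        n_c = int(rng.integers(2, 4))
        compounds = list(rng.choice(mets, size=min(n_c, len(mets)), replace=False))
        if rng.random() < 0.7:
            compounds.append(f"met:ext{ri + 1}")
        chosen_enz = list(rng.choice(enz, size=min(int(rng.integers(1, 3)), len(enz)), replace=False)) if enz else []
        rows.append(
            {
                "reaction_id": f"rx{ri + 1:02d}",
                "compounds": ";".join(compounds),
                "enzymes": ";".join(chosen_enz),
            }
        )
    return pd.DataFrame(rows)


def gen_cross_links(
    rna_ids: Sequence[str], prot_ids: Sequence[str], seed: int = 0, n_tf_target: int = 4
) -> pd.DataFrame:
    """Identifier cross-links: coding edges pairing shared symbols across the
    rna/prot namespaces plus a few TF-target rows."""
    rng = substream(seed, "crosslinks")
    rna_syms = {r.split(":", 1)[-1]: r for r in rna_ids}
    rows = []
    for p in prot_ids:
        sym = p.split(":", 1)[-1]
        if sym in rna_syms:
            rows.append({"id_a": p, "id_b": rna_syms[sym], "relation": "coding"})
    rna_list = list(rna_ids)
    for _ in range(n_tf_target):
        a, b = rng.choice(len(rna_list), size=2, replace=False)
        rows.append({"id_a": rna_list[a], "id_b": rna_list[b], "relation": "tf_target"})
    return pd.DataFrame(rows, columns=["id_a", "id_b", "relation"])


# -- annotation sets ----------------------------------------------------------


def gen_annotations(
    cluster_members: Mapping[int, Sequence[str]],
    universe: Sequence[str],
    terms_per_cluster: int = 1,
    background_terms: int = 20,
    term_size: int = 8,
    seed: int = 0,
    sources: Sequence[str] = ("GO:BP", "GO:MF", "GO:CC"),
) -> tuple:
    """Annotation set with one strongly enriched (planted) term per cluster.

    Planted terms draw their members entirely from one cluster; background
    terms sample the full universe.  Returns ``(AnnotationSet, truth)``."""
    rng = substream(seed, "annotations")
    ann = AnnotationSet()
    planted = {}
    universe = list(universe)
    for ci, cluster in enumerate(sorted(cluster_members)):
        members = list(cluster_members[cluster])
        for t in range(terms_per_cluster):
            size = min(term_size, len(members))
            chosen = sorted(rng.choice(members, size=size, replace=False))
            tid = f"go:C{cluster}T{t + 1}"
            source = sources[(ci * terms_per_cluster + t) % len(sources)]
            ann.add(tid, chosen, source=source, name=f"planted term for cluster {cluster}")
            if t == 0:
                planted[int(cluster)] = tid
    for b in range(background_terms):
        size = min(term_size, len(universe))
        chosen = sorted(rng.choice(universe, size=size, replace=False))
        ann.add(
            f"go:B{b + 1:03d}",
            chosen,
            source=sources[b % len(sources)],
            name=f"background term {b + 1}",
        )
    truth = FixtureTruth(seed=seed, planted_terms=planted)
    return ann, truth


# -- compositional counts -----------------------------------------------------


def gen_compositional(
    n_taxa: int = 20,
    n_samples: int = 500,
    planted_pairs: Sequence[tuple] = ((0, 1, 0.8),),
    depth: int = 50_000,
    seed: int = 0,
) -> tuple:
    """Compositional count table (samples x taxa) with planted log-basis
    correlations.

    Log basis abundances are multivariate normal with unit variances and the
    requested correlations; counts are multinomial draws of ``depth`` reads
    per sample from the closed fractions.  Returns ``(counts, truth)`` with
    the realized pairs recorded as ``(taxon_a, taxon_b, rho)``."""
    rng = substream(seed, "compositional")
    cov = np.eye(n_taxa)
    for i, j, rho in planted_pairs:
        cov[i, j] = cov[j, i] = rho
    means = rng.normal(2.0, 1.0, size=n_taxa)
    log_basis = rng.multivariate_normal(means, cov, size=n_samples, method="cholesky")
    basis = np.exp(log_basis)
    frac = basis / basis.sum(axis=1, keepdims=True)
    counts = np.vstack([rng.multinomial(depth, frac[s]) for s in range(n_samples)])
    taxa = [f"otu:{i + 1:03d}" for i in range(n_taxa)]
    df = pd.DataFrame(counts, index=[f"s{s + 1}" for s in range(n_samples)], columns=taxa)
    truth = FixtureTruth(
        seed=seed,
        basis_correlations=[(taxa[i], taxa[j], float(rho)) for i, j, rho in planted_pairs],
    )
    return df, truth


# -- propagation fixtures -----------------------------------------------------


def gen_guilt_by_association_net(
    n_terms: int = 4,
    members_per_term: int = 5,
    n_unlabeled: int = 10,
    seed: int = 0,
):
    """Network where every unlabeled molecule touches members of exactly one
    planted term, so guilt-by-association prediction has a known answer.

    Each term node annotates its member molecules (ring-wired internally);
    every unlabeled node gets knowledge edges to two members of one term.
    Returns ``(net, truth)`` with truth mapping unlabeled id -> term id."""
    from .graph_core import EdgeRecord, MultiOmicsNetwork, NodeRecord

    rng = substream(seed, "guilt")
    net = MultiOmicsNetwork("guilt_by_association")
    members: dict = {}
    for t in range(n_terms):
        tid = f"go:T{t + 1}"
        net.add_node(NodeRecord(id=tid, layer="go_term", ontology="GO:BP"))
        members[tid] = []
        for m in range(members_per_term):
            mid = f"rna:t{t + 1}m{m + 1}"
            net.add_node(NodeRecord(id=mid, layer="gene", measured=True))
            net.add_edge(EdgeRecord(u=tid, v=mid, provenance="annotation"))
            members[tid].append(mid)
        ring = members[tid]
        for i in range(len(ring)):
            net.add_edge(
                EdgeRecord(u=ring[i], v=ring[(i + 1) % len(ring)], provenance="knowledge_ppi")
            )
    truth = {}
    term_ids = sorted(members)
    for u in range(n_unlabeled):
        uid = f"rna:u{u + 1:02d}"
        net.add_node(NodeRecord(id=uid, layer="gene", measured=True))
        tid = term_ids[int(rng.integers(len(term_ids)))]
        picked = rng.choice(members[tid], size=2, replace=False)
        for mid in picked:
            net.add_edge(EdgeRecord(u=uid, v=str(mid), provenance="knowledge_ppi"))
        truth[uid] = tid
    return net, truth


def gen_cross_cluster_net(seed: int = 0, homogeneous: bool = False):
    """Two kinetic clusters with one planted cross-cluster regulator.

    Cluster 1 and cluster 2 molecules are ring-wired within their cluster;
    the regulator (cluster 1) also touches two cluster-2 molecules, and a GO
    term annotates part of cluster 2.  With ``homogeneous`` every molecule
    carries the same cluster label instead.  Returns ``(net, regulator_id)``."""
    from .graph_core import EdgeRecord, MultiOmicsNetwork, NodeRecord

    rng = substream(seed, "crosscluster")
    net = MultiOmicsNetwork("cross_cluster")
    groups = {1: [f"rna:a{i + 1}" for i in range(5)], 2: [f"prot:b{i + 1}" for i in range(5)]}
    for c, ids in groups.items():
        for nid in ids:
            layer = "gene" if nid.startswith("rna") else "protein"
            net.add_node(
                NodeRecord(id=nid, layer=layer, measured=True, cluster=1 if homogeneous else c)
            )
        for i in range(len(ids)):
            net.add_edge(
                EdgeRecord(u=ids[i], v=ids[(i + 1) % len(ids)], provenance="inferred_mi")
            )
    reg = "rna:reg"
    net.add_node(NodeRecord(id=reg, layer="gene", measured=True, cluster=1))
    net.add_edge(EdgeRecord(u=reg, v=groups[1][0], provenance="inferred_mi"))
    targets = [str(t) for t in rng.choice(groups[2], size=2, replace=False)]
    for target in targets:
        net.add_edge(EdgeRecord(u=reg, v=target, provenance="tf_target", source_role=reg))
    # the regulated process is annotated: the term covers the regulator's targets
    net.add_node(NodeRecord(id="go:T", layer="go_term", ontology="GO:BP"))
    for member in targets:
        net.add_edge(EdgeRecord(u="go:T", v=member, provenance="annotation"))
    return net, reg


# -- full input bundle --------------------------------------------------------


@dataclass
class FixtureBundle:
    blocks: list
    knowledge: KnowledgeTable
    reactions: pd.DataFrame
    cross_links: pd.DataFrame
    annotations: AnnotationSet
    truth: FixtureTruth


def default_fixture(
    seed: int = 0,
    n_clusters: int = 4,
    features_per_block: int = 20,
    timepoints: int = 6,
    subjects: int = 3,
    sigma: float = 0.2,
) -> FixtureBundle:
    """The default study design: three omics blocks with planted kinetics,
    a scored knowledge table over the protein layer, reactions over the
    metabolite layer, rna-prot coding links, and annotations with one
    planted term per cluster."""
    blocks, truth = gen_blocks(
        n_clusters=n_clusters,
        features_per_block=features_per_block,
        timepoints=timepoints,
        subjects=subjects,
        sigma=sigma,
        seed=seed,
    )
    feats = truth.features
    prot_ids = [f for f in feats.index if f.startswith("prot:")]
    met_ids = [f for f in feats.index if f.startswith("met:")]
    rna_ids = [f for f in feats.index if f.startswith("rna:")]
    knowledge, ktruth = gen_knowledge(prot_ids, seed=seed)
    reactions = gen_reactions(met_ids, prot_ids[: max(3, len(prot_ids) // 4)], seed=seed)
    # coding links pair rna:fNNN with prot:fNNN by shared symbol
    cross = gen_cross_links(rna_ids, prot_ids, seed=seed)
    clustered = feats[feats["cluster"] > 0]
    cluster_members = {
        int(c): sorted(clustered.index[clustered["cluster"] == c])
        for c in sorted(clustered["cluster"].unique())
    }
    ann, atruth = gen_annotations(cluster_members, universe=sorted(feats.index), seed=seed)
    truth.knowledge_unmeasured = ktruth.knowledge_unmeasured
    truth.planted_terms = atruth.planted_terms
    return FixtureBundle(
        blocks=blocks,
        knowledge=knowledge,
        reactions=reactions,
        cross_links=cross,
        annotations=ann,
        truth=truth,
    )


def write_bundle(bundle: FixtureBundle, outdir: Union[str, Path]) -> dict:
    """Write the full input bundle as plain-text files plus a truth JSON;
    returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for block in bundle.blocks:
        vp = outdir / f"{block.name}_values.csv"
        mp = outdir / f"{block.name}_samples.csv"
        block.values.to_csv(vp, float_format="%.10g")
        block.sample_meta.to_csv(mp)
        paths[f"block:{block.name}"] = {"values": str(vp), "meta": str(mp), "scale": block.scale}
    kp = outdir / "knowledge_ppi.tsv"
    bundle.knowledge.rows.to_csv(kp, sep="\t", index=False)
    paths["knowledge"] = str(kp)
    rp = outdir / "reactions.tsv"
    bundle.reactions.to_csv(rp, sep="\t", index=False)
    paths["reactions"] = str(rp)
    cp = outdir / "cross_links.tsv"
    bundle.cross_links.to_csv(cp, sep="\t", index=False)
    paths["cross_links"] = str(cp)
    gp = outdir / "annotations.gmt"
    write_gmt(bundle.annotations, gp)
    paths["annotations"] = str(gp)
    tp = outdir / "truth.json"
    with open(tp, "w") as fh:
        json.dump(bundle.truth.to_json(), fh, indent=2, sort_keys=True)
    paths["truth"] = str(tp)
    return paths
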