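"""End-to-end orchestration: filter -> model -> cluster -> build -> annotate
-> propagate, with a declarative config, cached stage artifacts, and
reproducible outputs.

Every stage writes its artifacts (CSV/TSV/GraphML/JSON) plus a provenance
record carrying the package version, the resolved stage configuration, the
seed, and a hash chained from the upstream stage, so a re-run with an
unchanged configuration resumes from cache and a change re-executes only
from the first affected stage onward.  All numeric output is written with a
fixed format; a run with the same config and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotate import EnrichmentResult, add_term_layer, compare_cluster_vs_entire, ora
from .build import (
    KnowledgeTable,
    assemble,
    correlation_link,
    cross_link_ids,
    knowledge_layer,
    mi_network,
    reaction_layer,
    sparcc_network,
)
from .clustering import KineticClustering, choose_k, pattern_cluster, sparse_signature
from .graph_core import read_gmt, read_graphml, summarize, write_edge_table, write_graphml
from .profiles import (
    ModeledProfileSet,
    OmicsBlock,
    fold_change_filter,
    model_profiles,
    noise_filter,
    read_omics_block,
    scale_profiles,
)
from .propagate import WalkConfig, cluster_intersection, mechanism_subnetworks, predict_function
from .synthfix import substream

log = logging.getLogger("netomics")

STAGES = ("filter", "model", "cluster", "build", "annotate", "propagate")
_FLOAT_FMT = "%.12g"


class PipelineError(RuntimeError):
    pass


# -- configuration ------------------------------------------------------------


@dataclass
class BlockConfig:
    name: str
    values: str
    meta: str
    layer: str = "gene"
    scale: str = "linear"
    log_base: float = 2.0
    fold_change: float = 1.5
    inference: str = "mi"  # mi | sparcc | none
    correlate_with_others: bool = False


@dataclass
class KnowledgeConfig:
    path: str
    layer: str = "protein"
    provenance: str = "knowledge_ppi"
    score_min: Optional[float] = None
    extend: bool = True


@dataclass
class RunConfig:
    blocks: list
    knowledge: list = field(default_factory=list)
    reactions: Optional[str] = None
    cross_links: Optional[str] = None
    annotations: Optional[str] = None
    seed: int = 0
    grid: Optional[list] = None
    r2_floor: float = 0.5
    cluster_method: str = "block_pls"  # block_pls | pattern
    ncomp_grid: list = field(default_factory=lambda: [1, 2, 3])
    keepX: Optional[int] = None
    zero_band: float = 0.01
    mi_bins: Optional[int] = None
    dpi_epsilon: float = 0.15
    mi_floor: Optional[float] = None
    sparcc_rho_min: float = 0.3
    cross_rho_min: float = 0.99
    alpha: float = 0.05
    universe: str = "measured"  # measured | measured+extended
    restart: float = 0.7
    walk_tolerance: float = 1e-10
    k_mechanism: int = 25
    k_intersection: int = 10

    def __post_init__(self) -> None:
        self.blocks = [b if isinstance(b, BlockConfig) else BlockConfig(**b) for b in self.blocks]
        self.knowledge = [
            k if isinstance(k, KnowledgeConfig) else KnowledgeConfig(**k) for k in self.knowledge
        ]
        if not self.blocks:
            raise PipelineError("config needs at least one block")
        if self.cluster_method not in ("block_pls", "pattern"):
            raise PipelineError(f"unknown cluster method {self.cluster_method!r}")
        if self.universe not in ("measured", "measured+extended"):
            raise PipelineError(f"unknown universe mode {self.universe!r}")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def stage_config(self, stage: str) -> dict:
        """The config subset a stage depends on (drives the cache hash)."""
        d = self.to_dict()
        subsets = {
            "filter": ["blocks", "seed"],
            "model": ["grid", "r2_floor"],
            "cluster": ["cluster_method", "ncomp_grid", "keepX", "zero_band"],
            "build": [
                "knowledge", "reactions", "cross_links", "mi_bins", "dpi_epsilon",
                "mi_floor", "sparcc_rho_min", "cross_rho_min",
            ],
            "annotate": ["annotations", "alpha", "universe"],
            "propagate": ["restart", "walk_tolerance", "k_mechanism", "k_intersection"],
        }
        return {key: d[key] for key in subsets[stage]}


def _hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


def _write_json(path: Path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


class _StageRunner:
    """Runs stages in order, resuming from cached artifacts when the chained
    provenance hash is unchanged."""

    def __init__(self, config: RunConfig, outdir: Path, force: bool = False) -> None:
        self.config = config
        self.outdir = outdir
        self.force = force
        self.upstream_hash = _hash({"seed": config.seed, "version": __version__})

    def run_stage(self, name: str, compute, load):
        stage_dir = self.outdir / name
        payload = _hash({"stage": self.stage_hash_input(name)})
        prov_path = stage_dir / "provenance.json"
        if not self.force and prov_path.exists():
            prov = json.loads(prov_path.read_text())
            if prov.get("hash") == payload:
                log.info("stage %s: cached", name)
                self.upstream_hash = payload
                return load(stage_dir)
        stage_dir.mkdir(parents=True, exist_ok=True)
        t0 = time.perf_counter()
        try:
            result = compute(stage_dir)
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        _write_json(
            prov_path,
            {
                "stage": name,
                "hash": payload,
                "upstream": self.upstream_hash,
                "config": self.config.stage_config(name),
                "seed": self.config.seed,
                "version": __version__,
            },
        )
        log.info("stage %s: %.2fs", name, time.perf_counter() - t0)
        self.upstream_hash = payload
        return result

    def stage_hash_input(self, name: str) -> dict:
        return {
            "name": name,
            "config": self.config.stage_config(name),
            "upstream": self.upstream_hash,
            "seed": self.config.seed,
        }


# -- stage implementations ----------------------------------------------------


def _stage_filter(config: RunConfig, stage_dir: Path) -> dict:
    out = {}
    reports = {}
    for bc in config.blocks:
        block = read_omics_block(
            bc.values, bc.meta, name=bc.name, scale=bc.scale, log_base=bc.log_base
        )
        filtered, report = fold_change_filter(block, bc.fold_change)
        filtered.values.to_csv(stage_dir / f"{bc.name}_filtered.csv", float_format=_FLOAT_FMT)
        filtered.sample_meta.to_csv(stage_dir / f"{bc.name}_samples.csv")
        out[bc.name] = filtered
        reports[bc.name] = report
    _write_json(stage_dir / "filter_report.json", reports)
    return out


def _load_filter(config: RunConfig, stage_dir: Path) -> dict:
    out = {}
    for bc in config.blocks:
        out[bc.name] = read_omics_block(
            stage_dir / f"{bc.name}_filtered.csv",
            stage_dir / f"{bc.name}_samples.csv",
            name=bc.name,
            scale=bc.scale,
            log_base=bc.log_base,
        )
    return out


def _common_grid(blocks: dict, config: RunConfig) -> np.ndarray:
    if config.grid is not None:
        return np.asarray(config.grid, dtype=float)
    times = [np.unique(b.times) for b in blocks.values()]
    lo = max(t.min() for t in times)
    hi = min(t.max() for t in times)
    pts = np.unique(np.concatenate(times))
    grid = pts[(pts >= lo) & (pts <= hi)]
    if len(grid) < 2:
        raise PipelineError("blocks share fewer than 2 timepoints")
    return grid


def _stage_model(config: RunConfig, blocks: dict, stage_dir: Path) -> dict:
    grid = _common_grid(blocks, config)
    out = {}
    for name, block in blocks.items():
        mset = noise_filter(model_profiles(block, grid), r2_floor=config.r2_floor)
        mset.fitted.to_csv(stage_dir / f"{name}_fitted.csv", float_format=_FLOAT_FMT)
        info = pd.DataFrame(
            {
                "model_class": mset.model_class,
                "fit_quality": mset.fit_quality,
                "kept": mset.kept,
                "reason": pd.Series(mset.drop_reason).reindex(mset.fitted.index).fillna(""),
            }
        )
        info.to_csv(stage_dir / f"{name}_models.csv", float_format=_FLOAT_FMT)
        out[name] = mset
    _write_json(stage_dir / "grid.json", {"grid": [float(g) for g in grid]})
    return out


def _load_model(config: RunConfig, stage_dir: Path) -> dict:
    grid = np.asarray(json.loads((stage_dir / "grid.json").read_text())["grid"], dtype=float)
    out = {}
    for bc in config.blocks:
        fitted = pd.read_csv(stage_dir / f"{bc.name}_fitted.csv", index_col=0)
        info = pd.read_csv(stage_dir / f"{bc.name}_models.csv", index_col=0)
        out[bc.name] = ModeledProfileSet(
            grid=grid,
            fitted=fitted,
            model_class=info["model_class"],
            fit_quality=info["fit_quality"].astype(float),
            kept=info["kept"].astype(bool),
            drop_reason={f: r for f, r in info["reason"].fillna("").items() if r},
            name=bc.name,
        )
    return out


def _stage_cluster(config: RunConfig, msets: dict, stage_dir: Path) -> KineticClustering:
    names = [bc.name for bc in config.blocks]
    scaled = {name: scale_profiles(msets[name]) for name in names}
    if config.cluster_method == "pattern":
        merged = ModeledProfileSet(
            grid=msets[names[0]].grid,
            fitted=pd.concat([msets[n].fitted.loc[msets[n].kept_ids()] for n in names]),
            model_class=pd.concat([msets[n].model_class for n in names]),
            fit_quality=pd.concat([msets[n].fit_quality for n in names]),
            kept=pd.concat([msets[n].kept for n in names]),
        )
        clustering = pattern_cluster(merged, zero_band=config.zero_band)
        from .clustering import silhouette_score as _sil

        if clustering.k >= 2:
            clustering.silhouette = float(
                _sil(pd.concat([scaled[n] for n in names]), clustering.labels)
            )
    else:
        clustering = choose_k(
            [scaled[n] for n in names], config.ncomp_grid, block_names=names
        )
        if config.keepX is not None:
            clustering = sparse_signature(clustering, config.keepX)
    rows = []
    block_of = {}
    for name in names:
        for f in scaled[name].index:
            block_of[f] = name
    sig_members = set()
    if clustering.signature:
        for members in clustering.signature.values():
            sig_members.update(members)
    for f in clustering.labels.index:
        rows.append(
            {
                "feature": f,
                "block": block_of.get(f, ""),
                "cluster": int(clustering.labels[f]),
                "in_signature": f in sig_members if clustering.signature else True,
            }
        )
    pd.DataFrame(rows).to_csv(stage_dir / "clusters.csv", index=False)
    _write_json(
        stage_dir / "clustering.json",
        {
            "method": clustering.method,
            "k": clustering.k,
            "silhouette": clustering.silhouette,
            "cluster_meta": {str(c): m for c, m in clustering.cluster_meta.items()},
        },
    )
    return clustering


def _load_cluster(config: RunConfig, stage_dir: Path) -> KineticClustering:
    table = pd.read_csv(stage_dir / "clusters.csv", index_col="feature")
    meta = json.loads((stage_dir / "clustering.json").read_text())
    signature = None
    if not table["in_signature"].all():
        signature = {}
        for f, row in table[table["in_signature"]].iterrows():
            signature.setdefault(int(row["cluster"]), []).append(f)
        signature = {c: sorted(m) for c, m in signature.items()}
    return KineticClustering(
        labels=table["cluster"].astype(int),
        k=int(meta["k"]),
        method=meta["method"],
        silhouette=meta["silhouette"],
        feature_block=table["block"],
        signature=signature,
    )


def _stage_build(
    config: RunConfig,
    blocks: dict,
    msets: dict,
    clustering: KineticClustering,
    stage_dir: Path,
):
    builders = []
    kept_by_block = {name: set(msets[name].kept_ids()) for name in blocks}

    for bc in config.blocks:
        if bc.inference == "mi":
            expr_all = blocks[bc.name].values.T  # features x samples
            builders.append(_MIBuilder(config, bc, expr_all, kept_by_block[bc.name]))
        elif bc.inference == "sparcc":
            builders.append(_SparccBuilder(config, bc, blocks[bc.name]))
        elif bc.inference != "none":
            raise PipelineError(f"unknown inference mode {bc.inference!r}")
    for kc in config.knowledge:
        table = KnowledgeTable.read_tsv(kc.path)
        builders.append(_KnowledgeBuilder(kc, table))
    if config.reactions:
        reactions = pd.read_csv(config.reactions, sep="\t")
        builders.append(_ReactionBuilder(reactions))

    cross = []
    if config.cross_links:
        cross.extend(cross_link_ids(pd.read_csv(config.cross_links, sep="\t")))
    corr_blocks = [bc for bc in config.blocks if bc.correlate_with_others]
    for bc in corr_blocks:
        prof_a = scale_profiles(msets[bc.name])
        for other in config.blocks:
            if other.name == bc.name or other.correlate_with_others:
                continue
            prof_b = scale_profiles(msets[other.name])
            cross.extend(correlation_link(prof_a, prof_b, rho_min=config.cross_rho_min))

    measured = sorted(set().union(*kept_by_block.values()))
    labels = {f: int(c) for f, c in clustering.labels.items()}
    assembled = assemble(builders, measured, labels, cross_links=cross)

    write_graphml(assembled.entire, stage_dir / "entire.graphml")
    write_edge_table(assembled.entire, stage_dir / "entire_edges.tsv")
    summary = {"entire": summarize(assembled.entire)}
    for c, net in assembled.per_cluster.items():
        write_graphml(net, stage_dir / f"cluster{c}.graphml")
        summary[f"cluster{c}"] = summarize(net)
    _write_json(
        stage_dir / "build_summary.json",
        {"summary": summary, "warnings": assembled.warnings,
         "clusters": sorted(assembled.per_cluster)},
    )
    return assembled


class _MIBuilder:
    """MI + DPI inference layer, re-run from scratch on any id subset."""

    def __init__(self, config: RunConfig, bc: BlockConfig, expr, kept_ids) -> None:
        self.config, self.bc, self.expr, self.kept = config, bc, expr, kept_ids

    def __call__(self, ids):
        ids = [i for i in ids if i in self.kept and i in self.expr.index]
        if len(ids) < 2:
            from .graph_core import MultiOmicsNetwork, NodeRecord, layer_for_id

            net = MultiOmicsNetwork(f"mi:{self.bc.name}")
            for i in ids:
                net.add_node(NodeRecord(id=i, layer=layer_for_id(i, self.bc.layer), measured=True))
            return net
        return mi_network(
            self.expr.loc[ids],
            layer=self.bc.layer,
            bins=self.config.mi_bins,
            mi_floor=self.config.mi_floor,
            epsilon=self.config.dpi_epsilon,
            rng=substream(self.config.seed, "mi", self.bc.name),
            name=f"mi:{self.bc.name}",
        )


class _SparccBuilder:
    def __init__(self, config: RunConfig, bc: BlockConfig, block: OmicsBlock) -> None:
        self.config, self.bc, self.block = config, bc, block

    def __call__(self, ids):
        ids = [i for i in ids if i in self.block.values.columns]
        if len(ids) < 4:
            from .graph_core import MultiOmicsNetwork, NodeRecord, layer_for_id

            net = MultiOmicsNetwork(f"sparcc:{self.bc.name}")
            for i in ids:
                net.add_node(NodeRecord(id=i, layer=layer_for_id(i, self.bc.layer), measured=True))
            return net
        return sparcc_network(
            self.block.values[ids],
            rho_min=self.config.sparcc_rho_min,
            layer=self.bc.layer,
            name=f"sparcc:{self.bc.name}",
        )


class _KnowledgeBuilder:
    def __init__(self, kc: KnowledgeConfig, table: KnowledgeTable) -> None:
        self.kc, self.table = kc, table

    def __call__(self, ids):
        return knowledge_layer(
            ids,
            self.table,
            score_min=self.kc.score_min,
            extend=self.kc.extend,
            layer=self.kc.layer,
            provenance=self.kc.provenance,
            name=f"knowledge:{self.table.source}",
        )


class _ReactionBuilder:
    def __init__(self, reactions: pd.DataFrame) -> None:
        self.reactions = reactions

    def __call__(self, ids):
        return reaction_layer(ids, self.reactions)


def _load_build(config: RunConfig, stage_dir: Path):
    from .build import AssembledNetworks

    meta = json.loads((stage_dir / "build_summary.json").read_text())
    entire = read_graphml(stage_dir / "entire.graphml")
    per_cluster = {
        int(c): read_graphml(stage_dir / f"cluster{c}.graphml") for c in meta["clusters"]
    }
    return AssembledNetworks(entire=entire, per_cluster=per_cluster, warnings=meta["warnings"])


def _stage_annotate(
    config: RunConfig, assembled, clustering: KineticClustering, stage_dir: Path
):
    if not config.annotations:
        _write_json(stage_dir / "annotate_summary.json", {"skipped": True})
        write_graphml(assembled.entire, stage_dir / "entire_annotated.graphml")
        for c, net in assembled.per_cluster.items():
            write_graphml(net, stage_dir / f"cluster{c}_annotated.graphml")
        return assembled, None
    ann = read_gmt(config.annotations)
    measured = sorted(nid for nid, n in assembled.entire.nodes.items() if n.measured)
    if config.universe == "measured":
        universe = set(measured)
    else:
        universe = {
            nid for nid, n in assembled.entire.nodes.items()
            if n.layer not in ("go_term", "disease")
        }
    entire_result = ora(measured, ann, universe, alpha=config.alpha, query_name="entire")
    cluster_results = {}
    for c in sorted(assembled.per_cluster):
        query = sorted(set(clustering.labels.index[clustering.labels == c]) & universe)
        if not query:
            continue
        cluster_results[c] = ora(query, ann, universe, alpha=config.alpha, query_name=f"cluster{c}")
    # the entire network carries the union of terms found significant in any
    # query (per cluster or on the entire feature set)
    entire_net = add_term_layer(assembled.entire, entire_result, ann)
    for res in cluster_results.values():
        entire_net = add_term_layer(entire_net, res, ann)
    per_cluster = {}
    for c, net in assembled.per_cluster.items():
        res = cluster_results.get(c)
        per_cluster[c] = add_term_layer(net, res, ann) if res is not None else net.copy()

    entire_result.table.to_csv(
        stage_dir / "enrichment_entire.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )
    for c, res in cluster_results.items():
        res.table.to_csv(
            stage_dir / f"enrichment_cluster{c}.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
        )
    comparison = compare_cluster_vs_entire(cluster_results, entire_result)
    _write_json(
        stage_dir / "annotate_summary.json",
        {
            "skipped": False,
            "correction": entire_result.correction,
            "alpha": config.alpha,
            "universe_mode": config.universe,
            "universe_size": entire_result.universe_size,
            "comparison": comparison,
            "clusters": sorted(cluster_results),
        },
    )
    write_graphml(entire_net, stage_dir / "entire_annotated.graphml")
    from .build import AssembledNetworks

    annotated = AssembledNetworks(entire=entire_net, per_cluster=per_cluster, warnings=[])
    for c, net in per_cluster.items():
        write_graphml(net, stage_dir / f"cluster{c}_annotated.graphml")
    return annotated, entire_result


def _load_annotate(config: RunConfig, stage_dir: Path):
    from .build import AssembledNetworks

    meta = json.loads((stage_dir / "annotate_summary.json").read_text())
    entire = read_graphml(stage_dir / "entire_annotated.graphml")
    per_cluster = {}
    for p in sorted(stage_dir.glob("cluster*_annotated.graphml")):
        c = int(p.name[len("cluster") : -len("_annotated.graphml")])
        per_cluster[c] = read_graphml(p)
    result = None
    if not meta.get("skipped"):
        table = pd.read_csv(stage_dir / "enrichment_entire.tsv", sep="\t")
        result = EnrichmentResult(
            table=table, alpha=meta["alpha"], universe_size=meta["universe_size"],
            query_name="entire",
        )
    return AssembledNetworks(entire=entire, per_cluster=per_cluster, warnings=[]), result


def _stage_propagate(config: RunConfig, annotated, stage_dir: Path) -> dict:
    net = annotated.entire
    walk = WalkConfig(restart=config.restart, tolerance=config.walk_tolerance)
    mech = mechanism_subnetworks(net, k=config.k_mechanism, config=walk)
    mech_rows = []
    for m in mech:
        for rank, nid in enumerate(m.top_nodes, start=1):
            node = net.nodes[nid]
            mech_rows.append(
                {
                    "seed": m.seed,
                    "node": nid,
                    "layer": node.layer,
                    "cluster": "" if node.cluster is None else str(node.cluster),
                    "rank": rank,
                    "reaches_gene_and_protein": m.screens["reaches_gene_and_protein"],
                }
            )
    pd.DataFrame(
        mech_rows,
        columns=["seed", "node", "layer", "cluster", "rank", "reaches_gene_and_protein"],
    ).to_csv(stage_dir / "mechanisms.tsv", sep="\t", index=False)

    predictions = predict_function(net, config=walk)
    _write_json(stage_dir / "function_predictions.json", predictions)

    inter = cluster_intersection(net, k=config.k_intersection, config=walk)
    inter_rows = []
    for m in inter:
        inter_rows.append(
            {
                "seed": m.seed,
                "clusters_reached": "|".join(str(c) for c in sorted(m.clusters_reached)),
                "terms_reached": "|".join(m.terms_reached),
                "top_nodes": "|".join(m.top_nodes),
            }
        )
        write_graphml(m.subnetwork, stage_dir / f"intersection_{m.seed.replace(':', '_')}.graphml")
    pd.DataFrame(
        inter_rows, columns=["seed", "clusters_reached", "terms_reached", "top_nodes"]
    ).to_csv(stage_dir / "cluster_intersections.tsv", sep="\t", index=False)

    summary = {
        "n_term_seeds": len(mech),
        "n_seeds_gene_and_protein": sum(m.screens["reaches_gene_and_protein"] for m in mech),
        "n_seeds_gene_protein_metabolite": sum(
            m.screens["reaches_gene_protein_metabolite"] for m in mech
        ),
        "n_unannotated": len(predictions),
        "n_predicted": sum(
            1 for per in predictions.values() if any(v is not None for v in per.values())
        ),
        "n_intersection_seeds": len(inter),
        "restart": config.restart,
    }
    _write_json(stage_dir / "propagate_summary.json", summary)
    return summary


def _load_propagate(config: RunConfig, stage_dir: Path) -> dict:
    return json.loads((stage_dir / "propagate_summary.json").read_text())


# -- public entry points ------------------------------------------------------


def run(
    config: RunConfig,
    outdir: Union[str, Path],
    through: str = "propagate",
    force: bool = False,
) -> dict:
    """Execute the pipeline up to stage ``through`` inside ``outdir``.

    Returns a dict of in-memory stage results.  Stages whose configuration
    and upstream hashes are unchanged are loaded from cached artifacts."""
    if through not in STAGES:
        raise PipelineError(f"unknown stage {through!r}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_json(outdir / "config.json", config.to_dict())
    runner = _StageRunner(config, outdir, force=force)
    results: dict = {"outdir": outdir}
    last = STAGES.index(through)

    blocks = runner.run_stage(
        "filter", lambda d: _stage_filter(config, d), lambda d: _load_filter(config, d)
    )
    results["blocks"] = blocks
    if last < 1:
        return results
    msets = runner.run_stage(
        "model", lambda d: _stage_model(config, blocks, d), lambda d: _load_model(config, d)
    )
    results["profiles"] = msets
    if last < 2:
        return results
    clustering = runner.run_stage(
        "cluster",
        lambda d: _stage_cluster(config, msets, d),
        lambda d: _load_cluster(config, d),
    )
    results["clustering"] = clustering
    if last < 3:
        return results
    assembled = runner.run_stage(
        "build",
        lambda d: _stage_build(config, blocks, msets, clustering, d),
        lambda d: _load_build(config, d),
    )
    results["networks"] = assembled
    if last < 4:
        return results
    annotated, enrichment = runner.run_stage(
        "annotate",
        lambda d: _stage_annotate(config, assembled, clustering, d),
        lambda d: _load_annotate(config, d),
    )
    results["annotated"] = annotated
    results["enrichment"] = enrichment
    if last < 5:
        return results
    results["propagation"] = runner.run_stage(
        "propagate",
        lambda d: _stage_propagate(config, annotated, d),
        lambda d: _load_propagate(config, d),
    )
    return results


def fixture_config(bundle_dir: Union[str, Path], seed: int = 0, **overrides) -> RunConfig:
    """RunConfig pointing at a bundle written by synthfix.write_bundle."""
    bundle_dir = Path(bundle_dir)
    blocks = []
    for prefix, layer in (("rna", "gene"), ("prot", "protein"), ("met", "metabolite")):
        values = bundle_dir / f"{prefix}_values.csv"
        if not values.exists():
            continue
        blocks.append(
            BlockConfig(
                name=prefix,
                values=str(values),
                meta=str(bundle_dir / f"{prefix}_samples.csv"),
                layer=layer,
                scale="log",
                fold_change=1.5,
                inference="mi" if prefix == "rna" else "none",
            )
        )
    kwargs = dict(
        blocks=blocks,
        knowledge=[KnowledgeConfig(path=str(bundle_dir / "knowledge_ppi.tsv"), layer="protein")],
        reactions=str(bundle_dir / "reactions.tsv"),
        cross_links=str(bundle_dir / "cross_links.tsv"),
        annotations=str(bundle_dir / "annotations.gmt"),
        seed=seed,
    )
    kwargs.update(overrides)
    return RunConfig(**kwargs)
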