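"""End-to-end pipeline: normalization -> SAM -> enrichment -> networks.

The stage order is fixed: quantile normalization, SAM differential
expression, over-representation against two gene-set collections
(GO-BP-like and pathway-like), the pathway-interaction network with
degree ranking, then the gene signal network with betweenness ranking.
``run_pipeline`` drives either real tabular inputs or the synthetic
generator from a single config and writes seven TSV tables plus a JSON
manifest; every table header records the parameters, seed and package
version, and a rerun with the same config is byte-identical.

Also here: plot-ready exports (volcano, dendrogram) and the 2^-ddCt
qRT-PCR fold-change helper.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.cluster import hierarchy

from . import __version__
from .expression_io import (ExpressionMatrix, quantile_normalize,
                            read_design, read_expression_table)
from .sam_de import SamParams, sam_analysis, write_sam_table
from .enrichment import (fisher_enrich, read_gmt, significant_sets,
                         write_enrichment_table, write_gmt)
from .networks import (build_gene_network, build_pathway_network,
                       betweenness, core_filter, node_degrees, pathway_features,
                       read_edge_list, write_centrality_table, write_edge_list)
from .synthetic import (SimulationSpec, simulate_expression, simulate_gene_sets,
                        simulate_relation_graph, write_truth_table)

logger = logging.getLogger(__name__)

TABLE_NAMES = ("deg", "go_enrichment", "pathway_enrichment", "pathway_network",
               "core_pathways", "gene_network", "hub_genes")


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; the message names the stage."""


@dataclass
class PipelineConfig:
    """Everything one run needs; exactly one of synthetic/inputs is set.

    ``synthetic`` holds :class:`SimulationSpec` keyword overrides plus the
    optional gene-set-simulation keys n_go_sets, n_pathway_sets,
    planted_fraction.  ``inputs`` maps the real-data file roles
    (expression, design, go_gmt, pathway_gmt, pathway_relations,
    gene_interactions) to paths.
    """

    outdir: str = "samnet_out"
    seed: int = 0
    synthetic: dict | None = None
    inputs: dict | None = None
    sam: dict = field(default_factory=dict)
    enrichment: dict = field(default_factory=dict)
    network: dict = field(default_factory=dict)
    normalize: bool = True
    expression_dialect: str = "plain_tsv"

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.inputs is None):
            raise ValueError("config must set exactly one of 'synthetic' or 'inputs'")
        for key in ("q_threshold", "fc_threshold"):
            if key in self.sam and self.sam[key] <= 0:
                raise ValueError(f"sam.{key} must be positive")
        if self.enrichment.get("fdr_threshold", 0.05) <= 0:
            raise ValueError("enrichment.fdr_threshold must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        return wrapped
    return deco


def _header(config: PipelineConfig, stage: str, extra: Mapping | None = None) -> list[str]:
    bits = [f"samnet {__version__}", f"stage={stage}", f"seed={config.seed}"]
    if extra:
        bits.append(" ".join(f"{k}={v}" for k, v in sorted(extra.items())))
    return bits


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return (and write) the output manifest.

    The manifest maps the seven canonical table names to their files and
    records parameters, seed, version and (for synthetic runs) the
    planted structure.  Any stage failure raises
    :class:`PipelineError` naming the stage.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.seed)
    sam_params = SamParams(seed=(seed + 5) % (2**31), **config.sam)
    fdr_threshold = config.enrichment.get("fdr_threshold", 0.05)
    sig_field = config.enrichment.get("sig_field", "fdr")
    min_degree = config.network.get("min_degree", 1)

    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "params": {
            "sam": asdict(sam_params),
            "enrichment": {"fdr_threshold": fdr_threshold, "sig_field": sig_field},
            "network": {"min_degree": min_degree},
            "normalize": config.normalize,
        },
        "tables": {},
        "planted": {},
        "partial": [],
    }

    @_stage("input")
    def load_inputs():
        if config.synthetic is not None:
            syn = dict(config.synthetic)
            n_go = syn.pop("n_go_sets", 50)
            n_pw = syn.pop("n_pathway_sets", 40)
            planted_fraction = syn.pop("planted_fraction", 0.8)
            spec = SimulationSpec(seed=seed, **syn)
            exp = simulate_expression(spec)
            write_truth_table(exp.truth, spec, outdir / "truth.tsv")
            manifest["planted"]["truth_table"] = "truth.tsv"
            return exp.matrix, exp.design, exp.truth, (n_go, n_pw, planted_fraction)
        paths = config.inputs
        matrix = read_expression_table(paths["expression"], dialect=config.expression_dialect)
        design = read_design(paths["design"])
        return matrix, design, None, None

    matrix, design, truth, syn_extra = load_inputs()

    @_stage("normalization")
    def normalize(m):
        return quantile_normalize(m) if config.normalize else m

    matrix = normalize(matrix)

    @_stage("sam")
    def run_sam():
        res = sam_analysis(matrix, design, sam_params)
        write_sam_table(res, outdir / "deg_table.tsv",
                        _header(config, "sam", {"s0": res.attrs["s0"],
                                                "n_null": res.attrs["n_null_assignments"]}))
        manifest["tables"]["deg"] = "deg_table.tsv"
        return res

    sam_results = run_sam()
    deg_mask = sam_results["regulation"] != "none"
    deg_genes = list(sam_results.index[deg_mask])
    deg_regulation = sam_results.loc[deg_mask, "regulation"].to_dict()

    @_stage("gene_sets")
    def load_gene_sets():
        if config.synthetic is not None:
            n_go, n_pw, planted_fraction = syn_extra
            # scale planted-set sizes to the DE genes actually planted
            n_de = int((truth["planted"] != "none").sum())
            planted_size = min(50, max(4, n_de // 2))
            if n_de == 0:
                planted_fraction = 0.0
            need = max(1, int(round(planted_fraction * planted_size)))
            go_coll, go_planted = simulate_gene_sets(
                truth, n_sets=n_go, planted_fraction=planted_fraction,
                planted_size=planted_size,
                seed=(seed + 1) % (2**31), n_planted=1, prefix="GO")
            pw_coll, pw_planted = simulate_gene_sets(
                truth, n_sets=n_pw, planted_fraction=planted_fraction,
                planted_size=planted_size,
                seed=(seed + 2) % (2**31),
                n_planted=max(1, min(5, n_pw, n_de // need)), prefix="PW")
            write_gmt(go_coll, outdir / "go_sets.gmt")
            write_gmt(pw_coll, outdir / "pathway_sets.gmt")
            manifest["planted"]["go_sets"] = go_planted
            manifest["planted"]["pathway_sets"] = pw_planted
            return go_coll, pw_coll
        universe = matrix.feature_ids
        return (read_gmt(config.inputs["go_gmt"], universe),
                read_gmt(config.inputs["pathway_gmt"], universe))

    go_coll, pw_coll = load_gene_sets()

    @_stage("enrichment")
    def run_enrichment():
        go = fisher_enrich(deg_genes, go_coll)
        pw = fisher_enrich(deg_genes, pw_coll)
        write_enrichment_table(significant_sets(go, fdr_threshold, sig_field),
                               outdir / "go_enrichment.tsv",
                               _header(config, "go_enrichment",
                                       {"threshold": fdr_threshold, "field": sig_field}))
        write_enrichment_table(significant_sets(pw, fdr_threshold, sig_field),
                               outdir / "pathway_enrichment.tsv",
                               _header(config, "pathway_enrichment",
                                       {"threshold": fdr_threshold, "field": sig_field}))
        manifest["tables"]["go_enrichment"] = "go_enrichment.tsv"
        manifest["tables"]["pathway_enrichment"] = "pathway_enrichment.tsv"
        return go, pw

    go_enr, pw_enr = run_enrichment()
    sig_pw = significant_sets(pw_enr, fdr_threshold, sig_field)

    @_stage("pathway_network")
    def run_pathway_network():
        if len(sig_pw) == 0:
            raise ValueError("no significant pathways; cannot build the pathway network")
        if config.synthetic is not None:
            # planted hub pathway first so the simulated relation graph
            # centres on a set the enrichment stage should have found
            planted_first = [s for s in manifest["planted"]["pathway_sets"]]
            rest = [s for s in sorted(pw_coll.sets) if s not in planted_first]
            node_ids = planted_first + rest
            graph, man = simulate_relation_graph(
                len(node_ids), "pathway", seed=(seed + 3) % (2**31), node_ids=node_ids)
            relations = graph.edges
            manifest["planted"]["pathway_hub"] = man["hub"]
            write_edge_list(relations, outdir / "pathway_relations.tsv")
        else:
            relations = read_edge_list(config.inputs["pathway_relations"])
        hits = {row.set_id: row.members_hit.split("|") if row.members_hit else []
                for row in pw_enr.itertuples()}
        feats = pathway_features(hits, deg_regulation)
        names = {sid: pw_coll.sets[sid].name for sid in pw_coll.sets}
        net = build_pathway_network(list(sig_pw["set_id"]), relations, names, feats)
        degrees = node_degrees(net)
        core = core_filter(degrees, min_degree=min_degree, sort_by="degree")
        write_edge_list(net.edges, outdir / "pathway_network.tsv",
                        _header(config, "pathway_network"))
        write_centrality_table(core, outdir / "core_pathways.tsv",
                               _header(config, "core_pathways",
                                       {"min_degree": min_degree}))
        manifest["tables"]["pathway_network"] = "pathway_network.tsv"
        manifest["tables"]["core_pathways"] = "core_pathways.tsv"
        return net, core

    run_pathway_network()

    @_stage("gene_network")
    def run_gene_network():
        if len(deg_genes) < 4:
            raise ValueError(f"only {len(deg_genes)} DEGs; need >= 4 for a gene network")
        features = {g: ("Up" if deg_regulation[g] == "up" else "Down") for g in deg_genes}
        if config.synthetic is not None:
            n_nodes = min(41, len(deg_genes))
            if n_nodes % 2 == 0 and n_nodes > 4:
                n_nodes -= 1  # equal bridge clusters => strict top betweenness
            node_ids = deg_genes[:n_nodes]  # rank order: strongest DEGs
            graph, man = simulate_relation_graph(
                n_nodes, "gene", seed=(seed + 4) % (2**31), node_ids=node_ids)
            interactions = graph.edges
            manifest["planted"]["gene_bridge"] = man["bridge"]
            write_edge_list(interactions, outdir / "gene_interactions.tsv")
        else:
            interactions = read_edge_list(config.inputs["gene_interactions"])
        net = build_gene_network(features, interactions)
        records = betweenness(net)
        hubs = core_filter(records, min_degree=min_degree, sort_by="betweenness")
        write_edge_list(net.edges, outdir / "gene_network.tsv",
                        _header(config, "gene_network"))
        write_centrality_table(hubs, outdir / "hub_genes.tsv",
                               _header(config, "hub_genes",
                                       {"min_degree": min_degree}))
        manifest["tables"]["gene_network"] = "gene_network.tsv"
        manifest["tables"]["hub_genes"] = "hub_genes.tsv"
        return net, hubs

    run_gene_network()

    missing = [t for t in TABLE_NAMES if t not in manifest["tables"]]
    manifest["partial"] = missing
    with (outdir / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


# ---------------------------------------------------------------------------
# plot-ready exports


def volcano_data(results: pd.DataFrame) -> pd.DataFrame:
    """Volcano-plot table: x = signed fold change, y = -log10 p, call flag.

    The flag is +1 for called-up genes, -1 for called-down, 0 otherwise;
    the add-one permutation p keeps y finite.
    """
    if (results["p"] <= 0).any():
        raise ValueError("p-values must be positive")
    flag = np.zeros(len(results), dtype=int)
    flag[(results["regulation"] == "up").to_numpy()] = 1
    flag[(results["regulation"] == "down").to_numpy()] = -1
    return pd.DataFrame(
        {"fold_change": results["fold_change"],
         "neg_log10_p": -np.log10(results["p"]),
         "call": flag},
        index=results.index,
    )


def dendrogram_data(m: ExpressionMatrix, degs: Iterable[str],
                    method: str = "average", metric: str = "euclidean") -> dict:
    """Hierarchical-clustering export for a DEG heatmap dendrogram.

    The DEG submatrix is z-scored per gene, then genes and samples are
    clustered (average linkage on Euclidean distance by default).
    Returns gene/sample linkage tables (merge order, heights, cluster
    sizes) and the leaf orders; deterministic for fixed input.
    """
    genes = [g for g in degs]
    if len(genes) < 2:
        raise ValueError("need at least 2 DEGs to cluster")
    sub = m.values.loc[genes]
    X = sub.to_numpy(dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0  # constant genes carry no shape; leave them at 0
    Z = (X - mu) / sd

    gene_linkage = hierarchy.linkage(Z, method=method, metric=metric)
    sample_linkage = hierarchy.linkage(Z.T, method=method, metric=metric)

    def _table(link: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(link, columns=["left", "right", "height", "size"])

    return {
        "gene_linkage": _table(gene_linkage),
        "sample_linkage": _table(sample_linkage),
        "gene_order": [genes[i] for i in hierarchy.leaves_list(gene_linkage)],
        "sample_order": [sub.columns[i] for i in hierarchy.leaves_list(sample_linkage)],
    }


def ddct_fold(ct_target_case: float, ct_ref_case: float,
              ct_target_ctrl: float, ct_ref_ctrl: float) -> float:
    """Relative qRT-PCR expression by the 2^-ddCt method.

    ddCt = (Ct_target - Ct_reference) in the case minus the same
    difference in the control; the returned fold is 2**(-ddCt), so equal
    Ct everywhere gives 1 and each extra cycle of the case target halves
    the fold.
    """
    ddct = (ct_target_case - ct_ref_case) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-ddct))
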