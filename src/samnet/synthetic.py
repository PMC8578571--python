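"""Synthetic two-group microarray data with planted, known structure.

The generator emulates the design of a 6 vs 6 rat soleus-muscle
microarray comparison: ~15,000 features on a log2 intensity scale, two
balanced groups, a small planted fraction of differentially expressed
genes with a down:up imbalance of roughly 3.5:1 (echoing the 720:205
split observed in that study), planted enriched gene sets, and planted
high-centrality nodes in the relation graphs.  Every stage of the
pipeline can therefore be scored against known truth with no download.

Noise is Gaussian on the log2 scale with equal variance in both groups —
the simplest model consistent with a two-group mean comparison.  Real
microarrays additionally show probe-level artefacts, batch effects and
intensity-dependent variance, which this generator deliberately omits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .expression_io import ExpressionMatrix, GroupDesign
from .enrichment import GeneSet, GeneSetCollection
from .networks import Edge, RelationGraph

TRUTH_UP = "up"
TRUTH_DOWN = "down"
TRUTH_NONE = "none"

_GENE_EDGE_TYPES = ("c", "a", "ind", "inh", "ex", "b")


@dataclass
class SimulationSpec:
    """Parameters of the planted two-group expression simulation.

    Defaults mirror the emulated study design: 6 samples per group,
    15,000 features, 4.8% planted down- and 1.4% planted up-regulated
    genes (the observed 720:205 imbalance at its observed overall rate),
    a planted effect of 1.5 log2 units (linear 2^1.5 ~ 2.83, comfortably
    beyond the |FC| > 1.5 gate), and a within-group SD of 0.25 log2
    units.  Baseline log2 intensities are Normal(8, 1.5).
    """

    n_genes: int = 15_000
    n_per_group: int = 6
    frac_down: float = 0.048
    frac_up: float = 0.014
    effect_log2: float = 1.5
    sigma: float = 0.25
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.frac_down < 1 and 0 <= self.frac_up < 1):
            raise ValueError("planted fractions must lie in [0, 1)")
        if self.frac_down + self.frac_up >= 1:
            raise ValueError("frac_down + frac_up must be < 1")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.n_per_group < 2:
            raise ValueError("need at least 2 samples per group")


class SimulatedExperiment(NamedTuple):
    matrix: ExpressionMatrix
    design: GroupDesign
    truth: pd.DataFrame  # gene-indexed, column 'planted' in {up, down, none}


def simulate_expression(spec: SimulationSpec) -> SimulatedExperiment:
    """Draw a planted two-group log2 expression matrix.

    Gene g has baseline mu_g ~ Normal(baseline_mean, baseline_sd); control
    samples ~ Normal(mu_g, sigma); experimental samples ~
    Normal(mu_g +/- effect_log2, sigma) for planted genes and
    Normal(mu_g, sigma) otherwise.  The truth table records each gene's
    planted direction.  Fixed seed => bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    G, n = spec.n_genes, spec.n_per_group
    genes = [f"G{i:06d}" for i in range(G)]
    samples = [f"ctrl_{i+1}" for i in range(n)] + [f"case_{i+1}" for i in range(n)]

    n_down = int(round(spec.frac_down * G))
    n_up = int(round(spec.frac_up * G))
    planted = np.array(rng.choice(G, size=n_down + n_up, replace=False))
    truth = np.full(G, TRUTH_NONE, dtype=object)
    truth[planted[:n_down]] = TRUTH_DOWN
    truth[planted[n_down:]] = TRUTH_UP

    mu = rng.normal(spec.baseline_mean, spec.baseline_sd, size=G)
    shift = np.zeros(G)
    shift[truth == TRUTH_DOWN] = -spec.effect_log2
    shift[truth == TRUTH_UP] = spec.effect_log2

    X = np.empty((G, 2 * n))
    X[:, :n] = rng.normal(mu[:, None], spec.sigma, size=(G, n))
    X[:, n:] = rng.normal((mu + shift)[:, None], spec.sigma, size=(G, n))

    matrix = ExpressionMatrix(pd.DataFrame(X, index=genes, columns=samples), scale="log2")
    design = GroupDesign(
        {s: ("control" if s.startswith("ctrl") else "experimental") for s in samples}
    )
    truth_df = pd.DataFrame({"planted": truth}, index=pd.Index(genes, name="gene"))
    return SimulatedExperiment(matrix, design, truth_df)


def simulate_gene_sets(
    truth: pd.DataFrame,
    n_sets: int = 50,
    planted_fraction: float = 0.8,
    seed: int = 0,
    set_size: tuple[int, int] = (10, 80),
    planted_size: int = 50,
    n_planted: int = 1,
    prefix: str = "SET",
) -> tuple[GeneSetCollection, list[str]]:
    """Random gene sets with planted enriched ones.

    Background sets are uniform draws from the universe (the truth
    table's genes).  The first ``n_planted`` sets are each filled to
    ``planted_fraction`` with planted-DE genes, so a correct Fisher test
    must rank them first.  Returns the collection and the planted set ids.
    """
    rng = np.random.default_rng(seed)
    universe = list(truth.index)
    de_genes = list(truth.index[truth["planted"] != TRUTH_NONE])
    lo, hi = set_size
    sets: dict[str, GeneSet] = {}
    planted_ids: list[str] = []

    n_de_needed = int(round(planted_fraction * planted_size))
    if n_planted * n_de_needed > len(de_genes):
        raise ValueError(
            f"planted sets need {n_planted * n_de_needed} DE genes but only "
            f"{len(de_genes)} are planted"
        )
    de_pool = list(rng.permutation(de_genes))
    for i in range(n_planted):
        sid = f"{prefix}{i:04d}"
        de_part = [de_pool.pop() for _ in range(n_de_needed)]
        rest = [g for g in universe if g not in set(de_part)]
        filler = rng.choice(len(rest), size=planted_size - n_de_needed, replace=False)
        members = frozenset(de_part + [rest[j] for j in filler])
        sets[sid] = GeneSet(sid, f"planted enriched set {i}", members)
        planted_ids.append(sid)

    for i in range(n_planted, n_sets):
        sid = f"{prefix}{i:04d}"
        size = int(rng.integers(lo, hi + 1))
        members = frozenset(np.array(universe)[rng.choice(len(universe), size=size, replace=False)])
        sets[sid] = GeneSet(sid, f"background set {i}", members)

    return GeneSetCollection(sets, frozenset(universe)), planted_ids


def simulate_relation_graph(
    n_nodes: int,
    style: str,
    seed: int = 0,
    node_ids: list[str] | None = None,
) -> tuple[RelationGraph, dict]:
    """Relation graph with a planted high-centrality node.

    ``pathway`` style: sparse random directed graph in which a designated
    node is linked to every other node, guaranteeing it the maximum
    degree.  ``gene`` style: two complete undirected clusters joined
    through a single bridge node (one anchor per cluster), guaranteeing
    the bridge the top betweenness; edge types are drawn from the
    interaction legend.  The manifest names the planted node.
    """
    if n_nodes < 4:
        raise ValueError("need at least 4 nodes")
    rng = np.random.default_rng(seed)
    if node_ids is None:
        node_ids = [f"N{i:03d}" for i in range(n_nodes)]
    if len(node_ids) != n_nodes:
        raise ValueError("node_ids length must equal n_nodes")
    nodes = {nid: {"name": nid, "feature": ""} for nid in node_ids}

    if style == "pathway":
        hub = node_ids[0]
        edges: list[Edge] = []
        for other in node_ids[1:]:
            if rng.random() < 0.5:
                edges.append(Edge(hub, other, "link", True))
            else:
                edges.append(Edge(other, hub, "link", True))
        # sparse background arcs; per-node extra degree capped well below hub's
        others = node_ids[1:]
        max_extra = max(0, n_nodes - 4)
        extra_deg = {nid: 0 for nid in others}
        n_extra = int(rng.integers(n_nodes // 2, n_nodes))
        for _ in range(n_extra):
            a, b = rng.choice(len(others), size=2, replace=False)
            u, v = others[a], others[b]
            if extra_deg[u] >= max_extra or extra_deg[v] >= max_extra:
                continue
            edges.append(Edge(u, v, "link", True))
            extra_deg[u] += 1
            extra_deg[v] += 1
        graph = RelationGraph(nodes, edges)
        return graph, {"style": "pathway", "hub": hub, "seed": seed}

    if style == "gene":
        # bridge node + two complete clusters, each touching the bridge
        # through a single anchor; all edges undirected, typed at random
        bridge = node_ids[0]
        rest = node_ids[1:]
        half = len(rest) // 2
        cluster_a, cluster_b = rest[:half], rest[half:]
        edges = []

        def _etype() -> str:
            return _GENE_EDGE_TYPES[int(rng.integers(len(_GENE_EDGE_TYPES)))]

        for cluster in (cluster_a, cluster_b):
            for i in range(len(cluster)):
                for j in range(i + 1, len(cluster)):
                    edges.append(Edge(cluster[i], cluster[j], _etype(), False))
        edges.append(Edge(bridge, cluster_a[0], _etype(), False))
        edges.append(Edge(bridge, cluster_b[0], _etype(), False))
        graph = RelationGraph(nodes, edges)
        manifest = {
            "style": "gene",
            "bridge": bridge,
            "anchors": [cluster_a[0], cluster_b[0]],
            "clusters": [cluster_a, cluster_b],
            "seed": seed,
        }
        return graph, manifest

    raise ValueError(f"unknown style {style!r}; expected 'pathway' or 'gene'")


def random_relation_graph(n_nodes: int, edge_prob: float = 0.3, seed: int = 0
                          ) -> RelationGraph:
    """Seeded random mixed directed/undirected typed graph (test fodder
    for centrality oracles; no planted structure)."""
    rng = np.random.default_rng(seed)
    node_ids = [f"n{i:02d}" for i in range(n_nodes)]
    nodes = {nid: {"name": nid, "feature": ""} for nid in node_ids}
    edges: list[Edge] = []
    types = sorted(_GENE_EDGE_TYPES)
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() >= edge_prob:
                continue
            etype = types[int(rng.integers(len(types)))]
            directed = bool(rng.random() < 0.5)
            if directed and rng.random() < 0.5:
                edges.append(Edge(node_ids[j], node_ids[i], etype, True))
            else:
                edges.append(Edge(node_ids[i], node_ids[j], etype, directed))
    return RelationGraph(nodes, edges)


def write_truth_table(truth: pd.DataFrame, spec: SimulationSpec, path) -> None:
    """Truth table as TSV; the header records the generating parameters."""
    from pathlib import Path

    with Path(path).open("w") as fh:
        fh.write(
            "# simulation: n_genes=%d n_per_group=%d frac_down=%g frac_up=%g "
            "effect_log2=%g sigma=%g baseline=(%g,%g) seed=%d\n"
            % (spec.n_genes, spec.n_per_group, spec.frac_down, spec.frac_up,
               spec.effect_log2, spec.sigma, spec.baseline_mean, spec.baseline_sd,
               spec.seed)
        )
        truth.to_csv(fh, sep="\t")
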