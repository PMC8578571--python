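"""Pathway-interaction and gene-signal networks with centrality rankings.

Two graphs are built from typed edge lists:

* the pathway network — a directed graph induced on the significant
  pathways, arcs oriented upstream -> downstream; pathways are ranked by
  degree (indegree + outdegree), and "core" pathways are those of degree
  at least 1;
* the gene signal network — the interaction graph induced on the DEGs,
  with mixed directed/undirected typed edges (compound c, activation a,
  indirect ind, inhibition inh, expression ex, binding b); genes are
  ranked by betweenness centrality, and "hub" genes are those of degree
  at least 1.

Betweenness is the unnormalised ordered-pair count
B(i) = sum over s != i != t of sigma_st(i) / sigma_st, computed on the
0/1 adjacency view in which every undirected edge is usable in both
directions; disconnected pairs contribute nothing, multiple shortest
paths share credit fractionally, and endpoints are excluded.  Edge types
annotate but do not alter traversal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EDGE_TYPES = {"c", "a", "ind", "inh", "ex", "b", "link"}

FEAT_UP = "Up"
FEAT_DOWN = "Down"
FEAT_BOTH = "Up|down"


@dataclass(frozen=True)
class Edge:
    source: str
    target: str
    etype: str = "link"
    directed: bool = True

    def __post_init__(self) -> None:
        if self.etype not in EDGE_TYPES:
            raise ValueError(f"unknown edge type {self.etype!r}; expected one of {sorted(EDGE_TYPES)}")

    def canonical(self) -> "Edge":
        """Undirected edges are stored once, endpoints in sorted order."""
        if self.directed or self.source <= self.target:
            return self
        return Edge(self.target, self.source, self.etype, False)


@dataclass
class RelationGraph:
    """Mixed directed/undirected typed graph over annotated nodes.

    ``nodes`` maps node id -> payload dict (keys used here: ``name``,
    ``feature``).  ``edges`` hold each undirected edge once; the adjacency
    view (:meth:`adjacency`) expands it to both arcs, so an undirected
    edge contributes one indegree and one outdegree to each endpoint.
    """

    nodes: dict[str, dict]
    edges: list[Edge] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple] = set()
        kept: list[Edge] = []
        for e in self.edges:
            if e.source not in self.nodes or e.target not in self.nodes:
                raise ValueError(f"edge endpoint not in node set: {e.source!r} -> {e.target!r}")
            if e.source == e.target:
                logger.info("dropping self-loop on %r", e.source)
                continue
            e = e.canonical()
            key = (e.source, e.target, e.etype, e.directed)
            if key in seen:
                continue
            seen.add(key)
            kept.append(e)
        self.edges = kept

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> nx.DiGraph:
        """0/1 adjacency view: every undirected edge becomes two arcs."""
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(e.source, e.target)
            if not e.directed:
                g.add_edge(e.target, e.source)
        return g


def read_edge_list(path: str | Path) -> list[Edge]:
    """Read ``source<TAB>target<TAB>type<TAB>directed(0/1)`` lines."""
    edges: list[Edge] = []
    with Path(path).open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("source\t"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}: malformed edge line {line!r}")
            src, dst, etype, directed = parts
            edges.append(Edge(src, dst, etype, directed == "1"))
    return edges


def write_edge_list(edges: Iterable[Edge], path: str | Path,
                    header_lines: Iterable[str] = ()) -> None:
    with Path(path).open("w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("source\ttarget\ttype\tdirected\n")
        for e in edges:
            fh.write(f"{e.source}\t{e.target}\t{e.etype}\t{int(e.directed)}\n")


def _induced(node_payload: Mapping[str, dict], relations: Iterable[Edge],
             what: str) -> RelationGraph:
    kept: list[Edge] = []
    n_skipped = 0
    for e in relations:
        if e.source in node_payload and e.target in node_payload:
            kept.append(e)
        else:
            n_skipped += 1
    if n_skipped:
        logger.info("skipped %d %s relations referencing nodes outside the graph",
                    n_skipped, what)
    return RelationGraph(dict(node_payload), kept)


def build_pathway_network(
    significant: Sequence[str],
    relations: Iterable[Edge],
    names: Mapping[str, str] | None = None,
    features: Mapping[str, str] | None = None,
) -> RelationGraph:
    """Directed network induced on the significant pathways.

    Arcs keep the relation list's upstream -> downstream orientation;
    relations touching non-significant pathways are skipped (logged).
    ``features`` optionally carries each pathway's Up/Down/Up|down label
    (the union of its member-DEG directions).
    """
    if not significant:
        raise ValueError("no significant pathways to build a network from")
    names = names or {}
    features = features or {}
    payload = {p: {"name": names.get(p, p), "feature": features.get(p, "")} for p in significant}
    return _induced(payload, relations, "pathway")


def build_gene_network(
    deg_features: Mapping[str, str],
    interactions: Iterable[Edge],
    names: Mapping[str, str] | None = None,
) -> RelationGraph:
    """Typed interaction network induced on the DEGs.

    ``deg_features`` maps gene -> 'Up'/'Down' (its regulation call);
    interactions involving non-DEG genes are skipped (logged).
    """
    if not deg_features:
        raise ValueError("no DEGs to build a network from")
    names = names or {}
    payload = {g: {"name": names.get(g, g), "feature": f} for g, f in deg_features.items()}
    return _induced(payload, interactions, "gene")


def node_degrees(g: RelationGraph) -> pd.DataFrame:
    """Per-node indegree, outdegree and degree from the adjacency view.

    degree = indegree + outdegree; an undirected edge adds 1 to both the
    in- and outdegree of each endpoint.
    """
    adj = g.adjacency()
    rows = []
    for node in sorted(g.nodes):
        indeg = adj.in_degree(node)
        outdeg = adj.out_degree(node)
        rows.append((node, g.nodes[node].get("name", node),
                     g.nodes[node].get("feature", ""), indeg, outdeg, indeg + outdeg))
    return pd.DataFrame(rows, columns=["node", "name", "feature",
                                       "indegree", "outdegree", "degree"]).set_index("node")


def betweenness(g: RelationGraph) -> pd.DataFrame:
    """Degrees plus unnormalised ordered-pair betweenness B(i).

    Brandes' algorithm on the directed adjacency view with unit weights
    and endpoints excluded; undirected edges are traversable both ways.
    """
    out = node_degrees(g)
    bc = nx.betweenness_centrality(g.adjacency(), normalized=False)
    out["betweenness"] = [bc[n] for n in out.index]
    return out


def core_filter(records: pd.DataFrame, min_degree: int = 1,
                sort_by: str = "degree") -> pd.DataFrame:
    """Keep nodes with degree >= min_degree, ranked by the given column.

    Pathway tables are ranked by decreasing degree, gene tables by
    decreasing betweenness; ties break by decreasing degree (for
    betweenness sorting) then node id.
    """
    if sort_by not in ("degree", "betweenness"):
        raise ValueError("sort_by must be 'degree' or 'betweenness'")
    if sort_by == "betweenness" and "betweenness" not in records.columns:
        raise ValueError("betweenness column missing; run betweenness() first")
    out = records[records["degree"] >= min_degree].copy()
    out.sort_index(kind="stable", inplace=True)
    if sort_by == "degree":
        out.sort_values("degree", ascending=False, kind="stable", inplace=True)
    else:
        out.sort_values(["betweenness", "degree"], ascending=False, kind="stable", inplace=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def rank_hubs(records: pd.DataFrame, top_k: int) -> pd.DataFrame:
    """Top-k nodes by descending betweenness (ties: degree, then id)."""
    if top_k <= 0:
        raise ValueError("top_k must be positive")
    if "betweenness" not in records.columns:
        raise ValueError("betweenness column missing; run betweenness() first")
    out = records.copy()
    out.sort_index(kind="stable", inplace=True)
    out.sort_values(["betweenness", "degree"], ascending=False, kind="stable", inplace=True)
    out = out.head(top_k)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def pathway_features(set_members_hit: Mapping[str, Iterable[str]],
                     deg_regulation: Mapping[str, str]) -> dict[str, str]:
    """Up/Down/Up|down label per pathway from its member DEG directions."""
    out: dict[str, str] = {}
    for sid, members in set_members_hit.items():
        regs = {deg_regulation.get(g, "") for g in members}
        has_up = "up" in regs or FEAT_UP in regs
        has_down = "down" in regs or FEAT_DOWN in regs
        if has_up and has_down:
            out[sid] = FEAT_BOTH
        elif has_up:
            out[sid] = FEAT_UP
        elif has_down:
            out[sid] = FEAT_DOWN
        else:
            out[sid] = ""
    return out


def write_centrality_table(records: pd.DataFrame, path: str | Path,
                           header_lines: Iterable[str] = ()) -> None:
    with Path(path).open("w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        records.to_csv(fh, sep="\t", index_label="node")
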