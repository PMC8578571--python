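"""Fisher's-exact over-representation of DEGs in gene-set collections.

Given a DEG list and a collection of gene sets (GO-biological-process-like
or KEGG-pathway-like, read from GMT), each set is scored with the
upper-tail hypergeometric probability P[X >= k] of drawing k or more set
members among the n DEGs from a universe of N genes of which K are in the
set.  Benjamini–Hochberg correction yields an FDR per set; significant
sets are those below the FDR (or, optionally, raw-p) threshold.

The universe is the set of genes actually present on the analysed
expression matrix — the only background the pipeline can know.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class GeneSet:
    set_id: str
    name: str
    members: frozenset[str]


@dataclass
class GeneSetCollection:
    """Named gene sets plus the background universe.

    Members outside the universe are removed on construction via
    :meth:`restricted`; sets emptied by the restriction are dropped (and
    counted in the log).
    """

    sets: dict[str, GeneSet]
    universe: frozenset[str]

    def restricted(self) -> "GeneSetCollection":
        kept: dict[str, GeneSet] = {}
        n_dropped = 0
        for sid, gs in self.sets.items():
            members = gs.members & self.universe
            if members:
                kept[sid] = GeneSet(sid, gs.name, members)
            else:
                n_dropped += 1
        if n_dropped:
            logger.info("dropped %d empty gene sets after universe restriction", n_dropped)
        return GeneSetCollection(kept, self.universe)

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path, universe: Iterable[str]) -> GeneSetCollection:
    """Read a GMT file: ``set_id<TAB>description<TAB>member...`` per line."""
    sets: dict[str, GeneSet] = {}
    with Path(path).open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: malformed GMT line {line[:60]!r}")
            sid, name, members = parts[0], parts[1], [g for g in parts[2:] if g]
            if sid in sets:
                raise ValueError(f"duplicate gene-set id: {sid!r}")
            sets[sid] = GeneSet(sid, name, frozenset(members))
    return GeneSetCollection(sets, frozenset(universe)).restricted()


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for sid in sorted(coll.sets):
            gs = coll.sets[sid]
            fh.write("\t".join([gs.set_id, gs.name, *sorted(gs.members)]) + "\n")


def fisher_enrich(degs: Iterable[str], coll: GeneSetCollection) -> pd.DataFrame:
    """One-sided Fisher / hypergeometric enrichment of every set.

    Returns a DataFrame sorted by increasing p with columns set_id, name,
    k (DEGs in set), K (universe genes in set), n (DEGs), N (universe),
    p, fdr, members_hit (pipe-delimited).  DEGs outside the universe are
    dropped (logged).
    """
    coll = coll.restricted()
    deg_set = set(degs)
    outside = deg_set - coll.universe
    if outside:
        logger.info("dropped %d DEGs absent from the universe", len(outside))
        deg_set -= outside
    if not deg_set:
        raise ValueError("no DEGs within the universe")
    if not coll.universe:
        raise ValueError("empty universe")

    N = len(coll.universe)
    n = len(deg_set)
    rows = []
    for sid in sorted(coll.sets):
        gs = coll.sets[sid]
        K = len(gs.members)
        hit = gs.members & deg_set
        k = len(hit)
        # P[X >= k] for X ~ Hypergeom(N, K, n)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((sid, gs.name, k, K, n, N, p, "|".join(sorted(hit))))
    out = pd.DataFrame(rows, columns=["set_id", "name", "k", "K", "n", "N", "p", "members_hit"])
    out["fdr"] = bh_fdr(out["p"].to_numpy())
    out = out.sort_values(["p", "set_id"], kind="stable").reset_index(drop=True)
    return out[["set_id", "name", "k", "K", "n", "N", "p", "fdr", "members_hit"]]


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def significant_sets(records: pd.DataFrame, fdr_threshold: float = 0.05,
                     sig_field: str = "fdr") -> pd.DataFrame:
    """Keep sets with ``sig_field`` (fdr or p) below the threshold.

    Ordering by increasing p is preserved and ranks 1..n attached.
    """
    if sig_field not in ("fdr", "p"):
        raise ValueError("sig_field must be 'fdr' or 'p'")
    out = records[records[sig_field] < fdr_threshold].copy().reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def collapse_probes(results: pd.DataFrame, probe_to_gene: Mapping[str, str]) -> pd.DataFrame:
    """Collapse probe-level SAM results to gene symbols.

    When several probes map to one symbol the probe with the smallest p
    (ties: smallest q, then probe id) represents the gene.  Probes with no
    mapping are dropped.
    """
    mapped = results[results.index.isin(probe_to_gene.keys())].copy()
    mapped["__gene"] = [probe_to_gene[p] for p in mapped.index]
    mapped = mapped.sort_index(kind="stable").sort_values(["p", "q"], kind="stable")
    collapsed = mapped.groupby("__gene", sort=False).head(1)
    collapsed = collapsed.reset_index().rename(columns={"gene": "probe"})
    collapsed = collapsed.rename(columns={"__gene": "gene"}).set_index("gene")
    return collapsed


def write_enrichment_table(records: pd.DataFrame, path: str | Path,
                           header_lines: Iterable[str] = ()) -> None:
    with Path(path).open("w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        records.to_csv(fh, sep="\t", index=False)
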