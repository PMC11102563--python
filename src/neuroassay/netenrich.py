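"""Gene-set enrichment network.

Differentially expressed genes (FDR < 0.05 and |log2FC| > 1.1, strict) are
intersected with a gene-set collection; per-set overrepresentation is
scored with a one-sided hypergeometric test against a user-supplied
universe, adjusted by Benjamini-Hochberg. Significant sets become network
nodes sized by their DEG hit count; two sets are connected when their
overlap coefficient — the average of |A∩B|/|A| and |A∩B|/|B| — is at least
0.3 (inclusive), with edge weight the number of shared genes.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .config import NetworkConfig
from .stats import benjamini_hochberg


def filter_degs(deg_table: pd.DataFrame, cfg: NetworkConfig) -> Dict[str, Set[str]]:
    """Apply the DEG inclusion rule (strict inequalities).

    Returns ``{"up": ..., "down": ..., "all": ...}`` gene-id sets.
    """
    passing = deg_table[
        (deg_table.fdr < cfg.fdr_max) & (deg_table.log2fc.abs() > cfg.log2fc_min)
    ]
    up = set(passing.loc[passing.log2fc > 0, "gene_id"])
    down = set(passing.loc[passing.log2fc < 0, "gene_id"])
    return {"up": up, "down": down, "all": up | down}


def overlap_coefficient(a: Set[str], b: Set[str]) -> float:
    """OC(A, B) = (|A∩B|/|A| + |A∩B|/|B|) / 2; symmetric, in [0, 1]."""
    if not a or not b:
        raise ValueError("overlap_coefficient requires non-empty sets")
    inter = len(a & b)
    return (inter / len(a) + inter / len(b)) / 2.0


def enrich(
    genesets: Dict[str, Set[str]],
    degs: Set[str],
    universe: Set[str],
) -> pd.DataFrame:
    """Per-set DEG hit counts with hypergeometric overrepresentation p.

    ``p = P(X >= hits)`` for X hypergeometric(|universe|, |set|, |degs|);
    Benjamini-Hochberg adjusted values across all sets are in the ``fdr``
    column. Sets extending beyond the universe are intersected with it
    (with a warning via the returned ``trimmed`` flag column).
    """
    if not degs <= universe:
        degs = degs & universe
    M = len(universe)
    N = len(degs)
    rows = []
    for name, genes in genesets.items():
        trimmed = not genes <= universe
        genes = genes & universe
        hits = len(genes & degs)
        n = len(genes)
        p = float(hypergeom.sf(hits - 1, M, n, N)) if n else 1.0
        rows.append(
            {"set_id": name, "set_size": n, "deg_hits": hits, "p": p, "trimmed": trimmed}
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df["fdr"] = benjamini_hochberg(df["p"].to_numpy())
    else:
        df["fdr"] = []
    return df


def build_network(
    genesets: Dict[str, Set[str]],
    degs: Set[str],
    universe: Set[str],
    cfg: NetworkConfig,
) -> nx.Graph:
    """Assemble the enrichment network.

    Nodes are the gene sets significant after BH adjustment
    (fdr < ``fdr_max``), annotated with set size, DEG hit count and
    adjusted FDR; edges connect node pairs with overlap coefficient
    >= ``oc_min`` (inclusive) and carry the OC plus the shared-gene count.
    An empty network is a valid result.
    """
    table = enrich(genesets, degs, universe)
    g = nx.Graph()
    sig = table[table.fdr < cfg.fdr_max]
    for _, row in sig.iterrows():
        g.add_node(
            row.set_id,
            set_size=int(row.set_size),
            deg_hits=int(row.deg_hits),
            enrich_fdr=float(row.fdr),
        )
    names = list(g.nodes)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            sa = genesets[a] & universe
            sb = genesets[b] & universe
            if not sa or not sb:
                continue
            oc = overlap_coefficient(sa, sb)
            shared = len(sa & sb)
            if oc >= cfg.oc_min and shared > 0:
                g.add_edge(a, b, oc=float(oc), shared=shared)
    return g


def write_network_graphml(g: nx.Graph, path) -> Path:
    path = Path(path)
    nx.write_graphml(g, path)
    return path


def write_network_json(g: nx.Graph, path) -> Path:
    path = Path(path)
    payload = {
        "nodes": [{"id": n, **g.nodes[n]} for n in g.nodes],
        "edges": [{"source": a, "target": b, **g.edges[a, b]} for a, b in g.edges],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
    return path
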