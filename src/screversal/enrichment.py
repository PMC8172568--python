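"""Hypergeometric over-representation analysis of gene lists.

Given a query list (e.g. the top reversed genes of a cell type), a
collection of gene sets and a background universe (by default the genes
tested in the relevant contrast), each set is tested for over-representation
with the one-sided hypergeometric tail, and p-values are BH-adjusted across
sets.
"""

from __future__ import annotations

import logging

import pandas as pd
from scipy import stats

from .hurdle import bh_adjust
from .io import GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = ["ora_hypergeom", "enrich_collection"]


def ora_hypergeom(query_genes, gene_set, universe):
    """One-sided hypergeometric over-representation p-value.

    With universe size M, set size K (after intersecting with the universe),
    query size n and overlap k:
    ``p = sum_{k'=k}^{min(K,n)} C(K,k') C(M-K, n-k') / C(M,n)``.
    Returns ``(p_value, k, K, n, M, overlap_genes)``.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query_genes)
    if not query:
        raise ValueError("empty query")
    if not query <= universe:
        raise ValueError("query genes must be a subset of the universe")
    gset = set(gene_set) & universe
    overlap = sorted(query & gset)
    M, K, n, k = len(universe), len(gset), len(query), len(overlap)
    # survival function at k-1 = P(X >= k); hypergeom works in log space
    p = float(stats.hypergeom.sf(k - 1, M, K, n)) if k > 0 else 1.0
    p = min(max(p, 0.0), 1.0)
    return p, k, K, n, M, overlap


def enrich_collection(
    query_genes, collection: GeneSetCollection, universe, alpha: float = 0.05
) -> pd.DataFrame:
    """ORA of a query against every set of a collection, BH across sets.

    Sets without any universe gene are omitted with a warning. Rows are
    sorted by q, then p, then set name; ``significant`` marks q < alpha.
    """
    universe = set(universe)
    rows = []
    for name in collection.names():
        genes = collection.genes(name)
        if not set(genes) & universe:
            logger.warning("gene set %r has no genes in the universe, omitted", name)
            continue
        p, k, K, n, M, overlap = ora_hypergeom(query_genes, genes, universe)
        rows.append(
            {
                "set": name,
                "overlap_k": k,
                "set_size_K": K,
                "query_size_n": n,
                "universe_size_M": M,
                "p_value": p,
                "overlap_genes": ",".join(overlap),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "set",
            "overlap_k",
            "set_size_K",
            "query_size_n",
            "universe_size_M",
            "p_value",
            "overlap_genes",
        ],
    )
    if len(table):
        table["q_value"] = bh_adjust(table["p_value"].to_numpy())
        table["significant"] = table["q_value"] < alpha
        table = table.sort_values(
            ["q_value", "p_value", "set"], kind="stable"
        ).reset_index(drop=True)
    else:
        table["q_value"] = []
        table["significant"] = []
    return table
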