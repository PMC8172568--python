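"""Reversal statistics: does a treatment contrast undo an aging contrast?

Over the union of genes significant in either the aging (aged vs young) or
the treatment (treated vs aged) comparison, two summaries quantify
reversal: the proportion of genes whose fold changes have opposite signs in
the two contrasts, and the slope of the OLS line of best fit of the
treatment lnFC (y) on the aging lnFC (x). A slope near -1 with high r2
means the treatment moves expression back toward the young state
gene-for-gene; a slope near 0 means no systematic effect.

Also here: selection of the top reversed genes (|lnFC| rank <= 500 in both
contrasts, opposite signs) used for pathway enrichment, cross-subtype
consistency regressions, and replication against an independent contrast.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ReversalResult",
    "union_significant",
    "reversal_statistics",
    "select_top_reversed",
    "pairwise_consistency",
    "replication_check",
]


@dataclass
class ReversalResult:
    """Summary of one contrast-vs-contrast reversal comparison."""

    n_union: int
    prop_reversed: float
    slope: float
    intercept: float
    r2: float
    p_slope: float
    gene_table: pd.DataFrame  # gene, lnFC_age, lnFC_treat, reversed

    def __post_init__(self) -> None:
        if self.n_union != len(self.gene_table):
            raise ValueError("n_union must equal the gene-table length")
        if not 0.0 <= self.prop_reversed <= 1.0:
            raise ValueError("prop_reversed outside [0, 1]")

    def summary(self) -> str:
        lines = [
            "Transcriptomic reversal (treatment lnFC regressed on aging lnFC)",
            f"  union of significant DEGs: {self.n_union}",
            f"  proportion reversed:       {self.prop_reversed:.4f}",
        ]
        if np.isfinite(self.slope):
            lines += [
                f"  slope:                     {self.slope:.4f}",
                f"  intercept:                 {self.intercept:.4f}",
                f"  r2:                        {self.r2:.4f}",
                f"  slope p-value:             {self.p_slope:.3g}",
            ]
        else:
            lines.append("  regression: NA (<3 genes)")
        return "\n".join(lines)

    def to_frames(self):
        summary = pd.DataFrame(
            [
                {
                    "n_union": self.n_union,
                    "prop_reversed": self.prop_reversed,
                    "slope": self.slope,
                    "intercept": self.intercept,
                    "r2": self.r2,
                    "p_slope": self.p_slope,
                }
            ]
        )
        return summary, self.gene_table


def _sig_genes(deg: pd.DataFrame, alpha: float) -> set:
    q = deg["q_value"]
    return set(deg.loc[q.notna() & (q < alpha), "gene"])


def union_significant(deg_age: pd.DataFrame, deg_treat: pd.DataFrame, alpha: float = 0.05) -> list:
    """Union of significant DEGs (q < alpha in either contrast).

    A gene significant in one contrast but untested in the other has no fold
    change to compare, so it is excluded (counted and logged) rather than
    imputed.
    """
    sig = _sig_genes(deg_age, alpha) | _sig_genes(deg_treat, alpha)
    if not sig:
        raise ValueError("empty union: no significant DEGs in either contrast")
    tested_both = set(deg_age["gene"]) & set(deg_treat["gene"])
    dropped = sig - tested_both
    if dropped:
        logger.warning(
            "%d union gene(s) untested in one contrast, excluded", len(dropped)
        )
    kept = sorted(sig & tested_both)
    if not kept:
        raise ValueError("empty union after removing genes untested in one contrast")
    return kept


def reversal_statistics(deg_age: pd.DataFrame, deg_treat: pd.DataFrame, genes) -> ReversalResult:
    """Reversal proportion and treatment-on-aging lnFC regression.

    A gene is reversed iff its two fold changes have strictly opposite
    signs; an exactly-zero lnFC carries no direction and never counts as
    reversed. The regression is unweighted OLS with intercept of the
    treatment lnFC on the aging lnFC; with fewer than 3 genes the proportion
    is still returned and the regression fields are NaN.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("no genes supplied")
    x = deg_age.set_index("gene").loc[genes, "lnFC"].to_numpy(float)
    y = deg_treat.set_index("gene").loc[genes, "lnFC"].to_numpy(float)
    reversed_flag = np.sign(x) * np.sign(y) < 0
    prop = float(reversed_flag.mean())
    if len(genes) >= 3 and np.ptp(x) > 0:
        fit = stats.linregress(x, y)
        slope, intercept = float(fit.slope), float(fit.intercept)
        r2, p_slope = float(fit.rvalue**2), float(fit.pvalue)
    else:
        slope = intercept = r2 = p_slope = float("nan")
    table = pd.DataFrame(
        {"gene": genes, "lnFC_age": x, "lnFC_treat": y, "reversed": reversed_flag}
    )
    return ReversalResult(
        n_union=len(genes),
        prop_reversed=prop,
        slope=slope,
        intercept=intercept,
        r2=r2,
        p_slope=p_slope,
        gene_table=table,
    )


def _rank_by_abs_lnfc(deg: pd.DataFrame, significant_only: bool, alpha: float) -> pd.Series:
    """1-based rank of each gene by |lnFC| descending (ties by gene ID)."""
    t = deg
    if significant_only:
        q = t["q_value"]
        t = t[q.notna() & (q < alpha)]
    t = t.assign(_abs=t["lnFC"].abs()).sort_values(
        ["_abs", "gene"], ascending=[False, True], kind="stable"
    )
    return pd.Series(np.arange(1, len(t) + 1), index=t["gene"].to_numpy())


def select_top_reversed(
    deg_age: pd.DataFrame,
    deg_treat: pd.DataFrame,
    rank_limit: int = 500,
    alpha: float = 0.05,
    significant_only: bool = True,
) -> list:
    """Genes in the top ``rank_limit`` |lnFC| of BOTH contrasts with opposite signs.

    The ranking universe is each contrast's significant DEGs (a DEG is by
    definition significant); set ``significant_only=False`` to rank over all
    tested genes instead. Returns a sorted gene list (possibly empty).
    """
    if len(deg_age) == 0 or len(deg_treat) == 0:
        raise ValueError("both DEG tables must be non-empty")
    r_age = _rank_by_abs_lnfc(deg_age, significant_only, alpha)
    r_treat = _rank_by_abs_lnfc(deg_treat, significant_only, alpha)
    common = r_age.index.intersection(r_treat.index)
    keep = [
        g
        for g in common
        if r_age[g] <= rank_limit
        and r_treat[g] <= rank_limit
    ]
    lf_age = deg_age.set_index("gene")["lnFC"]
    lf_treat = deg_treat.set_index("gene")["lnFC"]
    out = [g for g in keep if np.sign(lf_age[g]) * np.sign(lf_treat[g]) < 0]
    return sorted(out)


def pairwise_consistency(deg_tables: dict, alpha: float = 0.05) -> pd.DataFrame:
    """Cross-subtype lnFC consistency regressions for one contrast.

    For each unordered pair of subtypes, genes significant in either
    subtype's table (and tested in both) are regressed: lnFC of subtype_b on
    lnFC of subtype_a and vice versa. Returns a long table with both
    directed slopes, shared r2 and slope p-value; pairs with an empty union
    get NaN rows (warned).
    """
    names = list(deg_tables)
    if len(names) < 2:
        raise ValueError("need at least two subtypes")
    rows = []
    for a, b in itertools.combinations(names, 2):
        try:
            genes = union_significant(deg_tables[a], deg_tables[b], alpha=alpha)
        except ValueError:
            logger.warning("subtype pair (%s, %s): empty union", a, b)
            rows.append(
                {
                    "subtype_a": a,
                    "subtype_b": b,
                    "n_union": 0,
                    "slope_b_on_a": np.nan,
                    "slope_a_on_b": np.nan,
                    "r2": np.nan,
                    "p_slope": np.nan,
                }
            )
            continue
        x = deg_tables[a].set_index("gene").loc[genes, "lnFC"].to_numpy(float)
        y = deg_tables[b].set_index("gene").loc[genes, "lnFC"].to_numpy(float)
        if len(genes) >= 3 and np.ptp(x) > 0 and np.ptp(y) > 0:
            f1 = stats.linregress(x, y)
            f2 = stats.linregress(y, x)
            rows.append(
                {
                    "subtype_a": a,
                    "subtype_b": b,
                    "n_union": len(genes),
                    "slope_b_on_a": float(f1.slope),
                    "slope_a_on_b": float(f2.slope),
                    "r2": float(f1.rvalue**2),
                    "p_slope": float(f1.pvalue),
                }
            )
        else:
            rows.append(
                {
                    "subtype_a": a,
                    "subtype_b": b,
                    "n_union": len(genes),
                    "slope_b_on_a": np.nan,
                    "slope_a_on_b": np.nan,
                    "r2": np.nan,
                    "p_slope": np.nan,
                }
            )
    return pd.DataFrame(rows)


def replication_check(
    top_reversed_genes, deg_replicate: pd.DataFrame, deg_age: pd.DataFrame
):
    """Replicate-contrast sign agreement for the selected top reversed genes.

    For each selected gene present in the replicate table, its replicate
    lnFC is paired with the aging lnFC; the summary is the fraction with
    strictly opposite signs (a zero lnFC does not count as reversed).
    Returns ``(per-gene table, agreement fraction)``.
    """
    genes = [g for g in top_reversed_genes if g in set(deg_replicate["gene"])]
    if not genes:
        raise ValueError("replicate table covers none of the selected genes")
    if len(genes) < len(list(top_reversed_genes)):
        logger.warning(
            "%d selected gene(s) absent from replicate table",
            len(list(top_reversed_genes)) - len(genes),
        )
    x = deg_age.set_index("gene").loc[genes, "lnFC"].to_numpy(float)
    y = deg_replicate.set_index("gene").loc[genes, "lnFC"].to_numpy(float)
    opposite = np.sign(x) * np.sign(y) < 0
    table = pd.DataFrame(
        {"gene": genes, "lnFC_age": x, "lnFC_replicate": y, "opposite": opposite}
    )
    return table, float(opposite.mean())
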