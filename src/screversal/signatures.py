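"""Gene-signature module scores and nonparametric group comparison.

A cell's module score for a signature (e.g. the disease-associated
microglia signature) is the mean normalized expression of the signature
genes minus the mean of a pooled control draw: for every signature gene,
``nctrl`` control genes are sampled from the same average-expression bin,
which cancels the dependence of the score on overall expression level.
Group differences in scores are assessed with the Kruskal-Wallis omnibus
test and post hoc pairwise Dunn tests on rank means.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .preprocess import NormMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ScoreVector",
    "GroupComparisonResult",
    "module_score",
    "kruskal_wallis",
    "dunn_posthoc",
    "compare_groups",
]


@dataclass
class ScoreVector:
    """Per-cell signature scores plus the scoring parameters used."""

    scores: np.ndarray
    barcodes: np.ndarray
    signature_name: str
    nbins: int
    nctrl: int
    seed: int

    def to_frame(self, groups=None) -> pd.DataFrame:
        df = pd.DataFrame({"barcode": self.barcodes, "score": self.scores})
        if groups is not None:
            df["group"] = np.asarray(groups)
        return df


@dataclass
class GroupComparisonResult:
    """Kruskal-Wallis omnibus + Dunn pairwise comparison of score groups."""

    H: float
    df: int
    p_omnibus: float
    pairwise: pd.DataFrame  # group_i, group_j, mean_rank_diff, z, p
    group_medians: dict

    def summary(self) -> str:
        lines = [
            f"Kruskal-Wallis: H = {self.H:.4f}, df = {self.df}, p = {self.p_omnibus:.3g}",
            "group medians: "
            + ", ".join(f"{g}: {m:.4f}" for g, m in self.group_medians.items()),
            "post hoc Dunn (unadjusted two-sided p):",
        ]
        for _, r in self.pairwise.iterrows():
            lines.append(
                f"  {r['group_i']} vs {r['group_j']}: z = {r['z']:.4f}, p = {r['p']:.3g}"
            )
        return "\n".join(lines)


def module_score(
    norm: NormMatrix,
    signature,
    nbins: int = 24,
    nctrl: int = 100,
    seed: int = 0,
    name: str = "signature",
) -> ScoreVector:
    """Binned-control module score of a gene signature, per cell.

    Genes are partitioned into ``nbins`` equal-size bins by their average
    normalized expression over all cells (ties broken by gene ID). For each
    signature gene, ``nctrl`` control genes are drawn from its bin without
    replacement (with replacement when the bin is smaller), seeded. The
    score is the mean signature expression minus the mean over the pooled
    control draw. Signature genes absent from the matrix are dropped with a
    warning; if none remain this is an error.
    """
    if nbins < 2:
        raise ValueError("nbins must be >= 2")
    gene_index = {g: i for i, g in enumerate(norm.gene_ids)}
    sig_rows = [gene_index[g] for g in signature if g in gene_index]
    n_missing = len(list(signature)) - len(sig_rows)
    if n_missing:
        logger.warning("signature %r: %d gene(s) absent, dropped", name, n_missing)
    if not sig_rows:
        raise ValueError(f"signature {name!r}: no genes present in the matrix")

    V = norm.values
    dense = V.toarray() if sp.issparse(V) else np.asarray(V, float)
    avg = dense.mean(axis=1)

    # equal-size bins on the rank of average expression, ties by gene ID
    order = np.lexsort((norm.gene_ids.astype(str), avg))
    bin_of = np.empty(len(avg), dtype=int)
    for b, chunk in enumerate(np.array_split(order, nbins)):
        bin_of[chunk] = b

    rng = np.random.default_rng(seed)
    control_rows = []
    for g in sig_rows:
        pool = np.where(bin_of == bin_of[g])[0]
        replace = len(pool) < nctrl
        control_rows.append(rng.choice(pool, size=nctrl, replace=replace))
    control_rows = np.concatenate(control_rows)

    scores = dense[sig_rows, :].mean(axis=0) - dense[control_rows, :].mean(axis=0)
    return ScoreVector(
        scores=scores,
        barcodes=norm.barcodes,
        signature_name=name,
        nbins=nbins,
        nctrl=nctrl,
        seed=seed,
    )


def _check_groups(scores, groups):
    scores = np.asarray(scores, dtype=float)
    groups = np.asarray(groups)
    if len(scores) != len(groups):
        raise ValueError("scores and groups differ in length")
    labels = list(pd.unique(groups))
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    split = [scores[groups == g] for g in labels]
    for g, v in zip(labels, split):
        if len(v) == 0:
            raise ValueError(f"group {g!r} has no observations")
    return scores, groups, labels, split


def kruskal_wallis(scores, groups):
    """Tie-corrected Kruskal-Wallis H test; returns ``(H, df, p)``.

    When every observation is tied the statistic is defined as H = 0 with
    p = 1 (no evidence of any group difference).
    """
    scores, groups, labels, split = _check_groups(scores, groups)
    df = len(labels) - 1
    if np.ptp(scores) == 0:
        return 0.0, df, 1.0
    H, p = stats.kruskal(*split)
    return float(H), df, float(p)


def dunn_posthoc(scores, groups, holm: bool = False) -> pd.DataFrame:
    """Pairwise Dunn z tests on rank means with tie correction.

    ``z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - sum(T)/(12(N-1))) *
    (1/n_i + 1/n_j))`` with ``T = t^3 - t`` per tie group; two-sided normal
    p-values, unadjusted unless ``holm``.
    """
    scores, groups, labels, _ = _check_groups(scores, groups)
    N = len(scores)
    ranks = stats.rankdata(scores)
    _, tie_counts = np.unique(scores, return_counts=True)
    tie_sum = float(np.sum(tie_counts**3 - tie_counts))
    var_term = N * (N + 1) / 12.0 - tie_sum / (12.0 * (N - 1))
    rbar = {g: float(ranks[groups == g].mean()) for g in labels}
    n = {g: int((groups == g).sum()) for g in labels}
    rows = []
    for gi, gj in itertools.combinations(labels, 2):
        diff = rbar[gi] - rbar[gj]
        se = np.sqrt(var_term * (1.0 / n[gi] + 1.0 / n[gj]))
        z = diff / se if se > 0 else 0.0
        p = float(2.0 * stats.norm.sf(abs(z)))
        rows.append(
            {
                "group_i": gi,
                "group_j": gj,
                "mean_rank_diff": diff,
                "z": float(z),
                "p": p,
            }
        )
    table = pd.DataFrame(rows)
    if holm:
        order = np.argsort(table["p"].to_numpy())
        m = len(table)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * table["p"].iloc[idx])
            adj[idx] = min(running, 1.0)
        table["p_holm"] = adj
    return table


def compare_groups(scores, groups) -> GroupComparisonResult:
    """Omnibus Kruskal-Wallis plus post hoc Dunn tests in one result."""
    H, df, p = kruskal_wallis(scores, groups)
    pairwise = dunn_posthoc(scores, groups)
    scores_arr = np.asarray(scores, dtype=float)
    groups_arr = np.asarray(groups)
    medians = {
        g: float(np.median(scores_arr[groups_arr == g])) for g in pd.unique(groups_arr)
    }
    return GroupComparisonResult(
        H=H, df=df, p_omnibus=p, pairwise=pairwise, group_medians=medians
    )
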