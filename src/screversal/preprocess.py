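"""Cell and gene quality control, normalization, and HVG selection.

QC follows the common droplet scRNA-seq workflow: genes detected in fewer
than ``min_cells_per_gene`` cells are dropped from the raw matrix; cells are
then removed when their total UMI count or detected-gene count falls
strictly below the 5th or strictly above the 95th percentile of all cells
(linear-interpolation percentiles), or when their mitochondrial read
fraction exceeds 20%. Default normalization is log1p of counts per 10k
(log_cp10k); a simplified Pearson-residual normalization based on per-gene
negative-binomial regression on log10 library size is available as an
alternative. Highly variable genes are ranked by a variance-stabilizing
score: the variance of counts standardized by a smooth mean-variance trend.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io import CountMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "QCThresholds",
    "NormMatrix",
    "compute_cell_qc",
    "filter_cells",
    "filter_genes",
    "lognormalize",
    "pearson_residual_normalize",
    "select_hvg",
]

MITO_PREFIX = "mt-"


@dataclass(frozen=True)
class QCThresholds:
    """Cell-level QC cutoffs.

    ``low_pct``/``high_pct`` are percentile bounds applied jointly to total
    UMI and detected-gene counts; ``mito_max`` is the maximum tolerated
    mitochondrial read fraction.
    """

    low_pct: float = 5.0
    high_pct: float = 95.0
    mito_max: float = 0.20
    min_cells_per_gene: int = 5

    def __post_init__(self) -> None:
        if not 0 <= self.low_pct < self.high_pct <= 100:
            raise ValueError("need 0 <= low_pct < high_pct <= 100")
        if not 0 < self.mito_max <= 1:
            raise ValueError("mito_max must be in (0, 1]")
        if self.min_cells_per_gene < 1:
            raise ValueError("min_cells_per_gene must be >= 1")


@dataclass
class NormMatrix:
    """Normalized genes x cells expression with a method tag."""

    values: object  # sparse or dense genes x cells
    gene_ids: np.ndarray
    barcodes: np.ndarray
    method: str = "log_cp10k"
    scale_factor: float = 1e4

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        v = self.values
        return v.toarray() if sp.issparse(v) else np.asarray(v)

    def subset_cells(self, cell_mask) -> "NormMatrix":
        cell_mask = np.asarray(cell_mask)
        return NormMatrix(
            values=self.values[:, cell_mask],
            gene_ids=self.gene_ids,
            barcodes=self.barcodes[cell_mask],
            method=self.method,
            scale_factor=self.scale_factor,
        )


def compute_cell_qc(counts: CountMatrix, mito_prefix: str = MITO_PREFIX) -> pd.DataFrame:
    """Per-cell QC statistics: total UMI, detected genes, mito fraction.

    Cells with zero total counts get ``mito_fraction = NaN`` and are flagged
    for unconditional removal via the ``zero_total`` column.
    """
    if counts.n_cells == 0 or counts.n_genes == 0:
        raise ValueError("empty count matrix")
    X = counts.X
    total = np.asarray(X.sum(axis=0)).ravel()
    n_genes = np.asarray((X > 0).sum(axis=0)).ravel()
    is_mito = np.array(
        [str(g).lower().startswith(mito_prefix.lower()) for g in counts.gene_ids]
    )
    mito_total = (
        np.asarray(X[is_mito, :].sum(axis=0)).ravel()
        if is_mito.any()
        else np.zeros(counts.n_cells)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_fraction = np.where(total > 0, mito_total / np.maximum(total, 1), np.nan)
    return pd.DataFrame(
        {
            "barcode": counts.barcodes,
            "total_umi": total.astype(np.int64),
            "n_genes": n_genes.astype(np.int64),
            "mito_fraction": mito_fraction,
            "zero_total": total == 0,
        }
    )


def filter_cells(qc_stats: pd.DataFrame, thresholds: QCThresholds) -> np.ndarray:
    """Boolean retained-cell mask from QC statistics.

    A cell is removed iff its total UMI or detected-gene count is strictly
    outside the [low_pct, high_pct] percentile band (percentiles over all
    cells jointly, linear interpolation), its mito fraction exceeds
    ``mito_max``, or it has zero total counts.
    """
    if len(qc_stats) < 2:
        raise ValueError("need at least 2 cells to compute QC percentiles")
    keep = np.ones(len(qc_stats), dtype=bool)
    for col in ("total_umi", "n_genes"):
        v = qc_stats[col].to_numpy(float)
        lo = np.percentile(v, thresholds.low_pct)
        hi = np.percentile(v, thresholds.high_pct)
        keep &= (v >= lo) & (v <= hi)
    mito = qc_stats["mito_fraction"].to_numpy(float)
    keep &= ~(mito > thresholds.mito_max)  # NaN mito never trips this test
    keep &= ~qc_stats["zero_total"].to_numpy(bool)
    return keep


def filter_genes(counts: CountMatrix, min_cells: int = 5) -> np.ndarray:
    """Boolean mask of genes detected (count > 0) in at least ``min_cells`` cells."""
    if min_cells < 1:
        raise ValueError("min_cells must be >= 1")
    det = np.asarray((counts.X > 0).sum(axis=1)).ravel()
    return det >= min_cells


def lognormalize(counts: CountMatrix, scale_factor: float = 1e4) -> NormMatrix:
    """log1p counts-per-``scale_factor``: ``ln(1 + count * sf / cell_total)``."""
    X = sp.csc_matrix(counts.X, dtype=float)
    totals = np.asarray(X.sum(axis=0)).ravel()
    if (totals == 0).any():
        raise ValueError("zero-total cells present; filter cells first")
    X = X.multiply(scale_factor / totals[None, :]).tocsr()
    X.data = np.log1p(X.data)
    return NormMatrix(
        values=X,
        gene_ids=counts.gene_ids,
        barcodes=counts.barcodes,
        method="log_cp10k",
        scale_factor=scale_factor,
    )


def _nb_theta_mom(y: np.ndarray, mu: np.ndarray) -> float:
    """Method-of-moments NB size estimate; inf means Poisson-like."""
    num = float(np.sum(mu**2))
    den = float(np.sum((y - mu) ** 2 - mu))
    if den <= 0:
        return np.inf
    return max(num / den, 1e-4)


def _poisson_irls(y: np.ndarray, design: np.ndarray, max_iter: int = 50) -> np.ndarray:
    """Poisson GLM (log link) fitted means via IRLS with a small ridge."""
    beta = np.zeros(design.shape[1])
    beta[0] = np.log(max(y.mean(), 1e-8))
    for _ in range(max_iter):
        eta = np.clip(design @ beta, -30, 30)
        mu = np.exp(eta)
        W = mu
        z = eta + (y - mu) / np.maximum(mu, 1e-12)
        XtW = design.T * W
        H = XtW @ design + 1e-8 * np.eye(design.shape[1])
        new = np.linalg.solve(H, XtW @ z)
        if np.max(np.abs(new - beta)) < 1e-10:
            beta = new
            break
        beta = new
    return np.exp(np.clip(design @ beta, -30, 30))


def pearson_residual_normalize(
    counts: CountMatrix, n_bins: int = 20, min_detected: int = 10
) -> NormMatrix:
    """Simplified NB-regression Pearson residuals.

    Per gene, counts are regressed on log10 library size through a Poisson
    GLM with log link; the NB dispersion is a method-of-moments estimate
    smoothed by bin-median pooling across genes of similar mean expression.
    Residuals ``(y - mu)/sqrt(mu + mu^2/theta)`` are clipped to
    ``+/- sqrt(n_cells)``. Genes detected in fewer than ``min_detected``
    cells use the pooled bin dispersion directly (logged).
    """
    X = counts.X.toarray().astype(float)
    n_genes, n_cells = X.shape
    totals = X.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("zero-total cells present; filter cells first")
    design = np.column_stack([np.ones(n_cells), np.log10(totals)])
    mu = np.empty_like(X)
    for g in range(n_genes):
        mu[g] = _poisson_irls(X[g], design)

    theta = np.empty(n_genes)
    detected = (X > 0).sum(axis=1)
    for g in range(n_genes):
        theta[g] = _nb_theta_mom(X[g], mu[g])

    # pool dispersion across genes of similar mean: bin-median smoothing
    mean_expr = mu.mean(axis=1)
    order = np.argsort(mean_expr, kind="stable")
    bins = np.array_split(order, min(n_bins, n_genes))
    theta_smooth = theta.copy()
    for b in bins:
        finite = theta[b][np.isfinite(theta[b])]
        med = np.median(finite) if finite.size else np.inf
        theta_smooth[b] = np.where(np.isfinite(theta[b]), theta[b], med)
        low = detected[b] < min_detected
        if low.any():
            logger.info(
                "%d gene(s) with < %d detected cells use pooled dispersion",
                int(low.sum()),
                min_detected,
            )
            theta_smooth[b[low]] = med
    with np.errstate(divide="ignore", invalid="ignore"):
        var = mu + mu**2 / theta_smooth[:, None]
    resid = (X - mu) / np.sqrt(var)
    clip = np.sqrt(n_cells)
    resid = np.clip(np.nan_to_num(resid), -clip, clip)
    return NormMatrix(
        values=resid,
        gene_ids=counts.gene_ids,
        barcodes=counts.barcodes,
        method="pearson_residual",
        scale_factor=np.nan,
    )


def hvg_scores(counts: CountMatrix, span: float = 0.3) -> pd.DataFrame:
    """Variance-stabilizing HVG scores (standardized variances).

    A lowess trend of log10 variance on log10 mean (span 0.3) predicts each
    gene's expected standard deviation; counts standardized by it (and
    clipped at sqrt(n_cells)) yield the standardized variance used for
    ranking. Zero-variance genes score 0.
    """
    X = counts.X.tocsr().astype(float)
    n_cells = X.shape[1]
    mean = np.asarray(X.mean(axis=1)).ravel()
    sq = X.copy()
    sq.data **= 2
    ex2 = np.asarray(sq.mean(axis=1)).ravel()
    var = (ex2 - mean**2) * n_cells / max(n_cells - 1, 1)
    # cancellation fuzz: a constant gene must score an exact zero variance
    var[np.abs(var) <= 1e-10 * np.maximum(mean**2, 1e-30)] = 0.0
    var = np.maximum(var, 0.0)

    score = np.zeros(X.shape[0])
    variable = (var > 0) & (mean > 0)
    if variable.sum() >= 3:
        lx = np.log10(mean[variable])
        ly = np.log10(var[variable])
        fit = lowess(ly, lx, frac=span, return_sorted=False)
        sd_exp = np.sqrt(10.0**fit)
        clip = np.sqrt(n_cells)
        vidx = np.where(variable)[0]
        dense = X[vidx, :].toarray()
        z = (dense - mean[vidx, None]) / sd_exp[:, None]
        np.clip(z, -clip, clip, out=z)
        score[vidx] = (np.sum(z**2, axis=1) - n_cells * np.mean(z, axis=1) ** 2) / max(
            n_cells - 1, 1
        )
    elif variable.any():
        score[variable] = 1.0
    return pd.DataFrame(
        {"gene": counts.gene_ids, "mean": mean, "variance": var, "score": score}
    )


def select_hvg(counts: CountMatrix, n_hvg: int = 3000, span: float = 0.3) -> list:
    """Top ``n_hvg`` genes by standardized variance, ties broken by gene ID."""
    scores = hvg_scores(counts, span=span)
    if len(scores) < n_hvg:
        logger.warning(
            "requested %d HVGs but only %d genes present; returning all",
            n_hvg,
            len(scores),
        )
        n_hvg = len(scores)
    ranked = scores.sort_values(
        ["score", "gene"], ascending=[False, True], kind="stable"
    )
    return ranked["gene"].head(n_hvg).tolist()
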