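"""Two-part hurdle differential expression for sparse log-normalized data.

Single-cell expression is zero-inflated: whether a gene is detected in a
cell and how high it is when detected carry separate information. The
hurdle model combines a logistic regression for detection (y > 0) with a
Gaussian regression for the positive log-normalized values; a contrast is
tested by a likelihood-ratio chi-square summed over both parts. Fold
changes are reported as natural-log fold change (lnFC) computed from
back-transformed mean normalized expression with a pseudocount of 1, and
p-values are Benjamini–Hochberg adjusted.

The model is exposed statsmodels-style: build a :class:`HurdleModel` from a
response vector and design matrix, call :meth:`~HurdleModel.fit`, and read
estimates off the returned :class:`HurdleResults`. ``run_de_contrast``
wraps this per gene for a whole contrast; for the default design
(intercept + group, no covariates) it uses an exact closed-form fast path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import NormMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ContrastSpec",
    "HurdleModel",
    "HurdleResults",
    "compute_lnfc",
    "fit_hurdle",
    "hurdle_lrt",
    "bh_adjust",
    "run_de_contrast",
]

DEG_TABLE_SCHEMA = {
    "gene": str,
    "lnFC": float,
    "p_value": float,
    "q_value": float,
    "pct_A": float,
    "pct_B": float,
    "chi2": float,
    "df": float,
}


@dataclass(frozen=True)
class ContrastSpec:
    """One differential-expression contrast (group_A relative to group_B)."""

    cell_type: str | None
    group_A: str
    group_B: str
    covariates: tuple = ()  # recognised: "cdr" (cellular detection rate)
    min_detection_fraction: float = 0.1
    min_abs_lnfc_prefilter: float = 0.0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.group_A == self.group_B:
            raise ValueError("group_A and group_B must differ")
        if not 0 <= self.min_detection_fraction <= 1:
            raise ValueError("min_detection_fraction must be in [0, 1]")


def _logistic_ll(d: np.ndarray, eta: np.ndarray) -> float:
    return float(d @ eta - np.logaddexp(0.0, eta).sum())


def _fit_logistic(d: np.ndarray, X: np.ndarray, ridge: float = 1e-8):
    """Logistic MLE by Newton iteration with a small ridge jitter.

    Returns (beta, unpenalized log-likelihood, separated_flag). Under
    complete separation the coefficients diverge; the fit is then flagged
    and refit under a stronger penalty.
    """
    beta = np.zeros(X.shape[1])
    separated = False
    for it in range(100):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        W = p * (1 - p)
        grad = X.T @ (d - p) - ridge * beta
        H = (X.T * W) @ X + ridge * np.eye(X.shape[1])
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            separated = True
            break
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
        if np.max(np.abs(beta)) > 25:
            separated = True
            break
    if separated:
        beta = np.zeros(X.shape[1])
        for _ in range(200):  # penalized fit: ridge strong enough to converge
            eta = X @ beta
            p = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
            W = p * (1 - p)
            grad = X.T @ (d - p) - 1e-3 * beta
            H = (X.T * W) @ X + 1e-3 * np.eye(X.shape[1])
            step = np.linalg.solve(H, grad)
            beta = beta + step
            if np.max(np.abs(step)) < 1e-10:
                break
    return beta, _logistic_ll(d, X @ beta), separated


@dataclass
class HurdleResults:
    """Fitted two-part hurdle model.

    ``llf`` is the total log-likelihood (detection + continuous part);
    ``df_model`` counts the columns of the design identifiable in each part.
    """

    model: "HurdleModel"
    detection_params: np.ndarray
    continuous_params: np.ndarray | None
    sigma2: float | None
    llf_detection: float
    llf_continuous: float
    detection_testable: bool
    continuous_testable: bool
    separated: bool = False
    flags: list = field(default_factory=list)

    @property
    def llf(self) -> float:
        return self.llf_detection + self.llf_continuous

    def summary(self) -> str:
        lines = [
            "Hurdle model (logistic detection + Gaussian continuous)",
            f"  n cells:            {len(self.model.endog)}",
            f"  n detected (y>0):   {int((self.model.endog > 0).sum())}",
            f"  detection params:   {np.array2string(self.detection_params, precision=4)}",
        ]
        if self.continuous_params is not None:
            lines.append(
                f"  continuous params:  {np.array2string(self.continuous_params, precision=4)}"
            )
            lines.append(f"  sigma^2 (ML):       {self.sigma2:.6g}")
        else:
            lines.append("  continuous part:    untestable (<3 detected cells)")
        lines.append(f"  log-likelihood:     {self.llf:.6f}")
        if self.flags:
            lines.append(f"  flags:              {'; '.join(self.flags)}")
        return "\n".join(lines)


class HurdleModel:
    """Two-part hurdle model of one gene's normalized expression.

    Parameters
    ----------
    endog : per-cell normalized expression values (zeros = not detected).
    exog : design matrix, first column conventionally the intercept.
    """

    def __init__(self, endog, exog):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.atleast_2d(np.asarray(exog, dtype=float))
        if self.exog.shape[0] != len(self.endog):
            raise ValueError("endog and exog have different numbers of cells")

    def fit(self) -> HurdleResults:
        y, X = self.endog, self.exog
        d = (y > 0).astype(float)
        flags = []

        det_testable = 0 < d.sum() < len(d)
        if det_testable:
            beta_d, ll_d, separated = _fit_logistic(d, X)
            if separated:
                flags.append("detection part: complete separation, penalized fit")
        else:
            # saturated detection part: likelihood constant, coefficient at
            # the boundary; contributes nothing to contrasts
            beta_d = np.zeros(X.shape[1])
            ll_d = 0.0
            separated = False
            flags.append("detection part saturated (all or none detected)")

        pos = y > 0
        n_pos = int(pos.sum())
        if n_pos >= 3:
            Xp, yp = X[pos], y[pos]
            beta_c, _, rank, _ = np.linalg.lstsq(Xp, yp, rcond=None)
            resid = yp - Xp @ beta_c
            sigma2 = float(resid @ resid) / n_pos  # Gaussian ML variance
            sigma2 = max(sigma2, 1e-30)
            ll_c = -0.5 * n_pos * (np.log(2 * np.pi * sigma2) + 1.0)
            cont_testable = rank == X.shape[1]
            if not cont_testable:
                flags.append("continuous design rank-deficient on detected cells")
        else:
            beta_c, sigma2, ll_c = None, None, 0.0
            cont_testable = False
            flags.append("continuous part untestable (<3 detected cells)")

        return HurdleResults(
            model=self,
            detection_params=beta_d,
            continuous_params=beta_c,
            sigma2=sigma2,
            llf_detection=ll_d,
            llf_continuous=ll_c,
            detection_testable=det_testable,
            continuous_testable=cont_testable,
            separated=separated,
            flags=flags,
        )


def fit_hurdle(y, design) -> HurdleResults:
    """Functional wrapper: fit the two-part hurdle model of ``y`` on ``design``."""
    return HurdleModel(y, design).fit()


def hurdle_lrt(y, group_indicator, covariates=None):
    """Likelihood-ratio test of a group term in the hurdle model.

    Full model: intercept + group + covariates; reduced: intercept +
    covariates. Returns ``(chi2, df, p_value)`` with df the number of group
    coefficients identifiable across the two parts (2 when both parts are
    testable, 1 when only one is); a gene untestable in both parts returns
    ``(nan, 0, nan)``.
    """
    y = np.asarray(y, dtype=float)
    a = np.asarray(group_indicator, dtype=float)
    n = len(y)
    if covariates is None:
        cov = np.empty((n, 0))
    else:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
    ones = np.ones((n, 1))
    X_full = np.column_stack([ones, a[:, None], cov])
    X_red = np.column_stack([ones, cov])

    full = HurdleModel(y, X_full).fit()
    red = HurdleModel(y, X_red).fit()

    d = y > 0
    det_ok = full.detection_testable and red.detection_testable
    cont_ok = (
        full.continuous_testable
        and red.continuous_testable
        and d[a > 0.5].any()
        and d[a <= 0.5].any()
    )
    chi2 = 0.0
    df = 0
    if det_ok:
        chi2 += max(2.0 * (full.llf_detection - red.llf_detection), 0.0)
        df += 1
    if cont_ok:
        chi2 += max(2.0 * (full.llf_continuous - red.llf_continuous), 0.0)
        df += 1
    if df == 0:
        return np.nan, 0, np.nan
    p = float(stats.chi2.sf(chi2, df))
    return float(chi2), df, p


def _grouped_lrt_closed_form(Y: np.ndarray, in_A: np.ndarray):
    """Vectorized hurdle LRT for the intercept + group design.

    With only an intercept and a group indicator both parts have closed-form
    MLEs: group-wise detection rates (binomial likelihood) and group-wise
    Gaussian means with pooled ML variance. Operates on a dense genes x
    cells value matrix; returns (chi2, df, p) arrays.
    """
    D = Y > 0
    nA, nB = int(in_A.sum()), int((~in_A).sum())
    kA = D[:, in_A].sum(axis=1).astype(float)
    kB = D[:, ~in_A].sum(axis=1).astype(float)
    k = kA + kB
    n = nA + nB

    def _binom_ll(k_, n_):
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = np.where(k_ > 0, k_ * np.log(k_ / n_), 0.0)
            t2 = np.where(n_ - k_ > 0, (n_ - k_) * np.log(1 - k_ / n_), 0.0)
        return t1 + t2

    ll_det_full = _binom_ll(kA, nA) + _binom_ll(kB, nB)
    ll_det_red = _binom_ll(k, n)
    chi2_det = np.maximum(2.0 * (ll_det_full - ll_det_red), 0.0)
    det_ok = (k > 0) & (k < n)

    YA = np.where(D, Y, 0.0)[:, in_A]
    YB = np.where(D, Y, 0.0)[:, ~in_A]
    SA, SB = YA.sum(axis=1), YB.sum(axis=1)
    SSA, SSB = (YA**2).sum(axis=1), (YB**2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rss_full = (SSA - SA**2 / np.maximum(kA, 1)) + (SSB - SB**2 / np.maximum(kB, 1))
        rss_red = (SSA + SSB) - (SA + SB) ** 2 / np.maximum(k, 1)
    rss_full = np.maximum(rss_full, 1e-30)
    rss_red = np.maximum(rss_red, 1e-30)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2_cont = np.maximum(k * np.log(rss_red / rss_full), 0.0)
    cont_ok = (kA >= 1) & (kB >= 1) & (k >= 3)

    chi2 = np.where(det_ok, chi2_det, 0.0) + np.where(cont_ok, chi2_cont, 0.0)
    df = det_ok.astype(int) + cont_ok.astype(int)
    p = np.full(len(chi2), np.nan)
    testable = df > 0
    p[testable] = stats.chi2.sf(chi2[testable], df[testable])
    chi2 = np.where(testable, chi2, np.nan)
    return chi2, df, p


def compute_lnfc(norm: NormMatrix, cells_A, cells_B) -> np.ndarray:
    """Natural-log fold change of A relative to B (Seurat v3 convention).

    ``lnFC = ln(mean_A(e^y - 1) + 1) - ln(mean_B(e^y - 1) + 1)`` with y the
    log-normalized expression; the pseudocount keeps zeros finite.
    """
    cells_A = np.asarray(cells_A)
    cells_B = np.asarray(cells_B)
    if cells_A.dtype == bool:
        cells_A = np.where(cells_A)[0]
    if cells_B.dtype == bool:
        cells_B = np.where(cells_B)[0]
    if len(cells_A) == 0 or len(cells_B) == 0:
        raise ValueError("both groups must be non-empty")
    V = norm.values
    if sp.issparse(V):
        VA = V[:, cells_A].copy()
        VA.data = np.expm1(VA.data)
        VB = V[:, cells_B].copy()
        VB.data = np.expm1(VB.data)
        mA = np.asarray(VA.sum(axis=1)).ravel() / len(cells_A)
        mB = np.asarray(VB.sum(axis=1)).ravel() / len(cells_B)
    else:
        mA = np.expm1(V[:, cells_A]).mean(axis=1)
        mB = np.expm1(V[:, cells_B]).mean(axis=1)
    return np.log(mA + 1.0) - np.log(mB + 1.0)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values with monotonicity enforcement.

    NaN entries (untestable genes) pass through unadjusted and do not count
    toward the number of tests m.
    """
    p = np.asarray(p_values, dtype=float)
    q = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        if ((p[mask] < 0) | (p[mask] > 1)).any():
            raise ValueError("p-values must lie in [0, 1]")
        _, q_adj, _, _ = multipletests(p[mask], method="fdr_bh")
        q[mask] = q_adj
    return q


def run_de_contrast(norm: NormMatrix, cell_meta: pd.DataFrame, spec: ContrastSpec) -> pd.DataFrame:
    """Differential expression for one contrast; returns the DEG table.

    Genes are prefiltered to a detection fraction of at least
    ``spec.min_detection_fraction`` in one of the groups (and optionally a
    minimum |lnFC|); each remaining gene is tested by the hurdle LRT, with
    the centered cellular detection rate as covariate when requested;
    q-values are BH-adjusted over tested genes. Sorted by q, then |lnFC|
    descending, then gene ID.
    """
    meta = cell_meta.reset_index(drop=True)
    in_type = (
        np.ones(len(meta), dtype=bool)
        if spec.cell_type is None
        else (meta["cell_type"] == spec.cell_type).to_numpy()
    )
    gA = in_type & (meta["group"] == spec.group_A).to_numpy()
    gB = in_type & (meta["group"] == spec.group_B).to_numpy()
    if gA.sum() == 0 or gB.sum() == 0:
        raise ValueError(
            f"contrast {spec.group_A} vs {spec.group_B} in cell type "
            f"{spec.cell_type!r}: empty group"
        )
    sel = gA | gB
    V = norm.values[:, np.where(sel)[0]]
    Y = V.toarray() if sp.issparse(V) else np.asarray(V, dtype=float)
    in_A = gA[sel]

    D = Y > 0
    pct_A = D[:, in_A].mean(axis=1)
    pct_B = D[:, ~in_A].mean(axis=1)
    sub = NormMatrix(
        values=Y,
        gene_ids=norm.gene_ids,
        barcodes=norm.barcodes[sel],
        method=norm.method,
        scale_factor=norm.scale_factor,
    )
    lnfc = compute_lnfc(sub, in_A, ~in_A)

    tested = np.maximum(pct_A, pct_B) >= spec.min_detection_fraction
    if spec.min_abs_lnfc_prefilter > 0:
        tested &= np.abs(lnfc) >= spec.min_abs_lnfc_prefilter
    if not tested.any():
        logger.warning(
            "contrast %s vs %s: no genes pass the prefilters, empty table",
            spec.group_A,
            spec.group_B,
        )
        return pd.DataFrame(columns=list(DEG_TABLE_SCHEMA)).astype(DEG_TABLE_SCHEMA)

    use_cdr = "cdr" in spec.covariates
    if use_cdr:
        cdr = D.mean(axis=0)
        cdr = cdr - cdr.mean()
        chi2 = np.full(Y.shape[0], np.nan)
        df = np.zeros(Y.shape[0], dtype=int)
        p = np.full(Y.shape[0], np.nan)
        for g in np.where(tested)[0]:
            chi2[g], df[g], p[g] = hurdle_lrt(Y[g], in_A.astype(float), cdr)
    else:
        chi2_all, df_all, p_all = _grouped_lrt_closed_form(Y[tested], in_A)
        chi2 = np.full(Y.shape[0], np.nan)
        df = np.zeros(Y.shape[0], dtype=int)
        p = np.full(Y.shape[0], np.nan)
        chi2[tested], df[tested], p[tested] = chi2_all, df_all, p_all

    n_untestable = int(tested.sum() - np.isfinite(p[tested]).sum())
    if n_untestable:
        logger.info(
            "%d gene(s) untestable in both hurdle parts (NA p, excluded from FDR)",
            n_untestable,
        )
    q = bh_adjust(p)
    table = pd.DataFrame(
        {
            "gene": norm.gene_ids,
            "lnFC": lnfc,
            "p_value": p,
            "q_value": q,
            "pct_A": pct_A,
            "pct_B": pct_B,
            "chi2": chi2,
            "df": df.astype(float),
        }
    )[tested]
    table = table.assign(_abs=table["lnFC"].abs()).sort_values(
        ["q_value", "_abs", "gene"],
        ascending=[True, False, True],
        na_position="last",
        kind="stable",
    )
    return table.drop(columns="_abs").reset_index(drop=True)
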