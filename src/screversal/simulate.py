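"""Synthetic multi-group, multi-cell-type single-cell UMI count generator.

The generator emulates the design of a brain-aging treatment study: three
experimental groups (young, aged, drug-treated aged; optionally a vehicle-
treated aged group), a small number of animals per group, and several cell
types. Per gene and cell type it plants

* an aging effect ``delta`` (natural-log fold change, aged vs young) for a
  fraction ``f_de`` of genes,
* a treatment effect ``tau`` (treated vs aged) that for a fraction ``p_rev``
  of aging-DE genes is an exact negative multiple of the aging effect,
  ``tau = -rho * delta`` — the planted reversal structure,
* cell-type marker genes, mitochondrial genes (IDs prefixed ``mt-``), a
  fraction of QC-failing high-mitochondrial cells, and a disease-associated
  gene signature upregulated with age in one designated cell type and
  partially reversed by treatment.

Counts are negative-binomial with log-normal library sizes and log-normal
per-gene dispersions; relative expression is renormalized within each cell
so that library size is independent of group (composition effects are
isolated from depth effects). Mouse-to-mouse variation is a log-normal
per-sample, per-gene jitter shared by all cells of that sample.

Everything is driven by one integer seed: the same configuration and seed
reproduce the count matrix bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .io import CountMatrix

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "InvalidConfigError",
    "simulate_dataset",
    "planted_effect_table",
    "expected_reversal",
]


class InvalidConfigError(ValueError):
    """Simulation configuration violates an invariant."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Effect sizes are on the natural-log scale throughout. ``rho`` may be a
    single float (shared by all cell types) or a sequence with one reversal
    coefficient per cell type, which allows a dataset to carry both a
    reversed cell type and an untreated-control-like type with ``rho = 0``.
    """

    n_genes: int = 2000
    n_cell_types: int = 2
    cells_per_sample_per_type: int = 80
    samples_per_group: int = 3  # three animals per experimental group
    groups: tuple = ("young", "aged", "treated")
    f_de: float = 0.10
    de_effect_mean: float = 0.6
    de_effect_sd: float = 0.2
    rho: float | tuple = 0.8
    p_rev: float = 0.9
    f_treat_only: float = 0.0
    baseline_meanlog: float = 1.0
    baseline_sdlog: float = 1.0
    theta_meanlog: float = 1.0
    theta_sdlog: float = 0.5
    libsize_meanlog: float = 8.0
    libsize_sdlog: float = 0.3
    marker_genes_per_type: int = 20
    marker_boost_ln: float = float(np.log(5.0))
    n_mito_genes: int = 10
    mito_boost_ln: float = float(np.log(10.0))
    f_high_mito_cells: float = 0.02
    high_mito_target: float = 0.30
    signature_size: int = 50
    signature_shift_ln: float = 0.5
    signature_cell_type: int = 0
    sample_noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_cell_types < 1:
            raise InvalidConfigError("need at least one gene and one cell type")
        if self.cells_per_sample_per_type < 1 or self.samples_per_group < 1:
            raise InvalidConfigError("need at least one cell per sample and one sample")
        required = {"young", "aged", "treated"}
        if not required.issubset(self.groups):
            raise InvalidConfigError(
                f"groups must contain {sorted(required)} for reversal experiments"
            )
        for name in ("f_de", "p_rev", "f_treat_only", "f_high_mito_cells"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidConfigError(f"{name} = {v} outside [0, 1]")
        for r in self.rho_per_type():
            if not 0.0 <= r <= 1.5:
                raise InvalidConfigError(f"rho = {r} outside [0, 1.5]")
        if not 0 <= self.signature_cell_type < self.n_cell_types:
            raise InvalidConfigError("signature_cell_type out of range")
        n_special = (
            self.n_mito_genes
            + self.marker_genes_per_type * self.n_cell_types
            + self.signature_size
        )
        if n_special >= self.n_genes:
            raise InvalidConfigError(
                f"{n_special} special genes (mito+marker+signature) leave no "
                f"room among {self.n_genes} genes"
            )

    def rho_per_type(self) -> np.ndarray:
        if np.isscalar(self.rho):
            return np.full(self.n_cell_types, float(self.rho))
        rho = np.asarray(self.rho, dtype=float)
        if rho.shape != (self.n_cell_types,):
            raise InvalidConfigError(
                f"rho must be scalar or length {self.n_cell_types}"
            )
        return rho


@dataclass
class SimulationTruth:
    """Per-gene, per-cell-type ground truth of the generator.

    ``delta[g, k]`` is the planted aging lnFC of gene g in cell type k;
    ``tau[g, k]`` the treatment lnFC relative to aged. For reversed genes
    ``tau = -rho * delta`` exactly; genes without aging or treatment-only
    effects have ``delta = tau = 0``.
    """

    config: SimulationConfig
    gene_ids: np.ndarray
    cell_types: list
    m: np.ndarray          # baseline log mean, (n_genes,)
    theta: np.ndarray      # NB size, (n_genes,)
    delta: np.ndarray      # (n_genes, n_cell_types)
    tau: np.ndarray        # (n_genes, n_cell_types)
    is_marker: np.ndarray  # (n_genes, n_cell_types) bool
    is_mito: np.ndarray    # (n_genes,) bool
    is_signature: np.ndarray  # (n_genes,) bool
    is_reversed: np.ndarray   # (n_genes, n_cell_types) bool

    def cell_type_index(self, cell_type) -> int:
        if isinstance(cell_type, (int, np.integer)):
            if not 0 <= cell_type < len(self.cell_types):
                raise KeyError(f"unknown cell type index {cell_type}")
            return int(cell_type)
        try:
            return self.cell_types.index(cell_type)
        except ValueError:
            raise KeyError(f"unknown cell type {cell_type!r}") from None

    def to_frame(self) -> pd.DataFrame:
        """Long-format truth table (one row per gene x cell type)."""
        rows = []
        for k, ct in enumerate(self.cell_types):
            rows.append(
                pd.DataFrame(
                    {
                        "gene": self.gene_ids,
                        "cell_type": ct,
                        "m": self.m,
                        "theta": self.theta,
                        "delta": self.delta[:, k],
                        "tau": self.tau[:, k],
                        "is_marker": self.is_marker[:, k],
                        "is_mito": self.is_mito,
                        "is_signature": self.is_signature,
                        "is_reversed": self.is_reversed[:, k],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def _truncated_normal(rng, mean, sd, size):
    """|effect| magnitudes: Normal(mean, sd) truncated at zero."""
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(
        a, np.inf, loc=mean, scale=sd, size=size, random_state=rng
    )


def _gene_roles(config: SimulationConfig):
    """Deterministic partition of gene indices into mito/marker/signature."""
    n = config.n_genes
    idx = 0
    mito = np.arange(idx, idx + config.n_mito_genes)
    idx += config.n_mito_genes
    markers = []
    for _ in range(config.n_cell_types):
        markers.append(np.arange(idx, idx + config.marker_genes_per_type))
        idx += config.marker_genes_per_type
    signature = np.arange(idx, idx + config.signature_size)
    idx += config.signature_size
    free = np.arange(idx, n)
    return mito, markers, signature, free


def _draw_effects(config: SimulationConfig, rng) -> tuple:
    """Draw (delta, tau, is_reversed) — the stochastic effect structure."""
    n, K = config.n_genes, config.n_cell_types
    mito, markers, signature, free = _gene_roles(config)
    rho = config.rho_per_type()
    delta = np.zeros((n, K))
    tau = np.zeros((n, K))
    is_reversed = np.zeros((n, K), dtype=bool)

    for k in range(K):
        n_de = int(round(config.f_de * len(free)))
        de_genes = rng.choice(free, size=n_de, replace=False) if n_de else np.array([], int)
        signs = rng.choice([-1.0, 1.0], size=n_de)
        mags = _truncated_normal(rng, config.de_effect_mean, config.de_effect_sd, n_de)
        delta[de_genes, k] = signs * mags
        rev = rng.random(n_de) < config.p_rev
        rev_genes = de_genes[rev]
        tau[rev_genes, k] = -rho[k] * delta[rev_genes, k]
        is_reversed[rev_genes, k] = rho[k] > 0

        if config.f_treat_only > 0:
            pool = np.setdiff1d(free, de_genes, assume_unique=False)
            n_to = int(round(config.f_treat_only * len(free)))
            to_genes = rng.choice(pool, size=min(n_to, len(pool)), replace=False)
            tau[to_genes, k] = rng.choice([-1.0, 1.0], size=len(to_genes)) * (
                _truncated_normal(
                    rng, config.de_effect_mean, config.de_effect_sd, len(to_genes)
                )
            )

    # planted disease-associated signature: up with age in one cell type,
    # reversed by treatment in proportion to rho
    ks = config.signature_cell_type
    if config.signature_size and config.signature_shift_ln != 0.0:
        delta[signature, ks] = config.signature_shift_ln
        tau[signature, ks] = -rho[ks] * config.signature_shift_ln
        is_reversed[signature, ks] = rho[ks] > 0
    return delta, tau, is_reversed


def _make_truth(config: SimulationConfig, rng) -> SimulationTruth:
    n, K = config.n_genes, config.n_cell_types
    mito, markers, signature, _ = _gene_roles(config)

    m = rng.normal(config.baseline_meanlog, config.baseline_sdlog, size=n)
    m[mito] += config.mito_boost_ln  # mitochondrial transcripts are abundant
    theta = rng.lognormal(config.theta_meanlog, config.theta_sdlog, size=n)

    is_mito = np.zeros(n, dtype=bool)
    is_mito[mito] = True
    is_marker = np.zeros((n, K), dtype=bool)
    for k in range(K):
        is_marker[markers[k], k] = True
    is_signature = np.zeros(n, dtype=bool)
    is_signature[signature] = True

    delta, tau, is_reversed = _draw_effects(config, rng)

    gene_ids = np.array(
        [f"mt-g{i:05d}" if is_mito[i] else f"g{i:05d}" for i in range(n)],
        dtype=object,
    )
    cell_types = [f"type{k}" for k in range(K)]
    return SimulationTruth(
        config=config,
        gene_ids=gene_ids,
        cell_types=cell_types,
        m=m,
        theta=theta,
        delta=delta,
        tau=tau,
        is_marker=is_marker,
        is_mito=is_mito,
        is_signature=is_signature,
        is_reversed=is_reversed,
    )


_GROUP_EFFECT = {
    "young": (0.0, 0.0),  # coefficients of (delta, tau)
    "aged": (1.0, 0.0),
    "treated": (1.0, 1.0),
    "vehicle": (1.0, 0.0),
}


def simulate_dataset(config: SimulationConfig):
    """Generate a (CountMatrix, cell metadata, SimulationTruth) triple.

    Counts follow ``NB(mean = L_c * q_gc, size = theta_g)`` where ``q_gc``
    is the within-cell-renormalized relative expression and ``L_c`` the
    log-normal library size. Cell metadata records barcode, sample, group,
    true cell type and the planted high-mito QC flag.
    """
    unknown = set(config.groups) - set(_GROUP_EFFECT)
    if unknown:
        raise InvalidConfigError(f"unknown group label(s): {sorted(unknown)}")
    rng = np.random.default_rng(config.seed)
    truth = _make_truth(config, rng)
    n, K = config.n_genes, config.n_cell_types

    base_logw = truth.m.copy()
    marker_term = config.marker_boost_ln * truth.is_marker.astype(float)

    blocks = []
    meta_rows = []
    cell_idx = 0
    for group in config.groups:
        cd, ct_coef = _GROUP_EFFECT[group]
        for s in range(config.samples_per_group):
            sample_id = f"{group}_m{s + 1}"
            jitter = rng.normal(0.0, config.sample_noise_sd, size=n)
            for k in range(K):
                ncells = config.cells_per_sample_per_type
                logw = (
                    base_logw
                    + marker_term[:, k]
                    + cd * truth.delta[:, k]
                    + ct_coef * truth.tau[:, k]
                    + jitter
                )
                w = np.exp(logw)
                high_mito = rng.random(ncells) < config.f_high_mito_cells
                libsize = rng.lognormal(
                    config.libsize_meanlog, config.libsize_sdlog, size=ncells
                )
                counts = np.empty((n, ncells), dtype=np.int64)
                for flag in (False, True):
                    cols = np.where(high_mito == flag)[0]
                    if cols.size == 0:
                        continue
                    wf = w.copy()
                    if flag:
                        # rescale mito mass so its expected share hits target
                        t = config.high_mito_target
                        mito_mass = wf[truth.is_mito].sum()
                        other = wf.sum() - mito_mass
                        if mito_mass > 0:
                            wf[truth.is_mito] *= (t / (1.0 - t)) * other / mito_mass
                    q = wf / wf.sum()
                    mean = q[:, None] * libsize[None, cols]
                    lam = rng.gamma(
                        shape=truth.theta[:, None], scale=mean / truth.theta[:, None]
                    )
                    counts[:, cols] = rng.poisson(lam)
                blocks.append(sp.csr_matrix(counts))
                for j in range(ncells):
                    meta_rows.append(
                        (
                            f"c{cell_idx + j:06d}",
                            sample_id,
                            group,
                            truth.cell_types[k],
                            bool(high_mito[j]),
                        )
                    )
                cell_idx += ncells

    X = sp.hstack(blocks, format="csr")
    meta = pd.DataFrame(
        meta_rows, columns=["barcode", "sample", "group", "cell_type", "is_high_mito"]
    )
    matrix = CountMatrix(
        X=X, gene_ids=truth.gene_ids, barcodes=meta["barcode"].to_numpy(object)
    )
    return matrix, meta, truth


def planted_effect_table(truth: SimulationTruth, cell_type) -> pd.DataFrame:
    """Ground-truth (gene, delta, tau) table for one cell type.

    This is the oracle against which estimated DEG tables are judged.
    """
    k = truth.cell_type_index(cell_type)
    return pd.DataFrame(
        {"gene": truth.gene_ids, "delta": truth.delta[:, k], "tau": truth.tau[:, k]}
    )


def _truth_level_stats(delta: np.ndarray, tau: np.ndarray):
    """Slope of tau on delta and sign-discordance proportion over the genes
    carrying any planted effect. A zero effect carries no direction and is
    never counted as reversed."""
    mask = (delta != 0) | (tau != 0)
    if not mask.any():
        raise ValueError("no genes with planted effects: reversal statistic undefined")
    d, t = delta[mask], tau[mask]
    prop = float(np.mean(np.sign(d) * np.sign(t) < 0))
    dc = d - d.mean()
    sxx = float(dc @ dc)
    slope = float(dc @ (t - t.mean()) / sxx) if sxx > 0 else np.nan
    return slope, prop


def expected_reversal(truth: SimulationTruth, cell_type, n_mc: int = 0, seed=None):
    """Truth-level oracle for the reversal statistics of one cell type.

    Returns ``(expected_slope, expected_prop_reversed)`` computed from the
    planted effects alone (no counts). With ``n_mc > 0`` the effect structure
    is redrawn ``n_mc`` times from the generating configuration (Monte Carlo
    over generator randomness) and the statistics averaged, which is the
    appropriate oracle when the planted effects themselves are stochastic.
    """
    k = truth.cell_type_index(cell_type)
    if n_mc <= 0:
        return _truth_level_stats(truth.delta[:, k], truth.tau[:, k])
    rng = np.random.default_rng(seed)
    slopes, props = [], []
    for _ in range(n_mc):
        delta, tau, _ = _draw_effects(truth.config, rng)
        s, p = _truth_level_stats(delta[:, k], tau[:, k])
        slopes.append(s)
        props.append(p)
    return float(np.nanmean(slopes)), float(np.mean(props))
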