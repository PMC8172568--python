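import numpy as np
import pandas as pd
import pytest

from screversal import (
    ContrastSpec,
    SimulationConfig,
    filter_genes,
    lognormalize,
    run_de_contrast,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def small_dataset():
    """A small two-cell-type dataset with planted reversal in type0 only."""
    cfg = SimulationConfig(
        n_genes=600,
        n_cell_types=2,
        cells_per_sample_per_type=50,
        samples_per_group=3,
        f_de=0.12,
        rho=(0.8, 0.0),
        p_rev=0.9,
        signature_size=40,
        seed=7,
    )
    counts, meta, truth = simulate_dataset(cfg)
    return counts, meta, truth


@pytest.fixture(scope="session")
def small_norm(small_dataset):
    counts, meta, truth = small_dataset
    counts = counts.subset(gene_mask=filter_genes(counts, 5))
    return lognormalize(counts), meta, truth


@pytest.fixture(scope="session")
def deg_tables(small_norm):
    """Aging and treatment DEG tables for both cell types of the fixture."""
    norm, meta, truth = small_norm
    out = {}
    for ct in ("type0", "type1"):
        out[ct] = {
            "aging": run_de_contrast(
                norm, meta, ContrastSpec(cell_type=ct, group_A="aged", group_B="young")
            ),
            "treatment": run_de_contrast(
                norm, meta, ContrastSpec(cell_type=ct, group_A="treated", group_B="aged")
            ),
        }
    return out


def make_deg_table(genes, lnfc, q=None, p=None):
    """Hand-built DEG table for unit tests of the reversal statistics."""
    genes = list(genes)
    n = len(genes)
    lnfc = np.asarray(lnfc, dtype=float)
    q = np.full(n, 0.01) if q is None else np.asarray(q, dtype=float)
    p = q / 2 if p is None else np.asarray(p, dtype=float)
    return pd.DataFrame(
        {
            "gene": genes,
            "lnFC": lnfc,
            "p_value": p,
            "q_value": q,
            "pct_A": 0.5,
            "pct_B": 0.5,
            "chi2": 1.0,
            "df": 2.0,
        }
    )
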