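import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from scsubpop.containers import CountMatrix, NormalizedMatrix
from scsubpop.synth import SimConfig, simulate_experiment


def make_count_matrix(dense, symbols=None, samples=None, **gene_cols):
    """CountMatrix from a dense genes x cells array."""
    dense = np.asarray(dense)
    n_genes, n_cells = dense.shape
    genes = pd.DataFrame(
        {"symbol": symbols if symbols is not None else [f"GENE{i}" for i in range(n_genes)]},
        index=pd.Index([f"G{i}" for i in range(n_genes)], name="gene_id"),
    )
    for k, v in gene_cols.items():
        genes[k] = v
    cells = pd.DataFrame(index=pd.Index([f"C{i}" for i in range(n_cells)], name="cell_id"))
    if samples is not None:
        cells["sample"] = samples
    return CountMatrix(sp.csr_matrix(dense), genes, cells)


def make_norm(dense):
    """NormalizedMatrix directly from a dense genes x cells array."""
    dense = np.asarray(dense, float)
    return NormalizedMatrix(
        sp.csr_matrix(dense),
        pd.Index([f"G{i}" for i in range(dense.shape[0])], name="gene_id"),
        pd.Index([f"C{i}" for i in range(dense.shape[1])], name="cell_id"),
    )


@pytest.fixture(scope="session")
def small_experiment():
    """Two samples (one donor pair, one medium), 300 cells each, 400 genes."""
    cfg = SimConfig(
        n_donors=2,
        n_media=1,
        cells_per_sample=300,
        n_genes=400,
        n_snps=60,
        discriminating_snps=True,
        seed=7,
    )
    matrix, truth, genotypes, alleles = simulate_experiment(cfg)
    return cfg, matrix, truth, genotypes, alleles
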