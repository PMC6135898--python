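"""Core in-memory containers and 10x-style triplet I/O.

The pipeline substrate is a sparse gene x cell UMI count matrix with gene
annotation (mitochondrial / ribosomal flags) and per-cell sample labels,
stored on disk as a Matrix Market triplet directory (matrix.mtx, genes.tsv,
barcodes.tsv) the way Cell Ranger emits counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = ["CountMatrix", "NormalizedMatrix"]

_MITO_PREFIXES = ("MT-",)
_RIBO_PREFIXES = ("RPL", "RPS")


@dataclass
class CountMatrix:
    """Sparse genes x cells UMI count matrix with annotation.

    Parameters
    ----------
    counts
        Non-negative integer sparse matrix, genes on rows, cells on columns.
    genes
        DataFrame indexed by unique gene id with at least a ``symbol``
        column; ``is_mito`` / ``is_ribo`` boolean columns are added from
        symbol prefixes (MT- / RPL, RPS) when absent.
    cells
        DataFrame indexed by unique cell barcode; a ``sample`` column
        (donor_medium label, e.g. ``WAB0450_SF``) is expected for grouped
        analyses but not required.
    """

    counts: sp.csr_matrix
    genes: pd.DataFrame
    cells: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise ValueError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")
        if not self.genes.index.is_unique:
            raise ValueError("gene ids must be unique")
        if not self.cells.index.is_unique:
            raise ValueError("cell ids must be unique")
        if "symbol" not in self.genes.columns:
            self.genes = self.genes.assign(symbol=self.genes.index)
        for col, prefixes in (("is_mito", _MITO_PREFIXES), ("is_ribo", _RIBO_PREFIXES)):
            if col not in self.genes.columns:
                sym = self.genes["symbol"].astype(str).str.upper()
                self.genes[col] = sym.str.startswith(prefixes)
            self.genes[col] = self.genes[col].astype(bool)

    # -- basic accessors -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def gene_ids(self) -> pd.Index:
        return self.genes.index

    @property
    def cell_ids(self) -> pd.Index:
        return self.cells.index

    @property
    def sample_labels(self) -> pd.Series:
        if "sample" not in self.cells.columns:
            raise KeyError("CountMatrix has no per-cell 'sample' column")
        return self.cells["sample"]

    def symbol_to_rows(self) -> dict[str, int]:
        """Map gene symbol -> row index (first occurrence wins)."""
        out: dict[str, int] = {}
        for i, s in enumerate(self.genes["symbol"]):
            out.setdefault(str(s), i)
        return out

    # -- subsetting ------------------------------------------------------
    def subset_cells(self, keep) -> "CountMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = self.cells.index.get_indexer(keep)
            if (idx < 0).any():
                raise KeyError("unknown cell ids in subset")
        return CountMatrix(self.counts[:, idx], self.genes.copy(), self.cells.iloc[idx].copy())

    def subset_genes(self, keep) -> "CountMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = self.genes.index.get_indexer(keep)
            if (idx < 0).any():
                raise KeyError("unknown gene ids in subset")
        return CountMatrix(self.counts[idx], self.genes.iloc[idx].copy(), self.cells.copy())

    # -- I/O -------------------------------------------------------------
    def write_mtx_dir(self, outdir: str | Path) -> None:
        """Write matrix.mtx + genes.tsv + barcodes.tsv (+ samples.tsv)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        coo = self.counts.tocoo()
        order = np.lexsort((coo.row, coo.col))  # canonical order => byte-stable
        canon = sp.coo_matrix(
            (coo.data[order].astype(np.int64), (coo.row[order], coo.col[order])),
            shape=coo.shape,
        )
        scipy.io.mmwrite(str(outdir / "matrix.mtx"), canon, field="integer")
        self.genes.reset_index(names="gene_id").to_csv(outdir / "genes.tsv", sep="\t", index=False)
        with open(outdir / "barcodes.tsv", "w") as fh:
            fh.write("\n".join(map(str, self.cells.index)) + "\n")
        if len(self.cells.columns):
            self.cells.reset_index(names="cell_id").to_csv(
                outdir / "samples.tsv", sep="\t", index=False
            )

    @classmethod
    def read_mtx_dir(cls, indir: str | Path) -> "CountMatrix":
        indir = Path(indir)
        counts = sp.csr_matrix(scipy.io.mmread(str(indir / "matrix.mtx")))
        genes = pd.read_csv(indir / "genes.tsv", sep="\t")
        if "gene_id" in genes.columns:
            genes = genes.set_index("gene_id")
        else:  # bare 10x two-column file without header
            genes = pd.read_csv(
                indir / "genes.tsv", sep="\t", header=None, names=["gene_id", "symbol"]
            ).set_index("gene_id")
        barcodes = [ln.strip() for ln in open(indir / "barcodes.tsv") if ln.strip()]
        cells = pd.DataFrame(index=pd.Index(barcodes, name="cell_id"))
        samples = indir / "samples.tsv"
        if samples.exists():
            meta = pd.read_csv(samples, sep="\t").set_index("cell_id")
            cells = meta.loc[barcodes]
        return cls(counts, genes, cells)

    def to_anndata(self):
        """Convenience export to an AnnData (cells x genes) object."""
        import anndata

        return anndata.AnnData(
            X=self.counts.T.tocsr(), obs=self.cells.copy(), var=self.genes.copy()
        )


@dataclass
class NormalizedMatrix:
    """log2(1 + count * scale / column_total) expression, genes x cells.

    Zero counts map to exactly zero, so sparsity is preserved.
    """

    values: sp.csr_matrix
    genes: pd.Index
    cells: pd.Index
    scale: float = 1e6
    sample_labels: pd.Series | None = field(default=None, repr=False)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())

    def subset_cells(self, keep) -> "NormalizedMatrix":
        keep = np.asarray(keep)
        idx = np.flatnonzero(keep) if keep.dtype == bool else self.cells.get_indexer(keep)
        if (np.asarray(idx) < 0).any():
            raise KeyError("unknown cell ids in subset")
        labels = None if self.sample_labels is None else self.sample_labels.iloc[idx]
        return NormalizedMatrix(
            self.values[:, idx], self.genes, self.cells[idx], self.scale, labels
        )
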