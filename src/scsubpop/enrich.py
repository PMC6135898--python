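"""Over-representation analysis (ORA) against GMT gene-set collections.

For a gene list drawn from a universe of tested genes, each set's overlap
is scored with the upper-tail hypergeometric probability P(X >= k) and
Benjamini-Hochberg FDR across sets. Genes outside the universe are removed
from both the list (with a warning) and the sets before testing, the
standard ORA hygiene. The universe should be the post-filter tested genes,
not the whole genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from ._utils import log

__all__ = ["GeneSetCollection", "ora", "read_gmt", "write_gmt"]


@dataclass
class GeneSetCollection:
    """Named gene sets (name -> list of symbols)."""

    sets: dict[str, list[str]]
    source: str = ""

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (name, description, genes...; tab-separated)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return GeneSetCollection(sets, source=str(path))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            fh.write("\t".join([name, collection.source or "na", *genes]) + "\n")


def ora(
    gene_list,
    universe,
    collection: GeneSetCollection,
    min_overlap: int = 1,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``gene_list`` in each set.

    Returns one row per set: overlap k, set size m (within the universe),
    list size n, universe size N, p-value P(X >= k), BH FDR (across sets
    with overlap >= min_overlap) and the overlapping symbols.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe is empty")
    genes = set(gene_list)
    outside = genes - universe
    if outside:
        log.warning("%d list genes outside the universe dropped", len(outside))
        genes &= universe
    N, n = len(universe), len(genes)
    rows = []
    for name, members in collection.sets.items():
        mset = set(members) & universe
        m = len(mset)
        overlap = sorted(genes & mset)
        k = len(overlap)
        p = float(hypergeom.sf(k - 1, N, m, n)) if m else 1.0
        rows.append((name, k, m, n, N, p, ",".join(overlap)))
    out = pd.DataFrame(
        rows,
        columns=["set", "overlap", "set_size", "list_size", "universe_size", "p_value", "genes"],
    ).set_index("set")
    out["fdr"] = float("nan")
    testable = out["overlap"] >= min_overlap
    if testable.any():
        out.loc[testable, "fdr"] = multipletests(
            out.loc[testable, "p_value"], method="fdr_bh"
        )[1]
    return out.sort_values(["p_value", "set"])
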