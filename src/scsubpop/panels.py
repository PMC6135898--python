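"""Built-in marker panels and plain-text gene-list I/O.

Panels cover the core pluripotency trio (POU5F1/OCT-4, SOX2, NANOG), the
media-specific pluripotency markers reported higher in StemFlex- or
TeSR-E8-cultured cells, and the trio of genes driving the naive-to-primed
pluripotency transition. All panels are user-overridable; readers accept
one symbol per line (``#`` comments allowed).
"""

from __future__ import annotations

from pathlib import Path

__all__ = ["PANELS", "get_panel", "read_gene_list", "write_gene_list"]

PANELS: dict[str, list[str]] = {
    "core_pluripotency": ["POU5F1", "SOX2", "NANOG"],
    "stemflex_higher": [
        "LEFTY1", "LEFTY2", "IFITM1", "SFRP2", "REST", "OTX2", "TCF3",
        "BRIX1", "KLF4", "KLF5", "HESX1", "CRABP2", "NR5A2", "FOXD3",
        "DNMT3B", "UTF1", "PTEN",
    ],
    "tesr_e8_higher": [
        "TCL1B", "CD7", "GDF3", "LIFR", "GBX2", "CXCL5", "CDH1", "FGF4",
        "GAL", "SOX2", "POU5F1", "DPPA2", "PODXL", "IFITM2", "NANOG",
        "ZFP42", "TCL1A", "NODAL", "DPPA5", "COMMD3", "SEMA3A", "POU3F1",
        "PRDM14", "SALL4",
    ],
    "naive_primed_transition": ["FGF4", "FOXD3", "OTX2"],
}


def get_panel(name: str) -> list[str]:
    try:
        return list(PANELS[name])
    except KeyError:
        raise KeyError(f"unknown panel {name!r}; available: {sorted(PANELS)}") from None


def read_gene_list(path: str | Path) -> list[str]:
    genes = []
    for line in open(path):
        g = line.split("#")[0].strip()
        if g:
            genes.append(g)
    return genes


def write_gene_list(genes: list[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(genes) + "\n")
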