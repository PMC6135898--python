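"""End-to-end orchestration: synth-or-load through transition scoring.

``run_all`` executes the full analysis from a single config with one master
seed: generate or load counts; QC cells then genes; demultiplex when allele
counts are available; normalize; cluster per sample and on the merged
matrix; rank subpopulations by size; score cell-cycle phases; run the media
DE contrast (pooled and per donor) and the subpopulation 1+2 vs 3 contrast
per sample; compute marker panel statistics; over-representation of up/down
lists when a GMT is supplied; and transition scoring for the configured
sample pairs. Every stage writes plain-text outputs under its own
subdirectory and contributes counts to a machine-readable JSON run report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._utils import child_seed, log
from .cluster import cluster_pipeline, normalize, score_cell_cycle
from .containers import CountMatrix
from .de import (
    coexpression_fraction,
    de_test,
    detection_percentile,
    percent_expressing,
    standardized_marker_summary,
)
from .demux import assign_donors
from .enrich import ora, read_gmt
from .panels import PANELS
from .qc import QCPolicy, run_qc
from .synth import QCPlant, SimConfig, simulate_experiment, write_experiment
from .transition import score_transitions, select_features, train_transition_model

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    """Configuration of one full pipeline run (YAML-loadable)."""

    outdir: str = "scsubpop_run"
    seed: int = 0
    # either a synthetic experiment ...
    synth: dict | None = None
    # ... or paths to real inputs
    mtx_dir: str | None = None
    genotypes: str | None = None
    alleles: str | None = None
    gmt: str | None = None
    # stage parameters
    qc_policy: dict = field(default_factory=dict)
    min_cell_fraction: float = 0.001
    demux_error: float = 0.01
    demux_min_reads: int = 10
    n_dims: int = 4
    max_k: int = 10
    n_windows: int = 40
    de_fdr: float = 0.05
    ora_min_overlap: int = 1
    transition_pairs: list | None = None  # [[source_sample, target_sample], ...]
    n_bootstraps: int = 50
    subsample_frac: float = 0.8
    top_n_features: int = 50
    cycle_n_bins: int = 25
    cycle_n_ctrl: int = 50

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def sim_config(self) -> SimConfig:
        raw = dict(self.synth or {})
        if "planted_qc_failures" in raw and isinstance(raw["planted_qc_failures"], dict):
            raw["planted_qc_failures"] = QCPlant(**raw["planted_qc_failures"])
        raw.setdefault("seed", self.seed)
        return SimConfig(**raw)

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("outdir", None)  # location does not affect the analysis
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _load_inputs(cfg: RunConfig, outdir: Path, report: dict):
    if cfg.synth is not None:
        sim = cfg.sim_config()
        matrix, truth, genotypes, alleles = simulate_experiment(sim)
        write_experiment(outdir / "synth", matrix, truth, genotypes, alleles)
        report["synth"] = {
            "n_cells": matrix.n_cells,
            "n_genes": matrix.n_genes,
            "samples": sorted(matrix.cells["sample"].unique()),
        }
        return matrix, genotypes, alleles
    if cfg.mtx_dir is None:
        raise ValueError("config needs either 'synth' or 'mtx_dir'")
    matrix = CountMatrix.read_mtx_dir(cfg.mtx_dir)
    genotypes = (
        pd.read_csv(cfg.genotypes, sep="\t").set_index("snp_id") if cfg.genotypes else None
    )
    alleles = pd.read_csv(cfg.alleles, sep="\t") if cfg.alleles else None
    report["load"] = {"n_cells": matrix.n_cells, "n_genes": matrix.n_genes}
    return matrix, genotypes, alleles


def run_all(cfg: RunConfig) -> dict:
    """Execute the full pipeline; returns (and writes) the run report."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "config_hash": cfg.config_hash(), "seed": cfg.seed}
    stage = "load"
    try:
        matrix, genotypes, alleles = _load_inputs(cfg, outdir, report)

        stage = "qc"
        filtered, qcrep = run_qc(matrix, QCPolicy(**cfg.qc_policy), cfg.min_cell_fraction)
        qcrep.write(outdir / "qc")
        filtered.write_mtx_dir(outdir / "qc" / "filtered")
        report["qc"] = qcrep.summary()

        stage = "demux"
        if alleles is not None and genotypes is not None:
            res = assign_donors(alleles, genotypes, cfg.demux_error, cfg.demux_min_reads)
            (outdir / "demux").mkdir(exist_ok=True)
            res.write(outdir / "demux" / "demux.tsv")
            report["demux"] = {
                "n_cells": len(res.table),
                "flags": res.table["flag"].value_counts().to_dict(),
            }
        else:
            report["demux"] = {"skipped": "no allele counts / genotypes provided"}

        stage = "normalize"
        norm = normalize(filtered)

        stage = "cluster"
        samples = sorted(filtered.cells["sample"].unique())
        labels_by_sample: dict[str, pd.Series] = {}
        cluster_report = {}
        norms = {}
        for name, sub in [("merged", filtered)] + [
            (s, filtered.subset_cells((filtered.cells["sample"] == s).to_numpy()))
            for s in samples
        ]:
            cres, snorm, _ = cluster_pipeline(
                sub, n_dims=cfg.n_dims, max_k=cfg.max_k, n_windows=cfg.n_windows
            )
            d = outdir / "cluster" / name
            d.mkdir(parents=True, exist_ok=True)
            pd.DataFrame(
                cres.embedding.coords,
                index=cres.labels.index,
                columns=[f"PC{i + 1}" for i in range(cres.embedding.coords.shape[1])],
            ).reset_index().to_csv(d / "embedding.tsv", sep="\t", index=False, float_format="%.6g")
            cres.labels.reset_index().to_csv(d / "labels.tsv", sep="\t", index=False)
            cres.stability.to_csv(d / "stability_trace.tsv", sep="\t", index=False, float_format="%.6g")
            (d / "dendrogram.nwk").write_text(cres.newick())
            sizes = cres.labels.value_counts().sort_index()
            cluster_report[name] = {
                "selected_k": cres.selected_k,
                "sizes": {int(k): int(v) for k, v in sizes.items()},
            }
            if name != "merged":
                labels_by_sample[name] = cres.labels
                norms[name] = snorm
        report["cluster"] = cluster_report

        stage = "cell_cycle"
        ann = filtered.genes
        if "cycle_program" in ann.columns and (ann["cycle_program"] != "").any():
            s_genes = list(ann.index[ann["cycle_program"] == "S"])
            g2m_genes = list(ann.index[ann["cycle_program"] == "G2M"])
            phases = score_cell_cycle(
                norm, s_genes, g2m_genes, cfg.cycle_n_bins, cfg.cycle_n_ctrl,
                seed=child_seed(cfg.seed, 11),
            )
            phases.reset_index().to_csv(
                outdir / "phases.tsv", sep="\t", index=False, float_format="%.6g"
            )
            frac = (
                phases.join(filtered.cells["sample"])
                .groupby("sample")["phase"]
                .value_counts(normalize=True)
                .unstack(fill_value=0.0)
            )
            report["cell_cycle"] = {
                s: {p: round(float(v), 4) for p, v in row.items()} for s, row in frac.iterrows()
            }
        else:
            report["cell_cycle"] = {"skipped": "no cell-cycle gene annotation"}

        stage = "de"
        (outdir / "de").mkdir(exist_ok=True)
        media = sorted(filtered.cells["medium"].unique()) if "medium" in filtered.cells else []
        de_report = {}
        de_media = None
        if len(media) == 2:
            m_a, m_b = media[1], media[0]  # e.g. SF vs E8
            contrasts = {f"media_{m_a}_vs_{m_b}_pooled": (None, m_a, m_b)}
            for donor in sorted(filtered.cells["donor"].unique()):
                contrasts[f"media_{m_a}_vs_{m_b}_{donor}"] = (donor, m_a, m_b)
            for cname, (donor, a, b) in contrasts.items():
                mask = (
                    np.ones(filtered.n_cells, bool)
                    if donor is None
                    else (filtered.cells["donor"] == donor).to_numpy()
                )
                ga = mask & (filtered.cells["medium"] == a).to_numpy()
                gb = mask & (filtered.cells["medium"] == b).to_numpy()
                res = de_test(norm, ga, gb, name_a=a, name_b=b)
                res.write(outdir / "de" / f"{cname}.tsv")
                de_report[cname] = {
                    "n_tested": int(res.table["tested"].sum()),
                    "n_significant": int(len(res.significant(cfg.de_fdr))),
                }
                if donor is None:
                    de_media = res
        for s, labels in labels_by_sample.items():
            if labels.max() < 3:
                de_report[f"subpop_12_vs_3_{s}"] = {"skipped": "fewer than 3 subpopulations"}
                continue
            ga = labels.isin([1, 2]).to_numpy()
            gb = (labels == 3).to_numpy()
            res = de_test(norms[s], ga, gb, name_a="subpop12", name_b="subpop3")
            res.write(outdir / "de" / f"subpop_12_vs_3_{s}.tsv")
            de_report[f"subpop_12_vs_3_{s}"] = {
                "n_tested": int(res.table["tested"].sum()),
                "n_significant": int(len(res.significant(cfg.de_fdr))),
            }
        report["de"] = de_report

        stage = "markers"
        (outdir / "markers").mkdir(exist_ok=True)
        symbols = filtered.genes["symbol"]
        marker_report = {}
        core = [s for s in PANELS["core_pluripotency"] if s in set(symbols)]
        if core:
            rows = []
            for s in sorted(filtered.cells["sample"].unique()):
                grp = (filtered.cells["sample"] == s).to_numpy()
                pct = percent_expressing(filtered, core, grp)
                co = coexpression_fraction(filtered, core, "any", grp)
                rows.append({"sample": s, "coexpr_any_pct": co, **pct.to_dict()})
            pd.DataFrame(rows).to_csv(
                outdir / "markers" / "core_markers.tsv", sep="\t", index=False, float_format="%.6g"
            )
            marker_report["core_panel"] = core
            nanog = detection_percentile(filtered, core[-1])
            marker_report["detection_percentile_example"] = nanog
        else:
            marker_report["skipped"] = "no built-in panel symbols present (synthetic genes)"
        report["markers"] = marker_report

        stage = "enrich"
        if cfg.gmt and de_media is not None:
            coll = read_gmt(cfg.gmt)
            universe = list(de_media.table.index[de_media.table["tested"]])
            enr_report = {}
            for dname in (f"up_{de_media.group_a}", f"up_{de_media.group_b}"):
                genes = list(de_media.significant(cfg.de_fdr, dname))
                res = ora(genes, universe, coll, cfg.ora_min_overlap)
                (outdir / "enrich").mkdir(exist_ok=True)
                res.reset_index().to_csv(
                    outdir / "enrich" / f"{dname}.tsv", sep="\t", index=False, float_format="%.6g"
                )
                enr_report[dname] = {
                    "n_list": len(genes),
                    "n_enriched": int((res["fdr"] < cfg.de_fdr).sum()),
                }
            report["enrich"] = enr_report
        else:
            report["enrich"] = {"skipped": "no GMT collection configured"}

        stage = "transition"
        pairs = cfg.transition_pairs
        if pairs is None and len(samples) >= 2:
            pairs = [[samples[0], samples[1]], [samples[1], samples[0]]]
        tr_report = {}
        if pairs:
            (outdir / "transition").mkdir(exist_ok=True)
            for src, tgt in pairs:
                lab_t = labels_by_sample[tgt]
                des = {}
                for c in sorted(lab_t.unique()):
                    des[c] = de_test(
                        norms[tgt],
                        (lab_t == c).to_numpy(),
                        (lab_t != c).to_numpy(),
                        name_a=f"subpop{c}", name_b="rest",
                    )
                feats = select_features(des, cfg.top_n_features)
                model = train_transition_model(
                    norms[tgt], lab_t.to_numpy(), feats,
                    n_bootstraps=cfg.n_bootstraps,
                    subsample_frac=cfg.subsample_frac,
                    seed=child_seed(cfg.seed, 21),
                    target_name=tgt,
                )
                tm = score_transitions(model, norms[src], labels_by_sample[src].to_numpy())
                tm.write(outdir / "transition" / f"{src}__to__{tgt}.tsv")
                tm.per_cell_probability.add_prefix("p_subpop").reset_index().to_csv(
                    outdir / "transition" / f"{src}__to__{tgt}_cell_probs.tsv",
                    sep="\t", index=False, float_format="%.6g",
                )
                tr_report[f"{src}->{tgt}"] = {
                    "diagonal": {
                        int(c): round(float(tm.mean.loc[c, c]), 2)
                        for c in tm.mean.index
                        if c in tm.mean.columns
                    },
                    "n_features": len(feats),
                }
        report["transition"] = tr_report

    except Exception:
        report["failed_stage"] = stage
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=str)
        log.error("pipeline failed at stage %s (partial outputs kept)", stage)
        raise

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str, sort_keys=True)
    log.info("pipeline complete: %s", outdir / "report.json")
    return report
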