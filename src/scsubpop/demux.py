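"""Genetic demultiplexing of pooled cells.

Each cell's donor of origin is recovered by comparing its ref/alt read
counts at a SNP panel against the candidate donors' genotypes under a
binomial read model: at a SNP with alt-allele dosage g the probability a
read shows the alt allele is ``error`` (g=0), 0.5 (g=1) or ``1 - error``
(g=2). Cells are assigned to the maximum-posterior donor under a uniform
prior; cells with few informative reads are flagged low-confidence and
cells with none are unassignable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from ._utils import log

__all__ = ["DemuxResult", "donor_loglik", "assign_donors", "read_genotype_vcf"]


@dataclass
class DemuxResult:
    """Per-cell donor assignment with log-likelihoods and posteriors."""

    table: pd.DataFrame  # index cell_id; best_donor, n_informative_reads, flag
    logliks: pd.DataFrame  # cell x donor
    posteriors: pd.DataFrame  # cell x donor

    def write(self, path: str | Path) -> None:
        out = self.table.join(self.posteriors.add_prefix("post_"))
        out.reset_index().to_csv(path, sep="\t", index=False)


def _alt_prob(dosage: np.ndarray, error: float) -> np.ndarray:
    p = np.full(dosage.shape, np.nan)
    p[dosage == 0] = error
    p[dosage == 1] = 0.5
    p[dosage == 2] = 1.0 - error
    return p


def donor_loglik(
    alt: np.ndarray, total: np.ndarray, dosage: np.ndarray, error: float
) -> float:
    """Binomial log-likelihood of one cell's allele counts for one donor.

    SNPs with missing genotype (NaN dosage) are skipped. A cell with no
    covered SNP has log-likelihood 0 for every donor.
    """
    if not (0 < error < 0.5):
        raise ValueError("error must be in (0, 0.5)")
    alt = np.asarray(alt, float)
    total = np.asarray(total, float)
    dosage = np.asarray(dosage, float)
    ok = (total > 0) & ~np.isnan(dosage)
    if not ok.any():
        return 0.0
    a, t = alt[ok], total[ok]
    p = _alt_prob(dosage[ok].astype(int), error)
    logc = gammaln(t + 1) - gammaln(a + 1) - gammaln(t - a + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = logc + a * np.log(p) + (t - a) * np.log1p(-p)
    ll = np.where((a == 0) & (p == 0), logc, ll)  # 0*log(0) := 0
    ll = np.where((a == t) & (p == 1), logc, ll)
    return float(ll.sum())


def assign_donors(
    alleles: pd.DataFrame,
    genotypes: pd.DataFrame,
    error: float = 0.01,
    min_reads: int = 10,
) -> DemuxResult:
    """Assign every cell to its maximum-posterior donor.

    Parameters
    ----------
    alleles
        Long table with columns cell_id, snp_id, ref_count, alt_count.
    genotypes
        SNP x donor dosage matrix in {0, 1, 2} (NaN = missing).
    error
        Sequencing error rate, in (0, 0.5).
    min_reads
        Cells with fewer informative reads are flagged ``low_confidence``
        (assignment still reported); cells with none are ``unassignable``.
    """
    if not (0 < error < 0.5):
        raise ValueError("error must be in (0, 0.5)")
    donors = list(genotypes.columns)
    if len(donors) < 2:
        raise ValueError("need at least 2 donors to demultiplex")
    gt = genotypes.to_numpy(dtype=float)
    if not np.any(np.nanstd(gt, axis=1) > 0):
        log.warning("all donors have identical genotypes: cells are unidentifiable")

    known = alleles["snp_id"].isin(genotypes.index)
    alleles = alleles[known]
    snp_idx = genotypes.index.get_indexer(alleles["snp_id"])
    cells = pd.Index(pd.unique(alleles["cell_id"]), name="cell_id")
    cell_idx = cells.get_indexer(alleles["cell_id"])
    alt = alleles["alt_count"].to_numpy(float)
    tot = alt + alleles["ref_count"].to_numpy(float)

    logc = gammaln(tot + 1) - gammaln(alt + 1) - gammaln(tot - alt + 1)
    ll = np.zeros((len(cells), len(donors)))
    reads = np.zeros(len(cells))
    for j in range(len(donors)):
        dos = gt[snp_idx, j]
        ok = ~np.isnan(dos) & (tot > 0)
        p = _alt_prob(dos[ok].astype(int), error)
        term = logc[ok] + alt[ok] * np.log(p) + (tot[ok] - alt[ok]) * np.log1p(-p)
        np.add.at(ll[:, j], cell_idx[ok], term)
    informative = ~np.isnan(gt[snp_idx]).all(axis=1) & (tot > 0)
    np.add.at(reads, cell_idx[informative], tot[informative])

    post = np.exp(ll - logsumexp(ll, axis=1, keepdims=True))
    best = np.asarray(donors, object)[np.argmax(post, axis=1)]
    flag = np.where(
        reads == 0, "unassignable", np.where(reads < min_reads, "low_confidence", "ok")
    )
    table = pd.DataFrame(
        {
            "best_donor": best,
            "n_informative_reads": reads.astype(int),
            "max_posterior": post.max(axis=1),
            "flag": flag,
        },
        index=cells,
    )
    log.info(
        "demultiplexed %d cells (%d low-confidence, %d unassignable)",
        len(cells), int((flag == "low_confidence").sum()), int((flag == "unassignable").sum()),
    )
    return DemuxResult(
        table=table,
        logliks=pd.DataFrame(ll, index=cells, columns=donors),
        posteriors=pd.DataFrame(post, index=cells, columns=donors),
    )


def read_genotype_vcf(path: str | Path) -> pd.DataFrame:
    """Minimal VCF reader: biallelic SNPs, GT field only, to a dosage table."""
    snp_ids, rows, samples = [], [], None
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            fields = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                samples = fields[9:]
                continue
            if samples is None:
                raise ValueError("VCF header line #CHROM... not found")
            chrom, pos, vid, ref, alt = fields[:5]
            if len(ref) != 1 or len(alt) != 1 or alt == ".":
                continue  # not a biallelic SNP
            fmt = fields[8].split(":")
            gi = fmt.index("GT")
            dosages = []
            for s in fields[9:]:
                gtf = s.split(":")[gi].replace("|", "/")
                al = [a for a in gtf.split("/") if a not in (".", "")]
                dosages.append(sum(int(a) for a in al) if al else np.nan)
            snp_ids.append(vid if vid != "." else f"{chrom}:{pos}")
            rows.append(dosages)
    return pd.DataFrame(
        rows, index=pd.Index(snp_ids, name="snp_id"), columns=samples
    )
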