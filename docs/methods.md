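# Methods

This note records the models, numerical choices and known limitations of
the package; every empirical statement here is recomputed by the test
suite or by `scripts/acceptance.py`.

## Synthetic experiment generator

The generator states the world the pipeline is tested in: a pooled
experiment of `n_donors × n_media` samples (defaults 2 × 2, 5,000 cells per
sample, 16,000 genes) sharing `K` latent subpopulations (default
proportions 0.60/0.25/0.15 — one dominant and one minor subpopulation).

**Counts.** Each gene receives a baseline relative expression
x_g ~ lognormal(0, 0.6), floored so that every gene has at least ~0.2
expected counts per cell: the simulated gene universe represents the
post-filter "reliably detected" genes, so under-detected genes exist only
when explicitly planted (`planted_rare_genes`). Mitochondrial (1 % of
genes) and ribosomal (5 %) genes are rescaled so their expected library
shares are 6 % and 20 %. Subpopulation k multiplies its
`n_marker_genes_per_subpop` (default 50) markers by 2^`marker_log2fc`
(default 2 in log2 units). Cell library sizes are
lognormal(mean 8,000 UMIs, σ_log = 0.35) — the emulated study reports
under 20,000 UMIs per cell. Given the per-cell mean μ, counts are
gamma–Poisson (negative binomial) with dispersion φ = 0.3
(Var = μ + φμ²).

**Dropout.** An extra Bernoulli zero is applied on top of the NB draw with
probability 1/(1 + exp(s·(u − m))), where u = log2(1 + CPM) of the entry's
true relative expression, m = 4.0 and s = 1.0 by default. The curve lives
on the same log2-CPM axis the downstream imputation model is fitted on.
These defaults give a median gene detection rate of ~28 % of cells at the
default scale, the calibration target for sparse droplet data. Because
dropout only zeroes entries, observed zero fractions are bounded below by
the NB-only zero fractions for every gene (tested).

**Cell cycle.** Two 30-gene programs (S, G2M) are multiplied by 2^1.5 in
cells assigned to those phases (fractions 60/20/20 G1/S/G2M).

**Planted QC failures.** Mito (ribo) failures add multinomially
distributed counts on mito (ribo) genes until the share reaches 45 %
(65 %); reads failures thin the library by ×0.02 or inflate it ×25
(alternating). These severities sit far from the baseline distributions,
so absolute thresholds (log10 totals outside [3.0, 4.6]; mito > 20 %;
ribo > 40 %) separate planted from natural cells essentially surely —
which is what makes the QC bookkeeping checks exact.

**SNPs.** Donor genotypes are Hardy–Weinberg draws with MAF ~ U(0.05, 0.5)
(optionally forced discriminating). Per cell and SNP, total reads are
Poisson(depth/n_snps) and alt reads Binomial(total, p_g) with p = ε, ½,
1 − ε for dosage 0/1/2.

**Determinism.** Every component (genes, cells, counts, dropout, QC
planting, genotypes, alleles, cycle) draws from its own stream derived
from the master seed by fixed offsets, so outputs are bit-reproducible and
structurally independent across components.

**What the generator does not emulate:** ambient RNA, doublets, batch
effects, gene–gene correlation beyond the subpopulation/cycle programs,
UMI saturation, or read-level errors. A green test therefore establishes
correctness of the algorithms against this stated world, not performance
on any particular real dataset.

## QC

"Mapped reads" is proxied by total UMI counts, since the pipeline starts
from the count matrix. Default policy: two-sided median ± 3·MAD on
log10(total + 1) (capturing both low and high outliers), one-sided
median + 3·MAD on mito % and ribo %; all criteria can be overridden by
absolute thresholds (strict `>` semantics). A constant metric (MAD = 0)
flags nothing and records a warning. Cells with zero counts are always
reads outliers. Gene filtering keeps a gene iff its detection count is
≥ `min_cell_fraction` × n_cells (default 0.001, i.e. the "< 0.1 % of
cells" removal rule), with the denominator being the cells that survived
cell QC (cells are filtered first). Re-running with the same absolute
thresholds is idempotent; MAD thresholds re-estimated on filtered data can
shift, which is inherent to robust rules.

## Demultiplexing

A singlet-only binomial likelihood with a uniform donor prior; doublet
mixtures are out of scope. SNPs with missing genotypes are skipped per
donor. Defaults ε = 0.01, `min_reads` = 10 (below: `low_confidence`; zero
informative reads: `unassignable` with uniform posterior). Genotypes are
read from a dosage TSV or a minimal VCF (biallelic SNPs, GT field only).

## Clustering

Normalization is log2(1 + count·scale/total), scale 10⁶; a zero count maps
to exactly 0.

**Dropout candidates.** Per cell, a kernel density (Gaussian, Silverman
bandwidth, 256-point grid) of the full expression profile *including
zeros* is scanned for the first pair of modes whose connecting valley is
genuinely bimodal: the valley density must fall below 0.5× the lower mode
and each side must hold ≥ 2 % of the values (so lone outliers and KDE
wiggles on unimodal profiles are not modes). The threshold is that valley;
unimodal cells inherit the median threshold of the others, and if no cell
is bimodal the matrix is treated as dropout-free (no candidates), making
the dropout-free limit exact. Entries below their cell's threshold
(including zeros) are candidates. The per-gene candidate rate is regressed
on mean nonzero expression by least squares on the logistic P(u); fit
failure falls back to (a, b) = (1, 2) with a warning.

The fitted midpoint b is *not* an unbiased estimate of a generative
dropout midpoint: mean nonzero expression is floored at
log2(1 + 10⁶/library) by count discreteness and biased upward by
conditioning on detection. The curve's role is relative weighting inside
the imputation, and tests verify monotonicity plus that candidate rates
track true planted dropout probabilities (rank correlation), not raw
parameter recovery.

**Dissimilarity.** For cells i, j and gene values (u, v): (u − v)² if
neither is a candidate; imputing the candidate as P(v)·u + (1 − P(v))·v
gives weight P(v)²(u − v)² if exactly one is; 0 if both are. D is the root
of the gene sum; the computation is a handful of dense matrix products, so
it is never materialized per gene pair and the expression matrix is never
modified.

**PCoA.** Classical MDS: eigendecomposition of the double-centered squared
dissimilarities; coordinates for the top `n_dims` (default 4; displays use
2) positive eigenvalues; negative eigenvalues are dropped and counted as a
diagnostic.

**Cluster number.** Ward linkage on the embedding; the dendrogram is cut
at 40 evenly spaced heights in (0, h_max]; the cluster count (≤ `max_k`)
persisting over the longest run of consecutive windows is selected, ties
toward fewer clusters, and labels are renamed 1..K by decreasing size
(ties by original label). Adjacent-window adjusted Rand indices are
recorded as the stability trace. Limitation: k = 1 occurs only at the
topmost cut, so homogeneous data is reported as a *weak* low-k plateau
(short `plateau_length`) rather than literally one cluster; genuine
structure shows plateaus several-fold longer (tested).

**Cell cycle.** Per cell, each program's score is the mean expression of
its markers minus the mean of control genes drawn (50 per marker) from the
markers' average-expression bins (25 quantile bins); phase is G1 when both
scores are ≤ 0, else the argmax. A fixed draw of program genes carries a
bin-matching offset of up to a few tenths; the score is unbiased over
draws (tested over 10 independent simulations).

## Differential expression and markers

Wilcoxon rank-sum (two-sided, asymptotic with tie correction) per gene on
normalized values — chosen as the assumption-light standard for
single-cell data; a t-test on log values is available. log2FC =
log2((mean_A + 0.01)/(mean_B + 0.01)); genes expressed in < 1 % of cells
in both groups are excluded from testing. BH FDR across tested genes.
"Expressed" means UMI count > 0 throughout (percent-expressing,
coexpression, detection percentile). The detection percentile uses the
mid-rank convention 100·(n_lower + 0.5·ties)/(n_genes − 1). Marker
summaries z-score group means across groups; constant genes give zero
rows. Significance defaults to FDR < 0.05 where a cutoff is needed.

## Over-representation

Upper-tail hypergeometric P(X ≥ k) per set with BH FDR across sets with
overlap ≥ `min_overlap`. Genes outside the universe are removed from both
list and sets before testing (standard ORA hygiene); the recommended
universe is the post-filter tested genes, not the genome. GMT is the
interchange format. Note that enlarging the universe does not monotonely
shrink p-values — only the exact tail identity is guaranteed (tested
against rational-arithmetic and brute-force-enumeration oracles).

## Transition scoring

For each target subpopulation: `n_bootstraps` (default 50) stratified 80 %
subsamples, each fitted with L1-penalized logistic one-vs-rest regression
on the selected feature genes (union of top-50 DE genes per subpopulation,
ranked by FDR then |log2FC| with deterministic tie-breaks), penalty chosen
by internal stratified 5-fold CV over 5 log-spaced strengths. Scoring
renormalizes the one-vs-rest probabilities into conditional class
probabilities and assigns each source cell to its argmax class, so each
row of the matrix sums to 100 exactly per bootstrap; means and SDs are
reported across bootstraps. The argmax (row-percentage) convention is the
default because similarity is reported as "% of source cells similar to
target class"; a probability-cutoff variant can be derived from the
per-cell probability table. The package reports matrices only and makes
no biological state-transition claims.

## Pipeline

`run_all` chains synth-or-load → QC → demux (when allele counts exist) →
normalize → clustering (merged and per sample) → cell-cycle scoring → DE
(media contrast pooled and per donor; subpopulations 1+2 vs 3 per sample)
→ marker statistics → ORA (when a GMT is supplied) → transition scoring
for the configured sample pairs. Each stage consumes and writes plain
files, so stages can be re-run alone; all randomness derives from the
single config seed and reruns are byte-identical (the config hash excludes
the output directory). Test fixtures and the acceptance script run the
pipeline at reduced sizes (hundreds of cells per sample, hundreds of
genes) so the full suite stays within desk-scale time budgets; the
defaults encode the full-scale design.
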