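# Methods

## The problem

Bulk RNA-seq studies of early prenatal development often need each sample's
genetic sex — sexual dimorphism confounds expression analyses — at stages
where no gonadal phenotype is visible and no DNA assay was run. In early pig
conceptuses (embryos at 25 days, fetuses at 35 days of gestation) sex can be
called directly from the expression data: genes in the male-specific region
of the Y chromosome (DDX3Y, KDM5D, ZFY, EIF2S3Y, EIF1AY and several
uncharacterized LOC genes) are expressed in genetic males and essentially
absent in females, where only a trickle of reads lands on Y through
mismapping from X/Y-homologous regions. SRY is deliberately not used: its
expression window closes before these stages.

## The statistic

For a gene g and sample s with read count c(g,s) and library size
N(s) = Σ_g c(g,s) over retained genes,

    CPM(g,s) = c(g,s) / N(s) × 10⁶
    ΣCPM_chrY(s) = Σ_{g ∈ G} CPM(g,s)

where G is the set of *informative* Y-chromosome genes. A sample is called
**male** if ΣCPM_chrY > 400, **female** if ΣCPM_chrY < 2, and
**undetermined** otherwise. Both inequalities are strict; the wide open
interval (2, 400) is a deliberate dead zone — a sample there is flagged
rather than forced into a call. On the bundled 35-sample reference dataset
males span 427.29–573.09 and females 0.00–1.75, so the thresholds sit far
from both groups.

The library-size denominator is the column sum over retained genes;
HTSeq-style `__`-prefixed bookkeeping totals are stripped at parse time and
excluded by default (`include_summary_in_library=True` reverses this). The
choice moves every CPM by well under 20% in typical data and cannot move a
sample across both thresholds at once.

## Informative-gene selection

"Discrepant" expression is formalized as largest-gap bimodality. For each
candidate gene on the target chromosome, sort its per-sample CPM and split
at the widest consecutive gap. The gene is selected iff

* both groups contain at least `min_group` (default 2) samples,
* the high-group minimum is at least `min_high_cpm` (default 0.5 CPM), and
* high-group minimum / max(low-group maximum, 0.01 CPM) ≥ `min_fold`
  (default 20).

The 0.01-CPM floor keeps all-zero female rows finite. Defaults are
calibrated on the reference dataset: its weakest informative gene (KDM5D)
separates 5.35 / 0.08 ≈ 67-fold and its faintest male band bottoms out at
1.23 CPM (LOC396706), so 20-fold and 0.5 CPM accept all ten known genes
with room for counting noise, while artifact-only Y genes — which never
assemble a coherent high group above ~0.1 CPM — are rejected by orders of
magnitude. Ties in the gap location break toward the lowest index; genes
are reported in input order with per-gene diagnostics (low max, high min,
ratio, group sizes).

## Group summaries

Per label: n, mean, sample standard deviation (n−1 denominator; omitted for
singleton groups), min and max of ΣCPM_chrY. Report files round to exactly
two decimals, half-up — the precision at which the reference values are
stated; all internal computation is full-precision.

## MDS check

As an orthogonal check that samples segregate by sex, the package embeds
samples by classical MDS on pairwise leading-logFC distances:

* log-expression = log2(CPM + p(s)) with pseudocount
  p(s) = prior / N(s) × 10⁶ (prior = 2 reads); when a pre-computed CPM
  table carries no library sizes, p(s) degrades to `prior` CPM, i.e. a
  nominal million-read library.
* distance(i,j) = RMS of the `top` (default 500) largest |log2FC| across
  genes, the gene subset chosen per pair.
* Torgerson scaling: double-center the squared distances, eigendecompose,
  scale the top-k eigenvectors by √eigenvalue. Negative eigenvalues
  (non-Euclidean input) are clamped to zero with a warning. Axis signs are
  arbitrary and nothing downstream depends on them.

On the reference dataset restricted to the ten informative genes, every
between-sex distance exceeds every within-sex distance (~8-fold margin) and
a two-group split of dimension 1 reproduces the sex calls exactly.

## Synthetic data

The generator emulates the count-level structure the analysis assumes and
nothing more:

* **Library sizes**: log-normal around 13 million counted reads (CV 0.1),
  matching post-QC depths of ~13–14 million in the kind of bulk experiment
  this pipeline targets.
* **Autosomal background** (default 20 000 genes): per-gene log-normal mean
  (σ = 1.5) scaled so the realized library hits its target, with
  gamma-Poisson (negative-binomial) counts at dispersion 0.1 — standard
  bulk RNA-seq texture whose only job is a realistic CPM denominator.
* **Y panel** (default 79 genes, 10 informative): for each informative gene,
  male samples draw a realized CPM uniformly inside a per-gene band and
  receive the matching (rounded) count; the default bands are the min–max
  male CPM of each reference gene. The bands are *realized* ranges — they
  already contain counting noise — so no further noise is layered on top
  (doing so would double-count variance and, for the faintest gene at
  ~16–30 reads, spread simulated males well outside the band). Females
  receive Poisson counts at a per-gene artifact rate defaulting to the
  reference female column means (≈0.01–0.09 CPM; ~0.04 on average):
  artifact reads are sparse technical noise and the Poisson reproduces the
  many exact zeros seen in female data. Uniform bands are
  assumption-minimal and keep ΣCPM_chrY inside the observed 427–573 range.
  The remaining 69 Y genes carry 0.02-CPM Poisson artifact counts in every
  sample.
* **Feasibility**: configurations whose band lower bound comes within
  100-fold of the artifact rate are rejected before sampling.
* **Determinism**: every gene owns a child `SeedSequence` of the global
  seed and library sizes have a per-sample substream, so a given seed is
  byte-reproducible and enlarging the Y panel never redraws existing genes.
  (Enlarging the autosomal panel rescales the background mean to hold the
  library-size target, so autosomal counts are panel-size-specific.)

Male samples generated at study scale place ~0.05% of reads on Y, the
order of magnitude seen in real male bulk libraries.

What passing on synthetic data does **not** show: robustness to degraded
RNA, 3′ bias, partial X/Y-homolog misannotation, sample contamination or
cross-species reuse of thresholds — the generator models none of these.
Thresholds of 400/2 are specific to deep (≫1 M reads) libraries and a
ten-gene panel; a different panel or very shallow libraries would need the
`classify` thresholds re-examined.

## Problem sizes used in validation

The test suite runs unit tests at reduced size (2 000 autosomal genes, 6–10
samples) and the end-to-end checks at study scale: 35 samples, 20 079
genes, 20 independent seeds. Across those 20 seeds the pipeline is expected
to recover all 35 true labels and the exact ten-gene informative set in at
least 19; single-seed misses are possible because the sum of the ten band
lower bounds (398.1) sits just below the male threshold of 400, so a male
drawing all ten targets near their band bottoms can land undetermined —
a property of the thresholds, not a defect of the generator.

## Known limitations

* The selection criterion assumes both sexes are present; an all-male or
  all-female cohort yields no informative genes (by design — the CLI warns
  rather than fails).
* Classification quality degrades gracefully but silently if the chromosome
  map omits informative genes; unmapped genes raise only when named
  explicitly.
* Classical MDS is exact only for Euclidean distances; leading-logFC
  distances are near-Euclidean in practice, and residual negative
  eigenvalues are clamped with a warning.
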