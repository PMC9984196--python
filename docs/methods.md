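# Methods

This note documents the models behind each module, the parameters that
matter, the numerical choices, and what the synthetic data do and do not
establish about real data.

## Fraction-enrichment model and test

### Normalization

Size factors use the median-of-ratios method: for each sample, the median
over reference genes (rows with no zero count) of the gene's count divided
by its geometric mean across samples, rescaled so the factors have
geometric mean 1. There is no pseudo-reference fallback: if no gene is
observed in every sample the estimator refuses, because a median over an
arbitrary subset silently changes the estimand.

### Bias

The reported bias is the log2 ratio of mean normalized counts between the
two fractions. When both group means are positive this is the maximum-
likelihood fold change of the saturated two-group model and is **exactly**
invariant under rescaling any sample's column (the rescaling is absorbed
by that sample's size factor and the common normalization anchor, which
cancels in the ratio). A pseudocount of 0.5 is added to both means only
when exactly one fraction is all-zero — a rescue that keeps the estimate
finite; such genes are necessarily outside the strict invariance
guarantee, since no finite surrogate for log(0) can be scale-free.
All-zero genes get bias 0 and a missing p-value.

### Dispersion and the Wald test

Counts are modeled as negative binomial with Var = μ + αμ² (gene-wise α).
With three replicates per fraction the per-gene residual information is
4 degrees of freedom, far too little for a stable per-gene variance: a
plain Wald test against the normal reference rejects ~12% of null genes
at p < 0.05, while a t(4) reference is calibrated but sacrifices power.
The implemented test therefore moderates the per-gene estimate:

1. For each gene, the pooled method-of-moments estimate of the **total
   squared coefficient of variation** q̂ = α̂ + (Poisson part) is formed
   from the within-group variances of normalized counts. q̂ is
   non-negative by construction and approximately q·χ²₄/4 distributed.
2. A scaled inverse-chi-square prior is fitted to the q̂ across genes by
   log-moment matching (the limma approach): the excess of var(log q̂)
   over trigamma(2) yields the prior degrees of freedom d₀; no trend on
   expression is fitted.
3. The prior is recentred at each gene's own Poisson floor (the median
   Poisson part across genes is swapped for the gene's), so weakly
   expressed genes keep their larger shot-noise term.
4. The moderated q̃ is the d₀-weighted average of prior and estimate; the
   implied dispersion is clipped to [1e-8, 10]. The Wald statistic is
   bias / se with se² = q̃·(1/n₁ + 1/n₂)/ln²2, and the p-value is
   two-sided from t with d₀ + n₁ + n₂ − 2 degrees of freedom.

Under the package's reference simulation conditions (5,000 genes, 3 vs 3
replicates, α = 0.05, log-normal base means around 500, 10% of genes at
log2 fold change 2) this test is calibrated — the null rejection rate at
p < 0.05 stays within [0.045, 0.055] across seeds — with essentially full
power at FDR < 0.05, while BH keeps the realized false-discovery
proportion near the nominal level. This moderation-toward-a-constant is
deliberately simpler than DESeq2's trended, shrunken dispersions;
reproducing DESeq2's exact significant-gene counts on the original
sequencing data is out of scope.

Genes enter a contrast only if some sample reaches `min_count` (default
10) raw counts; the FDR universe is the post-filter gene set. With a
single sample per fraction there is no replication: the test falls back
to the Poisson floor with a normal reference and should be treated as
descriptive.

## Dual transcriptome

For every transcript in a GFF3 annotation, two records are emitted: the
spliced form (exon sequences concatenated in genomic order, then
reverse-complemented for minus-strand transcripts so both read 5′→3′) and
the unspliced form (the genomic span from transcript start to end).
Record ids carry `::spliced` / `::unspliced` suffixes and are emitted in
sorted transcript order. GFF3 coordinates are 1-based closed; conversion
to Python slices happens only in this module. Single-exon transcripts
yield identical pair members by construction.

## PRRE scanner

A window of 10 nt qualifies with ≥ 9 pyrimidines (C, T, or U; case-
insensitive; N and all other IUPAC ambiguity codes count as
non-pyrimidine — conservative detection). Overlapping **or book-ended**
qualifying windows merge into one element spanning from the first
window's start to the last window's end; windows separated by one or more
non-qualifying positions stay separate elements. The element's position is
the merged start; position 1 means TOP, otherwise PRTE.

Two consequences of this rule are worth knowing. First, elements are
*merged window spans*, not trimmed pyrimidine runs: a window holding one
flanking purine plus nine run pyrimidines qualifies, so an element can
begin (or end) one base outside a solid pyrimidine run. This is the
reading consistent with classifying the RPS28 reporter element — whose
printed sequence begins with a purine A — as position-1 TOP. Second, the
synthetic UTR generator therefore records both the planted run start and
the rule-implied element start (one base earlier for interior runs).

Per-gene annotation scans the longest annotated 5′ UTR (ties broken
lexicographically by transcript id) and reports the most 5′ element. TOP
classification is strictly position == 1 of the provided sequence;
transcription-start heterogeneity is not modeled.

## smFISH position summaries

z runs apically from the basal surface at z = 0. QC keeps (cell, target)
groups whose spot count lies in [100, 1000] (inclusive; upper bound
removable for endogenous targets), matching the expression window in
which reporter thresholding is reliable. The per-cell mean z is
normalized by **subtracting** the experiment-wide median z of the control
transcript: the control and reporters are expressed in different cells,
so no per-cell reference exists, and subtraction (rather than division)
is well-defined regardless of where the coordinate origin sits. Readers
can convert stack slice indices to µm with a configurable slice spacing
(default 0.2 µm). All group comparisons are two-sided Wilcoxon rank-sum
tests over per-cell values — exact enumeration when the pooled sample is
≤ 30 without ties, otherwise the normal approximation with tie and
continuity corrections. Per-cell means are unweighted when pooling
(duplicating spots within a cell changes nothing).

Neurite/soma analysis counts spots per compartment and reports
n_neurite/n_soma per cell; cells with zero soma spots are excluded with a
logged warning (the ratio is undefined), while zero neurite spots give
ratio 0 and the cell is retained.

## LRz and cross-compartment correlation

Each dataset column of the LR matrix is z-normalized over its non-missing
genes (n−1 denominator); a gene's LRz is the median of its available
z-scores, reported only when the gene appears in at least `min_datasets`
datasets (default: half, rounded up — the pooled public experiments are
heterogeneous and no principled missingness rule is available). Columns
with fewer than 3 genes or zero variance are hard errors naming the
dataset. z-normalization makes LRz exactly invariant to per-dataset
affine distortions, which is the point of the statistic.

The cross-compartment comparison maps bias-table gene ids to LRz gene ids
through a required two-column ortholog table (inference is out of scope);
pairs touching any id that appears more than once are dropped with a
logged count, Spearman's rho is computed over the mapped genes (≥ 10
required), and an optional subset argument reproduces class-restricted
correlations (e.g. ribosomal-protein genes only).

The ΔΔCt qPCR localization ratio averages technical replicates, then
computes log2(efficiency) · [(Ct_ref − Ct_rep)_neurite − (Ct_ref −
Ct_rep)_soma]; at the default perfect-doubling efficiency this is the
plain ΔΔCt difference, and the generator's zero-noise tables invert to
the planted LR exactly.

Class summaries (motif classes on a bias axis, gene sets on the LRz axis)
all test class members against the complement of the gene universe with
the same rank-sum machinery, so the motif-module and cross-compartment
summaries agree to machine precision on shared inputs.

## Synthetic-data generators

The generators emulate the statistical structure each analysis assumes;
all randomness flows from explicit seeds and identical seeds give
bit-identical outputs.

* **Counts**: NB with Var = μ + αμ², log-normal base means
  (default: natural-log mean ln 500, sd 1 — a desk-scale stand-in for a
  sequencing library's expression spread), default dispersion α = 0.05
  (replicate-level variance of the original enrichment libraries is not
  published; 0.05 is a typical cell-line RNA-seq value and is exposed in
  the config), per-sample size factors uniform on [0.7, 1.4], a planted
  log2 effect for the enriched (and optionally depleted) gene fraction.
* **Spots**: per-cell clouds with uniform base z over a configurable band
  of the slab (default the full height, 12.6 µm — a differentiated
  monolayer's thickness), Gaussian localization noise, translation by the
  planted shift, and reject-and-resample at the slab boundaries (clamping
  would pile mass at the boundary and bias means). Choosing a band inset
  by |shift| + 3·noise keeps the translated law un-clipped so the planted
  shift equals the true mean displacement. Control and targets occupy
  different cells, as in reporter experiments.
* **UTRs**: background bases are pyrimidine with probability 0.3 (low
  enough that spurious elements arise in < 5% of clean sequences at the
  default lengths); planted elements are solid pyrimidine runs (default
  length 12) with one purine window on each side so their boundaries are
  unambiguous.
* **LR matrices**: entry (g, d) = offset_d + scale_d · (effect_g + noise),
  with an optional missing-at-random mask.
* **qPCR**: reference transcript with equal expected Ct in both
  fractions; the reporter's neurite Ct offset encodes the planted LR;
  Gaussian cycle noise per replicate.

What passing on synthetic data does **not** show: real fraction libraries
have trended dispersions, compositional effects, and batch structure that
the constant-α generator omits; real spot clouds have within-cell spatial
correlation and segmentation errors; real UTR backgrounds are not i.i.d.
The tests establish that the implementations compute their statistics
correctly and recover planted signal under the stated models — not that
those models capture every property of the original data.

## Numerical choices and degenerate inputs

* Dispersion bounds [1e-8, 10]; prior fitting falls back to a single
  shared value when the across-gene spread of q̂ is within sampling noise.
* The inverse-trigamma solve uses Newton iteration from the standard
  asymptotic start; 80 iterations cap (converges in < 10).
* Rank-sum: exact only without ties; identical samples return p = 1.
* Empty spot tables, zero-cell configs, and empty post-filter gene sets
  raise typed errors (`ConfigurationError` / `InputError`) that the CLI
  maps to exit code 1.
* Workflows write a verbatim YAML copy of their configuration and a JSON
  report into every output directory; reruns on identical inputs are
  byte-identical.

## Problem sizes

The test suite and the acceptance script run at desk scale by design:
5,000–10,000 genes with 3 + 3 replicates for enrichment recovery and
calibration, 20 cells × 200 spots for smFISH recovery, 1,000 replicates
for p-value uniformity, 2,000 genes × 8 datasets for the correlation
recovery. These sizes give sampling error comfortably inside each check's
tolerance while keeping the full suite under a minute.
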