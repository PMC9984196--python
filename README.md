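# rnaloc

Analysis toolkit for **subcellular RNA localization**: where transcripts sit
within polarized cells, which 5′ UTR elements send them there, and whether
the same transcripts localize the same way in very different cell shapes.

It is written for molecular biologists and computational groups working with
three complementary data types:

1. **Fraction-enrichment RNA-seq counts** — proximity-labeling pulldown vs
   input, apical vs basal pulldowns of epithelial monolayers, or neurite vs
   soma fractions of mechanically fractionated neurons;
2. **5′ UTR sequences** — scanned for pyrimidine-rich regulatory elements
   (PRREs), the 5′ TOP / PRTE motifs characteristic of ribosomal-protein
   mRNAs;
3. **smFISH spot coordinates** — per-cell summaries of transcript positions
   along the apicobasal axis and neurite/soma puncta ratios.

A first-class synthetic-data module generates every input with known ground
truth, so the full pipeline is testable without any sequencing or imaging
downloads.

## The statistics at the core

**Localization bias.** For a fraction pair (numerator *N*, denominator *D*)
and gene *g*, the bias is

```
bias_g = log2( mean_s∈N (k_gs / f_s)  /  mean_s∈D (k_gs / f_s) )
```

with `f_s` the median-of-ratios size factor of sample *s*. The same formula
houses the Cytoplasmic Bias (pulldown/input), Apical Bias (apical/basal) and
neuronal Localization Ratio LR (neurite/soma). Genes need ≥ 10 counts in
some sample to be tested. Significance comes from a Wald test under the
negative-binomial model Var = μ + αμ², with the per-gene dispersion
moderated toward a global prior (empirical Bayes, no trend) and a
t reference whose degrees of freedom include the prior weight; p-values are
Benjamini–Hochberg adjusted.

**PRRE scanning.** A 10-nt window qualifies if it holds ≥ 9 pyrimidines
(C/T/U); overlapping or book-ended qualifying windows merge into one
element. An element starting at UTR position 1 is a 5′ TOP motif, anything
downstream a PRTE. The mutant rule C→A, T/U→G erases every element.

**smFISH positions.** Per (cell, target), the mean spot z is reported
relative to the experiment-wide median z of a non-localized control
transcript (untagged Firefly luciferase); cells — not spots — are the unit
for the two-sided Wilcoxon rank-sum comparisons (exact for combined n ≤ 30
without ties).

**LRz.** Pooling many fractionation datasets: LR values are z-normalized
within each dataset, and a gene's LRz is the median of its z-scores across
datasets — per-dataset affine distortions cancel exactly. Cross-cell-type
agreement is a Spearman correlation between a bias table and LRz through a
two-column ortholog map.

## Worked example

```python
import rnaloc as rl

config = rl.EnrichmentSimConfig(
    n_genes=5000, n_replicates=3, dispersion=0.05,
    enriched_fraction=0.10, effect_log2fc=2.0, seed=1,
)
counts, truth = rl.generate_enrichment_counts(config, design=("pulldown", "input"))
bias = rl.compute_bias(counts, "pulldown", "input", min_count=10)

merged = bias.merge(truth, on="gene_id")
enriched = merged[merged.label == "enriched"]
print(enriched["bias"].mean(), (enriched["fdr"] < 0.05).mean())
```

Running `python examples/01_enrichment_bias.py` (this script with
reporting) prints:

```
genes tested after the 10-count filter: 5000
mean estimated bias of planted-enriched genes: 1.919 (planted: 2.0)
power at FDR < 0.05: 1.000
false positives among null genes at FDR < 0.05: 40
```

The mean estimated bias sits close to the planted log2 fold change of 2
(the small shortfall is the expected median-of-ratios shift when 10% of
genes are enriched in one direction); every planted gene is recovered at
FDR < 0.05, and false positives among the 4,500 null genes stay near the
nominal rate. The other scripts in `examples/` walk through the PRRE
scanner, the dual spliced/unspliced transcriptome builder, smFISH position
summaries, the LRz meta-statistic and the cross-compartment correlation,
each printing the numbers it computes and what they mean.

## Command line

A thin CLI wraps the library for shell pipelines:

```
rnaloc simulate --kind counts --seed 1
rnaloc bias --counts sim_counts.tsv --samples sim_samples.tsv --metric CB
rnaloc scan --fasta utrs.fasta
rnaloc zpos --spots spots.csv --control Fluc
rnaloc lrz --lr-matrix lr.tsv
rnaloc correlate --bias bias_CB.tsv --lrz lrz.tsv --gene-map orthologs.tsv
rnaloc qpcr-lr --ct ct.csv
rnaloc run-all --config run.yaml
```

Exit codes: 0 ok, 1 user error, 2 internal error. Every workflow writes a
verbatim copy of its configuration and a JSON report into the output
directory.

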