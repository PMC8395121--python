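# degconcord

Cross-platform differential-expression concordance and transient
time-course dynamics for altered-gravity transcriptomics.

## The problem

Short exposures to hyper- or microgravity trigger fast, largely transient
transcriptional responses in immune cells.  Because each altered-gravity
experiment is an endpoint measurement, a time course has to be assembled
across campaigns — and across measurement technologies, since older data
sets were recorded on microarrays while newer ones use RNA-Seq.  Any such
meta-analysis must first answer: when the same RNA is profiled on both
platforms, how well do the per-gene differential-expression (DE) calls
agree, where do they disagree, and at which level of aggregation (single
genes, biotypes, chromosomes, gene sets) does the agreement become robust?

`degconcord` implements that comparison pipeline for people doing
cross-platform DE meta-analyses.  It consumes per-gene DE result tables
(gene id, log2 fold change, raw and BH-adjusted p-value, chromosome,
biotype, optional ranking statistic — the output of DESeq2, limma and
friends), never raw reads or CEL files.

## What it computes

* **Regulation calls** — UP iff adjusted p < α and log2FC > 0, DOWN iff
  adjusted p < α and log2FC < 0 (α = 0.05), NS otherwise, UNOBSERVED when
  the adjusted p is missing.
* **Directional overlap** — upset-style intersection counts between two
  platforms that expose contradictions (UP on one, DOWN on the other),
  which Venn diagrams cannot.
* **Set-inclusion sweep** — one platform fixed at α = 0.05 while the
  other's cutoff is halved stepwise (0.05, 0.025, …, 0.003125 after four
  halvings); overlap counts are reported as frequencies of the swept set.
* **Spearman ρ** of paired log2 fold changes; **consensus DEG sets**
  (significant with the same sign on both platforms) and top-N tables by
  average log2FC; gene-level **differential-exon-usage overlap**.
* **Biotype composition** of up/down DEGs, after dropping biotypes with
  fewer than 20 occurrences in the whole table.
* **Chromosomal enrichment** — expected DEG counts per chromosome under a
  random distribution, E[n_deg(c)] = N_deg · n_obs(c)/N_obs, plus two
  Fisher exact test families per chromosome (total DEG count; up/down
  ratio), each BH-adjusted across chromosomes and starred at adjusted
  p < 0.05 (\*) / < 0.01 (\*\*).
* **Trajectory flows** over three time points: each gene gets a label
  (c1, c2, c3) ∈ {U, D, N}³, counted hierarchically into 3/9/27 groups,
  with adaptation fractions (initially regulated genes that no longer
  carry their initial call later) and persistence fractions.
* **Pre-ranked GSEA** — weighted Kolmogorov–Smirnov-style running sum
  ES ∈ [−1, 1], gene-permutation null, NES = ES / mean |ES_perm| over
  same-sign permutations, BH-FDR over sets, and a cross-platform NES
  comparison classifying shared significant sets as concordant or
  contradictory.
* **Statistical primitives** — BH step-up FDR, two-sided Fisher exact test
  by point-probability summation, quantile normalization and Tukey median
  polish (the RMA-style summarization whose fold-change compression
  explains much of the microarray/RNA-Seq discrepancy for upregulated
  genes).
* **A synthetic-data generator** with planted ground truth: a Markov chain
  over {U, D, N} across three time points, shared latent effects observed
  by both platforms with microarray attenuation, shift and upregulated-gene
  dropout, planted chromosome enrichment and planted gene sets — so every
  stage is testable end to end without downloads.

## Worked example

```python
import dataclasses
import degconcord as dc
from degconcord.synthetic import SyntheticConfig, simulate_paired_study, true_calls

cfg = dataclasses.replace(SyntheticConfig(), n_genes=3000, seed=1, n_gene_sets=0)
study = simulate_paired_study(cfg)
rna, micro = study.table("rnaseq", 3), study.table("microarray", 3)

calls_rna = dc.classify_regulation(rna)
calls_micro = dc.classify_regulation(micro)
print("RNA-Seq t3 calls:   ", calls_rna.counts())
print("Microarray t3 calls:", calls_micro.counts())

ov = dc.directional_overlap(calls_rna, calls_micro)
print(f"both_down={ov.both_down}  "
      f"contradictory={ov.contradictory_AupBdown + ov.contradictory_AdownBup}")

curve = dc.inclusion_sweep(rna, micro)
print("sweep frequencies:", [round(f, 3) for f in curve.rows["frequency"]])

adapt = dc.adaptation_fraction(true_calls(study.truth, 1), true_calls(study.truth, 3))
print(f"adaptation t1->t3: {adapt.fraction_pct}% of {adapt.n_initially_altered} genes")
```

prints

```
RNA-Seq t3 calls:    {'UP': 7, 'DOWN': 191, 'NS': 2802, 'UNOBSERVED': 0}
Microarray t3 calls: {'UP': 12, 'DOWN': 135, 'NS': 2853, 'UNOBSERVED': 0}
both_down=132  contradictory=0
sweep frequencies: [0.898, 0.953, 0.964, 0.97, 1.0]
adaptation t1->t3: 100.0% of 170 genes
```

Read: at the third time point the (more sensitive) RNA-Seq table calls 198
DEGs against the microarray's 147, dominated by downregulation; 132 genes
are significant and downregulated on both platforms with zero direction
contradictions; as the microarray cutoff is halved down to 0.003125 its
surviving DEGs are increasingly contained in the RNA-Seq set (89.8% →
100%); and every gene regulated at the first time point has lost its
initial call by the third — the transient-response design of the
generator's default Markov chain.

The same operations are available as a CLI (`degconcord simulate |
classify | overlap | sweep | consensus | deu-overlap | biotype |
chrom-enrich | dynamics | gsea | gsea-compare | replay`); `replay` chains
every stage on a simulated study and writes a TSV + JSON bundle with a
provenance record.

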