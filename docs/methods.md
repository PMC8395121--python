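# Methods

This note documents the models, conventions and numerical choices behind
`degconcord`, and what the synthetic-data experiments do and do not show.

## Regulation calls and universe bookkeeping

A gene's call is derived solely from its BH-adjusted p-value and the sign
of its log2 fold change: UP iff adj p < α and log2FC > 0, DOWN iff
adj p < α and log2FC < 0, with α = 0.05 by default.  Both inequalities are
strict: a gene at exactly adj p = α, or with log2FC exactly 0, is NS.
This is the conservative reading of call definitions that leave equality
unassigned, and it makes the UP/DOWN/NS partition unambiguous.

A missing adjusted p-value marks a gene as UNOBSERVED — present in the
table but excluded from every significance count.  Genes absent from one
table of a pair are UNOBSERVED there; all pairwise operations run over the
union universe.  Joins are by exact (whitespace-trimmed, case-sensitive)
gene id; symbol aliasing is out of scope, as the package assumes tables
already keyed by a stable identifier such as Ensembl gene ids.

"Detected in the other data set" has two senses that the literature mixes
freely: significant in any direction, or significant with matching
direction.  `DirectionalOverlap` exposes both (`fraction_*_any`,
`fraction_*_same`) rather than choosing.

## Set-inclusion sweep

One platform's cutoff stays at α; the other's is α/2^k for k = 0..4 by
default, i.e. 0.05, 0.025, 0.0125, 0.00625, 0.003125 — the last value is
the 0.0031 endpoint at the precision such schedules are quoted at.
Frequencies are overlap counts divided by the swept set's size, so a
rising curve means the stricter survivors are increasingly contained in
the other platform's significant set.

## Statistical primitives

**BH adjustment** is the textbook step-up: adjusted_(i) = min over j ≥ i
of min(1, p_(j)·m/j) on the sorted scale, with missing values passed
through and excluded from m.  Adjustment is always applied within one
declared test family, never pooled across families (the two chromosome
test families are adjusted separately).

**Fisher exact test** (two-sided) sums hypergeometric point probabilities
≤ that of the observed table over all tables with the same margins — the
convention of mainstream scientific libraries, against which it is
cross-checked in the tests.  Point probabilities are compared with
relative tolerance 1e-7 so exactly-tied tables are not dropped by float
rounding.  A zero row or column margin is degenerate (nothing to test)
and returns p = 1.  Probabilities come from a vectorized gammaln-based
log-pmf, which keeps the ~50 tests per enrichment run at sub-millisecond
cost.

**Quantile normalization** maps every column onto the per-rank mean of the
sorted columns, preserving within-column rank order; ties within a column
receive the mean of the target values across the tied ranks.  Note a
subtlety: with that tie rule the operation is exactly idempotent only for
tie-free input (tie-averaging perturbs a column's value multiset); with
ties the second pass moves values by at most the tie-averaging spread.
The tests assert exact idempotence on tie-free data and bounded drift with
ties.

**Median polish** is Tukey's alternating row/column median sweep, rows
first, default max_iter = 10 and tol = 1e-6 on the change in the sum of
absolute residuals (the common convention for this summarization; the
decomposition overall + row + col + residual reconstructs the input to
machine precision by construction).  `rma_summarize` chains quantile
normalization over probe columns with a per-gene median polish and returns
overall + sample effects — a deliberately simplified stand-in for full RMA
(no convolution background correction), sufficient to demonstrate the
distribution-narrowing behaviour: when one condition carries a heavy
one-sided tail of effects, forcing all samples onto a common distribution
compresses the tail's fold changes, which the test suite verifies as a
strictly smaller IQR of estimated effects.

## Chromosomal enrichment

Counts are restricted to observable genes (adjusted p present) with a
chromosome annotation.  Expected totals spread the global DEG count
proportionally to each chromosome's share of observable genes; expected
up-counts split each chromosome's observed DEG count by the global
up:down ratio.  Family 1 tests each chromosome's DEG count against the
rest of the observable universe; family 2 tests its up:down ratio against
the complement (the complement form keeps the two margins independent).
Stars come from the FDR-adjusted p-values — adjust first, threshold at
0.05/0.01 after.  Chromosomes are reported in natural order 1..22, X, Y,
MT; unannotated contigs are excluded from testing by default and can be
grouped as "other" with a flag.  Chromosomes with zero observable genes
are dropped with a warning record.

## Trajectory dynamics

Each gene observed (not UNOBSERVED) at all three time points gets a label
(c1, c2, c3) over {U, D, N}; unobserved genes are excluded and counted,
never imputed.  "Adaptation" of an initially regulated gene means its
later call differs from the initial one — reverted to N *or* reversed —
because a transient response can end in counter-regulation rather than
baseline; pure reversion is reported separately (`reverted_pct`).
Fractions are printed as percentages truncated to one decimal, matching
how such ratios are conventionally quoted (116/1058 → 10.9).  The
operation is platform-agnostic: the caller decides which platform (or
which consensus) supplies each time point's calls.

## Pre-ranked GSEA

Genes are ordered by descending ranking statistic (stable tie-break by
gene id so results are reproducible).  For a set of k genes among N, the
running sum rises by |stat|^w / Σ_hits |stat|^w at hits and falls by
1/(N−k) at misses; ES is the signed extremum (computed from hit positions
only, which makes the permutation loop cheap).  An exact |max| = |min|
tie resolves to the positive extremum.  Default weight w = 1; at w = 0
the increments are uniform and p-values are invariant to monotone
transformations of the statistic.

The null is gene-label permutation preserving set size (only per-gene
statistics are available to a table-level pipeline, so phenotype
permutation is not an option).  Null ES samples are cached per set size.
nominal_p = (1 + #{|ES_perm| ≥ |ES|, same sign}) / (1 + #{same-sign
perms}); NES = ES / mean |ES_perm| over same-sign permutations; BH over
the emitted sets.  Defaults: 1000 permutations, set size bounds 3/5000 —
artifact choices, exposed as parameters.

## Synthetic-data generator

The generator's defaults are the study conditions the analyses assume:

* **States.** 20,000 genes; initial state probabilities (U, D, N) =
  (0.049, 0.004, 0.947) — a ~5% immediate response dominated by
  upregulation.  Transition t1→t2 keeps a regulated state with probability
  0.89 (no direct reversal) while a delayed pool switches on from N (N→U
  0.185, N→D 0.183).  Transition t2→t3 is fully transient: U→(D 0.33,
  N 0.67), D→N, N→N.  Under this design no gene can carry its initial call
  at the third time point, so the t1→t3 adaptation fraction is exactly
  100% in the noise-free call mode — the structural version of the
  headline transience finding.
* **Effects.** True log2 effects are 0 for N and sign-truncated normals
  otherwise: mean 1.0 (up) / −1.5 (down), sd 0.5 — a downregulation-skewed
  fold-change distribution.  Truncation at zero prevents sign
  contradictions between state and effect.
* **Platforms.** RNA-Seq observes δ + ε with SE 0.15; the microarray
  observes 0.7·δ + 0.1 + ε with SE 0.25 (fold-change attenuation and
  shift), and a truly upregulated gene drops out of the microarray
  (missing adjusted p) with probability 0.3 — emulating the weaker
  microarray sensitivity for upregulated genes.  z = logFC/SE gives
  two-sided normal p-values, BH-adjusted within each table (dropout is
  applied before adjustment).  A `shared_noise` flag reuses the same
  standardized noise for both platforms, the degenerate mode in which
  attenuation 1 / shift 0 / equal SEs make the two platforms' tables
  identical.
* **Annotation.** Chromosomes follow approximate human per-chromosome gene
  counts; one chromosome (default 19) has its DEG odds multiplied by 3 to
  plant an enrichment.  Biotypes are drawn i.i.d. (protein_coding 0.76,
  lncRNA 0.14, …).
* **Gene sets.** Random sets of size 10–60; planted sets sample only from
  true-U genes at t1.

What the generator does *not* emulate: count-level noise (negative
binomial dispersion, library-size effects), correlated genes, batch
effects, probe-sequence biases, and annotation errors.  Passing tests
therefore demonstrate the correctness and calibration of the *analysis*
under the stated generative assumptions, not the platforms' real-world
error structure.

## Calibration and recovery experiments (problem sizes)

Chosen so the whole suite runs comfortably on one CPU:

* Null chromosome calibration: 200 replicates of 20,000 genes with DEGs
  placed uniformly at a genome-wide rate of 2511/20000; a replicate is
  clean when the total-DEG test family stars no chromosome after FDR
  (BH controls the family-wise null error per family, and the discreteness
  of Fisher p-values makes the realized rate conservative).
* GSEA null calibration: 200 random sets against an i.i.d. normal ranking
  of 2,000 genes, 1000 permutations.
* Attenuation recovery: 5,000 genes, attenuation 0.6.  The estimator is
  the rank-free regression of microarray on RNA-Seq log2FC over the true
  DEGs of *all three* time points (the delayed t2 pool contributes ~40% of
  genes, against ~5% at t1), with the regressor's known noise variance
  subtracted from its empirical variance — a standard errors-in-variables
  correction without which the slope is biased low by a few percent.
* Planted GSEA power: 50 replicates, 2,000 genes, 20 sets of which one is
  planted, 1000 permutations (the permutation-p floor must clear the BH
  threshold across 20 sets, which needs ≥ a few hundred permutations).
* Markov trajectory recovery: 10,000 genes in call-direct mode; empirical
  27-category frequencies against the product-chain probabilities within
  3 binomial standard errors.

## Known limitations

* The RMA-style operation is a two-step simplification (no background
  correction, no probe-level variance weighting); it supports the
  distributional argument, not production microarray preprocessing.
* The Fisher up:down family uses the complement-of-chromosome comparison
  group; with very few regulated genes its discrete p-values are strongly
  conservative.
* GSEA uses plain permutation p-values, not a multilevel split-ES
  approximation, so very small p-values are floor-limited at
  1/(n_perm + 1).
* Transcripts mapping to multiple genes are out of scope: tables are
  assumed to carry one row per gene.
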