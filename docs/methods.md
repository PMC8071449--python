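# Methods

This note records the statistical models behind `nbstates`, the parameter
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions that make results
reproducible.

## Normalization

Size factors use the median-of-ratios estimator: for sample *j*,
`s_j = median over eligible genes g of c_gj / geomean_g`, where `geomean_g`
is the geometric mean of gene *g* across samples and eligible genes have a
nonzero count in every sample. For sparse single-cell matrices, where no
gene may be positive everywhere, `positive_geomean_fallback=True` computes
each gene's geometric mean over its positive entries and takes the
per-sample median over positive-count ratios only.

Two properties worth stating precisely:

- The estimator is equivariant up to a common rescaling: multiplying one
  sample's column by *c* multiplies that sample's factor *relative to the
  others* by *c* and leaves all other factor *ratios* unchanged. Absolute
  factors all shift, because the geometric-mean reference includes the
  scaled sample (for two samples with `sample2 = 2 × sample1` the factors
  are `(1/√2, √2)`, not `(1, 2)`). Only ratios matter to any downstream
  quantity.
- Re-estimating size factors on noiseless proportional data after
  normalization returns factors of 1 (idempotence).

## Differential expression

Counts are modeled as negative binomial with variance `μ + αμ²`. For a
two-group comparison (reference A vs clone B):

1. Group means `μ̂_A, μ̂_B` are taken on normalized counts; genes whose raw
   total across the compared samples is below `min_total_count` (default 10)
   are removed first.
2. A per-gene dispersion is estimated by method of moments from the pooled
   within-group sum of squares, floored at 1e-8 and capped at 10, then
   **moderated**: `α̃_g = (d_g α̂_g + d₀ ᾱ) / (d_g + d₀)` with
   `d_g = n_A + n_B − 2`, prior weight `d₀ = 20`, and ᾱ the 10%-trimmed mean
   of the per-gene estimates.
3. `log2FC = log2((μ̂_B + ε)/(μ̂_A + ε))` with
   `ε = pseudo_fraction · (μ̂_A + μ̂_B + 1)` (default `pseudo_fraction`
   1e-3). The pseudo-count keeps fold changes finite for knockout genes
   with an all-zero group; such genes are flagged `zero_in_group` and still
   yield a large finite `|log2FC|`.
4. The standard error comes from the delta method on the log-ratio under
   the NB variance model (including the per-sample `1/s_j` Poisson term),
   the statistic is `W = log2FC / SE`, and the two-sided p-value is taken
   from a t distribution with `d_g + d₀` degrees of freedom.
5. BH adjustment runs over the tested genes; the DE call is
   `|log2FC| > lfc_threshold` (default 2) **and** `padj < alpha` (default
   0.01), both inequalities strict.

Why moderation and a t reference rather than raw per-gene dispersions with a
normal p-value: with two or three replicates per group — the regime this
package targets — a per-gene variance estimate has ~2–4 degrees of freedom.
Treating the resulting statistic as standard normal is badly
anticonservative (observed type-I error ≈ 0.11 at nominal 0.05 in our
simulations), while referring it to a t with `n−2` df restores calibration
but costs roughly half of the power at 16-fold planted changes. Sharing
dispersion information across genes in the empirical-Bayes style of limma
and DESeq2, with the augmented degrees of freedom, achieves both nominal
type-I error (~0.05) and full sensitivity in the same simulations. The test
is deliberately simpler than DESeq2 — no trended dispersion prior, no LFC
shrinkage, no Cook's-distance outlier handling, no independent filtering —
so its numbers will not match DESeq2 bit for bit; the downstream stages
consume only the fold change, the statistic, and the FDR calls.

DE lists from multiple clone-vs-parental comparisons are intersected per
direction; the full Venn-region counts are also returned. When a panel
contains a clone expected to respond in the opposite direction (an
overexpressor), it should be excluded from the intersection
(`intersect_groups` in the pipeline config).

## Pre-ranked GSEA

Genes are ranked by the DE statistic, by default by its absolute value so
that gene sets populated by strongly regulated genes of either sign score
highly; a signed ranking is also available. Ties break lexicographically by
gene symbol for reproducibility. The enrichment score is the classic
weighted Kolmogorov–Smirnov running sum with weight exponent `p = 1`: hits
advance the sum by `|score|^p / Σ_hits |score|^p`, misses retreat by
`1/(N − N_hits)`, and ES is the signed maximum deviation. The leading edge
is the set of hits at or before the positive extremum (at or after, for
negative ES).

Significance uses a gene-label permutation null: `n_perm` random same-sized
sets are placed on the observed ranking (null scores are shared across sets
of equal size and drawn once per size from the seeded generator).
`p = (1 + #{same-sign null with |ES*| ≥ |ES|}) / (1 + #{same-sign null})`,
so the attainable floor is `1/(n_perm+1)`; `NES = ES / mean |same-sign null
ES|`; BH runs across sets. Sets are filtered to an overlap of
`[min_size, max_size] = [5, 500]` with the ranked universe. This is a
deterministic, desk-scale alternative to adaptive multilevel p-value
schemes; p-values below the floor are simply reported at the floor.

## ADRN/MES signature scores

Within one sample, each gene's score is its rank percentile among all genes
of the matrix: ascending ranks, average ranks for ties, divided by N (not
N−1), so the top gene scores 1.0 and an all-tied column scores
`(N+1)/(2N)`. A signature's score is the mean gene score over its members
present in the matrix (at least half must be present; the count used is
reported). Scores therefore depend only on within-sample ranks: any
strictly increasing per-sample transform — including normalization — leaves
them unchanged. Higher expression maps to a higher percentile, so a clone
shifted toward the mesenchymal program has a higher MES score. Per-clone
medians accompany the per-sample table.

## Lineage mapping

Reference gene symbols are renamed to the analysis species through a
two-column ortholog map, or by case-normalized identity (`Yap1 → YAP1`)
when no map is given; symbols mapping many-to-one are dropped and counted.
Both matrices are median-of-ratios normalized, `log2(x+1)`-transformed by
default (a `use_log=False` flag preserves the untransformed reading), and a
clone's profile is the mean over its replicate columns. Pearson r is then
computed between each clone profile and each cell over the shared genes;
the log transform prevents a handful of very high-count genes from
dominating the correlation. Genes constant across all clone profiles or
across all reference cells carry no information and are removed (with a
count); any pair left with a zero-variance vector is reported as undefined
rather than given a number.

Per-cell-type mean correlations are arithmetic means over the annotated
cells, reported in developmental order. Mutual exclusivity between two
genes is tested on binarized expression (expressed ⇔ count > 0, a rule
unchanged by normalization since size factors preserve zeros): the 2×2 cell
count table goes into Fisher's exact test (two-sided probability-mass
rule), with odds ratio < 1 read as exclusive. The sample odds ratio gets
Haldane 0.5 continuity only when a cell of the table is zero, and only for
the reported OR, never for the p-value; a zero margin yields p = 1 and an
undefined OR. An alternative contingency — gene on/off versus membership in
one cell type — is provided for asking whether a gene is enriched or
depleted in, say, Schwann cell precursors.

Hierarchical clustering of the cell × clone correlation matrix uses
Manhattan (L1) distance with complete linkage by default (average and
single are exposed); complete linkage is monotone, so merge heights never
decrease and flat cuts are well defined. Dendrograms are exported as
Newick text.

## Synthetic study designs

`default_bulk_scenario` emulates the clone-panel design: one parental line,
five knockout clones and one overexpressing clone, two biological
replicates each, 2 000 genes. Counts are NB with a single shared dispersion
α = 0.05 (typical for biological replicates of a cell line) and baseline
log2 means uniform on (3, 11), giving the wide dynamic range that
rank-percentile scoring assumes. Planted programs: the knocked-out receptor
(mean forced to zero in KO clones, up in the overexpressor), AXL-like and
YAP1-like partners up 8-fold in KO clones and down in the overexpressor, a
60-gene mesenchymal program up 8-fold in KO clones and down in the
overexpressor, a 60-gene adrenergic program moving oppositely, a 300-gene
SCP program up 16-fold in KO clones, and a 300-gene committed
(chromaffin-like) program down in KO clones and up in the overexpressor.
Truth tables list every planted (gene, group) effect exactly once
(knockouts as −inf).

`default_single_cell_scenario` emulates a four-population labeled reference
(100 cells per type): NB counts with dispersion 0.4 and 20% extra dropout
(plausible for plate-based single-cell data), baseline log2 means on (1, 6).
Population marker programs are 300 genes each, elevated 32-fold; the bridge
population shares 60% of the SCP markers and sympathoblasts 30%, encoding
the developmental ordering, while chromaffin markers are disjoint.
Mutual-exclusivity pairs are modeled with explicit per-type Bernoulli
on/off states (on-cells draw `1 + NB`, so the expressed fraction equals the
on-probability exactly): the receptor is on in 17% of SCPs but 85% of
committed cells, its AXL-like partner on in 85% of SCPs, the YAP1-like
partner in 79%, with the pattern mirror-reversed in committed populations
and balanced (50%) in bridge cells.

Two design choices tie the bulk and single-cell generators together. Both
draw their per-gene baseline quantiles from the same seed-keyed
"gene-universe" stream, because correlation mapping in real data rides on
the conservation of relative expression levels between a bulk panel and a
reference atlas; an independent per-gene log2 jitter (sd 1.5) on the
reference side keeps that conservation imperfect. Marker strengths and
sizes were set so that the between-type spread of mean clone–cell
correlations (≈0.45 down to ≈0.05 along SCP → bridge → sympathoblast →
chromaffin for a KO clone) has the same order of magnitude as published
analyses of this design report, and so that the planted types are
recoverable from the correlation map by the package's own clustering.

All randomness flows from one scenario seed through named `SeedSequence`
sub-streams (gene universe, bulk counts, reference counts, reference
jitter, GSEA permutations), so bulk and single-cell halves regenerate
independently and every run is byte-reproducible.

What the generator does **not** emulate: sequencing-depth trends in
dispersion, batch effects, UMI or read-level noise, correlated gene
modules beyond the planted programs, ambient contamination, or doublets.
Passing tests therefore demonstrate the correctness and calibration of the
statistical machinery on its own generative model, not performance on any
particular real dataset.

## Numerical conventions and degenerate inputs

- Strict inequalities at DE thresholds; a gene at exactly `log2FC = 2` or
  `padj = 0.01` is not called.
- Identical group means give `W = 0`, `p = 1` exactly.
- Ranking ties break lexicographically; rank ties within a sample use
  average ranks; an all-constant expression column scores `(N+1)/(2N)`
  everywhere and emits a warning.
- A gene set covering the whole ranked universe, or missing from it
  entirely, is skipped and reported, not scored.
- Permutation p-values are floored at `1/(n_perm+1)`; `n_perm ≥ 100` is
  enforced.
- MatrixMarket input must be 1-based; an explicit 0 index is rejected.
- The pipeline aborts on the first stage error, names the stage, and
  removes the partial run directory; manifests are written atomically.

## Scale of the shipped simulations

The test suite and the acceptance script run the full design at 2 000
genes, 14 bulk samples and 400 reference cells, with 200–1 000 GSEA
permutations and 5–10 seed replicates per property — sizes chosen so the
entire suite completes in well under a minute per module while leaving the
Monte-Carlo margins of the calibration checks (type-I error in
[0.03, 0.07], ARI ≥ 0.8, exclusivity p < 1e-6) comfortably wide.

## Known limitations

- The DE test is two-group only: no covariates, likelihood-ratio tests, or
  multi-factor designs.
- No attempt at DESeq2 or fgsea numerical parity (see above).
- Signature scoring does not re-derive signature gene lists; they are
  inputs (a small built-in demo pair of canonical ADRN/MES markers ships
  for examples and tests).
- The single-cell reference's labels are taken as given; the package does
  not cluster or re-annotate the reference itself, and no pseudotime is
  inferred.
- Exclusivity testing treats cells as independent; within-type correlation
  structure would make the Fisher p-value optimistic on real data.
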