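# Methods

This note records the statistical model behind each stage of `mirpath`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the design choices made where the
procedure was genuinely open.

## Differential miRNA calling

Paired profiles carry one ΔCt vector per fraction (test = stem-enriched,
reference = bulk), in cycles; lower ΔCt means earlier amplification,
i.e. higher expression. The package accepts pre-normalized ΔCt, and
`delta_ct_from_controls` offers mean-of-controls normalization for cards
that include control assays — the aggregation across multiple controls
is a package choice (arithmetic mean of their Ct), since card layouts
vary.

Relative quantification: ΔΔCt = ΔCt(test) − ΔCt(reference), fold change
2^−ΔΔCt, and the log2 differential expression Δx = −ΔΔCt. The sign
convention (positive Δx = up in the test fraction) follows from
higher expression ⇒ lower Ct.

Calling rules, with defaults:

- a cell line is DE for a miRNA iff the readout exists and |Δx| ≥
  log2(`fold_threshold`); `fold_threshold` = 2.0;
- a miRNA is a DEmiR iff DE in ≥ `min_de_lines` (1) lines and missing in
  ≤ `max_missing_lines` (2) lines; a miRNA with no readout is treated as
  non-DE, never as DE;
- the signature additionally requires DE in ≥ `signature_min_lines` (4)
  of the lines. With 6 lines, a 4-line rule and a nominal 20% per-line
  DE rate, the chance for a null miRNA is the exact binomial tail
  P(X ≥ 4) ≈ 0.01696 (≈ 1/58); `signature_chance_probability` computes
  this by direct summation.

A signature DEmiR's direction is the majority sign among its DE lines;
ties are reported as "mixed". QC failure (Pearson concordance of the two
ΔCt vectors ≤ 0.75 over jointly observed miRNAs) is reported but not
fatal: the remedy is re-assaying, which software cannot do.

## Imputation and clustering

Probes with at most two blank measurements are retained for the heatmap;
remaining blanks are imputed by k-nearest neighbours (k = 3) where
neighbour similarity is the Pearson correlation over jointly observed
columns. Numerical choices the procedure leaves open: a neighbour needs
≥ 3 jointly observed columns for its correlation to count; correlation
ties break by row order (stable); a neighbour without a value in the
target column is skipped in favour of the next-nearest; a cell with no
eligible neighbour (e.g. all-constant rows, whose correlation is
undefined) falls back to the row mean and is logged.

Clustering uses dissimilarity d = 1 − Spearman ρ (so any monotone
transform of the data leaves the dendrogram unchanged) with average
linkage on both axes. A constant profile has undefined ρ; its
dissimilarity to every other profile is set to the maximum, 2.0, and
logged. Pearson similarity for imputation vs Spearman distance for
clustering is deliberate: imputation works on the raw log2 values where
linear agreement matters, ordering only needs rank agreement.

## Target-score integration

Candidate miRNA–mRNA pairs carry up to six algorithm scores. The
integration model is naive Bayes with gamma class-conditional marginals:
the per-algorithm, per-class fitting implies a factorized likelihood, and
gamma densities fit the right-skewed, positive-support shape of
prediction scores. Scores must be positive; `standardize_scores`
sign-flips negative-oriented scales and shifts columns onto positive
support, recorded per algorithm.

Fitting: maximum likelihood per algorithm per class with the location
fixed at zero, started from the method-of-moments estimate; the class
prior is the positive fraction of the training pairs (≈ 0.038 for the
929:23,319 reference split); detection rates are the observed fractions
per class. Degenerate inputs fail loudly: a single-class training set, a
zero-variance score column (named in the error), or non-positive scores.

Missing predictions are informative: an algorithm that scores validated
targets more often than negatives makes silence evidence *against* being
a target. The likelihood therefore multiplies, per algorithm, either
`detection_rate × gamma_pdf(x)` (observed) or `1 − detection_rate`
(silent). This keeps the posterior defined for every pair with at least
one observed score.

Calls use a strict posterior cutoff (> 0.6). Validated pairs enter the
scoring matrix at b = 1.0 — the natural certainty encoding for
experimental evidence — regardless of any predicted posterior; duplicate
entries resolve by max; pairs outside the declared universe are dropped,
counted and logged.

## Enrichment

With **B** (genes × miRNAs, entries in [0, 1]), Δx_j the signature-miRNA
differential expression of cell line j (missing entries contribute 0),
and **P** the set × gene indicator: g_j = **B**·|Δx_j|, s_j = **P**·g_j.
The magnitude |Δx| is the default so up- and down-regulated miRNAs
combine into one statistic; the signed variant is kept for directional
splits. Per-gene regulation is combined across cell lines by the mean
(configurable to max) before scoring.

The enrichment score is defined as fold-enrichment of mean
per-targeted-gene regulation:

ES_l = mean{ḡ_i : i targeted, i ∈ set l} / mean{ḡ_i : i targeted},

where "targeted" means nonzero b for at least one signature miRNA. This
is a ratio of means, hence scale-invariant in Δx, equal to 1 when
regulation is uniform across targeted genes, and > 1.5 only when a set's
members are systematically more heavily (or multiply) targeted than the
background — the co-targeting pattern the method is designed to surface.
Sets with no targeted member get ES = 0 with a no-signal flag. No
permutation null is used; significance comes from the coverage test.

Coverage significance is the one-sided Fisher's exact test on
[[m_l, n_l − m_l], [m_total − m_l, M − n_l − m_total + m_l]], computed
as the upper hypergeometric tail. The background universe M is all genes
of the scoring matrix (the prediction compendium's "genome"). Raw
p-values are compared against 0.01 without multiple-testing correction,
matching the three-part selection rule; selection requires coverage
strictly above 10% with ≥ 3 targeted genes, ES > 1.5 and p < 0.01. Sets
passing ES and p but failing the coverage criterion are emitted to a
secondary "near-miss" report. GO-style collections are conventionally
filtered to sets with ≥ 15 in-universe genes; pathway collections are
ingested unfiltered.

## Synthetic data

The generator reproduces the statistical structure every stage consumes,
with defaults chosen once to match the reference screen geometry:

- **Profiles**: 750 miRNAs × 6 cell lines. Reference ΔCt ~ N(6, 2.5²)
  cycles — a plausible qPCR dynamic range; purely a fixture choice. The
  30 planted DEmiRs (80% up) subtract direction × effect, effect ~
  U(1.2, 2.5) log2 units, on a consistent subset of lines: each line
  carries the effect with probability 0.9, redrawn until ≥ 4 lines do —
  modelling a genuine cross-line signature with occasional line-specific
  dropout. Null miRNAs receive independent spurious effects per line
  with probability 0.2, the nominal chance level of the binomial
  signature model. Gaussian noise (sd 0.3 cycles) is added everywhere.
  Missingness removes both fractions of a (miRNA, line) cell at rate
  0.05 — jointly, because a lowly expressed miRNA fails to amplify in
  both assays; a not-at-random mode instead drops the latest-amplifying
  cells, for robustness experiments.
- **Target map**: each planted DEmiR has 38 true target genes in a
  20,000-gene universe (human protein-coding scale; the resulting ~5%
  background targeted density leaves planted sets a large margin). A
  pool of "hub" genes is co-targeted by 3 distinct planted up-DEmiRs
  each — the multi-miRNA convergence onto pathway genes that the
  ratio-of-means ES detects; remaining target slots are filled with
  non-hub genes. 5% of true pairs are marked validated. Null miRNAs
  have no true targets.
- **Scores**: positives draw Gamma(3, 2) per algorithm, negatives
  Gamma(1, 1), detection rates 0.85 vs 0.5 — separations under which
  concordant evidence from a few algorithms overcomes the 0.038 prior
  while single-algorithm flukes do not. The training split is
  929:23,319; the candidate pool adds 380 false pairs per queried miRNA
  (≈ 10:1 against its 38 true targets).
- **Gene sets**: 5 planted sets (sizes 20–60) take 25% of their members
  from the hub pool, disjointly across sets, and the rest from
  never-targeted genes, so planted coverage is controlled; 50 background
  sets draw uniformly from the universe.

All three generators run from independent child streams of one seed;
identical seeds give byte-identical output files. The generator does
*not* emulate several properties of real data: probe-level technical
replicates and card batch effects, correlated (family-wise) miRNA
expression, miRNAs sharing targets outside the planted hubs, score
correlation between algorithms (real predictors agree far beyond
chance, which naive Bayes would over-count), or overlapping/nested gene
sets. Passing the planted-recovery suite therefore shows the pipeline's
statistical machinery is correct under its own assumptions, not that the
biological discoveries of any particular screen are reproduced.

## Problem sizes and numerical choices

The test suite and acceptance script run 20 end-to-end replicates at the
default conditions (750 miRNAs, 20,000 genes, ~24k training pairs,
~18k candidate pairs per run), sizes at which the full battery completes
in well under a minute; parameter-recovery checks use 2,000 training
scores per class. Exact-arithmetic oracles (binomial enumeration,
hypergeometric summation, naive O(n³) average linkage, closed-form
two-gamma Bayes) back the fast implementations at tolerances of 1e−10 to
1e−12. Posteriors are returned unclipped; log-likelihoods are summed in
log space to avoid underflow across six algorithms.

## Known limitations

- The ES definition (ratio of mean targeted-gene regulation) preserves
  the documented threshold semantics (ES > 0 enriched, select at
  ES > 1.5) but printed ES values from studies using an unspecified
  normalization are not comparable number-for-number.
- The naive-Bayes independence assumption over-weights concordant
  algorithms whose errors correlate; on real compendia the 0.6 cutoff
  is therefore effectively more permissive than on synthetic scores.
- The coverage criterion is applied strictly (> 10%); borderline sets at
  exactly 10.0% are excluded by design.
- KNN imputation assumes at least two observed entries per row; sparser
  rows must be filtered upstream (the ≤ 2-blank rule guarantees this for
  6-line designs).
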