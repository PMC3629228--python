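# mirpath

From differentially expressed microRNAs to the pathways they regulate.

`mirpath` implements a three-stage inference pipeline for miRNA profiling
studies that compare a stem-like (or otherwise enriched) cell fraction
against its bulk counterpart across several cell lines:

1. **Differential miRNA calling from paired qPCR profiles.** Expression is
   measured as normalized threshold cycles ΔCt; relative quantification uses
   the comparative-Ct convention ΔΔCt = ΔCt(test) − ΔCt(reference), so the
   log2 differential expression is Δx = −ΔΔCt and fold change is 2^−ΔΔCt.
   A miRNA is differentially expressed (a *DEmiR*) when |Δx| ≥ 1 (2-fold) in
   at least one cell line with at most two missing readouts, and enters the
   cross-line *signature* when it is DE in at least 4 of 6 lines — a
   fault-tolerant consistency rule whose chance level is the binomial tail
   P(X ≥ 4), X ~ Bin(6, 0.2) ≈ 0.017 ("1 in 58"). Profiles are QC'd by the
   Pearson concordance of the two fractions' ΔCt vectors (pass at r > 0.75),
   and the expression matrix can be completed by correlation-KNN imputation
   (k = 3) and ordered by average-linkage clustering under 1 − Spearman ρ.
2. **Bayesian integration of target-prediction scores.** Six prediction
   algorithms each score candidate miRNA–mRNA pairs on incompatible scales.
   With class-conditional gamma likelihoods fitted per algorithm on a
   labelled training set (validated targets vs constructed negatives,
   prior π = 929/24,248 ≈ 0.038 in the reference setting), the naive-Bayes
   posterior is

   p(y=1 | x₁…x₆) = π·∏ₐ p(xₐ|y=1) / [ π·∏ₐ p(xₐ|y=1) + (1−π)·∏ₐ p(xₐ|y=0) ],

   where an algorithm's silence contributes its class-conditional detection
   rate instead of a density. Pairs with posterior > 0.6, plus all
   experimentally validated pairs (b = 1), populate the gene × miRNA scoring
   matrix **B**.
3. **Expression-weighted gene-set enrichment.** Per cell line j, per-gene
   regulation is g_j = **B**·|Δx_j| and per-set regulation s_j = **P**·g_j
   with **P** the set × gene indicator matrix. The enrichment score of a set
   is the fold-enrichment of mean regulation among its targeted members over
   the mean across all targeted genes, and coverage significance is a
   one-sided Fisher's exact test. A set is reported when it passes all three
   criteria: coverage > 10% with ≥ 3 targeted genes, ES > 1.5, and p < 0.01.

The package is aimed at computational biologists who want this style of
miRNA→pathway analysis as a tested, scriptable library rather than a
one-off analysis. Because the original expression data and proprietary
score compendia for such studies are rarely released, `mirpath` ships a
first-class synthetic-data generator (`mirpath.simulate`) that reproduces
the statistical structure of every input — planted DEmiRs, gamma-separated
prediction scores, co-targeted pathway genes — so the whole pipeline is
exercised end-to-end against a known ground truth.

## Worked example

```python
import mirpath as mp

res = mp.run_all(mp.SimulationConfig(seed=1))
print(res.metrics)
```

Running `python examples/full_pipeline.py` prints:

```
Signature DEmiRs: 36 (sensitivity 0.93 on 30 planted; 8 false entries from 720 nulls)
Target calls: 975 predicted pairs, precision 0.999
Enriched sets selected: 5 (5/5 planted recovered, 0 unplanted)

Top selections (ES-ranked):
  PLANTED_SET_03: 6/22 genes (27%), ES=2.72, p=3.0e-04
  PLANTED_SET_01: 10/38 genes (26%), ES=2.66, p=4.2e-06
  ...
```

Reading: of 30 planted DEmiRs, 28 were recovered in the 4-of-6 signature
(93% sensitivity); 8 null miRNAs slipped in, consistent with the ≈12
expected from the 0.017 binomial chance level over 720 nulls. The
posterior > 0.6 cutoff called 975 predicted target pairs at 99.9%
precision, and all five gene sets planted with co-targeted members passed
the three selection criteria while no background set did.

The other scripts in `examples/` demonstrate each stage on its own:
`demir_calling.py`, `impute_and_cluster.py`, `target_posteriors.py`,
`enrichment_analysis.py`.

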