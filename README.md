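# mirdrugsurv

Drug-specific survival-biomarker screening for pan-cancer cohorts.

Most expression-based survival markers are discovered on all patients of a
cancer type, ignoring which drugs each patient actually received. This
package implements the opposite design: patients who share one cancer type
*and* one drug form a **cancer-drug group**, every miRNA (or gene) is
tested for survival association *within* each group, and a marker is kept
only when it is **drug-specific** — significant inside the group but not
across the cancer type as a whole. It is intended for bioinformaticians
working with TCGA-style cohorts (expression + clinical + treatment records)
who want drug-conditioned prognostic markers rather than generic ones.

## Method

1. **Binarization.** For each feature, the log-scale expression values of
   *all* patients (across all cancer types) are sorted and a one-step
   function is fitted by least squares: for each breakpoint *b* the fit is
   (mean of the first *b* values, mean of the rest), and *b* minimizes

   SSE(b) = Σ_{i≤b} (x_(i) − x̄_low)² + Σ_{i>b} (x_(i) − x̄_high)².

   The global threshold is the midpoint of the two segment means; patients
   above it form the highly-expressed class, the rest the lowly-expressed
   class.
2. **Group screen.** Cancer-drug groups need ≥ 15 patients with expression
   data; a feature is tested in a group only if both classes have ≥ 5
   patients there. The test is the standard (unweighted) log-rank:
   χ² = (Σ_t O_t − E_t)² / Σ_t V_t with hypergeometric moments at each
   distinct event time, 1 df. P-values are Benjamini–Hochberg adjusted
   within the group; markers need adjusted FDR < 0.1.
3. **Drug-specificity contrast.** The identical test is rerun on all
   patients of the marker's cancer type; the marker survives only if the
   cancer-wide adjusted value is *not* significant (≥ 0.1).
4. **Target genes.** Target genes of the surviving miRNAs (from a curated
   miRNA→target table) are screened the same way in the same group at
   FDR < 0.01; each (significant miRNA, significant target) pair in one
   group is an miRNA-mediated gene-cancer-drug combination. Its expression
   correlation (OLS of gene on miRNA, two-sided slope test, flag at
   p ≥ 0.05) and its survival-direction consistency are reported: an
   *inhibitory* pair is consistent when the miRNA and gene survival
   directions are opposite, an *activating* pair when they agree.
   Survival directions come from restricted-mean survival (area under the
   Kaplan–Meier curve over the common follow-up window).
5. **External validation.** On an independent cohort a marker is evaluated
   by splitting samples at the cohort's own median expression and running
   the log-rank test on any (time, event) endpoint (OS/DFS/DRFS).

A synthetic-cohort generator (`mirdrugsurv.simulate`) produces TCGA-like
data with planted drug-confined markers (bimodal expression mixtures whose
high/low component multiplies the exponential death hazard only inside one
cancer-drug group), inhibitory target genes, and null features, so the
whole pipeline is testable without external data.

## Worked example

Generate a synthetic cohort (1,200 patients, 3 cancer types, 3 drugs, one
planted marker with hazard ratio 4 confined to the CT1–drugA group) and run
the full pipeline:

```bash
mirdrugsurv simulate --seed 1 --out demo/cohort
# write demo/run.yaml pointing at the emitted files, then:
mirdrugsurv all --config demo/run.yaml
```

The run prints the manifest counts:

```
"groups": 9,                     # cancer-drug groups with >= 15 patients
"combinations_enumerated": 540,  # 9 groups x 60 miRNAs
"combinations_tested": 540,      # all passed the 5-low/5-high class gate
"group_significant_markers": 4,  # FDR < 0.1 within a group
"drug_specific_markers": 4,      # ... and not significant cancer-wide
"mediated_combinations": 1,
"verdict_consistent": 1
```

`demo/out/drug_specific_markers.tsv` then contains (abridged):

```
cancer_type  drug   feature_id   n_low  n_high  p_value   fdr       cancer_level_p  better_survival_class
CT1          drugA  mir-plant-1  25     23      0.000042  0.002526  0.817244        low
```

The planted marker is recovered: within its 48-patient group the log-rank p
is 4.2e-5 (group FDR 0.0025), while cancer-wide the adjusted value is 0.82,
so the association is specific to drugA-treated patients; the low class
survives better, matching the planted hazard ratio of 4 for high
expression. (Three null features reach group FDR < 0.1 as well — at FDR 0.1
across 9 groups of 60 features a few false discoveries are expected.) The
concordance table shows the planted inhibitory target:

```
mirna_id     gene_id       regulation  corr_slope  corr_p    mirna_direction  gene_direction  verdict
mir-plant-1  gene-plant-1  inhibit     -0.970      3.6e-34   low_better       high_better     consistent
```

i.e. the gene is anti-correlated with its miRNA (slope −0.97) and their
survival directions are opposite — consistent with inhibitory regulation.

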