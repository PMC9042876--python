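# Methods

This note records the statistical model the package implements, the
defaults and why they were chosen, what the synthetic cohorts do and do not
emulate, and the numerical conventions that make runs reproducible.

## The screening model

The unit of analysis is the cancer-drug group: every patient with a given
cancer type and a standardized exposure record for a given drug, provided
the group has at least `min_group_size` (default 15) patients with
expression data. A patient belongs to every group they qualify for, and
repeated records of one drug count once.

Expression is binarized by a global one-step least-squares fit per feature
(sorted values; for each breakpoint the fitted step is the pair of segment
means; the SSE-minimizing breakpoint wins, ties to the smallest
breakpoint). The threshold is the midpoint of the two segment means.
Because the fit pools all patients of all cancer types, "high" and "low"
mean the same thing in every group. Values equal to the threshold are
"low"; missing values leave a patient unclassified for that feature only.

Within a group, a feature is tested only when both classes have at least
`min_class_size` (default 5) members; otherwise the combination is
recorded as gated. Tested features get the standard unweighted log-rank
statistic (hypergeometric observed-minus-expected accumulation over
distinct event times; censored subjects at t remain at risk at t; interval
terms where one class has no subjects at risk contribute zero to all
sums). Benjamini–Hochberg adjustment is applied across the tested features
of each group (`fdr_scope="per_group"`, the default, matching per-group
reporting; `"global"` pools all groups). A group-significant feature
(FDR < `mirna_fdr`, default 0.1) is drug-specific when the identical
screen over *all* patients of the cancer type — same thresholds, same
gate, BH over all features tested cancer-wide — is not significant at the
same threshold. The cancer-wide population includes patients without drug
records; a feature gated cancer-wide counts as not significant there. A
raw-p variant of the contrast (`cancer_specificity_mode="raw"` with
`cancer_alpha`) is provided because the choice between adjusted and raw
cancer-wide values is a genuine design fork; the adjusted form is the
default so both sides of the contrast use the same threshold family.

Survival direction ("which class does better") is the comparison of
restricted-mean survival — the area under each class's Kaplan–Meier curve
up to the shorter class's last observed time — so the comparison never
extrapolates beyond common follow-up. Exact ties resolve to "low".

Target genes of drug-specific miRNAs are screened with the same machinery
in the same group, with BH across the target genes tested within that
group and a stricter cut (`gene_fdr`, default 0.01). Combination records
carry the OLS slope of gene on miRNA over the group's patients (two-sided
t-test on the slope; flagged, not dropped, at p ≥ `corr_alpha` = 0.05) and
the consistency verdict: inhibitory pairs are consistent iff the two
survival directions differ; activating pairs iff they agree; unknown
regulation yields an unknown verdict. The verdict is invariant to flipping
both directions simultaneously.

External validation deliberately does not reuse the global threshold: a
threshold learned on RNA-seq log scale is meaningless on a microarray
scale, so each validation cohort is split at its own per-feature median
(strictly above = high). Any (time, event) endpoint is accepted; the
endpoint label is metadata.

## Statistical kernel

Kaplan–Meier estimation and restricted-mean areas are delegated to
lifelines. The log-rank test is computed in-house (vectorized over event
times) because the screening result type reports the observed/expected
decomposition for the first group, which lifelines does not expose; the
test suite verifies exact agreement with lifelines' `logrank_test` on
random data, and the hot-loop restricted-mean path against lifelines'
`restricted_mean_survival_time`. BH adjustment is statsmodels'
`multipletests(method="fdr_bh")`, verified in tests against a directly
coded step-up recursion. Note the BH step-up is *not* idempotent as a map
(re-adjusting adjusted values can change them); the suite asserts
dominance, the cap at 1, and order preservation instead.

Degenerate situations are explicit: a two-group test with zero events or
zero total variance returns a flagged result with statistic 0 and p 1; a
constant (or < 2 values) feature has no valid threshold and is excluded
and logged; empty classes after a median split yield an untested
validation record.

## The synthetic cohort

`SimConfig`/`generate_cohort` emulate the statistical skeleton the screen
assumes: cancer types of equal size; per-(patient, drug) Bernoulli
exposure (so patients belong to several groups); planted marker miRNAs as
two-component Gaussian mixtures (defaults: means 2 and 6, sd 1 — four
standard deviations of separation — high fraction 0.5); null features as
unimodal Gaussians at the midpoint; survival exponential with the
marker's hazard ratio applied multiplicatively only to high-class patients
inside the marker's own cancer-drug group; independent exponential
censoring (observed time is the earlier of death and censoring); planted
inhibitory targets as decreasing affine functions of their miRNA plus
Gaussian noise (default sd 0.3–0.5), emitted as `inhibit` pairs next to
`unknown` decoy pairs. All randomness flows from one seeded generator, so
equal configurations give byte-identical written cohorts.

Defaults (`baseline_hazard` 1/500 per day ≈ 347-day median survival,
`censoring_rate` 1/2000) give roughly 80 % observed events — lighter
censoring than typical registry data, chosen so that desk-scale groups of
40–90 patients carry a measurable survival signal. What the generator does
*not* emulate: real expression distributions and batch effects, unequal
cancer-type frequencies, correlated drug regimens, competing risks, and
non-proportional hazards. Passing tests therefore demonstrate that the
pipeline's logic and calibration are correct under its own assumptions,
not that real TCGA effect sizes are recoverable.

## Benchmark scenarios (`mirdrugsurv.scenarios`)

The reference scenarios fix the study conditions the tests and the
reproduction script measure:

- **Recovery**: one drug-confined marker with hazard ratio 4 in a group of
  ~40 patients (2 % exposure within a 2,000-patient cancer), a 10-miRNA
  candidate panel, near-complete follow-up (censoring 1/20000). The panel
  is kept small because BH across hundreds of features demands raw
  p ≲ 2×10⁻⁴ — unreachable for a 40-patient group at hazard ratio 4 about
  half the time — while a focused candidate panel keeps the required raw p
  at the 10⁻² scale. The cancer is large relative to the group so the
  cancer-wide contrast stays null.
- **Null FDR**: a separate all-null group screened over 500 features
  reports the false-discovery count per 500 at FDR < 0.1.
- **End-to-end concordance**: a strongly protective marker (hazard ratio
  0.05) with one inhibitory target in a ~90-patient group inside a
  12,000-patient cancer, follow-up truncated at censoring rate 1/500. The
  truncation matters: with unbounded follow-up the cancer-wide log-rank
  reliably detects even a sub-1 % long-lived subgroup (protected patients
  dominate late at-risk sets and their eventual deaths accumulate drift),
  which would defeat the drug-specificity contrast; limited follow-up —
  a property of every real cohort — restores it.
- **Validation calibration**: 400 null cohorts of 200 samples (the size
  range of real microarray validation series; at 100 samples the χ²₁
  reference is visibly anti-conservative) measure the median-split
  log-rank's empirical type-I error at α = 0.05.

## Numerical conventions

Step-fit SSEs are computed from cumulative sums and clipped at zero;
`argmin` takes the first minimum, realizing the smallest-breakpoint tie
rule. P-values are floored at the smallest positive float. Output tables
are written with `%.6g` floats and sorted deterministically; two runs with
the same config and inputs are byte-identical apart from the manifest's
embedded paths. Sub-seeds for multi-cohort experiments come from
`numpy.random.SeedSequence.spawn`.

## Known limitations

Group-level BH is the default multiplicity scope; a cohort-wide scope is
available but interacts differently with the drug-specificity contrast.
The drug-specificity rule is a two-screen comparison, not an
interaction test, so it inherits the cancer-wide screen's power profile —
in particular, strongly protective markers in long-follow-up cohorts can
fail the contrast even when genuinely drug-confined (see the concordance
scenario note). Probe-to-feature mapping for external cohorts is the
user's responsibility; the validation module assumes ids already align.
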