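# Methods

This note documents the models, parameter choices and numerical conventions
behind `clonemark`, and what the synthetic cohorts do and do not establish
about real data.

## Problem and model

A patient contributes two or three tumor samples (esophageal T, optional
regional lymph-node metastasis LN, distant lung tumor D) plus a matched
normal. Under the metastasis hypothesis all tumors descend from one founder
clone and must share its somatic mutations (the *trunk*) and much of its
copy-number architecture; under the second-primary hypothesis D arose
independently, so T∩D mutation sharing is expected to be empty (exact-key
sharing between unrelated exomes is essentially impossible, which the
cross-patient overlap control verifies empirically) and copy-number
profiles are uncorrelated. The pipeline therefore treats mutation sharing
as the decisive statistic and everything else — B-allele-frequency
clustering, spectra, signature exposures, focal-SCNA cosine similarity —
as supporting evidence.

## Variant filtering

Thresholds (tumor/normal depth ≥ 10, tumor VAF > 10%, normal VAF < 2%,
tumor alt reads ≥ 3) are exposed in `FilterConfig`. The VAF bounds are
deliberately strict inequalities — a tumor VAF of exactly 0.10 fails — and
the boundary behavior is pinned by tests. Indels carry no tumor-VAF rule;
we require zero normal alt reads instead, a conservative stand-in for
somatic status, and represent upstream germline-indel filtering by a
caller-supplied key set. Records with zero depth in either compartment are
rejected with reason `zero_depth` rather than producing an undefined VAF.

## Partition, trees, BAF

Mutation identity is the exact tuple (chrom, pos, ref, alt); no fuzzy indel
matching, which could only manufacture spurious sharing. For two-sample
patients the pairwise intersection plays the trunk role. Trees use distinct
*gene* counts per set as edge lengths (partition counts use variant keys;
both are reported). The three pairwise branch sets of a trio need not be
tree-compatible; the pair with the largest gene count becomes the internal
clade and the remaining branch genes are folded into the terminal edges of
their member samples, preserving the invariant that the root-to-leaf path
length equals the sample's mutated-gene count. The BAF comparison is
operationalized as the fraction of the key-union observed at VAF ≥ τ in
both samples (τ = 0.05 default, configurable); the underlying visual
comparison has no published numeric rule, so the statistic is labelled an
operationalization in reports.

## Spectra and signature refitting

Spectra are strand-collapsed to the pyrimidine frame. The χ² contrast uses
the 6-class table; classes with expected count < 1 are pooled into one
"other" class to keep the asymptotic test valid on small callsets, and a
1-column table degenerates to (statistic 0, p 1). Refitting solves
min‖m − S·w‖₂, w ≥ 0 by NNLS; weights below a 6% floor (the published
default of the standard refitting tool) are zeroed and the surviving
signatures refit until stable. Because catalog columns are unit-sum, the
fitted weights sum to the explained fraction automatically; they are only
rescaled if numerical noise pushes the sum above 1.

The shipped 30-signature catalog is **synthetic**: the published reference
matrix cannot be redistributed, so `synthetic_signature_catalog()` builds a
deterministic stand-in with the same 96×30 shape in which S1 is
C>T-dominated with CpG enrichment, S4/S29 are C>A-dominated and S5 is flat
— the features the analyses and the cohort generator rely on. Any real
96×K catalog TSV can be supplied instead via `read_signature_catalog`.
SMG listing is recurrence-based (non-silently mutated in ≥ 2 patients,
optionally intersected with a known cancer-gene set) and explicitly not a
background-mutation-model test.

## Focal SCNA analysis

Windows are 1 kb, 0-based half-open; a window's value is the
length-weighted mean of overlapping segments, and uncovered windows are
missing (excluded from per-window G denominators), never zero. The
G-score folds frequency and amplitude into one number: the per-window mean
of positive (amp) or negative (del) log2 parts across samples. The
permutation scheme — independent circular shifts of each sample's vector
within each chromosome — preserves each sample's marginal distribution and
spatial autocorrelation; p-values are (1+#null ≥ obs)/(1+n_perm) per
window, calibrated to a 5% type-I rate by test. Focal regions are maximal
runs of significant windows per direction; the peak is the maximal-G window
extended while G ≥ 95% of the maximum. Recurrent regions are a cohort-level
quantity, so the pipeline calls them once across all samples and reuses the
level table for every patient. Level thresholds (0.9/0.1/−0.1/−1.3) leave
their boundary values unassigned in the printed inequalities; boundaries go
to the less extreme tier. Cosine similarity uses the numeric level vectors
(+2…−2) over regions non-missing in both samples and returns 0 when either
restricted vector is all-zero. This is a G-score/permutation skeleton, not
full GISTIC2: no peel-off arbitration and no arm-level separation.

## Synthetic cohorts

The generator emulates the cohort the method was designed for:

- **Mutation burden.** A per-patient distinct-mutation budget U uniform in
  (30, 120), so realized per-tumor counts bracket the reported cohort
  median of ~71 (range 13–237). Trunk fraction f is uniform in
  (0.12, 0.705), the observed range in related trios; trunk size is
  round(f·U), with the remainder split 25% to a T&LN branch and the rest
  equally among private sets. Independent patients get a disjoint D callset
  with its own budget.
- **Contexts.** Related-lineage mutations draw contexts from
  {S1: 0.8, S5: 0.2}; independent D tumors from {S4: 0.5, S29: 0.3,
  S1: 0.2}, reproducing the C>T-dominated vs C>A-dominated regimes. Half
  the SNVs are emitted on the purine strand to exercise strand collapse.
- **Read counts.** t_alt ~ Binomial(t_depth, purity·CCF/2) with
  t_depth ~ Poisson(150) (the cohort's ~149× coverage); purity 0.8; CCF
  1.0 / 0.8 / 0.6 for trunk / branch / private (purity and branch CCF are
  package choices; trunk and private CCFs create the two BAF clusters the
  clonal analysis displays). Normal alt reads are Binomial(n_depth, 0.001).
- **Copy number.** 100 focal regions (20 kb, window-aligned, evenly spaced
  over a 3×10 Mb toy genome). Per region a category is drawn — clonal to
  all tumors, clonal to T&LN, private to one tumor, or neutral — with
  probabilities solved so that (i) each tumor's marginal aberration
  probability is 0.4 (level prior P(0)=0.6, aberrant levels uniform on
  {±1, ±2}) and (ii) the shared fraction of a clonal pair's aberrant-region
  *union* equals the configured sharing fraction (0.8 related, 0.05
  independent across lineages). Aberrant region log2 values are level
  midpoints (1.2/0.5/−0.7/−1.6) + N(0, 0.1), modelling amplitude variation
  from purity and subclonality; neutral segment means carry only averaged
  marker noise (σ/√n_windows), as segmentation of real data produces.
  Expected T–D cosine is ≈ s/(s+(1−s)/3) ≈ 0.92 for related trios and
  ≈ 0.1 for independent pairs, matching the published group medians
  (> 0.8 vs < 0.6) with margin.

What passing tests on these cohorts show: the pipeline's statistics recover
the generative parameters (trunk fraction within binomial error, signature
weights to RMSE < 0.08 at 200 mutations, cosine separation, ≥ 19/20 label
recovery) under a faithful rendering of the study's stated conditions. What
they do not show: robustness to FFPE artifacts, subclonal copy number,
purity mis-specification, caller-specific error modes, or germline
contamination — none of which the generator models.

## Numerical choices and problem sizes

Default n_perm is 500 for the pipeline (1000 via `permutation_null`
directly); p-values are exact permutation p-values, so the smallest
attainable p is 1/(n_perm+1). The acceptance script uses 20 patients per
regime and n_perm = 500; statistical test suites use n_perm = 200 where the
quantity under test is a median over patients rather than a tail
probability. All randomness flows through `numpy` Generators seeded from a
single integer; cohort generation is byte-reproducible. Degenerate inputs
(empty callsets, all-missing regions, zero-total spectra, single-column χ²
tables) raise typed errors or documented fallbacks rather than NaNs.

## Known limitations

The verdict rule is intentionally the published dichotomy (min_shared = 1);
in noisy real data a single shared call can be an artifact, so the
threshold is a config knob and all supporting evidence is always reported.
When mutation sharing and SCNA similarity disagree the mutation rule wins
and the conflict surfaces as a discordant evidence flag. Effect annotation
is consumed, not computed; upstream alignment, calling and annotation are
out of scope.
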