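# clonemark

Genomic clonality analysis for patients with multiple squamous cell
carcinomas: given whole-exome somatic variant calls and copy-ratio profiles
for an esophageal tumor (T), its regional lymph-node metastasis (LN) and a
distant lung tumor (D), decide whether the lung lesion is a **lung
metastasis (LM)** — clonally related to the esophageal tumor — or an
**independent second primary tumor (SPT)**. The distinction matters
clinically (chemotherapy vs. resection-only management) and pathological
criteria alone frequently misclassify it.

`clonemark` is aimed at cancer-genomics analysts who already have
tumor/normal variant calls (MuTect-style, with per-sample depths) and
segmented log2 copy-ratio profiles, and want a reproducible, testable
implementation of the clonality workflow — plus a synthetic-cohort
generator with known ground truth, so every stage can be validated without
access-controlled patient data.

## Method

For each patient the pipeline computes:

1. **High-confidence somatic filtering.** An SNV passes iff
   depth(T) ≥ 10, depth(N) ≥ 10, VAF(T) > 10%, VAF(N) < 2% and
   alt-reads(T) ≥ 3 (VAF bounds strict). Indels require absence from a
   germline set, both depths ≥ 10 and zero normal alt reads.
2. **Trunk / branch / private partition.** Over nonsynonymous mutation keys
   (chrom, pos, ref, alt): *trunk* = present in all tumors, *branch* =
   exactly one pair, *private* = one sample. Any trunk or T&D-shared branch
   mutation is direct evidence of a common clone. Per-patient phylogenies
   (germline root, edge lengths = distinct mutated genes) are exported as
   Newick; a cross-patient overlap matrix controls for coincidental sharing.
3. **Spectra and signatures.** Strand-collapsed 6-class spectra compared by
   Pearson χ²; 96-context profiles refit against a 30-signature reference
   catalog by nonnegative least squares with a 6% weight floor (ageing
   signature S1 dominates clonally related trios; C>A-heavy tobacco
   signatures mark independent lung tumors).
4. **Focal SCNA similarity (GISTIC-like).** Segments are rasterized to 1-kb
   windows; per window G_amp = mean over samples of max(log2, 0) (G_del
   symmetric); significance from a permutation null (circular shifts per
   sample within chromosome, p = (1+#null ≥ obs)/(1+n_perm), threshold
   0.05); runs of significant windows become focal regions, classified per
   sample into 5 levels (+2/+1/0/−1/−2 at log2 thresholds 0.9/0.1/−0.1/−1.3)
   and compared between samples by cosine similarity of level vectors.
5. **Verdict.** trunk + T&D-shared branch count ≥ 1 ⇒ `metastasis`, else
   `primary`; SCNA cosine (0.8 / 0.6 reference bounds), spectra concordance
   and signature-1 dominance are reported as advisory evidence only.

## Worked example

Simulate a 20-patient cohort (10 clonally related, 10 independent) and run
the full pipeline:

```
$ clonemark simulate --out cohort --seed 3
wrote 20 patients to cohort (10 independent)

$ clonemark run --manifest cohort/manifest.yaml --nperm 150 --seed 1 --out cohort/out
20 verdicts (10 primary, 10 metastasis), 0 failed
```

All 10 independent patients are called `primary` and all 10 related
patients `metastasis` (compare `cohort/truth.json`). Stage outputs:

```
$ clonemark clonality --manifest cohort/manifest.yaml --out part.tsv --trees trees.nwk
$ head -3 part.tsv
patient_id  n_trunk  n_branch  n_private  trunk_fraction
P01         13       6         13         0.4062
P02         8        6         22         0.2222
```

P01 carries 13 trunk mutations shared by T, LN and D — 40.6% of its burden
— so its lung tumor is clonally related. Its tree
`(((P01_LN:4,P01_T:4):6,P01_D:4):13)germline;` shows the 13-gene trunk and
a 6-gene T&LN branch.

```
$ clonemark scna --manifest cohort/manifest.yaml --nperm 150 --out scna.tsv
analyzed 20 patients, 197 focal regions
$ head -4 scna.tsv
# 197 focal regions
patient_id  td_cosine  tln_cosine
P01         0.9478     0.8583
P02         0.8966     0.8693
```

T–D cosine ≈ 0.95 for the related patient P01; independent patients in the
same run fall near 0.1 while keeping T–LN cosine > 0.8 (the lymph-node
metastasis stays clonal with the esophageal tumor either way).

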