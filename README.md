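# pjflow

Somatic mutation and copy-number analysis for **pancreatic-juice
cell-free DNA (PJD) exomes**, built for studies that grade intraductal
papillary mucinous neoplasms (IPMN) by liquid biopsy. IPMN spans an
ordinal histologic spectrum — low-grade dysplasia (LGD), high-grade
dysplasia (HGD), invasive carcinoma (INC) — and the question the
pipeline answers is which genomic readouts of pancreatic juice track
that spectrum: per-sample mutation burden, tumor-derived DNA fraction,
and recurrent copy-number alterations.

The package is aimed at computational biologists who want every stage of
such an analysis as tested, importable code, together with a synthetic
cohort generator that reproduces the statistical structure of the real
assay (grade-dependent burden, partial tumor purity, oxidative-damage
artifacts, noisy copy-number profiles) so the whole pipeline runs and
validates at desk scale.

## What it computes

**Somatic calling.** At each site the paired tumor/normal pileup is
reduced, after read filters (mapping quality ≥ 20, base quality ≥ 15),
to the 2×2 table of alt/ref counts. The one-sided Fisher exact p-value
for tumor enrichment is the hypergeometric tail

P(X ≥ a_T), X ~ Hypergeom(N = n_T + n_N, K = a_T + a_N, n = n_T),

and a call passes when depth ≥ 8 in both samples, alt reads ≥ 3, tumor
VAF ≥ 0.05, normal VAF ≤ 0.1 and p ≤ 0.05.

**OxoG sample QC.** 8-oxoguanine damage creates spurious low-VAF C>A
(G>T) calls at the middle base of CCN trinucleotides. Three per-sample
evidences — depressed median VAF, the CCN-context C>A fraction of calls,
and the mass of the 96-bin trinucleotide spectrum in those bins — are
flagged as cohort-relative outliers (median ± 3·MAD); samples failing
two of three are excluded from SNV statistics.

**Copy number.** Per-bin log2 tumor/normal depth ratios (library-size
normalized) are segmented by circular binary segmentation with a
permutation test per split, splits less than 3 residual SDs apart are
undone, off-target-only segments are removed and equal-mean neighbors
re-fused; segment means beyond ±0.2 call amplification/deletion, and a
residual-variance screen drops unstable samples.

**Recurrence.** Segments project onto a marker grid; the per-marker
G-score Σ_s max(0, x_sm − 0.2) (amplitudes capped at |x| ≤ 2) is
compared with a cyclic-shift permutation null, Benjamini–Hochberg
q-values define significant regions with 0.90-confidence driver
intervals, whole-cohort and per grade subset (benign LGD vs malignant
HGD+INC).

**Cohort statistics.** Tumor fraction as 2 × median VAF (samples with
more than 10 calls), Spearman correlation of burden with grade, exact
2×K (Freeman–Halton) tests for region-by-grade association, and
mutation/deletion co-occurrence.

## Worked example

```python
from pjflow import (CohortConfig, simulate_cohort, call_sample, burden,
                    fisher_exact_2xk, spearman_burden_grade)

cohort = simulate_cohort(CohortConfig(seed=2019))   # 39 samples, 8/20/11
calls = {sid: call_sample(pu) for sid, pu in cohort.pileups.items()}
grades = [cohort.truth.grade[s] for s in calls]
rho, p = spearman_burden_grade(grades, [burden(c) for c in calls.values()])
print(f"rho = {rho:.3f}")
# association of a 2x3 amplification-by-grade table (altered / not,
# columns LGD, HGD, INC):
print(f"p = {fisher_exact_2xk([[1, 1, 7], [6, 16, 4]]).p:.4f}")
```

prints `rho = 0.536` and `p = 0.0019` (the correlation tightens to 0.747
once the three OxoG-contaminated samples are excluded by QC, as in
`analysis/06_cohort_stats.py`).

The full narrative lives in `analysis/01...06` (each script regenerates
the same seeded cohort and writes tables under `results/`). Running them
in order simulates the cohort, calls mutations (median burden per grade
17.5 / 19.5 / 66), excludes exactly the three OxoG-injected samples and
the four noise-inflated ones, segments copy number, recovers all three
planted recurrent regions (e.g. the INC-enriched amplification at
q = 3.3e-05, altered in 0/8 LGD, 1/16 HGD, 8/11 INC samples,
p = 9.7e-05), and reports TP53-mutation/17p-deletion co-occurrence
confined to invasive samples.

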