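# Methods

This note documents the models, parameter choices and numerical
conventions behind `pjflow`, and what the synthetic validation does and
does not establish about real pancreatic-juice cfDNA (PJD) data.

## Somatic site test

Calling is a pure function of the paired pileup and a threshold
configuration. Reads first pass quality filters (mapping quality ≥ 20,
base quality ≥ 15); quality-failing reads are invisible to every later
step. For each non-reference allele observed in the tumor, the 2×2
table `[[tumor_alt, tumor_ref], [normal_alt, normal_ref]]` is tested by
the one-sided Fisher exact test for tumor alt enrichment, computed as a
hypergeometric tail (`scipy.stats.hypergeom.sf`); an enumeration oracle
in the test suite confirms agreement to 1e-12. Sidedness is a design
choice: somatic calling is directional, and the fixed 0.05 call
threshold is interpreted on the one-sided p (a two-sided variant is a
config flag). Multi-allelic sites test each alternate against the
reference independently and report the lowest p; the VAF denominator is
the filtered ref+alt pair for the tested allele. Indels are atomic
alleles (`I:SEQ` / `D:SEQ`); there is no realignment.

Filters apply in a fixed order — depth (≥ 8 in **both** samples; the
minimum-depth rule does not say which sample, and requiring both is the
conservative reading, configurable via `depth_on_both`), supporting
reads (≥ 3), tumor VAF (≥ 0.05), normal VAF (≤ 0.1), Fisher p (≤ 0.05)
— and a failing site is retained with the first failed filter named.
No multiple-testing correction is applied to per-site p-values; the
fixed threshold is the method. Type-I control is instead verified
empirically: on 10,000 germline-heterozygous-like null sites (identical
allele fraction in tumor and normal, depth 100) the rejection fraction
at 0.05 stays near 0.04 — the discreteness of the exact test makes it
conservative.

## OxoG sample exclusion

Contamination by 8-oxoguanine damage is detected per sample from its
calls, not from read-level metrics (BAM-level oxidation metrics are out
of scope; the call-level oxidation score is a deliberate analog). The
three evidences are (a) median VAF of PASS calls, (b) oxidation score =
fraction of PASS SNVs that are C>A (pyrimidine strand) with a 5'
reference C, (c) the fraction of the 96-bin trinucleotide spectrum mass
in those same bins. Note (b) and (c) are near-duplicates when both are
computed from one call set — they are kept as separately configurable
evidences because real deployments feed (b) from sequencing metrics and
(c) from spectra, but with call-derived inputs the effective rule is
closer to "scores + VAF".

Outlier rule: median ± k·MAD per evidence (k = 3 default), exclusion on
2-of-3 (3-of-3 available; 2-of-3 is the robust default because small
cohorts make single-evidence ties common). The MAD for the score
evidences is floored at 0.1 and for VAF at 0.02: a sample with ~10 PASS
SNVs moves its score in steps of ~0.1, so a cohort MAD below that
granularity measures discreteness rather than spread, while genuine
contamination drives the scores to 0.5–0.9. An all-identical cohort
flags nothing. On synthetic cohorts of 20 clean + 3 injected samples
the procedure isolates exactly the injected trio in ≥ 95% of seeded
replicates; clean-cohort false exclusions average well under one per
cohort.

## Copy number

Bins derive from capture targets: targets split into pieces ≤ 100 kb,
pieces < 100 bp merged into a same-target neighbor (a lone short target
is kept, flagged). The log2 ratio of a bin is
`log2((t/n) · (N_total/T_total))`; bins with zero depth on either side
are dropped, not imputed, and no GC correction is applied (none is part
of the procedure being reproduced).

CBS searches circular arcs with the mean-shift statistic
`|mean_in − mean_out|·sqrt(k(n−k)/n)` — equivalent in ordering to the
two-sample t statistic, because the pooled SD is permutation-invariant —
and accepts a split when fewer than α = 0.01 of 1000 within-segment
shuffles reach the observed maximum (α configurable; 0.01 is the usual
CBS convention, chosen because the upstream raw-ratio p of 0.005
belongs to the binning tool, not to CBS). Minimum segment width is 2
bins. The undo rule then merges adjacent segments whose means differ by
less than 3 pooled residual SDs; "residual SD" is defined here as the
RMS deviation of bins from their segment means, fixed from the input
segmentation so the rule has a single, order-independent threshold;
merging proceeds smallest-difference first until stable.

Segments without any target overlap are removed (off-target exome
coverage is untrustworthy), then consecutive equal-mean segments
(|Δ| ≤ 1e-9) re-fuse; the operation is idempotent. States: amp above
+0.2, del below −0.2, strict inequalities, boundary neutral.
Coordinates are 0-based half-open internally; SEG output is 1-based
inclusive.

Sample QC: residual variance (mean squared bin deviation from segment
means) flags a sample above cohort median + 3·MAD. Because variance
estimates carry multiplicative error (relative SD ≈ sqrt(2/n_bins)),
the MAD is floored at 25% of the median; the pathology screened for is
a ~25-fold variance inflation, far above the floor.

## Recurrence

Per-marker G-scores sum above-threshold amplitude across samples, with
per-sample amplitudes capped at |log2| ≤ 2 so one extreme sample cannot
create a region. The null applies an independent random cyclic shift to
each sample's marker vector — preserving within-sample segment structure
while destroying cross-sample alignment; this permutation null is the
desk-scale analog of the semi-exact null of the standard tool.
Empirical p-values pool all null marker values (resolution
1/(n_perm·M)); Benjamini–Hochberg runs across markers, and maximal
q < 0.25 runs (0.25 is the conventional reporting threshold of the
field's tool) become regions. The driver ("wide") interval extends from
the peak while G stays within δ of the peak G, where δ is the 0.90
quantile of the null per-permutation maxima — the configured driver
confidence. Arm-level/focal separation is not implemented; all regions
are treated as focal. Per-grade runs repeat the procedure on the LGD
subset and the HGD+INC subset; subsets of fewer than two samples are
skipped.

## 2×K exact test and rank statistics

Region-by-grade association uses the Freeman–Halton extension of the
Fisher exact test: conditional on both margins, a table's probability
is multivariate hypergeometric, and the two-sided p sums the
probabilities of all tables no more likely than observed (minimum
likelihood criterion, with a 1e-7 relative tolerance for ties, matching
the standard R implementation this reproduces). Full enumeration runs
whenever the loose table-count bound is ≤ 1e7; beyond that a seeded
Monte-Carlo sampler (≥ 1e6 multivariate hypergeometric draws) reports
the estimate with its standard error. The 2×2 special case is verified
against the classical implementation to 1e-10.

Burden–grade correlation is Spearman's rho with mid-ranks (grade coded
1/2/3; any monotone coding gives the same rho). The p-value uses the
t approximation for n ≥ 10 and exact full permutation enumeration below
that. Tumor fraction is 2 × median VAF of PASS calls, clipped to [0, 1],
reported only when a sample has more than 10 calls (the median of fewer
calls is too unstable); a clonal heterozygous diploid event in a sample
of purity p has expected VAF p/2, which is the estimator's rationale and
its bias model — subclonality and copy-number changes at the measured
loci bias it downward/upward respectively. Reported percentages round
half-up to two decimals; note that 1/7 is 14.29%.

## Synthetic cohort: what it emulates

Defaults are the study-scale conditions: 8/20/11 samples across
LGD/HGD/INC; per-grade somatic burden negative-binomial (dispersion 8)
with the mean calibrated numerically so the distribution median hits
16 / 19.5 / 64; tumor purity Beta-distributed with mean 0.35 and SD
0.15 (median ≈ 0.33 — the real cohort reports only a median, so the
distribution shape is a modeling choice); tumor depth 200×, normal
100× (Poisson per site); symmetric sequencing error 1e-3 per read; base
and mapping qualities from truncated normals (32±4 on [2,41], 50±8 on
[0,60]) so the quality filters do real work. Each sample also carries
~200 somatic-free sites so specificity is measurable. Consequence
classes are sampled at the nonsynonymous-call mix the downstream
percentages describe and carried as labels (annotation itself is out of
scope); truth labels transfer to calls via `annotate_calls`.

Copy number: a small seeded reference genome (six 500 kb chromosomes,
GC 0.45) with exon-like targets every 2 kb; three recurrent profiles
(two amplifications, one deletion, |log2| = 0.6 — an
already-purity-diluted amplitude) with grade-dependent prevalence, plus
Poisson(2) random passenger segments per sample. Observed bin counts
are Poisson around 500 reads per bin with lognormal bin noise
(SD 0.12 in log2); noise-inflated samples (fraction 4/39) multiply that
SD by 5, and off-target bins (10% of bins) carry 2.5× extra noise.
OxoG contamination injects low-VAF (Beta, mean 0.05) C>A reads at
CCN-context positions in 3 samples by default; a TP53-like point
mutation is coupled to the deletion profile in invasive samples to
exercise the co-occurrence analysis.

What passing synthetic tests does **not** show: real PJD exomes have
GC- and mappability-structured coverage, correlated errors, FFPE-like
fragmentation effects, germline contamination and subclonal structure
none of which the generator models; the i.i.d. reference also makes
trinucleotide context frequencies uniform rather than genome-like.
Calibration results (type-I error, recovery rates) therefore validate
the statistical machinery under its own assumptions, not assay
performance on patients.

## Problem sizes of the validation experiments

The reproduction script and acceptance tests use: 10,000 null sites at
depth 100 for type-I error; 50 samples with purities 0.1–0.8 (30 clonal
events each, depth 200) for tumor-fraction recovery (MAE ≈ 0.01);
100 single-breakpoint profiles (100 bins, shift/noise = 10) for CBS
recovery within ±2 bins; 50 cohorts of 35 samples × 200 markers with a
10-marker spike (amplitude 0.8, prevalence 0.5) for recurrence power;
and 20 replicate cohorts each for the OxoG (20 clean + 3 injected) and
residual-variance (35 clean + 4 inflated, two 100-bin chromosomes per
sample) screens. These sizes keep every experiment within minutes on a
single core while leaving the acceptance margins comfortable.

## Known limitations

- The oxidation and spectrum-signature evidences coincide when both are
  computed from the same call set (above); the 2-of-3 rule is then
  effectively driven by the scores plus median VAF.
- The undo-splits threshold interacts with bin depth: with shallow bins
  (high Poisson noise) 3 residual SDs can exceed genuine event
  amplitudes and erase them; bin sizing should keep per-bin log2 noise
  well under a third of the smallest effect of interest.
- `fisher_exact_2xk` enumeration cost grows with the product of column
  margins; the Monte-Carlo fallback is accurate but only to its
  reported standard error.
- The cyclic-shift null treats chromosomes as one circular sequence per
  sample; with very few markers per chromosome, shift collisions make
  the null slightly conservative.
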