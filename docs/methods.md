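# Methods

This note documents the statistical models, parameter defaults and design
choices behind each stage of the package, what the synthetic-data
generators do and do not emulate, and the numerical conventions used
throughout.

## Coordinate and format conventions

Variant positions are 1-based (VCF convention); genes, exons, chromosome
arms, coverage windows and SV breakpoints are 0-based half-open (BED/BEDPE
convention). The package's minimal VCF dialect stores per-sample read
support as `AD = alt,ref`. Coverage tracks are bedGraph; SV tables are
10-column BEDPE with named extra columns for `unique_reads`,
`junction_fraction` and `variant_read_pairs`.

## Toy reference genome

Simulations run against a deterministic ~5.2 Mb synthetic genome with five
chromosomes (chr1, chr7, chr9, chr10, chr19), each split into p/q arms at
a fixed centromere, and four gene models: a large 14-exon *CNTNAP2* analog
on 7q (exon coding lengths chosen so deletions of transcript exons 2–8 and
9–12 are in-frame), a 10-exon minus-strand *PTPRD* analog on 9p, plus
*FUBP1* (1p) and *CIC* (19q) companions on the codeleted arms. The
sequence is drawn once from a fixed internal seed, so trinucleotide
contexts and all downstream coordinates are identical on every machine; it
is materialized to FASTA/BED on demand rather than shipped as a file.
Uniform base composition gives every trinucleotide ~1/64 frequency, so all
96 substitution channels are plantable.

## Variant filtering

Support filter: `alt_reads >= 3` and `VAF >= 0.10`, both inclusive.
"Unique supporting reads" are taken as the alt count of the input table;
read deduplication is an upstream concern.

Artifact test: for each site, each patient's primary and relapse reads are
pooled into (alt, total). Under the null that every patient shares one
allele fraction *f* (the behavior of a process artifact), the expected alt
count is *f*·total per patient and the Pearson statistic over the 2×P
table is referred to chi-squared with P−1 df. Patients with zero total are
excluded; fewer than two usable patients is an error; degenerate pooled
fractions (*f* = 0 or 1) give statistic 0 and p = 1, the Pearson
convention for degenerate margins. Calls are **retained** when p < α
(default α = 0.01, exposed in config): heterogeneity across patients is
evidence of a genuine patient-specific somatic event, homogeneity of a
shared artifact. Under the null an artifact is retained with probability
α, so the expected artifact leak-through equals the chosen α.

Germline exclusion matches (chrom, pos, ref, alt) exactly — a different
alt allele at a blacklisted position is kept.

## Mutational signatures

Substitutions are binned into the 96 COSMIC-style channels
(pyrimidine-strand reference; purine-reference calls reverse-complemented,
making counting strand-invariant). The POLE score is the fraction of a
sample's substitutions in T[C>A]T, T[C>T]G and T[T>G]T — the channels of
the POLE exonuclease-domain-mutant hypermutator spectrum. The hypermutator
flag requires both load ≥ 500 mutations and score ≥ 0.2; there is no
canonical threshold pair in the literature, so both are config defaults
chosen to separate a >1000-mutation POLE-dominated relapse from a
~100-mutation primary with a flat spectrum. All filtered SNVs enter the
spectrum (not only protein-altering ones).

## Copy number

Per 1000 bp window: log₂((tumorᵥ/T)/(normalᵥ/N)) with T, N the
genome-wide totals, so the track is invariant to library size. Windows
where either sample has zero reads are masked (NaN) to keep every reported
value finite. Median decimation collapses blocks of k windows to their
median (masked values excluded; fully masked blocks stay masked; the
terminal partial block uses its own median); the default 200-fold
decimation suppresses counting noise before arm-level calling. Arm calls
use the median of unmasked (decimated) windows, windows assigned to arms
by midpoint: loss ≤ −0.3, gain ≥ +0.3. These thresholds assume a
high-purity tumor — a hemizygous loss then sits near −1 and a one-copy
gain near +0.585 — and tumor purity is deliberately not modeled
(documented limitation). 1p/19q codeletion is simply loss on both arms.

Focal deletions are maximal runs of windows at or below a deletion
threshold, capped at 3 Mb so arm-scale events are not reported as focal.
The pipeline runs this detector on a 10-fold decimated track with
threshold −1.5 and a minimum run of 2 windows. The threshold sits
*between* the deep-focal level (≈ −2.3 at the simulated copy ratio 0.25)
and the hemizygous arm-loss level (−1): a cutoff at exactly −1 lets
Poisson noise on a genuinely lost arm masquerade as focal events, and the
span cap alone cannot separate the two when an arm is shorter than the
cap. The standalone function keeps permissive defaults (−1.0, no minimum
run) for use on clean or pre-segmented tracks.

## Rearrangements

Three pure record-level filters (they commute): unique-read support ≥ 5;
cohort recurrence — an SV matching records (both breakpoints within a
100 bp window, same orientations, after canonicalizing breakpoint order)
in strictly more than 30% of cohort samples is removed as a recurrent
artifact (presence in exactly 30% is kept); and the junction-evidence rule
junction_fraction ≥ 0.2 **or** variant_read_pairs ≥ 4 (inclusive OR;
records missing both fields are rejected with a counted warning). The
100 bp match window is a design choice — cross-sample breakpoint
resolution varies and exact matching would undercount recurrence.

An SV is intragenic when both breakpoints fall inside one gene's span on
its chromosome. With breakpoints ordered by position, the orientation pair
classifies the event — (+,−) deletion, (−,+) duplication, (+,+)/(−,−)
inversion — the standard BEDPE reading of paired-end evidence, independent
of the gene's strand. For deletions, exons fully contained in the deleted
interval are reported as 1-based transcript-order indices and the event is
in-frame iff the summed coding length removed is divisible by 3; for other
classes overlapping exons are reported and frame is not applicable.
Enhancer overlap for intronic events is available as an optional
user-supplied BED annotation.

## Methylation collapse

Probes with across-sample variance strictly above 0.01 (sample variance,
ddof = 1) survive. Surviving probes are clustered on Spearman correlation
distance (1 − ρ, midranks for ties) with average-linkage hierarchical
clustering cut into two clusters; clustering method and count are not
canonical, so both are exposed in config — two clusters is the simplest
scheme consistent with choosing "the" negatively correlated cluster, the
biological picture being promoter-like probes (silencing, anticorrelated
with expression) versus gene-body/noise probes. Per cluster the per-sample
median beta is correlated (Spearman) against the gene's expression over
the intersected samples (≥ 3 required); the most negative ρ wins, ties
broken by larger cluster then input order, for determinism. If no cluster
is negative the gene's methylation is flagged undefined rather than
guessed. Binary methylation status thresholds the representative beta at
0.3 (config default; beta distributions are bimodal well away from it).

## WHO-2021 classification

IDH-mutant with 1p/19q codeletion → oligodendroglioma; IDH-mutant without
→ astrocytoma; IDH-wildtype → glioblastoma when grade 4 or when carrying
combined chromosome 7 gain *and* chromosome 10 loss, a TERT promoter
mutation, or EGFR amplification; remaining IDHwt grade 2/3 cases are
unclassified and excluded from cohort analyses. Markers are tri-state: an
unknown value propagates to `unclassified` only when it is decisive
(unknown IDH, the primary split, is an error). The 7+/10− criterion is
evaluated at whole-chromosome level as provided in the clinical table.

## Survival and association statistics

Kaplan–Meier and the log-rank test are implemented from first principles
so their arithmetic is directly checkable: the product-limit estimator
with right-censored records leaving the risk set without an event, median
survival as the smallest t with S(t) ≤ 0.5 (undefined if never crossed);
the log-rank statistic (ΣO − ΣE)²/ΣV from per-event-time hypergeometric
expectations and variances, referred to chi-squared with 1 df. lifelines
serves only as an independent cross-check in the test suite.

Wilcoxon rank-sum uses exact enumeration when the pooled sample has ≤ 20
tie-free values and the midrank normal approximation with tie and
continuity corrections otherwise (at cohort sizes of several hundred the
asymptotic form is the operative one). Fisher's exact test is two-sided by
the probability-mass rule; the odds ratio is ad/bc with b·c = 0 reported
as infinite. Both delegate to scipy under this policy.

Expression dichotomization: low is **strictly below** the cutoff (a value
equal to the cutoff is high), with either a fixed cutoff (defaults 7.8 for
CNTNAP2, 10.5 for PTPRD) or the cohort mean. The combined low/low group
requires low status in both genes over identical case sets. All p-values
are reported raw; no multiplicity correction is applied across the
comparison grid.

## Expression utilities

Size factors are median-of-ratios: per sample, the median over
all-positive genes of the count divided by the gene's geometric mean (the
median taken in ratio space, per the stated contract). Paired fold change
is the ratio of normalized relapse to primary counts, with a pseudo-count
of 1 added to both when either is zero, keeping the value finite and
bounded. Full differential-expression inference (dispersion estimation,
shrinkage, Wald tests) is out of scope; pre-normalized matrices can be
used by passing unit size factors.

## Synthetic-data generators

`simulate_paired_cohort` defaults describe the study conditions: 5
patients with primary+relapse samples at mean depth 60 (per variant site
and per window); 92 true somatic SNVs per patient with a patient-specific
VAF drawn from U(0.25, 0.55) and binomial read counts; 30 shared-artifact
sites present in every patient at one common allele fraction (0.5); 5
rare-germline leak-through sites per patient (VAF 0.5, recorded in the
blacklist); one hypermutator patient (case2) whose relapse carries 1145
mutations (> 12× its primary) with 80% drawn from the three POLE channels
(per-mutation Bernoulli, so the realized score is binomial around 0.8;
non-POLE mutations are resampled to avoid those channels so the fraction
is interpretable); arm events 1p and 19q at copy ratio 0.5 and 7p/7q at
1.5 in every tumor; a 50 kb focal deletion at the PTPRD TSS at copy ratio
0.25 in relapse samples; intragenic CNTNAP2 deletion (spanning transcript
exons 2–8) and intronic inversion in relapse samples, plus sub-threshold
intragenic decoys (1–4 reads) and a recurrent junction present in every
sample and in all 10 recurrence-cohort samples. Cohort counts include
reference-only coverage of every variant in every patient, as the artifact
test requires. Paired expression counts are Poisson with per-sample
library factors; the rearranged genes' relapse counts are reduced 4-fold.

`simulate_tcga_like_tables` defaults to 581 cases (the analyzed-cohort
scale) with subtype mix ≈ 26% oligodendroglioma / 39% IDHmut astrocytoma /
35% IDHwt glioblastoma and grade-appropriate marker frequencies. Marker
gene expression is Gaussian (sd 0.7) around a base that drops by
`grade_effect` (default 0.8 log₂ units) per grade step. Survival follows
an exponential proportional-hazards model: baseline hazard 1/60 per month
(mean 60-month survival in the high-expression group), hazard ratio 3 for
cases below the cohort-mean expression of the survival gene (CNTNAP2),
with independent Uniform(0, τ) censoring where τ is solved numerically so
the *expected* censored fraction equals the configured rate (default 20%).
Methylation plants, per gene, a 5-probe cluster tracking
0.5 − 0.3·tanh(z(expression)) — strictly decreasing in expression, hence
Spearman ρ = −1 in the noiseless limit — and a 5-probe cluster tracking an
independent latent signal, each probe with a small constant offset and
Gaussian noise (sd 0.05 by default), clipped to [0, 1].

What the generators do **not** emulate: read-level data (no FASTQ/BAM),
alignment and duplicate-marking artifacts, GC/mappability bias, tumor
purity and subclonal structure, batch effects, non-proportional hazards,
and probe cross-hybridization. Passing tests therefore demonstrate the
correctness and calibration of the *statistical machinery* under its
stated model, not robustness to those real-data complications.

## Problem sizes and determinism

The test suite and acceptance script size their simulations for quick,
repeated runs: planted-event recovery uses 50 two-patient seeds
(copy-number, SV and focal calls across all tumor samples); methylation
recovery uses 50 seeds × 10 genes at n = 200 samples; log-rank power uses
100 seeds at n = 300 with 20% censoring; null calibration uses 200 seeds
at n = 150 with a Kolmogorov–Smirnov uniformity check. Identical seed and
config give byte-identical output files; every generator derives its
streams from the single config seed, and the acceptance script derives all
sub-seeds from its `--seed` argument.

## Known limitations

No purity/ploidy modeling or segmentation (HMM/CBS) in copy number; no SV
discovery from reads; no signature deconvolution against catalog
signatures; no Cox modeling or multivariate adjustment in survival; the
probe-collapse rule leaves a gene undefined when no cluster anticorrelates
with expression, which on real arrays can happen for genes whose
regulation is not methylation-driven.
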