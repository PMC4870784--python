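# Methods

This note documents the statistical procedures `xitools` implements, the
design choices made where the procedures were underspecified, what the
synthetic-data generator does and does not emulate, and the numerical
conventions used throughout.

## Coordinates and data model

Intervals (BED, bedGraph, peaks, genes, CGIs, repeats) are 0-based
half-open; point positions (SNPs, CpGs) are 1-based, VCF-style. The
single converter is `core.point_in_interval`: 1-based position *p* lies in
`[start, end)` iff `start <= p-1 < end`. Strand is carried but ignored by
all coverage and overlap computations. Every filter logs its input and
surviving record counts at INFO level, so record bookkeeping is greppable
from run logs.

## Allele-specific expression

The atom is a per-SNP, per-sample (Xi count, Xa count) pair, Xi being the
CAST allele in the hybrid system. Records are kept when the SNP is exonic
and covered by at least 10 reads, assessed per (SNP, sample) record; a
flag switches to cross-sample assessment. The Xi/Xa ratio is
`(xi+1)/(xa+1)` — the +1 pseudocount avoids division by zero and makes the
ratio strictly monotone in each count.

**Reactivation rule.** At the assessed time point (day 5 by default, where
the silencing failure is expected), a SNP is reactivating in a replicate
iff its ratio is *strictly* larger under both knockdown hairpins than
under the non-silencing control; ties fail (the pseudocount makes exact
ties possible at low counts, so the policy must be explicit). The
consensus set requires the call in every replicate; SNPs missing any
condition in a replicate are excluded from that replicate and cannot
reach consensus. A gene is reactivating in a replicate iff ≥ 1 of its
SNPs is; the headline list is the intersection across replicates.

**Null calibration — an important property.** Within a replicate, both
knockdown comparisons share the same control ratio. For i.i.d. continuous
ratios, P(both knockdowns > control) = P(control is the minimum of three)
= 1/3, so the two-replicate consensus rate under the null is (1/3)² = 1/9
≈ 11.1 % per SNP, slightly reduced by failing ties at finite coverage
(~10–11 % at 30×). The naive independence calculation (four fair
comparisons, (1/2)⁴ = 6.25 %) is **not** the null of this classifier; the
Monte-Carlo calibration tests pin the correct value. At the gene level the
null rate grows with the number of SNPs per gene (≥ (1/3)² with one SNP,
~45 % at three), so the intersection gene list has a high baseline false
discovery rate by construction; the recovery tests report sensitivity and
FDR against planted truth rather than assuming the list is clean.

**Informative (PGK) SNPs.** A variant is informative iff its reference
count in the PGK sample is exactly 0 and the alternate fraction pooled
over control samples is ≤ 0.5. "Does not predominate" is not otherwise
quantified; the 0.5 threshold is exposed as a parameter.

**Gene-level testing.** Allele counts of all variants within a gene's
span are summed into a (ref, alt) × (control, treated) table and tested
with the two-sided Fisher exact test (minimum-likelihood rule), pooling
replicates; BH q-values are added across genes. Degenerate margins give
p = 1 with a flag.

**t-tests.** Wherever a "two-tailed t test" is called for without a
variance-pooling statement, Welch's unequal-variance form is used
(`pooled_var`/`paired` switches restore the alternatives). Groups where
both sides have zero variance return p = 1 (equal means) or are flagged
degenerate (unequal means).

## Chromatin domains

**Broad peak caller.** Reads are counted in non-overlapping windows
(default 10 kb). The expected count per window is the control (H3) count
scaled by the mark/control library ratio, floored at the genome-wide mean
mark rate per window — the floor prevents zero-λ blow-ups in control
deserts. A window is significant when the Poisson upper-tail probability
P(X ≥ obs | λ) falls below the threshold (default 10⁻⁵); runs of adjacent
significant windows merge into one peak (strict adjacency by default,
`merge_gap` exposed) scored by the best window's −log10 p. Narrow calling
reuses the same engine at a smaller window. The caller's p-values are
checked against an independent log-space series summation to < 10⁻¹⁰.
The integer observed counts make the test conservative: the realised
false-window rate sits below the nominal threshold, which the 20-seed
null runs confirm.

**Densities, coverage, correlation.** Peaks per Mb are reported per
chromosome, for X, and pooled over autosomes (total peaks / total
length, which equals the length-weighted mean of per-chromosome
densities). Bin coverage is the exact overlap-bp percentage per 50-kb
bin; Pearson correlation drops undefined bins pairwise and flags
zero-variance inputs rather than returning a number.

**Allelic enrichment.** Allele-tagged reads are totalled per peak; peaks
without informative reads are excluded (logged). Xi vs Xa totals are
compared with a paired two-tailed t-test across regions. Non-peak
controls are size-matched regions drawn from the peak complement with a
fixed seed (the original choice of non-peak regions is not specified).

**Match normalisation.** All samples on a common bin grid are mapped to
the average empirical distribution at equal ranks (quantile normalisation
with average order statistics; ties share the mean of their rank range).
The mapping is rank-preserving and idempotent, and a depth-scaled copy of
a track becomes distribution-identical to it (Kolmogorov distance 0).
The H3 track is normalised together with the marks and then subtracted
windowwise.

**TMM.** Effective library sizes use the trimmed mean of M-values on
10-kb bin counts: reference = library whose 75th percentile of rates is
closest to the mean; per library, log-ratios trimmed 30 % two-sided and
average intensities 5 %, remaining M-values combined with delta-method
binomial weights; factors centred to geometric mean 1. The implementation
reproduces edgeR's `calcNormFactors(method="TMM")` to ~10⁻⁸ (asserted in
a cross-check test against Rscript/edgeR).

## CpG-island methylation

CpG records (methylated/unmethylated counts per allele, condition,
replicate) pass a *strict* coverage > 20 filter (21 reads keep, 20
drop). Per CpG, the replicate percentage-methylation values of the two
conditions are compared with a two-tailed Welch t-test (unpaired; the
3-vs-2 replicate design suggests no pairing), requiring ≥ 2 replicates a
side; direction is the sign of the mean difference. No multiple-testing
correction is applied per CpG by default (a BH switch exists), matching
the per-CpG usage of the source procedure. log2(mC/C) uses +1
pseudocounts on both counts. CGI-level calls pool all member CpGs'
replicate values per condition and t-test the pools; the CGI class is
"methylated" when the control mean is strictly above 20 % mC. The CGI
meta-profile maps each CpG to its relative position (pos − start)/width
and averages in equal relative-width bins; CGIs with < 2 CpGs are
skipped.

## Silencing classes and repeats

Expression is replicate-averaged before classification. Precedence:
maintained-silent (expression < 0.5 at every control time point) >
silenced (> 2 log2 drop between consecutive control time points *and*
gene edge within 200 kb of a Setdb1 peak edge; earliest qualifying
interval names the class) > stable (max pairwise |log2 FC| < 0.5 across
control time points; a consecutive-only switch exists) > unclassified.
log2 fold changes use a 0.1-unit pseudocount (zero handling is not
otherwise specified). Distances are gene-body edge to peak edge, 0 when
overlapping. Repeat differential expression is |log2 FC| > 1 on
replicate-averaged values; class enrichment uses the χ² test of
independence on the class × {DE, not DE} table with adjusted standardised
residuals per class, and warns toward an exact test when > 20 % of
expected cells fall below 1. 2^−ΔΔCt supports multiple housekeeping genes
via the mean ΔCt (equivalent to a geometric mean in expression space).

## shRNA screen

Reads are matched to hairpins and sample barcodes by exact substring at
fixed offsets (mismatch tolerance is a flag, default 0); matched +
unmatched always equals total reads. Hairpins below 1000 reads in *any*
initial replicate are excluded (1000 exactly passes). The default exact
test conditions each hairpin's total on the group library-size
proportion and computes the two-sided exact binomial p by the
minimum-likelihood rule; it matches exhaustive rational-arithmetic
enumeration exactly. With a user-supplied common dispersion the test
becomes the conditional negative-binomial exact test on
library-equalised counts (probabilities of all splits of the total under
two NB(size = 1/d) laws, two-sided by minimum likelihood); estimating
the dispersion itself is out of scope — on the synthetic data the truth
is multinomial, for which the binomial conditional test is exact. Hits
require p < 0.1 and positive fold change in the sorted (GFP+)
population; BH FDR is reported alongside.

## Immunofluorescence profiles

Profiles are smoothed with a centred 5-point moving average; edges use
the shrinking window that fits. An apex requires strictly increasing
values over ≥ 2 steps in, strictly decreasing over the 2 steps out
(plateaus break runs), and an apex value above the per-cell channel mean
(computed on the smoothed signal by default; a raw-signal switch
exists). A peak's extent is the maximal strictly-monotone run around its
apex — the source rule defines no extent, and overlap counting needs one;
consecutive extents are disjointed left-to-right. Overlap counts a
channel-A peak when its half-open extent intersects any channel-B extent
in the same cell. The apex rule is verified against an independent
transcription on *every* quaternary profile of length 5–12 (22.4 million
profiles, evaluated in batch), and against a per-profile brute force —
extents included — exhaustively at short lengths and on random samples.

## Synthetic-data generator

One RNG stream per simulation, seeded once; sub-generators draw in a
fixed order, so identical configurations give byte-identical outputs.
Sequencing depths are negative-binomial with dispersion 0.2
(Var = m + d·m²); allelic and methylation splits are binomial;
ChIP read starts are Poisson processes; screen counts are multinomial
over log-normal abundances.

Defaults encode the study conditions: a 10-Mb X plus two 10-Mb autosomes
in alternating 500-kb gene-dense/gene-poor blocks (half dense); 200 genes
per chromosome filling half of the dense bp, five exons covering half of
each gene, a 1-kb promoter CGI per gene; pseudogenes and repeats (six
classes) only in poor blocks; SNPs at 0.5/kb in genes and 0.1/kb outside
(the SNP paucity of gene-poor regions). The Xi expression fraction decays
0.5 → 0.3 → 0.1 over day 0/3/5; 15 % of X genes reactivate at day 5 under
knockdown only, with a 3× lift applied to the Xi:Xa odds. ChIP marks are
enriched 5× over their block class with an unenriched H3 and a 3× Xi:Xa
allele-tag skew inside female peaks. CGIs carry 80 % mC on the Xi and 5 %
on the Xa; 10 % of X CGIs lose 20 percentage points uniformly under
knockdown, sequenced at 3 control vs 2 knockdown replicates.
The screen pools 1000 hairpins at 10⁶ reads per sample with 1 % hits at
8× in the GFP+ population. IF profiles are 400 pixels with three
Gaussian bumps (σ = 3, height 10) per channel over a low sinusoid
baseline (amplitude 0.2) plus white noise (σ = 0.3); channel-B bumps
co-locate with probability 0.5, and non-co-located bumps keep ≥ 30 px
separation so that planted co-location — not extent leakage — determines
the overlap fraction. Effect sizes for individual-gene reactivation are
free parameters of the generator, documented here, not claims about the
biology.

What the generator does **not** emulate: mappability and GC structure,
fragment-length effects, read-level errors, bisulphite conversion
failure, XO-cell contamination (available as an option, off by default),
linked SNPs within reads, and overdispersion beyond the single NB
parameter. Passing recovery tests therefore demonstrate correctness of
the *computations* under the stated statistical structure, not robustness
to every artefact of real libraries.

## Problem sizes and determinism

Test and acceptance runs use deliberately compact inputs chosen to keep
Monte-Carlo error well inside the asserted bands: 10-Mb chromosomes for
parameter recovery, 2–5-Mb chromosomes for per-stage calibrations, 20
seeds for null-rate checks, and full enumeration wherever the domain is
finite (exact tests to margin 15, all quaternary profiles to length 12).
All randomness flows from explicit seeds; pipelines re-run to
byte-identical tables.
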