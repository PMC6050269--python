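# Methods

`mfsomics` implements the computational core of an integrated genetic and
epigenetic analysis of a complex-karyotype sarcoma cohort (myxofibrosarcoma
is the motivating disease): driver-gene discovery from somatic mutations and
focal copy-number events, purity/ploidy-adjusted copy-number calling,
fusion-transcript detection from discordant paired-end RNA alignments,
extreme-group differential expression, methylation-based subtyping, and the
integration statistics tying subtypes to drivers and survival. Because the
underlying patient data are controlled-access, every stage is exercised on a
seeded synthetic cohort generator that reproduces the statistical structure
each stage assumes.

## Driver-gene significance (SMG)

For each gene the observed aggregate of non-silent substitutions, short
indels, focal amplifications and homozygous deletions is tested against a
Poisson expectation

λ_g = Σ_c r_c · L_g · N + r_CNA · N,

where r_c is the cohort-wide per-class mutation rate per base per sample
(class count divided by total CDS exposure times samples), L_g the gene's
CDS length, N the number of samples, and r_CNA the cohort focal-event rate
per gene per sample. The p value is the upper tail P(X ≥ obs).

Two companion tests capture the signatures of oncogene activation and
tumor-suppressor inactivation. The published descriptions of these tests
cite prior work without formulas, so this package uses documented
surrogates with the same intent, not claimed identical to the originals:

* **activation (recurrence) test** — the maximum per-position count among a
  gene's mutations is scored by a binomial tail under uniform placement of
  n mutations over L CDS positions, Bonferroni-corrected over L and capped
  at 1;
* **inactivation (truncation) test** — the count of truncating classes
  (nonsense, frameshift indel, splice site) out of all the gene's mutations
  is scored by a binomial upper tail at the cohort truncating fraction.

Each test family is Benjamini–Hochberg adjusted across genes and the three
q values are combined as a geometric mean (zeros floored at 1e-300 to avoid
annihilation). A gene whose variant allele fractions are rank-sum shifted
below the cohort distribution (one-sided p < 0.01, requiring ≥ 3 VAFs) is
treated as a subclonally biased passenger and removed. Final driver calls
require combined q < 0.1. Background estimation accepts a caller-supplied
candidate-gene exclusion list so that planted or suspected drivers do not
inflate the background rate.

Note that the BH step-up procedure is not idempotent in general; the tests
assert the definitional oracle, monotonicity and q ≥ p instead.

## Copy number

Depth ratios R(x) = tumor/normal per probe are computed after median-
normalizing each sample (library-size removal; zero-normal probes are
masked). Total copy number is

adjusted CN = [1 − (1 − R(x))/purity] × ploidy,

so R = 1 maps to the sample ploidy for any purity. log2 adjusted CN
(floored at 0.01 before the log) is segmented by a circular binary
segmentation: the two-breakpoint window maximizing a window-vs-rest Z
statistic is accepted when Z exceeds 6, with minimum segment size 5 probes
and a noise scale estimated robustly as the MAD of first differences
(insensitive to the jumps contributed by true breakpoints). The
two-breakpoint search is essential for short focal events embedded in long
neutral stretches, where any single-split statistic is diluted.

Focal calls on segment means: amplification at adjusted CN ≥ 6 (inclusive);
homozygous deletion at adjusted CN ≤ 0, except that apparent HDs with raw
ratio > 0.5 are discarded — 0.5 is exactly the raw ratio of a true HD at
the cohort-average purity of 0.5, so a larger ratio indicates a
purity-estimation artifact rather than a real deletion.

A degeneracy worth stating: when the analysis purity equals the true
purity, a true CN-0 segment has expected adjusted CN exactly 0 and expected
raw ratio exactly at the 0.5 cutoff, so both inclusive rules sit on the
expectation and the call is a coin flip under noise. The recovery
experiments therefore use the scenario the HD filter was designed for:
a tumor of true purity 0.6 adjusted at the cohort-average 0.5 (margins 0.4
and 0.1 on the two rules), and a purity-confounded sample (true purity 0.5,
purity estimate 0.2, het-loss region at R = 0.75) whose apparent HD the
raw-ratio filter removes.

Targeted-panel mode normalizes each gene's mean coding depth by the
panel-wide mean per sample before forming the tumor/normal ratio, and
estimates purity as min(1, 2 × mean somatic VAF) under a heterozygous
diploid clonal model; ploidy defaults to 2 when no estimate is supplied.
Variants with strand bias strictly above 95% (max(fwd, rev)/(fwd+rev) >
0.95) are removed beforehand.

## Fusion detection

Paired-end alignments (transcript coordinates, reference-oriented
sequences) are cropped to their 5′-most 50 bases — shorter ends leave a
longer spacer across a junction — then pairs mapping uniquely to two
different genes with ≤ 2 mismatches per end are clustered per gene and
direction by single-linkage chaining: neighbours ≤ 300 bp apart join
(inclusive), and chained clusters spanning > 1000 bp are discarded. The
pairwise "not farther apart" wording is implemented as chaining because it
is the only transitive closure consistent with the subsequent span check.
A forward cluster in one gene and a reverse cluster in another linked by at
least one read pair form a candidate.

Filters: at least one supporting pair perfectly matched on both ends; then
a realignment-artifact filter that locally realigns both ends of every
supporting pair against each partner transcript with a permissive score
cutoff (0.6 of the maximum local-alignment score, so ends with lowered
similarity across paralog-like duplications still align) — if both ends of
any pair are explainable by one transcript with proper orientation and a
fragment span within 500 bp (configurable), the candidate is removed.

Breakpoints are cluster-edge based: the forward cluster's rightmost end
position and the reverse cluster's leftmost. The junction is in-frame when
the 5′ codon-phase surplus plus the 3′ distance-to-next-codon-boundary is
divisible by three; breakpoints outside either CDS give "undetermined".
Final reporting requires ≥ 2 supporting pairs for in-frame candidates and
≥ 3 otherwise.

## Expression

RPKM = count / ((exonic length/10³) × (mapped reads/10⁶)). Genes with zero
reads in strictly more than half the samples are dropped. Expression is
log2(RPKM + 1); the pseudocount keeps zero-RPKM genes finite and is a
documented departure from a bare log2. Differential expression uses the
extreme-group design: per gene, the k = round(0.20 n) highest- (lowest-)
expressing samples versus the remaining n − k by Welch's unequal-variance
t-test (six versus twenty-three at n = 29), BH-adjusted within each
direction. Because the extreme groups are selected per gene by the
expression values themselves, these p values are selection-biased and serve
as a ranking score, not a calibrated error rate; the suite verifies the
underlying Welch test's calibration on fixed random splits instead.
Promoter methylation–expression association is Spearman's rank correlation
per gene, with "silenced" genes reported at ρ < 0 and BH q below threshold.

## Methylation

β values (methylated fraction, [0,1]) are logit-transformed to
M = log2(β/(1−β)) with β clamped to [ε, 1−ε], ε = 1e-6. Probes with
|coefficient of variation| of M above 60 (percent scale) are retained;
because the CV diverges as the mean approaches zero, probes with |mean M|
< 0.05 are instead kept when their sd exceeds 1.0. Samples are clustered
with Euclidean distance and Ward linkage (Ward.D2 convention, as in scipy),
the tree cut at k = 3 by default to mirror the three-subtype structure; a
gap-statistic helper exists but is not used by the default pipeline.
Cluster labels are letters ordered by first occurrence. Per-cluster
hypermethylation uses a one-sided (greater) Wilcoxon rank-sum test of each
cluster versus the rest per probe, BH-adjusted, reported at q < 0.2.

## Integration statistics

Cluster–driver associations use Pearson's χ² on the k×2 contingency table
(designated-cluster-vs-rest collapse available; Fisher's exact fallback on
2×2 tables when any expected cell is below 1). Mutual exclusivity is a
permutation test preserving per-gene totals. Survival uses the Kaplan–Meier
product-limit estimator and the log-rank test across groups (times measured
from diagnosis). Mutation burden between clusters uses pairwise
equal-variance Student t-tests. Cox proportional-hazards modelling is
deliberately out of scope.

## Synthetic cohort generator

The default cohort emulates a 41-tumor discovery set (29 with RNA data,
all with methylation), average purity 0.5, diploid, background rate
1.6e-6 mutations/base/sample — the rate implied by ~48 non-silent
mutations per exome — with the non-silent class mix fixed to the observed
cohort proportions (85% missense, 5.9% nonsense, 2.1% splice site, 6.9%
indel split 80/20 frameshift/in-frame, 0.4% read-through). Genes are 2400-bp
single-exon models with a 1500-bp CDS tiled along one pseudo-chromosome
(0-based half-open coordinates throughout).

Planted structure: a 50× driver with hotspot recurrence (60% of its
mutations at one position) and truncation bias (80% truncating); a 20×
subclonally biased passenger (VAF mean 0.05); clonal VAFs Beta-distributed
around purity/2 with concentration 50; 2% of records violate the 95%
strand-balance rule; a focal amplification (true CN 8) and a homozygous
deletion (true CN 0) spanning two genes each; an in-frame fusion with 5
support pairs (the first abuts the junction exactly, so the cluster-edge
breakpoint estimate sits at a fixed offset whose codon phase cancels
between the two genes) and 3 decoy pairs built by duplicating a 300-bp
block of the 5′ gene into the 3′ gene's reference with one substitution;
a 3-cluster β matrix (2000 probes, 300 cluster-specific differential
probes, β separation 0.4, Beta concentration 40); 50 genes whose log2
expression is 6 − 4β(promoter) plus N(0, 0.5) noise; and per-cluster
exponential survival hazards (1e-4, 4e-4, 1.2e-3 per day) with uniform
censoring.

Depth noise is Poisson around the expected depth (default 100×, probes
every 500 bp), with the tumor mean scaled by
E[R] = 1 − purity(1 − CN/ploidy) over event regions. All generators draw
from per-stage streams of one seed sequence, so identical seeds give
byte-identical outputs.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: mutational signatures and sequence-context
rate variation, GC/mappability waves in depth, read-level errors and
alignment ambiguity, array normalization artifacts in β values, correlated
probe structure, FFPE degradation, and subclonal copy-number mixtures.
Recovery rates on this generator measure the correctness of the
implemented rules under their own assumptions, not field performance.

## Problem sizes and numerics

Recovery experiments use 20-seed batteries (10 in the acceptance script) at
1000 genes × 100 samples for driver/null cohorts and the 300-gene default
cohort elsewhere; these sizes give the planted effects comfortable
detection margins while keeping a full run in the order of a minute.
Numerical choices: Poisson/binomial tails via scipy survival functions;
q = 0 floored at 1e-300 before the geometric mean; log2 adjusted CN floored
at 0.01; segmentation Z threshold 6 (above the null maximum of the
two-breakpoint scan at these probe counts); ties in extreme-group selection
broken by stable sort on sample id; cluster letters assigned by first
occurrence so label identity is deterministic.
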