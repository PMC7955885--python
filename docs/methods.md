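# Methods

This note documents the statistical models, estimators, numerical
conventions and design choices behind each stage, and what the synthetic
data do and do not establish.

## Synthetic data model

**Population panel.** Every SNP has an ancestral alternate-allele
frequency p ~ Beta(α, β) (default α = β = 0.8, a mildly U-shaped site
frequency spectrum typical of resequencing panels). Each group's
frequency is a binomial resample of p with resample size 200, giving mild
background differentiation (E[F<sub>ST</sub>] ≈ 1/200) without a
coalescent simulator — sufficient because the scan consumes allele
frequencies only. Diploid genotypes are two independent haploid
Bernoulli(p<sub>g</sub>) draws (Hardy–Weinberg), exactly the sampling
model the π and Weir–Cockerham estimators assume. A sweep in window w for
group s multiplies s's minor-allele frequency by (1 − f) (f =
`sweep_diversity_factor`, default 0.9: heterozygosity collapsed to ~10%)
and moves every other group a fraction `sweep_divergence_shift` (default
0.6) toward the allele s is fixing away from. The defaults describe a
strong, recent sweep; the null configuration (f = 0, shift = 0) leaves
frequencies untouched. SNP count is `round(density × chromosome length)`
with positions sampled uniformly without replacement.

What this emulates: diversity loss plus differentiation at selected loci
against a drift background. What it does not: linkage disequilibrium,
recombination gradients, demography, genotyping error or missingness
patterns of real panels. Passing recovery tests therefore shows the scan
is correct for its frequency-based definition of a sweep, not that the
definition is powerful against realistic confounders.

**LTR elements.** Each element is 5′LTR + internal + 3′LTR; both LTRs
start as one random ancestral sequence and independently substitute each
site with probability r·age (always to a different base), so expected
pairwise divergence is slightly below 2·r·age (coincident hits agree with
probability 1/3). Placement inside the centromeric interval is Bernoulli
with an age-group-specific probability (defaults 0.45/0.29/0.26,
mirroring the published centromeric fractions); otherwise uniform over
the two arms. The parameter object has a `chrom_len` field (default
3 × centromere end) because placements need a chromosome, though no
chromosome sequence is materialised. No indels, nested insertions or
solo-LTR recombination are simulated, so the dating suite validates the
divergence→age arithmetic, not structural-annotation robustness.

**Satellite arrays.** One random monomer, `n_copies` copies each mutated
independently (per-site substitutions; optional 1-bp indels), flanked by
random sequence. Truth is the array interval and the ancestral monomer.

**Gene annotation.** Genes are placed left to right with ≥200 bp spacers
and multinomially distributed slack. Head-to-head pairs are planted as a
'−' gene then a '+' gene separated by exactly `pair_intergenic_dist`;
non-pair NLRs are forced to '+' so no spurious divergent NLR pair can
arise by adjacency. Single-CDS genes (phase 0) keep the effect
classifier's codon logic testable without splicing.

All generators are pure functions of their parameter objects: one RNG
(PCG64) seeded from `seed`, fixed text formatting, byte-identical reruns.

## Sweep scan

Per-site π uses the unbiased pairwise estimator
c<sub>ref</sub>c<sub>alt</sub>/C(n,2) over non-missing haploid calls
(sites with n < 2 skipped); window π divides the per-site sum by the
*nominal* window length, so monomorphic and uncalled bases contribute
zero — the convention of the standard windowed-VCF tools. The window grid
is anchored at 0 with trailing partial windows computed but flagged.

F<sub>ST</sub> is Weir & Cockerham (1984) for two populations of
diploids, with per-site components a (among populations), b (among
individuals within) and c (within individuals) computed from sample
sizes, allele frequencies and heterozygote frequencies; only individuals
with both alleles called enter a site, and sites with fewer than two such
diploids in either group are excluded. Windowed F<sub>ST</sub> is the
ratio of sums Σa/Σ(a+b+c) ("weighted" estimator); windows with zero
denominator are NaN and excluded from quantiles. Negative values are
retained: clamping at zero would distort the empirical tail.

Thresholds are empirical quantiles with ties kept together: the upper-q
threshold is the smallest v with #{x ≥ v} ≤ ⌈qN⌉, computed genome-wide
(not per chromosome). The π ratio A/B uses +∞ as the sentinel when only B
is monomorphic (it belongs to the upper tail by construction) and is
excluded when both groups are monomorphic. A window is a sweep window
when it is in the F<sub>ST</sub> upper tail *and* in either π-ratio tail;
the lower tail selects the numerator group, the upper tail the
denominator group. Significant windows of one selected group that overlap
or abut merge into regions (with 100-kb windows at 10-kb steps,
per-window reporting would be redundant). Annotation overlap is strict
half-open intersection of ≥1 bp.

Two calibration facts the tests rely on: (i) the marginal tail holds
exactly ⌈qN⌉ windows when values are distinct, by construction; (ii) the
*joint* tail on null data is sparser than either marginal but exceeds the
independence product 2·q<sub>FST</sub>·q<sub>π</sub>, because windowed
F<sub>ST</sub> and π ratio are positively correlated under drift (a group
that drifts to low diversity in a window is also more differentiated
there). The null-calibration test bounds the joint fraction by
2·q² + 0.02, still 2.5× below the marginal 5%. Recovery of planted
windows is only attainable when the number of planted windows does not
exceed the tail capacity ⌈qN⌉; the recovery suites plant 3 windows in a
60-window scan accordingly.

## SNP effects

One record per (SNP, overlapping gene): exon (with coding subtype when a
genome is supplied), intron, or strand-aware upstream/downstream within
a 5 kb flank (the paper-independent convention of common annotators;
configurable); SNPs hitting nothing give a single intergenic record, so
records ≥ SNPs and "one SNP, multiple annotations" is reproduced. Codon
calls splice the CDS in transcript orientation, apply the first segment's
phase, and translate the reference and alternate codons; genes whose
phase-adjusted CDS length is not a multiple of 3 get a warning and no
codon calls. Percentages are of total records, rounded half-up to two
decimals (`decimal.Decimal`, matching printed tables rather than
banker's rounding). Exact arithmetic on the published count table gives
22.32% for the intergenic class where the table prints 22.33%; the
package reports the computed value.

## LTR dating

Divergence is measured on a global alignment of the two LTRs with match
+1, mismatch −2, gap open −4, gap extend −1 — near-identical sequences
make results insensitive to these scores, but fixing them makes the
pipeline deterministic. p is mismatches over gap-free, N-free columns;
the default Jukes–Cantor correction K = −(3/4)ln(1 − 4p/3) (the simplest
one-parameter correction; raw p available by flag) saturates at p ≥ 0.75,
where the element is reported undatable rather than clamped. T = K/(2r)
with r = 1.4 × 10⁻⁸/site/year; the age groups [0, 0.2 My), [0.2 My,
1 My], (1 My, ∞) partition the axis (the source notation "<0.2 / 0.2–1 /
>1" leaves boundary membership ambiguous; boundaries were placed to make
the groups a partition). An identical pair of equal-length LTRs skips
alignment (p = K = 0 exactly). Centromere membership is by element
midpoint; the young-vs-older contrast is a two-sided Fisher exact test.
The flank presence test maps 1-kb flanks by 31-mer exact seed plus edlib
extension at ≥90% identity, calls `absent_specific` when the flanks map
adjacently (gap < 0.1 × element length), `present` when separated by
≥0.9 × element length with element-like sequence between, and
`unresolved` otherwise, including flanks seeding at more than three
places.

## Centromere detection

The monomer length estimator records, for every k-mer (k = 13), the
distance to its nearest previous occurrence when ≤ `max_period`
(2000 bp); the modal distance is the fundamental period. Among periods
with counts within 5% of the mode the smallest is returned, suppressing
the 2L/3L harmonics a near-perfect array also produces. Array
segmentation marks positions whose k-mer recurs at monomer_len ± 10% as
periodic and merges runs with internal gaps ≤ 5 kb; runs shorter than
10 monomers are dropped. The reported mean identity is the per-site
copy-to-copy match rate estimated from the periodic fraction as
fraction^(1/k) (a 13-mer survives in adjacent copies only if all 13
sites match), and arrays below 0.7 estimated identity are discarded.
Centromere calling clusters arrays with gaps ≤ 100 kb (pericentromeric
arrays are interrupted by TE insertions) and takes the cluster with the
greatest total array bp per chromosome; the call interval is the cluster
span, and the mean call length is reported over called chromosomes.
Higher-order repeat structure and strand orientation of monomers are
ignored.

## NLR analysis

The seed scan translates all six frames, anchors candidate windows by
exact 5-aa seed words, and extends each window by local alignment
(BLOSUM62, gap open 11 / extend 1), keeping hits with score ≥
`min_score` and ≥ 80 aligned residues, merged by genomic overlap (union
span, max score). `min_score` defaults to the 99.9th percentile of
window scores on a dinucleotide-shuffled copy of the genome (shuffling
preserves codon-ish composition, so the null is conservative); when the
shuffled genome produces no anchors at all, a floor of 50 is used.
Reconciliation pairs each annotation gene with the first unconsumed scan
locus overlapping it by ≥1 bp on gene span (the categories are then a
partition and the union is |both| + |scan_only| + |annotation_only|).
Head-to-head pairing considers consecutive non-overlapping genes (A, B)
with A on '−' and B on '+' — both 5′ ends facing the shared intergenic
interval — at distance ≤ 10 kb (no published distance exists for the
arrangement; the cap is exposed and written into output headers), then
matches greedily by ascending distance with each gene used once. The
paired percentage is 100·2·pairs/genes, half-up to one decimal.
Sensor/executor identity is not assigned: that requires clade
information outside this package's scope.

## Pipeline and summaries

The orchestrator runs simulate → scan → report from one YAML config;
every output carries a 12-hex SHA-256 config hash header and identical
configs reproduce byte-identical outputs. Anchoring arithmetic sums
chromosome lengths, groups A*/C* prefixes into subgenomes, and reports
percentages of the assembly total, half-up to one decimal.

## Problem sizes

The test and acceptance suites run on deliberately small instances: 500
kb–600 kb panels of 30–40 diploids at 3 SNPs/kb (≈1,500–1,800 SNPs),
satellite chromosomes of ≈0.4–1 Mb, LTR cohorts of 500 elements per age
at 2-kb LTRs, annotations of tens to hundreds of genes, and 50–60 kb
genomes for the protein scan. These sizes keep every distributional
check well-powered (binomial standard errors of a few percent) while the
whole suite completes in a few minutes.

## Known limitations

- No linkage structure in the population generator; sweep windows are
  frequency deformations, not genealogical sweeps.
- The effect classifier handles SNPs only (no indels, splice-site or UTR
  subcategories) and uses the first mRNA of each gene.
- The divergence-based clock assumes equal rates in both LTRs and no
  gene conversion between them, which homogenises real LTR pairs and
  biases real ages downward — a property of the method, not the code.
- The monomer estimator assumes one dominant satellite per sequence; two
  interleaved satellites of similar abundance would contest the mode.
- The seed scan is exact-word anchored: seeds more diverged than ~any
  shared 5-mer from every true locus can miss it; profile HMMs are out
  of scope.
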