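# Methods

This note documents the models and procedures implemented in
`ddradmap`, the parameters that matter, the numerical choices, and what
the simulator does and does not emulate.

## The problem

In an outbred cross (a "CP" population in mapping terminology), two
highly heterozygous parents produce an F1 cohort in which each SNP
segregates in one of five informative configurations: lm×ll and nn×np
(heterozygous in one parent, 1:1), hk×hk (heterozygous in both with the
same alleles, 1:2:1), and the multi-allelic ef×eg and ab×cd (1:1:1:1,
realizable for SSRs but not for biallelic SNPs). Without a reference
genome, the catalog of loci must itself be built from the reads, and the
dominant failure mode of the resulting maps is *inflation*: collapsed
paralogs, genotyping errors and missing data force ordering algorithms —
especially maximum-likelihood ordering, which must accommodate every
marker — to stretch linkage groups far beyond their true length. The
package therefore couples marker discovery to an aggressive premapping
filter cascade and to quality diagnostics, rather than maximizing the
number of SNPs mapped.

## De novo reference construction

**Digital normalization (DNR).** Reads are streamed in lexicographic
(individual, read id) order — the true sequencing order is irrelevant to
the rule and lexicographic order makes the output reproducible. A read
is saved as a putative allele iff at least `novelty_fraction` (default
0.5) of its distinct 15-mers are absent from the k-mer index of
previously saved alleles; saving adds its k-mers to the index. For a
101 bp read (87 15-mers) the boundary is exact: 44 novel k-mers save the
read, 43 do not. K-mers are counted as distinct strings without
reverse-complement canonicalization (only forward, restriction-anchored
reads exist here). The rule discards redundant coverage in one pass and
collapses near-identical repeat copies (two sequences differing at ≤ 2
read positions share too many k-mers for the second to be saved) — that
collapse is precisely what later makes paralogous SNPs recognizable as
multi-SNP sequences.

**Lenient matching.** The internal matcher is end-gap-free and
substitution-only: candidate (allele, diagonal) pairs come from shared
15-mers probed at stride 15 along the read (falling back to probing
every offset when the sparse probes find nothing), the best hit is the
candidate with the fewest mismatches over the overlap, ties break by
allele id, and hits above `max_mismatches` (default 8) are discarded.
Because it is seed-based, an alignment with ≤ 8 mismatches but no clean
15-mer window can be missed; with 0.5% per-base error such reads are
vanishingly rare. Assignments from a real aligner can be substituted via
SAM import.

**Support filtering.** Every read (parents and progeny pooled) is
assigned to its best allele; alleles with support ≤ `min_support`
(default 4 — singleton error reads) are removed, as are alleles above a
high-copy bound (organelle DNA, unresolved repeats). The printed default
bound is 500, but an absolute number is only meaningful at one
sequencing scale, so the pipeline default is `max_support="auto"`: 10×
the median support of alleles that clear the low-support floor. Median
single-copy pooled support defines the experiment's natural scale; the
plastid-like sequence sits 20× above it and is always removed, at any
simulated depth.

**Reference deduplication.** Retained alleles within the matcher
tolerance of each other are one locus seen twice. The main source is a
heterozygous locus whose first-saved read carried ≥ 2 well-spread
errors: reads of the other haplotype then clear the half-novel rule, the
locus splits into one allele per haplotype, and the SNP becomes fixed
*between* references instead of segregating *on* one — silently deleting
the marker (~8% of heterozygous loci at 0.5% error). Single-linkage
clusters of near-identical retained alleles are therefore merged to the
highest-support representative and reads are re-assigned. Support bounds
are re-applied after the merge: error-derived variants of the
plastid-like sequence individually sit below the high-copy bound, but
their merged representative absorbs the full organelle read mass and
falls to the cap.

**Center-star reference (CSR).** The alternative builder clusters
progeny reads on parental alleles and emits, per cluster, the sequence
minimizing the total Hamming distance to all other members
(multiplicity-weighted; ties to the lexicographically smallest
sequence) — the member least likely to carry sequencing errors. CSR
recovers no more shared-heterozygous (hk×hk) loci than DNR on simulated
data, which is why DNR is the default.

## Genotyping

The pileup caller is deliberately simple and documented as a stand-in
for a production variant caller, not a reproduction of one: per sample
and position, missing below `min_depth` (default 5), heterozygous when
the minor base fraction reaches `het_min_fraction` (default 0.2),
homozygous for the majority base otherwise; base-count ties break
alphabetically. The defaults are tolerant at 15× progeny coverage (a
heterozygote needs 3 of 15 minor-allele reads) while suppressing error
bases at any realistic depth. A site is emitted when the called
genotypes contain exactly two alleles including the reference base;
positions with more called alleles, or whose two alleles exclude the
reference base (possible when the saved allele itself carries a read
error there), are dropped and counted. Note the 0.2 threshold is exact
at depth 5: one error read in five yields a spurious heterozygote, so
low-coverage samples generate singleton variant sites. These are almost
always non-informative (the deep parents cannot be miscalled this way)
and are swept out before marker encoding; they would appear as multi-SNP
F1 fodder in real data too.

Positions are 1-based throughout (VCF convention); "the first 9 bases"
means positions 1–9 inclusive. Genotypes can also be imported from a
VCF produced by an external caller; biallelic SNP records only.

Progeny genotypes impossible under the parental configuration become
missing and are counted per marker rather than raising an error — one
bad call should not kill a marker, and systematic problems are caught by
the segregation screen. Linkage phase is never inferred; mapping
software owns phase.

## The filter cascade

Order: F1 (multi-SNP sequences) → F2 (SNP position ≤ 9) → F3 (missing
data) → F4 (segregation) → individual exclusion → similarity
deduplication, with marker counts recorded per stage. All boundaries
follow the printed rules and are boundary-tested: support ≤ 4 removed /
5 retained; 500 retained / 501 removed under the printed bound; position
9 removed / 10 retained; missing fraction < 5% retained (11/217
removed, 10/217 retained); χ² = 20.0 removed / 19.99 retained;
individual missing > 90% removed, exactly 90% kept; similarity ≥ 0.945
merged. F1's per-sequence SNP count is a property of the calling stage,
so running F1 and F2 in either order retains the same set. The
missing-data denominator is the currently retained individual cohort
(the full cohort during F3, the reduced cohort afterwards).

The segregation screen offers two modes: the statistic mode (Pearson χ²
value < 20, the cascade default) and a p-value mode (keep p ≥ 0.025, no
multiple-testing correction — the alpha is per marker). How a single
statistic cutoff maps onto a genome-wide alpha when degrees of freedom
differ by configuration (1 for 1:1, 2 for 1:2:1, 3 for 1:1:1:1) is not
well defined, which is exactly why both modes are exposed. The p-value
mode's type-I error is calibration-tested: ~2.5% of true-Mendelian
markers are rejected at n = 217.

Similarity between two markers is the fraction of identical codes among
individuals scored in both; deduplication takes single-linkage clusters
at ≥ 0.945 and keeps the least-missing member (ties by marker id). Note
that in dense simulated maps most merged pairs are genuinely distinct
but tightly linked neighbours in coupling phase — similarity 1 − r —
which is the intended behaviour: they carry no independent ordering
information at the cohort size.

## Linkage QC

The grouping statistic is an independence LOD: a G-test of independence
on the joint genotype-class table of shared individuals, divided by
2 ln 10. It is phase-free, works across configuration types (hk×hk
markers bridge the two parental meioses; lm×ll and nn×np markers of
different parents are independent however tightly linked — the
pseudo-testcross structure), omits zero cells, and returns 0 for
degenerate tables. Grouping is single-linkage transitive closure at a
LOD threshold; the partition is invariant to input order and monotone in
the threshold. The exact grouping formula of commercial mapping software
is proprietary; this statistic implements the same concept.

Two-point recombination fractions are direct counts over unambiguous
meioses for same-type pairs informative through a common parent; phase
unknown means min(r̂, 1 − r̂) is reported. For hk×hk pairs the estimate
conditions on individuals homozygous at the first marker, where both
gametes are known: the second marker's genotype then counts recombinant
gametes exactly (same homozygote 0/2, heterozygote 1/2, opposite
homozygote 2/2). Conditioning instead on double homozygotes would
estimate r²/(r² + (1−r)²) and is avoided.

Distances use the Kosambi function d = 25 ln((1+2r)/(1−2r)) cM; the
length of a given order is the sum of adjacent-pair Kosambi distances.
Map ordering itself (regression or maximum likelihood) is out of scope:
diagnostics accept external map files or the simulator's true order. The
inflation ratio is length(ML)/length(regression) for one group (~1 is
clean, ≫ 1 inflated); order concordance is 1 minus the fraction of
inverted framework pairs, so interleaved SNPs never hurt the score.
Per-group summaries report length/loci **truncated** (not rounded) to
two decimals, matching how published per-group densities are printed
(e.g. 79.9 cM / 51 loci → 1.56).

## The simulator

What it emulates: two heterozygous diploid parents over 12 chromosomes
(85 cM each by default); single-copy restriction loci of 300–500 bp with
uniform random map positions; per-parent heterozygosity `het_rate`
(default 0.3; when both parents are heterozygous they share the SNP, the
shared-polymorphism configuration expected within one population);
Mendelian transmission with crossovers from a Poisson (no-interference)
process on the cM axis; reads as error-perturbed 101 bp prefixes of the
locus haplotypes at the restriction anchor, with Poisson per
locus-individual depth (parents 248×, progeny 15×) and constant high
quality; repeat families as near-identical copies (one private
substitution per copy by default, so copies collapse under the novelty
rule) at scattered positions; and one plastid-like sequence emitted at
`plastid_copy_factor` (default 20) times normal depth in every
individual. Identical config + seed gives byte-identical FASTQ.

What it does not emulate: paired-end reads (reverse reads are not
simulated; only forward reads are used downstream), indels, PCR
duplicates, quality-score error profiles and trimming, allele dropout
from restriction-site polymorphism, crossover interference, or
real repeat-family evolution. Passing tests therefore demonstrate that
the pipeline's logic is correct under a clean generative model of
stacked ddRAD reads — not that any particular real library would yield
the same marker counts.

Because crossovers are Poisson, true pairwise recombination follows
Haldane's map function; at the short distances where tests compare
against the Kosambi inverse (10 cM, n = 2000) the two functions differ
by less than the sampling band, as intended by the choice of the
simplest no-interference process.

A read-free path (`markers_from_truth`) derives error-free CP markers
directly from the truth table, for testing segregation, grouping and
distance machinery in isolation.

## Problem sizes and validation conditions

The package's own validation uses: a 500-locus, 50-progeny family at
248×/15× with 0.5% per-base error for recovery and downsampling-trend
checks (≈ 650k reads, the largest routine computation); a 150-locus,
3-chromosome, 150-progeny family (het_rate 0.5, LOD threshold 10) for
exact linkage-group recovery — chosen so true adjacent LODs sit well
above the null tail of sparse hk×hk tables, verified across several
seeds; 2000 simulated Mendelian markers at n = 217 for χ² calibration;
and printed-table compositions for the exact accounting checks. The
downsampling design experiments reproduce their defining fractions
exactly (52% = 50/96 of each progeny file, 64% = 32/50 of each parent
file), with exact-count sampling without replacement and round-half-up
retained counts (50 reads at 52% → 26), per-read uniform sampling being
the natural reading of "randomly selecting X% of the data".

## Known limitations

* The lenient matcher is a stand-in; its seeded search can miss
  adversarial alignments a full aligner would find.
* The pileup caller has no likelihood model, no base-quality use and no
  indel support; at depth exactly 5 a single error read can fake a
  heterozygote (see above).
* Support-bound semantics at scales far from the defaults rely on the
  auto-scaled cap; a fixed 500 is kept for compatibility with the
  printed rule.
* hk×hk two-point estimates discard heterozygous-at-A individuals and
  are noisier than a likelihood estimator; map-length diagnostics on
  mixed-phase hk×hk chains can be biased toward 0.5 when phases
  alternate.
* Grouping is single-linkage: one spurious high-LOD pair can merge two
  true groups; the threshold must be chosen with cohort size in mind.
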