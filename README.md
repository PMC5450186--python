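# ddradmap

Marker discovery and linkage quality control for ddRADseq in an outbred
F1 family of a species **without a reference genome** — from raw lane
FASTQ to mapping-ready CP markers, with a built-in synthetic family
simulator so every stage can be validated against known truth.

The package is aimed at people building dense genetic maps in
non-model, highly heterozygous outcrossers (forest trees are the
canonical case): two heterozygous parents, a full-sib progeny cohort, a
sparse SSR framework map, and restriction-site-anchored short reads as
the only sequence resource.

## What it does

1. **Simulation** (`ddradmap.simulate`) — a two-parent F1 family over 12
   chromosomes: 300–500 bp restriction-fragment loci read as 101 bp
   single-end reads, parents at 248× and progeny at 15× mean depth,
   per-base substitution error, multi-copy repeat families and a
   plastid-like sequence at several-hundred-fold coverage. Ground truth
   (haplotypes, crossovers, genotypes) is recorded for scoring.
2. **Reads** (`ddradmap.reads`) — FASTQ demultiplexing by exact index
   tag, and seeded exact-count downsampling for sequencing-design
   experiments (Exp1: progeny to 52%; Exp2: progeny 52% and parents 64%).
3. **De novo reference** (`ddradmap.refbuild`) — digital normalization: a
   read is saved as a putative allele only if at least half of its
   15-mers are novel. Support counting by lenient (≤ 8 mismatches,
   15-mer-seeded) alignment of all reads; removal of alleles with ≤ 4
   supporting reads or organelle-scale coverage; deduplication of
   near-identical alleles. A center-star reference is available as an
   alternative.
4. **Genotyping** (`ddradmap.genotyping`) — a minimal pileup caller
   (missing below 5×, heterozygous at minor fraction ≥ 0.2), VCF
   import/export, and classification of parental genotype pairs into the
   five CP-informative configurations (lm×ll, nn×np, hk×hk, ef×eg,
   ab×cd) with per-individual code encoding.
5. **Filter cascade** (`ddradmap.filters`) — the premapping screens:
   F1 drops multi-SNP sequences (collapsed paralogs), F2 drops SNPs in
   the first 9 bases, F3 drops markers with ≥ 5% missing data, F4 drops
   segregation-distorted markers (Pearson χ² ≥ 20, or p < 0.025 in
   p-value mode); then individuals with > 90% missing data are excluded
   and markers with genotype similarity ≥ 0.945 are deduplicated. A
   stage-by-stage accounting report is produced.
6. **Linkage QC** (`ddradmap.mapqc`) — CP locus-file and fixed-order
   export, independence-LOD grouping (LOD = G/(2 ln 10) from a G-test of
   independence, phase-free), two-point recombination fractions, Kosambi
   distances *d* = 25 ln((1+2r)/(1−2r)) cM, map-inflation ratio
   (maximum-likelihood vs regression length), framework-order
   concordance, and per-linkage-group summaries.

`ddradmap.pipeline.run_pipeline` chains stages 3–5;
`ddradmap.evaluate` scores any result against a simulation's truth.

## Worked example

`python examples/04_genotype_and_filter.py` simulates a 60-locus,
10-progeny family, runs the full pipeline and prints:

```
reference alleles: 61
called biallelic sites: 33 (+0 triallelic dropped)
informative CP markers: 31

Sequential filtration
---------------------
input                             31
F1 multi-SNP                      28
F2 position                       26
MD 5%                             23
chi2 < 20                         23
similarity >= 0.945               22
individuals: 10 -> 10

surviving markers by configuration: {'lmxll': 7, 'hkxhk': 6, 'nnxnp': 9}
```

61 reference alleles recover the 60 single-copy loci (the three repeat
copies collapse into one allele and the plastid-like sequence is removed
by the support filter). Of 31 informative SNPs, three sit on the
collapsed repeat sequence and fall to F1, two sit in the artifact-prone
first 9 bases, three carry too much missing data, and one is a
near-duplicate of a tightly linked neighbour — leaving 22 mapping-ready
markers, written as a CP-format locus file. On the same simulated data,
`examples/05_linkage_qc.py` groups the filtered markers of a
3-chromosome family into exactly 3 linkage groups and converts a
two-point recombination fraction of 0.113 into 11.5 cM with the Kosambi
function.

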