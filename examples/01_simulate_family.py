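"""Simulate a two-parent F1 ddRADseq family with known ground truth.

The generator emulates the study conditions: restriction-fragment loci of
300-500 bp read as 101 bp single-end reads, deep parents (248x) and
moderate progeny (15x), per-base error, a multi-copy repeat family, and a
plastid-like sequence at very high copy number.
"""

from collections import Counter

from ddradmap import SimConfig, emit_reads, simulate_family

config = SimConfig(n_loci=60, n_progeny=10, n_chromosomes=3, seed=42)
truth = simulate_family(config)
reads = emit_reads(truth)

classes = Counter(loc.copy_class for loc in truth.loci)
print(f"simulated loci: {dict(classes)}")
informative = sum(
    1 for i in truth.single_copy_loci() if truth.loci[i].snp_position is not None
)
print(f"single-copy loci with a SNP in the read prefix: {informative}")

per_individual = Counter(r.individual_id for r in reads)
print(f"total reads: {len(reads)}")
print(f"reads for parent P1: {per_individual['P1']} (deep coverage)")
print(f"reads for progeny F001: {per_individual['F001']} (moderate coverage)")

# The truth table knows every genotype, so downstream stages can be scored
# against it; e.g. the true genotype of the first informative locus:
i = next(i for i in truth.single_copy_loci() if truth.loci[i].snp_position)
print(
    f"locus {truth.loci[i].locus_id}: parents "
    f"{truth.parent_genotype(i, 0)} x {truth.parent_genotype(i, 1)}, "
    f"progeny F001 {truth.progeny_genotype(i, 0)}"
)
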