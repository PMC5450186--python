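"""Build a de novo reference from reads with digital normalization.

A read becomes a putative allele only if at least half of its 15-mers are
novel; lenient re-alignment of all reads counts per-allele support, and
alleles with <= 4 supporting reads (singleton errors) or organelle-scale
coverage (the plastid-like sequence) are removed.
"""

from ddradmap import SimConfig, emit_reads, simulate_family
from ddradmap.refbuild import (
    DNRParams,
    assign_reads,
    auto_max_support,
    build_dnr,
    dedup_alleles,
    filter_support,
    support_from_matches,
)

truth = simulate_family(SimConfig(n_loci=60, n_progeny=10, n_chromosomes=3, seed=42))
reads = emit_reads(truth)
params = DNRParams()

putative, index = build_dnr(reads, params)
print(f"{len(reads)} reads -> {len(putative)} putative alleles "
      f"({len(index)} distinct 15-mers indexed)")

matches = assign_reads(reads, putative, params)
support_from_matches(putative, matches)
cap = auto_max_support(putative, params)
retained = filter_support(putative, params, max_support=cap)
print(f"high-copy cutoff (10x median single-copy support): {cap}")

flags = {}
for a in putative:
    flags[a.copy_flag] = flags.get(a.copy_flag, 0) + 1
print(f"support filtering: {flags}")
# low_support = singleton error reads; high_copy = the plastid-like
# sequence (support far above any nuclear locus)

final = dedup_alleles(retained, params)
print(f"reference after deduplication: {len(final)} alleles "
      f"(~one per restriction locus)")
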