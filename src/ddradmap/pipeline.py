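"""End-to-end glue: demultiplexed reads -> de novo reference -> genotypes
-> CP markers -> filter cascade.

Stages: digital normalization, lenient read assignment and support
counting, support filtering (with an optional auto-scaled high-copy
cutoff), reference deduplication (retained alleles within the matcher
tolerance of each other are one locus seen twice — typically a
heterozygous locus whose first saved read carried errors), a second
assignment pass against the deduplicated reference, pileup genotyping,
CP-configuration extraction, and the premapping filter cascade.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .filters import CascadeReport, FilterParams, run_cascade
from .genotyping import (
    CallerParams,
    MarkerSet,
    VariantTable,
    markers_from_sites,
    pileup_call,
)
from .reads import SeqRead
from .refbuild import (
    DNRParams,
    Match,
    RefAllele,
    assign_reads,
    auto_max_support,
    build_dnr,
    dedup_alleles,
    filter_support,
    support_from_matches,
)

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    """Everything the pipeline produced, stage by stage."""

    putative_alleles: list[RefAllele]
    alleles: list[RefAllele]
    matches: list[Match | None]
    variant_table: VariantTable
    markers_raw: MarkerSet
    markers: MarkerSet
    cascade: CascadeReport
    max_support_used: int = 0
    reads: list[SeqRead] = field(default_factory=list, repr=False)


def run_pipeline(
    reads: list[SeqRead],
    parents: tuple[str, str] = ("P1", "P2"),
    dnr_params: DNRParams = DNRParams(),
    caller_params: CallerParams = CallerParams(),
    filter_params: FilterParams = FilterParams(),
    max_support: int | str = "auto",
) -> PipelineResult:
    """Run the full marker-discovery pipeline on demultiplexed reads.

    max_support="auto" scales the high-copy cutoff to the experiment
    (10x the median support of alleles clearing the low-support floor),
    so the filter separates single-copy loci from organelle-scale
    coverage at any simulated depth; pass an integer to fix it.
    """
    putative, _ = build_dnr(reads, dnr_params)
    matches = assign_reads(reads, putative, dnr_params)
    support_from_matches(putative, matches)
    if max_support == "auto":
        cap = auto_max_support(putative, dnr_params)
    else:
        cap = int(max_support)
    retained = filter_support(putative, dnr_params, max_support=cap)
    retained = dedup_alleles(retained, dnr_params)
    # Recount support on the deduplicated reference and re-apply the
    # support bounds: a merged allele that absorbs an organelle-scale
    # read mass (e.g. plastid error variants that individually sat below
    # the cap) must still fall to the high-copy filter.
    kept_matches = assign_reads(reads, retained, dnr_params)
    support_from_matches(retained, kept_matches)
    retained = filter_support(retained, dnr_params, max_support=cap)
    retained_ids = {a.allele_id for a in retained}
    kept_matches = [
        m if (m is not None and m.allele_id in retained_ids) else None for m in kept_matches
    ]
    table = pileup_call(reads, kept_matches, retained, caller_params, parents)
    markers_raw = markers_from_sites(table)
    markers, cascade = run_cascade(markers_raw, filter_params)
    return PipelineResult(
        putative_alleles=putative,
        alleles=retained,
        matches=kept_matches,
        variant_table=table,
        markers_raw=markers_raw,
        markers=markers,
        cascade=cascade,
        max_support_used=cap,
        reads=reads,
    )
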