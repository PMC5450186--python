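"""Truth-aware evaluation of pipeline output on simulated families.

These metrics exist because the simulator knows the answers: which locus
sequences are real, which reference alleles are collapsed repeats, and
what every genotype should have been. On real data none of them can be
computed — they quantify how faithfully the pipeline recovers a known
simulated family, nothing more.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genotyping import VariantTable
from .refbuild import AlleleMatcher, DNRParams, RefAllele
from .simulate import PARENT1, PARENT2, TruthTable

__all__ = [
    "allele_recovery",
    "locus_to_allele",
    "genotype_recovery",
    "collapsed_alleles",
]


def locus_to_allele(
    truth: TruthTable,
    alleles: list[RefAllele],
    max_mismatches: int = 8,
) -> dict[str, str | None]:
    """Best-matching reference allele for each single-copy locus (lenient
    match of any of the locus's true read prefixes), or None."""
    params = DNRParams(max_mismatches=max_mismatches)
    matcher = AlleleMatcher(alleles, params)
    R = truth.config.read_length_bp
    out: dict[str, str | None] = {}
    for i in truth.single_copy_loci():
        loc = truth.loci[i]
        best = None
        for prefix in sorted(loc.read_prefixes(R)):
            m = matcher.match(prefix)
            if m is not None and (best is None or (m.mismatches, m.allele_id) < best[:2]):
                best = (m.mismatches, m.allele_id)
        out[loc.locus_id] = best[1] if best else None
    return out


def allele_recovery(
    truth: TruthTable,
    alleles: list[RefAllele],
    max_mismatches: int = 8,
) -> float:
    """Fraction of single-copy loci represented in the reference: a locus
    is recovered when some retained allele matches one of its true read
    prefixes within the lenient-matching tolerance."""
    mapping = locus_to_allele(truth, alleles, max_mismatches)
    if not mapping:
        return 0.0
    return sum(v is not None for v in mapping.values()) / len(mapping)


def genotype_recovery(
    truth: TruthTable,
    table: VariantTable,
    alleles: list[RefAllele],
    max_mismatches: int = 8,
) -> float:
    """Fraction of true genotypes (parents and progeny, at the SNPs of
    polymorphic single-copy loci) called correctly.

    A genotype at a site that was never called, or called missing, counts
    as not recovered. Reads are restriction-anchored, so a locus's SNP
    position maps to the same coordinate on its reference allele.
    """
    mapping = locus_to_allele(truth, alleles, max_mismatches)
    site_index = {(s.ref_allele_id, s.position): s for s in table.sites}
    prog_col = {pid: k for k, pid in enumerate(table.progeny_ids)}
    n_total = n_correct = 0
    for i in truth.single_copy_loci():
        loc = truth.loci[i]
        if loc.snp_position is None:
            continue
        site = site_index.get((mapping.get(loc.locus_id) or "", loc.snp_position))
        for ind in truth.individuals:
            if ind == PARENT1:
                true_gt, called = truth.parent_genotype(i, 0), site and site.parent1_gt
            elif ind == PARENT2:
                true_gt, called = truth.parent_genotype(i, 1), site and site.parent2_gt
            else:
                j = truth.progeny_ids.index(ind)
                true_gt = truth.progeny_genotype(i, j)
                called = site and site.progeny_gts[prog_col[ind]]
            n_total += 1
            n_correct += called is not None and tuple(called) == true_gt
    return n_correct / n_total if n_total else 0.0


@dataclass
class CollapseCheck:
    """Which alleles collapsed several true loci, and whether the
    multi-SNP filter removed every site they produced."""

    collapsed_allele_ids: set[str]
    n_sites_on_collapsed: int
    n_removed_by_f1: int

    @property
    def removed_fraction(self) -> float:
        if self.n_sites_on_collapsed == 0:
            return 1.0
        return self.n_removed_by_f1 / self.n_sites_on_collapsed


def collapsed_alleles(
    truth: TruthTable,
    alleles: list[RefAllele],
    table: VariantTable,
    max_mismatches: int = 8,
) -> CollapseCheck:
    """Identify reference alleles that absorb more than one true locus
    (repeat-family copies within the matcher tolerance) and check the
    multi-SNP filter against the sites they generated."""
    params = DNRParams(max_mismatches=max_mismatches)
    matcher = AlleleMatcher(alleles, params)
    R = truth.config.read_length_bp
    hits: dict[str, set[str]] = {}
    for loc in truth.loci:
        if loc.copy_class == "plastid":
            continue
        for prefix in sorted(loc.read_prefixes(R)):
            m = matcher.match(prefix)
            if m is not None:
                hits.setdefault(m.allele_id, set()).add(loc.locus_id)
    collapsed = {aid for aid, loci in hits.items() if len(loci) > 1}
    per_allele_sites: dict[str, int] = {}
    for s in table.sites:
        per_allele_sites[s.ref_allele_id] = per_allele_sites.get(s.ref_allele_id, 0) + 1
    n_sites = sum(per_allele_sites.get(aid, 0) for aid in collapsed)
    # F1 keeps only single-SNP sequences, so every site on an allele with
    # >= 2 sites is removed; a collapsed allele with exactly one site
    # would survive.
    n_removed = sum(
        per_allele_sites.get(aid, 0)
        for aid in collapsed
        if per_allele_sites.get(aid, 0) > 1
    )
    return CollapseCheck(collapsed, n_sites, n_removed)
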