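"""Biallelic SNP genotyping on the de novo reference and conversion of
parental configurations into mapping-ready CP markers.

In a cross of two outbred, heterozygous parents (a CP population), a SNP
is informative for mapping only if the parental genotype pair falls in one
of five configurations:

=========  ==================================  ==============  =========
seg type   parents                             progeny codes   ratio
=========  ==================================  ==============  =========
lm x ll    het in parent 1 only                lm, ll          1:1
nn x np    het in parent 2 only                nn, np          1:1
hk x hk    het in both, same two alleles       hh, hk, kk      1:2:1
ef x eg    het in both, one shared allele      ee, ef, eg, fg  1:1:1:1
ab x cd    het in both, four distinct alleles  ac, ad, bc, bd  1:1:1:1
=========  ==================================  ==============  =========

For biallelic SNPs only the first three are realizable; the multi-allelic
configurations arise for SSR-style genotype tables. Linkage phase is never
inferred here — downstream mapping software handles phase.

The pileup caller is a deliberately simple depth/fraction genotyper (an
internal stand-in for a production variant caller): a sample is missing
below min_depth, heterozygous when its minor base fraction reaches
het_min_fraction, homozygous for the majority base otherwise. Sites with
more than two observed alleles across samples are dropped. Externally
called genotypes can be imported from VCF instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .reads import SeqRead
from .refbuild import Match, RefAllele

__all__ = [
    "CallerParams",
    "VariantSite",
    "VariantTable",
    "CPMarker",
    "MarkerSet",
    "MISSING",
    "SEG_CODES",
    "pileup_call",
    "write_vcf",
    "read_vcf",
    "classify_configuration",
    "encode_genotype",
    "encode_cp",
    "markers_from_sites",
    "write_marker_table",
    "read_marker_table",
]

MISSING = "--"

#: Legal per-individual codes for each segregation type, in the class
#: order used for segregation tests.
SEG_CODES: dict[str, tuple[str, ...]] = {
    "lmxll": ("lm", "ll"),
    "nnxnp": ("nn", "np"),
    "hkxhk": ("hh", "hk", "kk"),
    "efxeg": ("ee", "ef", "eg", "fg"),
    "abxcd": ("ac", "ad", "bc", "bd"),
}

Genotype = tuple[str, str]  # unordered pair of alleles, stored sorted


@dataclass(frozen=True)
class CallerParams:
    """Thresholds of the internal pileup genotyper."""

    min_depth: int = 5
    het_min_fraction: float = 0.2
    max_alleles: int = 2

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise ValueError(f"min_depth must be >= 1, got {self.min_depth}")
        if not (0.0 < self.het_min_fraction <= 0.5):
            raise ValueError(
                f"het_min_fraction must be in (0, 0.5], got {self.het_min_fraction}"
            )
        if self.max_alleles != 2:
            raise ValueError("only biallelic calling is supported (max_alleles=2)")


@dataclass
class VariantSite:
    """A biallelic SNP on one reference allele sequence.

    position is 1-based within the reference sequence (VCF convention);
    genotypes are unordered allele pairs over {ref_base, alt_base}, or
    None for missing.
    """

    ref_allele_id: str
    position: int
    ref_base: str
    alt_base: str
    parent1_gt: Genotype | None
    parent2_gt: Genotype | None
    progeny_gts: list[Genotype | None]
    parent_depths: tuple[int, int] = (0, 0)
    progeny_depths: list[int] = field(default_factory=list)

    @property
    def site_id(self) -> str:
        return f"{self.ref_allele_id}:{self.position}"


@dataclass
class VariantTable:
    """Sites plus the sample bookkeeping shared by all of them."""

    parents: tuple[str, str]
    progeny_ids: list[str]
    sites: list[VariantSite]
    n_triallelic: int = 0
    n_ref_mismatch: int = 0
    n_skipped_records: int = 0


_BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
_BASES = "ACGT"


def pileup_call(
    reads: Sequence[SeqRead],
    matches: Sequence[Match | None],
    alleles: Sequence[RefAllele],
    params: CallerParams = CallerParams(),
    parents: tuple[str, str] = ("P1", "P2"),
) -> VariantTable:
    """Call biallelic SNP genotypes from read-to-allele assignments.

    ``matches[i]`` is the best lenient hit of ``reads[i]`` (None = not
    assigned). Every reference position where the called genotypes contain
    exactly two alleles, one of them the reference base, is emitted as a
    site; positions with three or more called alleles are dropped and
    counted (n_triallelic), as are two-allele sites whose alleles do not
    include the reference base (n_ref_mismatch, possible when the saved
    allele sequence itself carries a read error at the site).
    """
    allele_by_id = {a.allele_id: a for a in alleles}
    individuals = sorted({r.individual_id for r in reads if r.individual_id})
    for p in parents:
        if p not in individuals:
            raise ValueError(f"parent sample {p!r} absent from reads")
    progeny = [s for s in individuals if s not in parents]
    samples = [parents[0], parents[1]] + progeny
    sample_idx = {s: i for i, s in enumerate(samples)}
    n_samples = len(samples)

    grouped: dict[str, list[tuple[int, int, str]]] = {}
    for r, m in zip(reads, matches):
        if m is None or r.individual_id is None:
            continue
        grouped.setdefault(m.allele_id, []).append(
            (sample_idx[r.individual_id], m.offset, r.bases)
        )

    table = VariantTable(parents=parents, progeny_ids=progeny, sites=[])
    for allele_id in sorted(grouped):
        allele = allele_by_id[allele_id]
        L = len(allele.sequence)
        flat_parts = []
        for si, off, seq in grouped[allele_id]:
            codes = _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
            pos = np.arange(len(codes)) + off
            ok = (pos >= 0) & (pos < L) & (codes < 4)
            flat_parts.append((si * L + pos[ok]) * 4 + codes[ok])
        if not flat_parts:
            continue
        flat = np.concatenate(flat_parts)
        counts = np.bincount(flat, minlength=n_samples * L * 4).reshape(n_samples, L, 4)
        depth = counts.sum(axis=2)
        # Rank bases per sample/position by descending count; stable sort
        # keeps the alphabetically first base on ties.
        order = np.argsort(-counts, axis=2, kind="stable")
        c1 = np.take_along_axis(counts, order[:, :, :1], axis=2)[:, :, 0]
        c2 = np.take_along_axis(counts, order[:, :, 1:2], axis=2)[:, :, 0]
        callable_ = depth >= params.min_depth
        with np.errstate(invalid="ignore", divide="ignore"):
            is_het = callable_ & (c2 / np.maximum(depth, 1) >= params.het_min_fraction) & (c2 > 0)
        ref_codes = _BASE_CODE[np.frombuffer(allele.sequence.encode(), dtype=np.uint8)]

        for pos in range(L):
            gts: list[Genotype | None] = []
            observed: set[str] = set()
            any_called = False
            for si in range(n_samples):
                if not callable_[si, pos]:
                    gts.append(None)
                    continue
                b1 = _BASES[order[si, pos, 0]]
                if is_het[si, pos]:
                    b2 = _BASES[order[si, pos, 1]]
                    gt = tuple(sorted((b1, b2)))
                else:
                    gt = (b1, b1)
                gts.append(gt)
                observed.update(gt)
                any_called = True
            if not any_called or len(observed) < 2:
                continue
            if len(observed) > params.max_alleles:
                table.n_triallelic += 1
                continue
            ref_base = _BASES[ref_codes[pos]] if ref_codes[pos] < 4 else "N"
            if ref_base not in observed:
                table.n_ref_mismatch += 1
                continue
            alt_base = (observed - {ref_base}).pop()
            table.sites.append(
                VariantSite(
                    ref_allele_id=allele_id,
                    position=pos + 1,
                    ref_base=ref_base,
                    alt_base=alt_base,
                    parent1_gt=gts[0],
                    parent2_gt=gts[1],
                    progeny_gts=gts[2:],
                    parent_depths=(int(depth[0, pos]), int(depth[1, pos])),
                    progeny_depths=[int(d) for d in depth[2:, pos]],
                )
            )
    return table


# ---------------------------------------------------------------------------
# VCF interop
# ---------------------------------------------------------------------------


def write_vcf(
    table: VariantTable,
    path: str | Path,
    contig_lengths: dict[str, int] | None = None,
) -> int:
    """Write sites as a minimal VCF 4.2 with GT and DP; returns the number
    of records written."""
    import pysam

    if contig_lengths is None:
        contig_lengths = {}
        for s in table.sites:
            contig_lengths[s.ref_allele_id] = max(
                contig_lengths.get(s.ref_allele_id, 0), s.position
            )
    header = pysam.VariantHeader()
    for contig in sorted(contig_lengths):
        header.contigs.add(contig, length=contig_lengths[contig])
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    samples = [table.parents[0], table.parents[1]] + list(table.progeny_ids)
    for s in samples:
        header.add_sample(s)
    n = 0
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for site in sorted(table.sites, key=lambda s: (s.ref_allele_id, s.position)):
            rec = vf.new_record(
                contig=site.ref_allele_id,
                start=site.position - 1,
                alleles=(site.ref_base, site.alt_base),
            )
            gts = [site.parent1_gt, site.parent2_gt] + list(site.progeny_gts)
            depths = list(site.parent_depths) + list(site.progeny_depths)
            code = {site.ref_base: 0, site.alt_base: 1}
            for sample, gt, dp in zip(samples, gts, depths):
                rec.samples[sample]["GT"] = (
                    (None, None) if gt is None else (code[gt[0]], code[gt[1]])
                )
                rec.samples[sample]["DP"] = int(dp)
            vf.write(rec)
            n += 1
    return n


def read_vcf(path: str | Path, parents: tuple[str, str] = ("P1", "P2")) -> VariantTable:
    """Import biallelic SNP records from a VCF called against the de novo
    reference (CHROM = allele id, POS = 1-based position).

    Non-SNP and multiallelic records are skipped and counted. The two
    parent sample names must be present in the VCF header.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for p in parents:
        if p not in samples:
            raise ValueError(f"parent sample {p!r} missing from VCF {path}")
    progeny = [s for s in samples if s not in parents]
    order = [samples.index(parents[0]), samples.index(parents[1])] + [
        samples.index(s) for s in progeny
    ]
    table = VariantTable(parents=parents, progeny_ids=progeny, sites=[])
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            table.n_skipped_records += 1
            continue
        ref, alt = v.REF, v.ALT[0]
        bases = (ref, alt)
        gts: list[Genotype | None] = []
        for i in order:
            a, b = v.genotypes[i][0], v.genotypes[i][1]
            if a < 0 or b < 0:
                gts.append(None)
            else:
                gts.append(tuple(sorted((bases[a], bases[b]))))
        try:
            dp = v.format("DP")
        except KeyError:  # DP absent from the VCF header
            dp = None
        if dp is not None:
            depths = [max(int(dp[i][0]), 0) for i in order]
        else:
            depths = [0] * len(order)
        table.sites.append(
            VariantSite(
                ref_allele_id=v.CHROM,
                position=int(v.POS),
                ref_base=ref,
                alt_base=alt,
                parent1_gt=gts[0],
                parent2_gt=gts[1],
                progeny_gts=gts[2:],
                parent_depths=(depths[0], depths[1]),
                progeny_depths=depths[2:],
            )
        )
    return table


# ---------------------------------------------------------------------------
# CP configurations
# ---------------------------------------------------------------------------


def classify_configuration(
    parent1_gt: Genotype | None, parent2_gt: Genotype | None
) -> str:
    """Classify a parental genotype pair into one of the five informative
    CP segregation types, or "non_informative".

    A missing parental genotype is non-informative (the marker cannot be
    phased to a configuration without both parents).
    """
    if parent1_gt is None or parent2_gt is None:
        return "non_informative"
    a1, a2 = set(parent1_gt), set(parent2_gt)
    p1_het, p2_het = len(a1) == 2, len(a2) == 2
    if not p1_het and not p2_het:
        return "non_informative"
    if p1_het and not p2_het:
        return "lmxll"
    if p2_het and not p1_het:
        return "nnxnp"
    shared = a1 & a2
    if len(shared) == 2:
        return "hkxhk"
    if len(shared) == 1:
        return "efxeg"
    return "abxcd"


def encode_genotype(
    seg_type: str,
    parent1_gt: Genotype,
    parent2_gt: Genotype,
    progeny_gt: Genotype | None,
) -> str:
    """Map one progeny genotype to its per-individual code, or "--" for
    missing and for genotypes impossible under the parental pair."""
    if progeny_gt is None:
        return MISSING
    a1, a2 = set(parent1_gt), set(parent2_gt)
    g = tuple(sorted(progeny_gt))
    if seg_type == "lmxll":
        diff = a1 - a2
        m = max(diff) if diff else max(a1)
        l = (a1 - {m}).pop()
        if g == tuple(sorted((l, l))):
            return "ll"
        if g == tuple(sorted((l, m))):
            return "lm"
        return MISSING
    if seg_type == "nnxnp":
        diff = a2 - a1
        p = max(diff) if diff else max(a2)
        n = (a2 - {p}).pop()
        if g == tuple(sorted((n, n))):
            return "nn"
        if g == tuple(sorted((n, p))):
            return "np"
        return MISSING
    if seg_type == "hkxhk":
        h, k = sorted(a1)
        return {(h, h): "hh", (h, k): "hk", (k, k): "kk"}.get(g, MISSING)
    if seg_type == "efxeg":
        e = (a1 & a2).pop()
        f = (a1 - a2).pop()
        gg = (a2 - a1).pop()
        mapping = {
            tuple(sorted((e, e))): "ee",
            tuple(sorted((e, f))): "ef",
            tuple(sorted((e, gg))): "eg",
            tuple(sorted((f, gg))): "fg",
        }
        return mapping.get(g, MISSING)
    if seg_type == "abxcd":
        a, b = sorted(a1)
        c, d = sorted(a2)
        mapping = {
            tuple(sorted((a, c))): "ac",
            tuple(sorted((a, d))): "ad",
            tuple(sorted((b, c))): "bc",
            tuple(sorted((b, d))): "bd",
        }
        return mapping.get(g, MISSING)
    raise ValueError(f"unknown segregation type {seg_type!r}")


@dataclass
class CPMarker:
    """A mapping-ready marker: segregation type plus per-individual codes
    ("--" for missing). Phase is recorded as unknown, never inferred."""

    marker_id: str
    seg_type: str
    codes: list[str]
    source_allele: str = ""
    position: int = 0
    phase: str = "unknown"
    n_mendel_inconsistent: int = 0

    def __post_init__(self) -> None:
        legal = set(SEG_CODES[self.seg_type]) | {MISSING}
        bad = set(self.codes) - legal
        if bad:
            raise ValueError(
                f"marker {self.marker_id}: codes {sorted(bad)} illegal for {self.seg_type}"
            )

    @property
    def missing_fraction(self) -> float:
        if not self.codes:
            return 1.0
        return sum(c == MISSING for c in self.codes) / len(self.codes)


@dataclass
class MarkerSet:
    """CP markers scored on a shared, ordered list of progeny individuals."""

    individuals: list[str]
    markers: list[CPMarker]

    def __len__(self) -> int:
        return len(self.markers)

    def subset_individuals(self, keep: Sequence[str]) -> "MarkerSet":
        idx = [self.individuals.index(i) for i in keep]
        markers = [
            CPMarker(
                m.marker_id,
                m.seg_type,
                [m.codes[j] for j in idx],
                m.source_allele,
                m.position,
                m.phase,
                m.n_mendel_inconsistent,
            )
            for m in self.markers
        ]
        return MarkerSet(list(keep), markers)


def encode_cp(site: VariantSite, seg_type: str) -> CPMarker:
    """Transform one informative site into a CP marker.

    Progeny genotypes impossible under the parental pair become missing
    and are counted as Mendelian inconsistencies (one bad call should not
    kill a marker; systematic problems are caught by the segregation
    screen downstream).
    """
    if seg_type == "non_informative":
        raise ValueError(f"site {site.site_id} is not informative")
    assert site.parent1_gt is not None and site.parent2_gt is not None
    codes = []
    n_bad = 0
    for gt in site.progeny_gts:
        code = encode_genotype(seg_type, site.parent1_gt, site.parent2_gt, gt)
        if code == MISSING and gt is not None:
            n_bad += 1
        codes.append(code)
    return CPMarker(
        marker_id=site.site_id,
        seg_type=seg_type,
        codes=codes,
        source_allele=site.ref_allele_id,
        position=site.position,
        n_mendel_inconsistent=n_bad,
    )


def markers_from_sites(table: VariantTable) -> MarkerSet:
    """Keep the informative sites of a variant table as CP markers."""
    markers = []
    for site in table.sites:
        seg = classify_configuration(site.parent1_gt, site.parent2_gt)
        if seg == "non_informative":
            continue
        markers.append(encode_cp(site, seg))
    return MarkerSet(list(table.progeny_ids), markers)


# ---------------------------------------------------------------------------
# Marker table TSV
# ---------------------------------------------------------------------------

_META_COLS = ["marker_id", "seg_type", "source_allele", "position", "phase"]


def write_marker_table(ms: MarkerSet, path: str | Path) -> None:
    rows = []
    for m in ms.markers:
        row = {
            "marker_id": m.marker_id,
            "seg_type": m.seg_type,
            "source_allele": m.source_allele,
            "position": m.position,
            "phase": m.phase,
        }
        row.update(dict(zip(ms.individuals, m.codes)))
        rows.append(row)
    pd.DataFrame(rows, columns=_META_COLS + list(ms.individuals)).to_csv(
        path, sep="\t", index=False
    )


def read_marker_table(path: str | Path) -> MarkerSet:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna(MISSING)
    individuals = [c for c in df.columns if c not in _META_COLS]
    markers = [
        CPMarker(
            row["marker_id"],
            row["seg_type"],
            [row[i] for i in individuals],
            row["source_allele"],
            int(row["position"]),
            row["phase"],
        )
        for _, row in df.iterrows()
    ]
    return MarkerSet(individuals, markers)
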