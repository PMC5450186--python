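"""De novo reference construction from ddRADseq reads.

Two strategies are provided for species without a reference genome:

* **DNR** (digital-normalization reference): stream reads in a fixed order
  and save a read as a putative allele only if at least half of its 15-mers
  are novel, i.e. not seen in any previously saved allele. This discards
  redundant coverage and collapses repetitive sequence quickly. Putative
  alleles are then support-filtered: lenient alignment of *all* reads back
  onto the putative alleles counts per-allele support, and alleles with
  support <= min_support (likely singleton error reads) or > max_support
  (repeats and organelle-derived sequence, e.g. plastid DNA) are removed.

* **CSR** (center-star reference): progeny reads are clustered by lenient
  alignment to a parental allele; within each cluster all pairwise
  distances are computed and the sequence minimizing the total distance to
  the others (the center of the star) becomes the cluster's reference
  allele, on the premise that it carries the fewest sequencing errors.

The internal lenient matcher is an end-gap-free, substitution-only,
15-mer-seeded aligner with a mismatch budget (default 8), standing in for
a permissive short-read aligner. Assignments from an external aligner can
be imported from SAM instead (:func:`matches_from_sam`).
"""

from __future__ import annotations

import statistics
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .reads import SeqRead

__all__ = [
    "DNRParams",
    "RefAllele",
    "KmerIndex",
    "Match",
    "AlleleMatcher",
    "build_dnr",
    "lenient_match",
    "assign_reads",
    "support_from_matches",
    "count_support",
    "filter_support",
    "dedup_alleles",
    "auto_max_support",
    "build_csr",
    "matches_from_sam",
    "write_fasta",
    "read_fasta",
]


@dataclass(frozen=True)
class DNRParams:
    """Parameters of digital normalization and support filtering.

    k: k-mer size used for the novelty rule and for match seeding.
    novelty_fraction: minimum fraction of a read's distinct k-mers that
        must be novel for the read to be saved as a putative allele.
    min_support: alleles with support <= this are removed (low_support).
    max_support: alleles with support > this are removed (high_copy).
    max_mismatches: mismatch budget of the lenient matcher.
    """

    k: int = 15
    novelty_fraction: float = 0.5
    min_support: int = 4
    max_support: int = 500
    max_mismatches: int = 8

    def __post_init__(self) -> None:
        if not (0.0 < self.novelty_fraction <= 1.0):
            raise ValueError(f"novelty_fraction must be in (0, 1], got {self.novelty_fraction}")
        if self.min_support >= self.max_support:
            raise ValueError(
                f"min_support ({self.min_support}) must be < max_support ({self.max_support})"
            )
        if self.k < 1:
            raise ValueError(f"k must be positive, got {self.k}")
        if self.max_mismatches < 0:
            raise ValueError(f"max_mismatches must be >= 0, got {self.max_mismatches}")


@dataclass
class RefAllele:
    """A putative de novo locus sequence.

    copy_flag is "retained" after support filtering, or the reason for
    removal ("low_support" / "high_copy").
    """

    allele_id: str
    sequence: str
    support: int = 0
    source: str = "DNR"
    copy_flag: str = "retained"


class KmerIndex:
    """Membership set of the k-mers of all saved alleles.

    K-mers are counted as distinct strings: a k-mer occurring twice in a
    read counts once, and no reverse-complement canonicalization is done
    (only forward reads are used).
    """

    def __init__(self, k: int = 15) -> None:
        self.k = int(k)
        self.kmers: set[str] = set()

    def kmers_of(self, seq: str) -> set[str]:
        k = self.k
        return {seq[i : i + k] for i in range(len(seq) - k + 1)}

    def novelty(self, seq: str) -> tuple[int, int]:
        """(number of novel distinct k-mers, number of distinct k-mers)."""
        kmers = self.kmers_of(seq)
        return len(kmers - self.kmers), len(kmers)

    def add(self, seq: str) -> None:
        self.kmers |= self.kmers_of(seq)

    def __len__(self) -> int:
        return len(self.kmers)

    def __contains__(self, kmer: str) -> bool:
        return kmer in self.kmers


def _stream_order(reads: Iterable[SeqRead]) -> list[SeqRead]:
    # Deterministic, documented processing order: lexicographic by
    # (individual_id, read_id). Determinism matters more than matching any
    # particular sequencing-run order.
    return sorted(reads, key=lambda r: (r.individual_id or "", r.read_id))


def build_dnr(
    reads: Iterable[SeqRead],
    params: DNRParams = DNRParams(),
) -> tuple[list[RefAllele], KmerIndex]:
    """Digital normalization: save reads whose k-mer content is mostly novel.

    Reads are processed in lexicographic (individual_id, read_id) order. A
    read is saved as a putative allele iff its count of novel distinct
    k-mers is >= novelty_fraction * (its count of distinct k-mers); saving
    a read adds all its k-mers to the index. Reads shorter than k are
    skipped with a warning count.
    """
    index = KmerIndex(params.k)
    alleles: list[RefAllele] = []
    n_short = 0
    for r in _stream_order(reads):
        if len(r.bases) < params.k:
            n_short += 1
            continue
        novel, total = index.novelty(r.bases)
        if novel >= params.novelty_fraction * total:
            alleles.append(RefAllele(f"A{len(alleles) + 1:06d}", r.bases))
            index.add(r.bases)
    if n_short:
        warnings.warn(f"build_dnr: skipped {n_short} reads shorter than k={params.k}")
    return alleles, index


# ---------------------------------------------------------------------------
# Lenient matching
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Match:
    """Best lenient hit of a read: allele, mismatch count over the
    end-gap-free overlap, and the allele coordinate of the read's first
    base (negative if the read overhangs the allele start)."""

    allele_id: str
    mismatches: int
    offset: int


class AlleleMatcher:
    """15-mer-seeded, end-gap-free, substitution-only matcher.

    Candidate (allele, diagonal) pairs come from shared k-mers probed at
    stride k along the read; if the sparse probes find no candidate, every
    k-mer of the read is probed before giving up. The best hit is the
    candidate with the fewest mismatches over the overlap (overlap >= k
    required); ties break by lowest allele_id. No hit within the mismatch
    budget returns None.
    """

    def __init__(self, alleles: Sequence[RefAllele], params: DNRParams = DNRParams()) -> None:
        self.params = params
        self.alleles = sorted(alleles, key=lambda a: a.allele_id)
        self._arrs = [np.frombuffer(a.sequence.encode(), dtype=np.uint8) for a in self.alleles]
        self._by_seq: dict[str, int] = {}
        for i, a in enumerate(self.alleles):
            self._by_seq.setdefault(a.sequence, i)
        k = params.k
        seeds: dict[str, list[tuple[int, int]]] = {}
        for i, a in enumerate(self.alleles):
            seq = a.sequence
            for p in range(len(seq) - k + 1):
                seeds.setdefault(seq[p : p + k], []).append((i, p))
        self._seeds = seeds

    def _candidates(self, seq: str, positions: Iterable[int]) -> set[tuple[int, int]]:
        k = self.params.k
        cands: set[tuple[int, int]] = set()
        for p in positions:
            for i, ap in self._seeds.get(seq[p : p + k], ()):
                cands.add((i, ap - p))
        return cands

    def match(self, seq: str) -> Match | None:
        exact = self._by_seq.get(seq)
        if exact is not None:
            return Match(self.alleles[exact].allele_id, 0, 0)
        k = self.params.k
        if len(seq) < k:
            return None
        last = len(seq) - k
        probes = list(range(0, last, k)) + [last]
        cands = self._candidates(seq, probes)
        if not cands:
            cands = self._candidates(seq, range(last + 1))
        if not cands:
            return None
        r = np.frombuffer(seq.encode(), dtype=np.uint8)
        best: tuple[int, str] | None = None
        for i, off in sorted(cands):
            a = self._arrs[i]
            if off >= 0:
                n = min(len(r), len(a) - off)
                if n < k:
                    continue
                mm = int(np.count_nonzero(r[:n] != a[off : off + n]))
            else:
                n = min(len(a), len(r) + off)
                if n < k:
                    continue
                mm = int(np.count_nonzero(r[-off : -off + n] != a[:n]))
            if mm <= self.params.max_mismatches:
                key = (mm, self.alleles[i].allele_id)
                if best is None or key < best:
                    best = key
                    best_off = off
        if best is None:
            return None
        return Match(best[1], best[0], best_off)


def lenient_match(
    read: SeqRead | str,
    alleles: Sequence[RefAllele],
    max_mismatches: int = 8,
) -> Match | None:
    """One-shot lenient match of a read against an allele set.

    For matching many reads build one :class:`AlleleMatcher` and reuse it.
    """
    seq = read if isinstance(read, str) else read.bases
    params = DNRParams(max_mismatches=max_mismatches)
    return AlleleMatcher(alleles, params).match(seq)


def assign_reads(
    reads: Sequence[SeqRead],
    alleles: Sequence[RefAllele],
    params: DNRParams = DNRParams(),
) -> list[Match | None]:
    """Best lenient hit for every read (None where no hit)."""
    matcher = AlleleMatcher(alleles, params)
    return [matcher.match(r.bases) for r in reads]


def support_from_matches(
    alleles: Sequence[RefAllele], matches: Iterable[Match | None]
) -> list[RefAllele]:
    """Set allele.support = number of reads whose best hit is the allele."""
    counts: dict[str, int] = {a.allele_id: 0 for a in alleles}
    for m in matches:
        if m is not None:
            counts[m.allele_id] += 1
    for a in alleles:
        a.support = counts[a.allele_id]
    return list(alleles)


def count_support(
    reads: Sequence[SeqRead],
    alleles: Sequence[RefAllele],
    params: DNRParams = DNRParams(),
) -> list[RefAllele]:
    """Count pooled (parents + progeny) read support per putative allele."""
    return support_from_matches(alleles, assign_reads(reads, alleles, params))


def filter_support(
    alleles: Sequence[RefAllele],
    params: DNRParams = DNRParams(),
    max_support: int | None = None,
) -> list[RefAllele]:
    """Remove low-support and extraordinarily highly covered alleles.

    Retained iff min_support < support <= max_support; removed alleles are
    flagged low_support or high_copy. ``max_support`` overrides the value
    in ``params`` when given (e.g. an :func:`auto_max_support` bound scaled
    to the experiment's pooled coverage).
    """
    cap = params.max_support if max_support is None else max_support
    retained = []
    for a in alleles:
        if a.support <= params.min_support:
            a.copy_flag = "low_support"
        elif a.support > cap:
            a.copy_flag = "high_copy"
        else:
            a.copy_flag = "retained"
            retained.append(a)
    return retained


def dedup_alleles(
    alleles: Sequence[RefAllele],
    params: DNRParams = DNRParams(),
) -> list[RefAllele]:
    """Merge retained alleles that lie within the lenient-matching
    tolerance of each other.

    Two reference alleles closer than max_mismatches cannot be told apart
    by the matcher and are one locus seen twice — typically a
    heterozygous locus whose first saved read carried errors, letting the
    other haplotype slip past the novelty rule. Single-linkage clusters
    are reduced to the highest-support member (ties by lowest allele_id);
    re-assign reads against the deduplicated set afterwards so the merged
    locus pileup carries both haplotypes again.
    """
    alleles = sorted(alleles, key=lambda a: a.allele_id)
    k = params.k
    seeds: dict[str, list[int]] = {}
    for i, a in enumerate(alleles):
        for p in range(len(a.sequence) - k + 1):
            seeds.setdefault(a.sequence[p : p + k], []).append(i)
    parent = list(range(len(alleles)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    arrs = [np.frombuffer(a.sequence.encode(), dtype=np.uint8) for a in alleles]
    for i, a in enumerate(alleles):
        cands = set()
        for p in range(0, len(a.sequence) - k + 1, k):
            cands.update(seeds.get(a.sequence[p : p + k], ()))
        for j in cands:
            if j <= i or find(i) == find(j):
                continue
            n = min(len(arrs[i]), len(arrs[j]))
            if n >= k and int(np.count_nonzero(arrs[i][:n] != arrs[j][:n])) <= params.max_mismatches:
                ri, rj = find(i), find(j)
                parent[max(ri, rj)] = min(ri, rj)

    clusters: dict[int, list[int]] = {}
    for i in range(len(alleles)):
        clusters.setdefault(find(i), []).append(i)
    kept = []
    for members in clusters.values():
        members.sort(key=lambda i: (-alleles[i].support, alleles[i].allele_id))
        rep = alleles[members[0]]
        rep.support = sum(alleles[i].support for i in members)
        kept.append(rep)
    kept.sort(key=lambda a: a.allele_id)
    return kept


def auto_max_support(alleles: Sequence[RefAllele], params: DNRParams = DNRParams()) -> int:
    """High-copy cutoff scaled to the experiment: 10x the median support of
    alleles that already clear the low-support floor.

    An absolute cutoff only makes sense for one sequencing scale; the
    intent of the filter is to remove sequence covered at repeat or
    organelle scale, i.e. far above typical single-copy pooled coverage.
    """
    supports = [a.support for a in alleles if a.support > params.min_support]
    if not supports:
        return params.max_support
    return max(params.max_support, int(10 * statistics.median(supports)))


# ---------------------------------------------------------------------------
# Center-star reference
# ---------------------------------------------------------------------------


def _hamming_overlap(a: str, b: str) -> int:
    # Same-length, restriction-anchored reads: distance over the aligned
    # (equal-prefix) overlap.
    n = min(len(a), len(b))
    x = np.frombuffer(a[:n].encode(), dtype=np.uint8)
    y = np.frombuffer(b[:n].encode(), dtype=np.uint8)
    return int(np.count_nonzero(x != y))


def center_star(sequences: Sequence[str]) -> str:
    """The sequence minimizing the total Hamming distance to all other
    cluster members (a sequence present several times counts each time);
    ties break by the lexicographically smallest sequence.

    Distinct sequences are compared pairwise once and weighted by their
    multiplicity — identical copies are at distance zero anyway.
    """
    if not sequences:
        raise ValueError("center_star: empty cluster")
    counts = Counter(sequences)
    uniq = sorted(counts)
    if len(uniq) == 1:
        return uniq[0]
    weights = np.array([counts[s] for s in uniq])
    same_len = len({len(s) for s in uniq}) == 1
    if same_len:
        mat = np.stack([np.frombuffer(s.encode(), dtype=np.uint8) for s in uniq])
        totals = [
            int((np.count_nonzero(mat != mat[i], axis=1) * weights).sum()) for i in range(len(uniq))
        ]
    else:
        totals = [
            sum(_hamming_overlap(s, t) * counts[t] for t in uniq) for s in uniq
        ]
    best = min(range(len(uniq)), key=lambda i: (totals[i], uniq[i]))
    return uniq[best]


def build_csr(
    parent_alleles: Sequence[RefAllele],
    progeny_reads: Sequence[SeqRead],
    params: DNRParams = DNRParams(),
) -> list[RefAllele]:
    """Center-star reference: cluster progeny reads on parental alleles and
    emit each cluster's center-star sequence as the reference allele.

    A cluster of size 1 emits its sole sequence flagged "singleton".
    """
    matcher = AlleleMatcher(parent_alleles, params)
    clusters: dict[str, list[str]] = {}
    for r in progeny_reads:
        m = matcher.match(r.bases)
        if m is not None:
            clusters.setdefault(m.allele_id, []).append(r.bases)
    out: list[RefAllele] = []
    for i, pid in enumerate(sorted(clusters)):
        seqs = clusters[pid]
        allele = RefAllele(f"C{i + 1:06d}", center_star(seqs), support=len(seqs), source="CSR")
        if len(seqs) == 1:
            allele.copy_flag = "singleton"
        out.append(allele)
    return out


# ---------------------------------------------------------------------------
# Interop
# ---------------------------------------------------------------------------


def matches_from_sam(path: str, alleles: Sequence[RefAllele]) -> list[tuple[str, Match]]:
    """Import read-to-allele assignments from a SAM file produced by an
    external aligner, as (query_name, Match) pairs.

    Mismatch counts come from the NM tag (0 when absent); unmapped records
    and records on unknown references are skipped.
    """
    import pysam

    known = {a.allele_id for a in alleles}
    out: list[tuple[str, Match]] = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.reference_name not in known:
                continue
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            out.append((rec.query_name, Match(rec.reference_name, int(nm), rec.reference_start)))
    return out


def write_fasta(alleles: Iterable[RefAllele], path: str) -> int:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(a.sequence), id=a.allele_id, description=f"support={a.support}")
        for a in alleles
    ]
    return seqio_write(records, path, "fasta")


def read_fasta(path: str, source: str = "DNR") -> list[RefAllele]:
    from Bio.SeqIO import parse as seqio_parse

    return [RefAllele(rec.id, str(rec.seq), source=source) for rec in seqio_parse(path, "fasta")]
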