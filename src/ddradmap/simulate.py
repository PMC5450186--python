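"""Synthetic ddRADseq datasets for a two-parent outbred F1 family with
known ground truth, so every downstream stage is testable without
external data.

The generator emulates the structure of a restriction-site-associated
sequencing experiment in a diploid outcrosser with 12 chromosomes and no
reference genome: size-selected restriction-fragment loci of 300-500 bp,
two highly heterozygous parents sequenced deep (248x per locus) and a
moderately covered progeny cohort (15x), per-base substitution error,
multi-copy near-identical repeat families, and one plastid-like sequence
present at several-hundred-fold coverage in every individual. Reads are
single-end, constant-quality prefixes of the locus haplotypes, anchored
at the restriction site (the stacked-read structure of ddRADseq).

Meiosis is Mendelian with crossovers placed by a Poisson (no
interference) process along the centimorgan axis, so the expected
recombinant fraction between two loci follows Haldane's map function —
which agrees with other standard map functions at small distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import genotyping
from .genotyping import CPMarker, MarkerSet
from .reads import SeqRead

__all__ = [
    "RepeatFamily",
    "SimConfig",
    "Locus",
    "TruthTable",
    "simulate_parents",
    "simulate_progeny",
    "simulate_family",
    "emit_reads",
    "markers_from_truth",
    "write_truth_table",
    "PARENT1",
    "PARENT2",
]

PARENT1 = "P1"
PARENT2 = "P2"

_BASES = "ACGT"


@dataclass(frozen=True)
class RepeatFamily:
    """A multi-copy near-identical locus family.

    divergence is the per-copy fraction of substituted sites within the
    read-visible prefix; each copy receives max(1, round(divergence *
    read_length)) private substitutions at positions distinct across the
    family, so any two copies differ at >= 2 such sites. Note that copies
    only collapse into one reference allele when their pairwise
    difference stays below the half-novel threshold of the
    digital-normalization rule (about 3 differing read positions);
    1 substitution per copy (divergence ~0.01 at 101 bp) collapses,
    strongly diverged families behave as distinct loci.
    """

    copy_number: int
    divergence: float


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the simulated family.

    Defaults reflect the experimental design the simulator emulates: 12
    chromosomes, 300-500 bp size-selected loci read as 101 bp single-end
    prefixes, parents at 248x and progeny at 15x mean per-locus depth,
    and one plastid-like sequence at several-hundred-fold pooled support.
    het_rate is the probability that a locus is heterozygous in a given
    parent (0.3 by default — a highly heterozygous outcrosser).
    """

    n_chromosomes: int = 12
    n_loci: int = 500
    locus_length_range: tuple[int, int] = (300, 500)
    read_length_bp: int = 101
    n_progeny: int = 50
    depth_parent: float = 248.0
    depth_progeny: float = 15.0
    error_rate: float = 0.005
    het_rate: float = 0.3
    repeat_families: tuple[RepeatFamily, ...] = (RepeatFamily(3, 0.01),)
    plastid_copy_factor: float = 20.0
    chrom_length_cM: float = 85.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_chromosomes", "n_loci", "read_length_bp", "n_progeny"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        lo, hi = self.locus_length_range
        if not (0 < lo <= hi):
            raise ValueError(f"locus_length_range invalid: {self.locus_length_range}")
        if self.read_length_bp > lo:
            raise ValueError(
                f"read_length_bp ({self.read_length_bp}) exceeds minimum locus length ({lo})"
            )
        if not (0.0 <= self.error_rate < 1.0):
            raise ValueError(f"error_rate must be in [0, 1), got {self.error_rate}")
        if not (0.0 <= self.het_rate <= 1.0):
            raise ValueError(f"het_rate must be in [0, 1], got {self.het_rate}")
        if self.depth_parent <= 0 or self.depth_progeny <= 0:
            raise ValueError("depth_parent and depth_progeny must be positive")
        if self.chrom_length_cM < 0:
            raise ValueError(f"chrom_length_cM must be >= 0, got {self.chrom_length_cM}")
        for fam in self.repeat_families:
            if fam.copy_number < 2:
                raise ValueError(f"repeat_families copy_number must be >= 2, got {fam.copy_number}")
            if not (0.0 < fam.divergence < 1.0):
                raise ValueError(f"repeat_families divergence must be in (0,1), got {fam.divergence}")
        if self.plastid_copy_factor < 0:
            raise ValueError(f"plastid_copy_factor must be >= 0, got {self.plastid_copy_factor}")

    @classmethod
    def from_file(cls, path: str | Path) -> "SimConfig":
        """Load a flat key=value config file.

        repeat_families uses ``copies:divergence`` items separated by
        commas, e.g. ``repeat_families = 3:0.03,2:0.05``.
        """
        kwargs: dict = {}
        for lineno, line in enumerate(open(path), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key = value")
            key, value = (s.strip() for s in line.split("=", 1))
            if key == "repeat_families":
                fams = []
                if value:
                    for item in value.split(","):
                        c, d = item.split(":")
                        fams.append(RepeatFamily(int(c), float(d)))
                kwargs[key] = tuple(fams)
            elif key == "locus_length_range":
                lo, hi = value.split("-")
                kwargs[key] = (int(lo), int(hi))
            elif key in ("n_chromosomes", "n_loci", "read_length_bp", "n_progeny", "seed"):
                kwargs[key] = int(value)
            else:
                kwargs[key] = float(value)
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg


@dataclass
class Locus:
    """One restriction-fragment locus with its four parental haplotype
    sequences ((P1a, P1b), (P2a, P2b)) and, if polymorphic, the 1-based
    SNP position within the read-visible prefix."""

    locus_id: str
    chrom: int  # -1 for the plastid-like sequence
    pos_cM: float
    copy_class: str  # "single" | "repeat" | "plastid"
    haplotypes: tuple[tuple[str, str], tuple[str, str]]
    snp_position: int | None = None
    snp_alleles: tuple[str, str] | None = None
    family_id: str | None = None

    def read_prefixes(self, read_length: int) -> set[str]:
        return {h[:read_length] for pair in self.haplotypes for h in pair}


@dataclass
class TruthTable:
    """Ground truth of a simulated family.

    inheritance[j, i, p] is the haplotype label (0/1) progeny j inherited
    from parent p at locus i; loci are sorted by (chromosome, cM).
    """

    config: SimConfig
    loci: list[Locus]
    progeny_ids: list[str] = field(default_factory=list)
    inheritance: np.ndarray | None = None
    index_map: dict[str, str] = field(default_factory=dict)

    @property
    def individuals(self) -> list[str]:
        return [PARENT1, PARENT2] + list(self.progeny_ids)

    def single_copy_loci(self) -> list[int]:
        return [i for i, loc in enumerate(self.loci) if loc.copy_class == "single"]

    def progeny_genotype(self, locus_index: int, progeny_index: int) -> tuple[str, str] | None:
        """True unordered base pair of a progeny at a locus SNP position."""
        loc = self.loci[locus_index]
        if loc.snp_position is None or self.inheritance is None:
            return None
        h1 = self.inheritance[progeny_index, locus_index, 0]
        h2 = self.inheritance[progeny_index, locus_index, 1]
        b1 = loc.haplotypes[0][h1][loc.snp_position - 1]
        b2 = loc.haplotypes[1][h2][loc.snp_position - 1]
        return tuple(sorted((b1, b2)))

    def parent_genotype(self, locus_index: int, parent: int) -> tuple[str, str] | None:
        loc = self.loci[locus_index]
        if loc.snp_position is None:
            return None
        pair = loc.haplotypes[parent]
        return tuple(sorted(h[loc.snp_position - 1] for h in pair))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def _mutate(seq: str, pos0: int, rng: np.random.Generator) -> tuple[str, str, str]:
    """Substitute position pos0 (0-based) with a different base; returns
    (new_seq, old_base, new_base)."""
    old = seq[pos0]
    new = _BASES[(_BASES.index(old) + int(rng.integers(1, 4))) % 4]
    return seq[:pos0] + new + seq[pos0 + 1 :], old, new


def simulate_parents(config: SimConfig) -> TruthTable:
    """Generate the parental part of the truth: locus sequences, map
    positions, heterozygosity configurations, repeat families and the
    plastid-like sequence.

    With probability het_rate a locus is heterozygous in a given parent;
    when both parents are heterozygous they share the same SNP position
    and alleles (the shared-polymorphism configuration expected between
    outcrossing parents of the same population).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.locus_length_range
    R = config.read_length_bp

    raw: list[Locus] = []
    # Single-copy loci, round-robin across chromosomes.
    for i in range(config.n_loci):
        chrom = i % config.n_chromosomes
        pos = float(rng.uniform(0.0, config.chrom_length_cM))
        length = int(rng.integers(lo, hi + 1))
        seq = _random_seq(rng, length)
        p1_het = rng.random() < config.het_rate
        p2_het = rng.random() < config.het_rate
        snp_position = None
        snp_alleles = None
        h1: tuple[str, str] = (seq, seq)
        h2: tuple[str, str] = (seq, seq)
        if p1_het or p2_het:
            pos0 = int(rng.integers(0, R))
            alt_seq, ref_b, alt_b = _mutate(seq, pos0, rng)
            snp_position = pos0 + 1
            snp_alleles = (ref_b, alt_b)
            if p1_het:
                h1 = (seq, alt_seq) if rng.random() < 0.5 else (alt_seq, seq)
            if p2_het:
                h2 = (seq, alt_seq) if rng.random() < 0.5 else (alt_seq, seq)
        raw.append(Locus("", chrom, pos, "single", (h1, h2), snp_position, snp_alleles))

    # Repeat families: near-identical copies at distinct positions.
    for fi, fam in enumerate(config.repeat_families):
        length = int(rng.integers(lo, hi + 1))
        base = _random_seq(rng, length)
        n_mut = max(1, round(fam.divergence * R))
        sites = rng.choice(R, size=fam.copy_number * n_mut, replace=False)
        for c in range(fam.copy_number):
            seq = base
            for pos0 in sites[c * n_mut : (c + 1) * n_mut]:
                seq, _, _ = _mutate(seq, int(pos0), rng)
            chrom = int(rng.integers(0, config.n_chromosomes))
            pos = float(rng.uniform(0.0, config.chrom_length_cM))
            raw.append(
                Locus("", chrom, pos, "repeat", ((seq, seq), (seq, seq)), family_id=f"R{fi + 1}")
            )

    # Plastid-like very-high-copy sequence, off the nuclear map.
    if config.plastid_copy_factor > 0:
        length = int(rng.integers(lo, hi + 1))
        seq = _random_seq(rng, length)
        raw.append(Locus("", -1, 0.0, "plastid", ((seq, seq), (seq, seq))))

    # Sort by genome coordinate and assign ids; nudge cM ties apart so
    # positions are strictly increasing within a chromosome.
    raw.sort(key=lambda loc: (loc.chrom, loc.pos_cM))
    loci: list[Locus] = []
    prev: tuple[int, float] | None = None
    for i, loc in enumerate(raw):
        pos = loc.pos_cM
        if prev is not None and loc.chrom == prev[0] and pos <= prev[1]:
            pos = np.nextafter(prev[1], np.inf)
        prev = (loc.chrom, pos)
        loc.pos_cM = pos
        loc.locus_id = f"L{i + 1:05d}"
        loci.append(loc)

    truth = TruthTable(config=config, loci=loci)
    truth.index_map = _make_index_map(truth)
    return truth


def _make_index_map(truth: TruthTable) -> dict[str, str]:
    # Deterministic 8 bp index tags, one per individual.
    config = truth.config
    individuals = [PARENT1, PARENT2] + [
        f"F{j + 1:03d}" for j in range(config.n_progeny)
    ]
    tags = {}
    for idx, ind in enumerate(individuals):
        digits = []
        x = idx
        for _ in range(8):
            digits.append(_BASES[x % 4])
            x //= 4
        tags["".join(reversed(digits))] = ind
    return tags


def simulate_progeny(truth: TruthTable, config: SimConfig | None = None) -> TruthTable:
    """Draw the progeny cohort: one gamete per parent per chromosome, with
    crossovers placed by a Poisson process along the cM axis.

    Fills truth.progeny_ids and truth.inheritance in place (and returns
    the table). Off-chromosome sequence (the plastid-like locus) always
    carries label 0.
    """
    config = config or truth.config
    if not truth.loci:
        raise ValueError("parent part of the truth table is empty")
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))
    truth.progeny_ids = [f"F{j + 1:03d}" for j in range(config.n_progeny)]
    n_loci = len(truth.loci)
    inheritance = np.zeros((config.n_progeny, n_loci, 2), dtype=np.int8)

    by_chrom: dict[int, tuple[list[int], np.ndarray]] = {}
    for i, loc in enumerate(truth.loci):
        if loc.chrom >= 0:
            by_chrom.setdefault(loc.chrom, ([], None))[0].append(i)
    by_chrom = {
        c: (idxs, np.array([truth.loci[i].pos_cM for i in idxs]))
        for c, (idxs, _) in by_chrom.items()
    }

    L = config.chrom_length_cM
    for j in range(config.n_progeny):
        for p in (0, 1):
            for c, (idxs, positions) in by_chrom.items():
                n_x = rng.poisson(L / 100.0)
                xs = np.sort(rng.uniform(0.0, L, size=n_x))
                start = int(rng.integers(0, 2))
                labels = (start + np.searchsorted(xs, positions, side="right")) % 2
                inheritance[j, idxs, p] = labels
    truth.inheritance = inheritance
    return truth


def simulate_family(config: SimConfig) -> TruthTable:
    """Parents plus progeny in one call."""
    return simulate_progeny(simulate_parents(config), config)


def emit_reads(truth: TruthTable, config: SimConfig | None = None) -> list[SeqRead]:
    """Emit error-perturbed single-end reads for every individual.

    Per locus and individual the read count is Poisson around the
    configured mean depth (parents vs progeny; multiplied by
    plastid_copy_factor for the plastid-like sequence). Each read is a
    read_length prefix of one of the individual's two locus haplotypes,
    with per-base substitution errors and constant high quality. Output
    is deterministic for a fixed config + seed.
    """
    config = config or truth.config
    if truth.inheritance is None:
        raise ValueError("progeny part of the truth table is missing; run simulate_progeny")
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 2)))
    R = config.read_length_bp
    qual = "I" * R
    tag_of = {ind: tag for tag, ind in truth.index_map.items()}
    reads: list[SeqRead] = []

    individuals = [(PARENT1, None), (PARENT2, None)] + [
        (pid, j) for j, pid in enumerate(truth.progeny_ids)
    ]
    for ind, j in individuals:
        is_parent = j is None
        base_depth = config.depth_parent if is_parent else config.depth_progeny
        tag = tag_of[ind]
        for i, loc in enumerate(truth.loci):
            depth = base_depth * (config.plastid_copy_factor if loc.copy_class == "plastid" else 1.0)
            n = int(rng.poisson(depth))
            if n == 0:
                continue
            if is_parent:
                pair = loc.haplotypes[0 if ind == PARENT1 else 1]
            else:
                pair = (
                    loc.haplotypes[0][truth.inheritance[j, i, 0]],
                    loc.haplotypes[1][truth.inheritance[j, i, 1]],
                )
            prefixes = (pair[0][:R], pair[1][:R])
            which = rng.integers(0, 2, size=n)
            n_err = rng.binomial(R, config.error_rate, size=n)
            for r_i in range(n):
                s = prefixes[which[r_i]]
                if n_err[r_i]:
                    b = bytearray(s, "ascii")
                    for pos0 in rng.choice(R, size=n_err[r_i], replace=False):
                        old = _BASES.index(chr(b[pos0]))
                        b[pos0] = ord(_BASES[(old + int(rng.integers(1, 4))) % 4])
                    s = b.decode()
                reads.append(
                    SeqRead(f"{ind}:{loc.locus_id}:{r_i:04d}", s, qual, ind, tag)
                )
    return reads


def markers_from_truth(truth: TruthTable) -> MarkerSet:
    """Error-free CP markers derived directly from the truth table
    (single-copy polymorphic loci only) — the read-free path for testing
    segregation, grouping and map-distance machinery."""
    if truth.inheritance is None:
        raise ValueError("progeny part of the truth table is missing")
    markers: list[CPMarker] = []
    for i in truth.single_copy_loci():
        loc = truth.loci[i]
        if loc.snp_position is None:
            continue
        p1 = truth.parent_genotype(i, 0)
        p2 = truth.parent_genotype(i, 1)
        seg = genotyping.classify_configuration(p1, p2)
        if seg == "non_informative":
            continue
        codes = [
            genotyping.encode_genotype(seg, p1, p2, truth.progeny_genotype(i, j))
            for j in range(len(truth.progeny_ids))
        ]
        markers.append(
            CPMarker(
                marker_id=loc.locus_id,
                seg_type=seg,
                codes=codes,
                source_allele=loc.locus_id,
                position=loc.snp_position,
            )
        )
    return MarkerSet(list(truth.progeny_ids), markers)


def write_truth_table(truth: TruthTable, path: str | Path) -> None:
    """Dump the per-locus truth as tab-separated text."""
    rows = []
    for loc in truth.loci:
        rows.append(
            {
                "locus_id": loc.locus_id,
                "chrom": loc.chrom,
                "pos_cM": loc.pos_cM,
                "copy_class": loc.copy_class,
                "snp_position": loc.snp_position if loc.snp_position is not None else "",
                "snp_alleles": "/".join(loc.snp_alleles) if loc.snp_alleles else "",
                "family_id": loc.family_id or "",
                "p1_hap_a": loc.haplotypes[0][0],
                "p1_hap_b": loc.haplotypes[0][1],
                "p2_hap_a": loc.haplotypes[1][0],
                "p2_hap_b": loc.haplotypes[1][1],
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
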