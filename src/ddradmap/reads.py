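"""FASTQ handling for ddRADseq lanes: demultiplexing by index tag,
per-individual bookkeeping, and seeded downsampling for sequencing-design
experiments.

Reads are single-end, restriction-site anchored forward reads. Lane files
carry each read's index tag in an Illumina-style header comment
(``@id 1:N:0:TAG``); demultiplexing assigns reads to individuals by exact
tag match and renames headers to carry the individual ID.
"""

from __future__ import annotations

import gzip
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "SeqRead",
    "DownsampleSpec",
    "read_fastq",
    "write_fastq",
    "read_index_map",
    "write_index_map",
    "demultiplex",
    "demultiplex_files",
    "downsample",
    "downsample_fastq",
    "exp_harness",
    "reads_by_individual",
    "PROGENY_FRACTION",
    "PARENT_FRACTION",
]

#: Downsampling fractions of the two sequencing-design experiments:
#: Exp1 models 96 progeny per lane instead of 50 (50/96 = 52% of the data
#: per progeny, parents untouched); Exp2 additionally squeezes both parent
#: libraries into shared lanes (32/50 = 64% of the data per parent).
PROGENY_FRACTION = 0.52
PARENT_FRACTION = 0.64

MIN_READ_LENGTH = 15


@dataclass(slots=True)
class SeqRead:
    """A single sequencing read.

    ``individual_id`` is set after demultiplexing; ``index_tag`` is the
    inline library index the read carried on the lane.
    """

    read_id: str
    bases: str
    qualities: str | None = None
    individual_id: str | None = None
    index_tag: str | None = None

    def __post_init__(self) -> None:
        if self.qualities is not None and len(self.qualities) != len(self.bases):
            raise ValueError(
                f"read {self.read_id}: qualities length {len(self.qualities)} "
                f"!= bases length {len(self.bases)}"
            )
        if len(self.bases) < MIN_READ_LENGTH:
            raise ValueError(
                f"read {self.read_id}: length {len(self.bases)} < {MIN_READ_LENGTH}"
            )


@dataclass(frozen=True)
class DownsampleSpec:
    """How to subsample a per-individual FASTQ.

    fraction: proportion of reads to retain, in (0, 1].
    seed: RNG seed; identical spec + seed gives identical output.
    scope: which cohort the fraction applies to when used on a whole
        dataset ("progeny-only" or "progeny-and-parents").
    """

    fraction: float
    seed: int = 0
    scope: str = "progeny-only"

    def __post_init__(self) -> None:
        if not (0.0 < self.fraction <= 1.0):
            raise ValueError(f"fraction must be in (0, 1], got {self.fraction}")
        if self.scope not in ("progeny-only", "progeny-and-parents"):
            raise ValueError(f"unknown scope {self.scope!r}")


# ---------------------------------------------------------------------------
# FASTQ I/O (gzip-transparent)
# ---------------------------------------------------------------------------


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _parse_title(title: str) -> tuple[str, str | None]:
    """Split a FASTQ title into read id and index tag.

    The tag is taken from the last colon-separated field of an
    Illumina-style comment (``id 1:N:0:TAG``); titles without a comment
    have no tag.
    """
    if " " in title:
        read_id, comment = title.split(None, 1)
        tag = comment.rsplit(":", 1)[-1] or None
        return read_id, tag
    return title, None


def read_fastq(path: str | Path, individual_id: str | None = None) -> Iterator[SeqRead]:
    """Stream a (possibly gzipped) FASTQ file as :class:`SeqRead` records.

    Raises ValueError naming the record number on a malformed record.
    """
    with _open_text(path) as fh:
        n = 0
        try:
            for title, seq, qual in FastqGeneralIterator(fh):
                n += 1
                read_id, tag = _parse_title(title)
                yield SeqRead(read_id, seq, qual, individual_id, tag)
        except ValueError as exc:
            raise ValueError(f"{path}: malformed FASTQ at record {n + 1}: {exc}") from exc


def write_fastq(reads: Iterable[SeqRead], path: str | Path, lane_style: bool = False) -> int:
    """Write reads as 4-line FASTQ records; returns the number written.

    With ``lane_style=True`` the index tag is carried in an Illumina-style
    header comment so the file can be demultiplexed again.
    """
    n = 0
    try:
        with _open_text(path, "wt") as fh:
            for r in reads:
                qual = r.qualities if r.qualities is not None else "I" * len(r.bases)
                title = r.read_id
                if lane_style and r.index_tag:
                    title = f"{r.read_id} 1:N:0:{r.index_tag}"
                fh.write(f"@{title}\n{r.bases}\n+\n{qual}\n")
                n += 1
    except OSError as exc:
        raise OSError(f"cannot write FASTQ to {path}: {exc}") from exc
    return n


def read_index_map(path: str | Path) -> dict[str, str]:
    """Read a 2-column TSV (index_tag, individual_id).

    Duplicate tags are a configuration error.
    """
    mapping: dict[str, str] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            tag, individual = parts
            if tag in mapping:
                raise ValueError(f"{path}:{lineno}: duplicate index tag {tag!r}")
            mapping[tag] = individual
    return mapping


def write_index_map(mapping: Mapping[str, str], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for tag in sorted(mapping):
            fh.write(f"{tag}\t{mapping[tag]}\n")


# ---------------------------------------------------------------------------
# Demultiplexing
# ---------------------------------------------------------------------------


@dataclass
class DemuxResult:
    """Per-individual reads plus the unmatched bin."""

    by_individual: dict[str, list[SeqRead]]
    unmatched: list[SeqRead] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        return {ind: len(rs) for ind, rs in self.by_individual.items()}

    @property
    def n_unmatched(self) -> int:
        return len(self.unmatched)

    @property
    def n_total(self) -> int:
        return sum(len(rs) for rs in self.by_individual.values()) + len(self.unmatched)


def _check_index_map(index_map: Mapping[str, str] | Sequence[tuple[str, str]]) -> dict[str, str]:
    if not isinstance(index_map, Mapping):
        mapping: dict[str, str] = {}
        for tag, ind in index_map:
            if tag in mapping:
                raise ValueError(f"duplicate index tag {tag!r} in index map")
            mapping[tag] = ind
        return mapping
    return dict(index_map)


def demultiplex(
    lane_reads: Iterable[SeqRead],
    index_map: Mapping[str, str] | Sequence[tuple[str, str]],
) -> DemuxResult:
    """Assign lane reads to individuals by exact index-tag match.

    Every read lands in exactly one individual bin or the unmatched bin;
    read ids are renamed to ``individual_id:read_id``. Every individual in
    the map gets a bin, even if empty.
    """
    mapping = _check_index_map(index_map)
    result = DemuxResult(by_individual={ind: [] for ind in mapping.values()})
    for r in lane_reads:
        ind = mapping.get(r.index_tag) if r.index_tag is not None else None
        if ind is None:
            result.unmatched.append(r)
        else:
            result.by_individual[ind].append(
                SeqRead(f"{ind}:{r.read_id}", r.bases, r.qualities, ind, r.index_tag)
            )
    return result


def demultiplex_files(
    lane_fastq: str | Path,
    index_map_path: str | Path,
    out_dir: str | Path,
) -> dict[str, int]:
    """File-level demultiplexing: lane FASTQ -> per-individual FASTQs.

    Returns per-individual read counts (plus ``"unmatched"``).
    """
    mapping = read_index_map(index_map_path)
    result = demultiplex(read_fastq(lane_fastq), mapping)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for ind, rs in result.by_individual.items():
        write_fastq(rs, out_dir / f"{ind}.fastq")
    write_fastq(result.unmatched, out_dir / "unmatched.fastq", lane_style=True)
    counts = result.counts
    counts["unmatched"] = result.n_unmatched
    return counts


# ---------------------------------------------------------------------------
# Downsampling
# ---------------------------------------------------------------------------


def retained_count(n_reads: int, fraction: float) -> int:
    """Number of reads kept when downsampling: round-half-up of f*n."""
    return int(math.floor(fraction * n_reads + 0.5))


def downsample(reads: Sequence[SeqRead], spec: DownsampleSpec) -> list[SeqRead]:
    """Keep exactly round(fraction * n) reads, uniformly without replacement.

    Input order is preserved among retained reads; identical spec + seed
    gives identical output. An empty input yields an empty output with a
    warning.
    """
    n = len(reads)
    if n == 0:
        warnings.warn("downsample: empty input file", stacklevel=2)
        return []
    k = retained_count(n, spec.fraction)
    rng = np.random.default_rng(spec.seed)
    idx = np.sort(rng.choice(n, size=k, replace=False))
    return [reads[i] for i in idx]


def downsample_fastq(in_path: str | Path, out_path: str | Path, spec: DownsampleSpec) -> int:
    """Downsample a per-individual FASTQ file; returns reads written."""
    reads = list(read_fastq(in_path))
    return write_fastq(downsample(reads, spec), out_path)


def reads_by_individual(reads: Iterable[SeqRead]) -> dict[str, list[SeqRead]]:
    """Group already-demultiplexed reads into per-individual lists."""
    out: dict[str, list[SeqRead]] = {}
    for r in reads:
        if r.individual_id is None:
            raise ValueError(f"read {r.read_id} has no individual_id; demultiplex first")
        out.setdefault(r.individual_id, []).append(r)
    return out


def exp_harness(
    dataset: Mapping[str, Sequence[SeqRead]],
    experiment: str,
    parents: Sequence[str] = ("P1", "P2"),
    seed: int = 0,
) -> dict[str, list[SeqRead]]:
    """Apply a sequencing-design downsampling experiment to a dataset.

    Exp1 keeps the parent data intact and downsamples every progeny file
    to 52% (models 96 instead of 50 progeny per lane). Exp2 downsamples
    progeny to 52% and both parents to 64% (models parents sharing lanes
    with progeny). Per-individual subsampling seeds are derived
    deterministically from ``seed``.
    """
    experiment = experiment.lower()
    if experiment not in ("exp1", "exp2"):
        raise ValueError(f"unknown experiment {experiment!r}; expected 'exp1' or 'exp2'")
    parent_set = set(parents)
    missing = parent_set - set(dataset)
    if missing:
        raise ValueError(f"dataset lacks parent files: {sorted(missing)}")
    out: dict[str, list[SeqRead]] = {}
    for i, ind in enumerate(sorted(dataset)):
        reads = list(dataset[ind])
        if ind in parent_set:
            fraction = PARENT_FRACTION if experiment == "exp2" else None
        else:
            fraction = PROGENY_FRACTION
        if fraction is None:
            out[ind] = reads
        else:
            sub_seed = int(np.random.SeedSequence((seed, i)).generate_state(1)[0] % (2**31))
            out[ind] = downsample(reads, DownsampleSpec(fraction, seed=sub_seed))
    return out
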