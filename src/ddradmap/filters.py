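"""Premapping filter cascade for CP markers.

Dense maps built from restriction-site-associated SNPs inflate badly when
markers violate the single-locus assumption or carry too much missing
data. The cascade screens markers in four stages before any mapping is
attempted, then tidies the cohort:

* F1 — drop every SNP whose reference sequence carries more than one
  called SNP (collapsed paralogs masquerading as single loci are the
  main driver of map inflation).
* F2 — drop SNPs in the first 9 bases of the marker sequence (positions
  <= 9 are artifact-prone).
* F3 (MD) — drop markers whose missing-data fraction reaches the chosen
  threshold (the final-map standard is < 5%).
* F4 — drop markers whose segregation deviates from Mendelian
  expectation, either by the value of the Pearson chi-square statistic
  (default: statistic < 20 survives) or by p-value (alpha 0.025).

After the cascade, individuals with > 90% missing data are excluded and
near-duplicate markers (genotype similarity >= 0.945) are reduced to one
representative per cluster. A stage-by-stage accounting report records
the surviving counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from scipy import stats

from .genotyping import MISSING, SEG_CODES, CPMarker, MarkerSet

__all__ = [
    "FilterParams",
    "CascadeReport",
    "Chi2Result",
    "f1_multi_snp",
    "f2_position",
    "f3_missing",
    "chi2_segregation",
    "f4_chi2_filter",
    "drop_individuals",
    "similarity",
    "similarity_dedup",
    "run_cascade",
    "SEG_RATIOS",
]

#: Mendelian expected ratios over the code classes of each segregation
#: type (class order as in SEG_CODES).
SEG_RATIOS: dict[str, tuple[int, ...]] = {
    "lmxll": (1, 1),
    "nnxnp": (1, 1),
    "hkxhk": (1, 2, 1),
    "efxeg": (1, 1, 1, 1),
    "abxcd": (1, 1, 1, 1),
}


@dataclass(frozen=True)
class FilterParams:
    """Thresholds of the cascade.

    chi2_mode selects which cutoff is read: "statistic" keeps markers
    with chi-square statistic < chi2_cutoff; "pvalue" keeps markers with
    p >= chi2_alpha (no multiple-testing correction — the alpha is
    applied per marker, genome-wide).
    """

    max_snps_per_sequence: int = 1
    min_position: int = 10
    missing_threshold: float = 0.05
    chi2_mode: str = "statistic"
    chi2_cutoff: float = 20.0
    chi2_alpha: float = 0.025
    similarity_threshold: float = 0.945
    individual_missing_threshold: float = 0.90

    def __post_init__(self) -> None:
        if self.chi2_mode not in ("statistic", "pvalue"):
            raise ValueError(f"chi2_mode must be 'statistic' or 'pvalue', got {self.chi2_mode!r}")
        if not (0.0 <= self.missing_threshold <= 1.0):
            raise ValueError(f"missing_threshold must be in [0, 1], got {self.missing_threshold}")
        if not (0.0 < self.similarity_threshold <= 1.0):
            raise ValueError(
                f"similarity_threshold must be in (0, 1], got {self.similarity_threshold}"
            )
        if not (0.0 <= self.individual_missing_threshold <= 1.0):
            raise ValueError(
                "individual_missing_threshold must be in [0, 1], "
                f"got {self.individual_missing_threshold}"
            )


@dataclass
class CascadeReport:
    """Marker counts surviving each named stage, in cascade order."""

    stages: list[tuple[str, int]] = field(default_factory=list)
    individuals_dropped: list[str] = field(default_factory=list)
    n_individuals_before: int = 0
    n_individuals_after: int = 0

    def add(self, name: str, count: int) -> None:
        if self.stages and count > self.stages[-1][1]:
            raise ValueError(
                f"cascade stage {name!r} increased the marker count "
                f"({self.stages[-1][1]} -> {count})"
            )
        self.stages.append((name, count))

    def count(self, name: str) -> int:
        for stage, n in self.stages:
            if stage == name:
                return n
        raise KeyError(name)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages, columns=["stage", "markers"])

    def __str__(self) -> str:
        lines = ["Sequential filtration", "---------------------"]
        for stage, n in self.stages:
            lines.append(f"{stage:<28s}{n:>8d}")
        lines.append(
            f"individuals: {self.n_individuals_before} -> {self.n_individuals_after}"
            + (f" (dropped: {', '.join(self.individuals_dropped)})" if self.individuals_dropped else "")
        )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# F1-F4
# ---------------------------------------------------------------------------


def f1_multi_snp(
    ms: MarkerSet,
    max_snps_per_sequence: int = 1,
    site_counts: dict[str, int] | None = None,
) -> MarkerSet:
    """Keep markers whose reference sequence carries exactly one called SNP.

    Several SNPs on one short sequence usually mean the sequence is a
    collapsed multi-copy locus, not a single Mendelian locus. The
    per-sequence SNP count is a property of the calling stage: pass
    ``site_counts`` when this filter runs on an already-subset marker
    table; by default counts come from the markers given.
    """
    if site_counts is None:
        site_counts = {}
        for m in ms.markers:
            site_counts[m.source_allele] = site_counts.get(m.source_allele, 0) + 1
    kept = [m for m in ms.markers if site_counts[m.source_allele] <= max_snps_per_sequence]
    return MarkerSet(ms.individuals, kept)


def f2_position(ms: MarkerSet, min_position: int = 10) -> MarkerSet:
    """Keep markers whose SNP sits at 1-based position >= min_position
    (default: drop the artifact-prone first 9 bases)."""
    return MarkerSet(ms.individuals, [m for m in ms.markers if m.position >= min_position])


def f3_missing(ms: MarkerSet, missing_threshold: float) -> MarkerSet:
    """Missing-data filter over the currently retained individuals.

    threshold > 0: survive iff missing_fraction < threshold;
    threshold == 0: survive iff no missing data at all.
    """
    if missing_threshold == 0:
        kept = [m for m in ms.markers if m.missing_fraction == 0.0]
    else:
        kept = [m for m in ms.markers if m.missing_fraction < missing_threshold]
    return MarkerSet(ms.individuals, kept)


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    df: int
    pvalue: float
    defined: bool = True


def chi2_segregation(marker: CPMarker) -> Chi2Result:
    """Pearson chi-square of the marker's non-missing code counts against
    its Mendelian expected ratio (1:1, 1:2:1 or 1:1:1:1 by type).

    A marker with zero non-missing individuals is flagged undefined.
    """
    classes = SEG_CODES[marker.seg_type]
    ratio = SEG_RATIOS[marker.seg_type]
    counts = [marker.codes.count(c) for c in classes]
    n = sum(counts)
    df = len(classes) - 1
    if n == 0:
        return Chi2Result(float("nan"), df, float("nan"), defined=False)
    expected = [n * r / sum(ratio) for r in ratio]
    stat, p = stats.chisquare(counts, f_exp=expected)
    return Chi2Result(float(stat), df, float(p))


def f4_chi2_filter(ms: MarkerSet, params: FilterParams = FilterParams()) -> MarkerSet:
    """Segregation-distortion screen.

    statistic mode: survive iff statistic < chi2_cutoff (strict);
    pvalue mode: survive iff p >= chi2_alpha. Markers with an undefined
    statistic are removed.
    """
    kept = []
    for m in ms.markers:
        res = chi2_segregation(m)
        if not res.defined:
            continue
        if params.chi2_mode == "statistic":
            if res.statistic < params.chi2_cutoff:
                kept.append(m)
        else:
            if res.pvalue >= params.chi2_alpha:
                kept.append(m)
    return MarkerSet(ms.individuals, kept)


# ---------------------------------------------------------------------------
# Cohort tidying
# ---------------------------------------------------------------------------


def drop_individuals(
    ms: MarkerSet, individual_missing_threshold: float = 0.90
) -> tuple[MarkerSet, list[str]]:
    """Remove individuals with missing fraction strictly above the
    threshold, computed over all current markers."""
    if not ms.markers:
        return ms, []
    frac = np.zeros(len(ms.individuals))
    for m in ms.markers:
        frac += np.array([c == MISSING for c in m.codes], dtype=float)
    frac /= len(ms.markers)
    dropped = [ind for ind, f in zip(ms.individuals, frac) if f > individual_missing_threshold]
    if not dropped:
        return ms, []
    keep = [ind for ind in ms.individuals if ind not in dropped]
    return ms.subset_individuals(keep), dropped


def similarity(marker_a: CPMarker, marker_b: CPMarker) -> float | None:
    """Fraction of individuals, among those non-missing in both markers,
    with identical codes; None when no individual is shared."""
    shared = eq = 0
    for a, b in zip(marker_a.codes, marker_b.codes):
        if a != MISSING and b != MISSING:
            shared += 1
            eq += a == b
    if shared == 0:
        return None
    return eq / shared


def _code_matrix(ms: MarkerSet) -> np.ndarray:
    all_codes = sorted({c for codes in SEG_CODES.values() for c in codes})
    lut = {c: i for i, c in enumerate(all_codes)}
    lut[MISSING] = -1
    mat = np.empty((len(ms.markers), len(ms.individuals)), dtype=np.int8)
    for i, m in enumerate(ms.markers):
        mat[i] = [lut[c] for c in m.codes]
    return mat


def similarity_dedup(ms: MarkerSet, similarity_threshold: float = 0.945) -> MarkerSet:
    """Collapse near-duplicate markers.

    Single-linkage clusters over pairs with similarity >= threshold; one
    representative is kept per cluster — the marker with the least
    missing data, ties broken by lexicographic marker_id. Pairs with no
    shared non-missing individual contribute no edge.
    """
    m = len(ms.markers)
    if m <= 1:
        return ms
    mat = _code_matrix(ms)
    present = mat >= 0
    parent = list(range(m))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    for i in range(m - 1):
        both = present[i] & present[i + 1 :]
        shared = both.sum(axis=1)
        eq = ((mat[i] == mat[i + 1 :]) & both).sum(axis=1)
        with np.errstate(invalid="ignore"):
            sim = np.where(shared > 0, eq / np.maximum(shared, 1), -1.0)
        for j in np.nonzero(sim >= similarity_threshold)[0]:
            union(i, i + 1 + int(j))

    clusters: dict[int, list[int]] = {}
    for i in range(m):
        clusters.setdefault(find(i), []).append(i)
    kept_idx = []
    for members in clusters.values():
        members.sort(
            key=lambda i: (ms.markers[i].missing_fraction, ms.markers[i].marker_id)
        )
        kept_idx.append(members[0])
    kept_idx.sort()
    return MarkerSet(ms.individuals, [ms.markers[i] for i in kept_idx])


# ---------------------------------------------------------------------------
# The full cascade
# ---------------------------------------------------------------------------


def run_cascade(
    ms: MarkerSet, params: FilterParams = FilterParams()
) -> tuple[MarkerSet, CascadeReport]:
    """F1 -> F2 -> MD -> chi-square, then individual exclusion and
    similarity deduplication, with stage-by-stage accounting.

    The missing-data denominator is the individual set current at each
    stage: the full cohort during MD, the reduced cohort after exclusion.
    """
    report = CascadeReport(n_individuals_before=len(ms.individuals))
    report.add("input", len(ms))
    ms = f1_multi_snp(ms, params.max_snps_per_sequence)
    report.add("F1 multi-SNP", len(ms))
    ms = f2_position(ms, params.min_position)
    report.add("F2 position", len(ms))
    ms = f3_missing(ms, params.missing_threshold)
    report.add(f"MD {params.missing_threshold:.0%}", len(ms))
    ms = f4_chi2_filter(ms, params)
    if params.chi2_mode == "statistic":
        report.add(f"chi2 < {params.chi2_cutoff:g}", len(ms))
    else:
        report.add(f"chi2 p >= {params.chi2_alpha:g}", len(ms))
    ms, dropped = drop_individuals(ms, params.individual_missing_threshold)
    report.individuals_dropped = dropped
    report.n_individuals_after = len(ms.individuals)
    ms = similarity_dedup(ms, params.similarity_threshold)
    report.add(f"similarity >= {params.similarity_threshold:g}", len(ms))
    return ms, report
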