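"""Linkage quality control and export.

Covers the steps around map ordering itself (which is delegated to
external mapping software and is out of scope here): writing CP-format
locus files and fixed-order framework files, grouping markers by an
independence LOD, two-point recombination fractions, Kosambi map
distances, map-inflation diagnostics (maximum-likelihood vs regression
length), framework-order concordance, and per-linkage-group summaries.

The independence LOD between two markers is a likelihood-ratio (G) test
of independence on the contingency table of their genotype classes over
shared scored individuals, expressed in LOD units: LOD = G / (2 ln 10).
Being a test of independence, it needs no knowledge of linkage phase.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genotyping import MISSING, SEG_CODES, CPMarker, MarkerSet

__all__ = [
    "GroupingParams",
    "MapOrder",
    "LinkageGroupSummary",
    "write_loc",
    "read_loc",
    "write_fixed_order",
    "read_fixed_order",
    "independence_lod",
    "group_markers",
    "two_point_rf",
    "kosambi_cM",
    "inverse_kosambi",
    "map_length",
    "inflation_ratio",
    "order_concordance",
    "summarize_map",
    "summary_totals",
    "write_map_tsv",
    "read_map_tsv",
]

LN10 = math.log(10.0)


@dataclass(frozen=True)
class GroupingParams:
    """Independence-LOD threshold for grouping (20 is a typical framework
    threshold, 30 the stricter final-map default)."""

    lod_threshold: float = 30.0

    def __post_init__(self) -> None:
        if self.lod_threshold <= 0:
            raise ValueError(f"lod_threshold must be > 0, got {self.lod_threshold}")


@dataclass
class MapOrder:
    """An ordered linkage group: (marker_id, position_cM) pairs with the
    label of the algorithm that produced it."""

    group_id: str
    entries: list[tuple[str, float]]
    algorithm_label: str = "external"

    def __post_init__(self) -> None:
        positions = [p for _, p in self.entries]
        if positions:
            if any(b < a for a, b in zip(positions, positions[1:])):
                raise ValueError(f"group {self.group_id}: positions must be non-decreasing")
            if positions[0] != 0:
                raise ValueError(f"group {self.group_id}: first position must be 0")

    @property
    def marker_ids(self) -> list[str]:
        return [m for m, _ in self.entries]

    @property
    def length_cM(self) -> float:
        if not self.entries:
            return 0.0
        return self.entries[-1][1] - self.entries[0][1]


# ---------------------------------------------------------------------------
# CP-format export
# ---------------------------------------------------------------------------


def write_loc(
    ms: MarkerSet,
    path: str | Path,
    name: str = "ddradmap",
    population_type: str = "CP",
) -> None:
    """Write a CP-population locus file: header (name, popt, nloc, nind),
    one record per marker with its segregation-type tag and per-individual
    codes, then the individual names. Byte-stable for fixed input."""
    for m in ms.markers:
        legal = set(SEG_CODES[m.seg_type]) | {MISSING}
        bad = set(m.codes) - legal
        if bad:
            raise ValueError(
                f"marker {m.marker_id}: codes {sorted(bad)} illegal for type {m.seg_type}"
            )
        if len(m.codes) != len(ms.individuals):
            raise ValueError(f"marker {m.marker_id}: wrong number of codes")
    with open(path, "w") as fh:
        fh.write(f"name = {name}\n")
        fh.write(f"popt = {population_type}\n")
        fh.write(f"nloc = {len(ms.markers)}\n")
        fh.write(f"nind = {len(ms.individuals)}\n\n")
        for m in ms.markers:
            fh.write(f"{m.marker_id} <{m.seg_type}>\n")
            for start in range(0, len(m.codes), 20):
                fh.write(" " + " ".join(m.codes[start : start + 20]) + "\n")
        fh.write("\nindividual names:\n")
        for ind in ms.individuals:
            fh.write(f"{ind}\n")


def read_loc(path: str | Path) -> MarkerSet:
    """Parse a CP-format locus file written by :func:`write_loc`."""
    header: dict[str, str] = {}
    records: list[tuple[str, str, list[str]]] = []
    individuals: list[str] = []
    mode = "header"
    current: tuple[str, str, list[str]] | None = None
    for line in open(path):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        if line.strip() == "individual names:":
            mode = "names"
            continue
        if mode == "names":
            individuals.append(line.strip())
            continue
        if "=" in line and mode == "header":
            key, value = (s.strip() for s in line.split("=", 1))
            header[key] = value
            continue
        if line.startswith(" ") and current is not None:
            current[2].extend(line.split())
            continue
        mode = "records"
        marker_id, tag = line.split()
        current = (marker_id, tag.strip("<>"), [])
        records.append(current)
    nind = int(header.get("nind", 0))
    markers = []
    for marker_id, seg_type, codes in records:
        if nind and len(codes) != nind:
            raise ValueError(f"{path}: marker {marker_id} has {len(codes)} codes, expected {nind}")
        markers.append(CPMarker(marker_id, seg_type, codes))
    if nind and individuals and len(individuals) != nind:
        raise ValueError(f"{path}: {len(individuals)} individual names, expected {nind}")
    return MarkerSet(individuals or [f"ind{i + 1}" for i in range(nind)], markers)


def write_fixed_order(order: Mapping[str, Sequence[str]], ms: MarkerSet | None, path: str | Path) -> None:
    """Write one fixed marker order per linkage group (order only — no
    distances). Markers absent from the table, or duplicated within a
    group, are an error."""
    known = {m.marker_id for m in ms.markers} if ms is not None else None
    with open(path, "w") as fh:
        for group_id in order:
            names = list(order[group_id])
            if len(set(names)) != len(names):
                dup = sorted({n for n in names if names.count(n) > 1})
                raise ValueError(f"group {group_id}: duplicate markers in fixed order: {dup}")
            if known is not None:
                missing = [n for n in names if n not in known]
                if missing:
                    raise ValueError(
                        f"group {group_id}: fixed-order markers absent from table: {missing}"
                    )
            fh.write(f"group {group_id}\n")
            for n in names:
                fh.write(f"{n}\n")


def read_fixed_order(path: str | Path) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    current: list[str] | None = None
    for line in open(path):
        line = line.strip()
        if not line:
            continue
        if line.startswith("group "):
            current = out.setdefault(line[6:].strip(), [])
        elif current is not None:
            current.append(line)
        else:
            raise ValueError(f"{path}: marker line before any group header")
    return out


# ---------------------------------------------------------------------------
# Grouping
# ---------------------------------------------------------------------------


def independence_lod(marker_a: CPMarker, marker_b: CPMarker) -> float:
    """G-test of independence on the joint genotype-class table of shared
    scored individuals, in LOD units (G / (2 ln 10)).

    Zero-count cells contribute nothing; a degenerate table (fewer than
    two distinct classes for either marker) has LOD 0.
    """
    classes_a = {c: i for i, c in enumerate(SEG_CODES[marker_a.seg_type])}
    classes_b = {c: i for i, c in enumerate(SEG_CODES[marker_b.seg_type])}
    table = np.zeros((len(classes_a), len(classes_b)))
    for a, b in zip(marker_a.codes, marker_b.codes):
        if a != MISSING and b != MISSING:
            table[classes_a[a], classes_b[b]] += 1
    n = table.sum()
    if n < 2:
        return 0.0
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    if np.count_nonzero(rows) < 2 or np.count_nonzero(cols) < 2:
        return 0.0
    expected = np.outer(rows, cols) / n
    mask = table > 0
    g = 2.0 * float((table[mask] * np.log(table[mask] / expected[mask])).sum())
    return g / (2.0 * LN10)


def group_markers(
    ms: MarkerSet, params: GroupingParams = GroupingParams()
) -> tuple[list[list[str]], list[str]]:
    """Partition markers into linkage groups by single-linkage transitive
    closure over pairs with independence LOD >= threshold.

    Returns (groups, singletons); groups are sorted by size then by first
    marker id, markers within a group by marker id, so the partition is
    invariant to input order.
    """
    m = len(ms.markers)
    parent = list(range(m))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(m):
        for j in range(i + 1, m):
            if find(i) == find(j):
                continue
            if independence_lod(ms.markers[i], ms.markers[j]) >= params.lod_threshold:
                ri, rj = find(i), find(j)
                parent[max(ri, rj)] = min(ri, rj)

    clusters: dict[int, list[str]] = {}
    for i in range(m):
        clusters.setdefault(find(i), []).append(ms.markers[i].marker_id)
    groups = [sorted(v) for v in clusters.values() if len(v) > 1]
    groups.sort(key=lambda g: (-len(g), g[0]))
    singletons = sorted(v[0] for v in clusters.values() if len(v) == 1)
    return groups, singletons


# ---------------------------------------------------------------------------
# Two-point distances
# ---------------------------------------------------------------------------

_SAME_PARENT_PAIRS = {("lmxll", "lmxll"), ("nnxnp", "nnxnp"), ("hkxhk", "hkxhk")}


def two_point_rf(marker_a: CPMarker, marker_b: CPMarker) -> tuple[float, float] | None:
    """Two-point recombination fraction and independence LOD.

    Only same-type pairs informative through a common parent are
    supported (lmxll x lmxll, nnxnp x nnxnp, hkxhk x hkxhk). Phase is
    unknown, so min(r, 1-r) is reported. For hkxhk pairs only the
    unambiguous genotype combinations (both individuals homozygous at
    both markers) are used. Returns None when no shared informative
    meioses exist.
    """
    pair = (marker_a.seg_type, marker_b.seg_type)
    if pair not in _SAME_PARENT_PAIRS:
        raise ValueError(f"two_point_rf: unsupported segregation-type pair {pair}")
    if marker_a.seg_type == "hkxhk":
        # Condition on individuals homozygous at the first marker: both of
        # their gametes are known there, so the second marker's genotype
        # counts recombinant gametes unambiguously (same homozygote: 0 of
        # 2, heterozygote: 1 of 2, opposite homozygote: 2 of 2).
        # Heterozygotes at the first marker are ambiguous and excluded.
        n = opp = 0
        for a, b in zip(marker_a.codes, marker_b.codes):
            if a in ("hh", "kk") and b != MISSING:
                n += 2
                if b == "hk":
                    opp += 1
                elif b != a:
                    opp += 2
    else:
        n = opp = 0
        for a, b in zip(marker_a.codes, marker_b.codes):
            if a != MISSING and b != MISSING:
                n += 1
                opp += a != b
    if n == 0:
        return None
    r = opp / n
    return min(r, 1.0 - r), independence_lod(marker_a, marker_b)


def kosambi_cM(r: float) -> float:
    """Kosambi map distance in cM: d = 25 ln((1 + 2r) / (1 - 2r)).

    Defined for 0 <= r < 0.5.
    """
    if not (0.0 <= r < 0.5):
        raise ValueError(f"recombination fraction must be in [0, 0.5), got {r}")
    return 25.0 * math.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))


def inverse_kosambi(d_cM: float) -> float:
    """Recombination fraction at a Kosambi distance: r = tanh(d/50) / 2."""
    if d_cM < 0:
        raise ValueError(f"distance must be >= 0, got {d_cM}")
    return 0.5 * math.tanh(d_cM / 50.0)


def map_length(order: MapOrder, ms: MarkerSet) -> float:
    """Length of a given order as the sum of adjacent-pair Kosambi
    distances; an undefined adjacent rf is an error naming the pair."""
    by_id = {m.marker_id: m for m in ms.markers}
    total = 0.0
    ids = order.marker_ids
    for a, b in zip(ids, ids[1:]):
        if a not in by_id or b not in by_id:
            missing = a if a not in by_id else b
            raise ValueError(f"map_length: marker {missing} absent from marker set")
        est = two_point_rf(by_id[a], by_id[b])
        if est is None:
            raise ValueError(f"map_length: recombination fraction undefined for pair ({a}, {b})")
        rf, _ = est
        if rf >= 0.5:
            raise ValueError(f"map_length: rf >= 0.5 for adjacent pair ({a}, {b})")
        total += kosambi_cM(rf)
    return total


def inflation_ratio(map_ml: MapOrder, map_reg: MapOrder) -> float:
    """Length ratio of the maximum-likelihood map to the regression map
    for one group: ~1 for a clean map, >> 1 under inflation."""
    reg_len = map_reg.length_cM
    if reg_len == 0:
        raise ValueError(f"group {map_reg.group_id}: regression map has zero length")
    return map_ml.length_cM / reg_len


def order_concordance(map_order: MapOrder, framework_order: Sequence[str]) -> float:
    """Preservation of the framework order within a map: 1 minus the
    fraction of framework pairs inverted relative to the fixed order.

    Markers interleaved between framework markers do not matter; fewer
    than two shared framework markers leaves the score undefined (None).
    """
    pos_in_map = {m: i for i, m in enumerate(map_order.marker_ids)}
    shared = [m for m in framework_order if m in pos_in_map]
    n = len(shared)
    if n < 2:
        return None  # type: ignore[return-value]
    ranks = [pos_in_map[m] for m in shared]
    inversions = sum(
        1 for i in range(n) for j in range(i + 1, n) if ranks[i] > ranks[j]
    )
    return 1.0 - inversions / (n * (n - 1) / 2)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


def _truncate2(x: float) -> float:
    """Two-decimal truncation (matches how published per-group marker
    densities are printed)."""
    return math.floor(x * 100 + 1e-9) / 100


@dataclass(frozen=True)
class LinkageGroupSummary:
    """Per-group bookkeeping: locus count, framework EST-SSR count, map
    length, and density as cM per marker (length / loci, 2 dp)."""

    group_id: str
    n_loci: int
    n_framework_est_ssr: int
    length_cM: float

    @property
    def spacing_cM_per_marker(self) -> float:
        return _truncate2(self.length_cM / self.n_loci)


def summarize_map(
    maps: Sequence[MapOrder],
    est_ssr_ids: Iterable[str] = (),
) -> list[LinkageGroupSummary]:
    """Per-group summaries from ordered maps; the EST-SSR count is taken
    from membership in ``est_ssr_ids``."""
    ssr = set(est_ssr_ids)
    out = []
    for mo in maps:
        ids = mo.marker_ids
        out.append(
            LinkageGroupSummary(
                group_id=mo.group_id,
                n_loci=len(ids),
                n_framework_est_ssr=sum(m in ssr for m in ids),
                length_cM=mo.length_cM,
            )
        )
    return out


def summary_totals(summaries: Sequence[LinkageGroupSummary]) -> dict[str, float]:
    """Column sums of a per-group summary table."""
    return {
        "n_loci": sum(s.n_loci for s in summaries),
        "n_framework_est_ssr": sum(s.n_framework_est_ssr for s in summaries),
        "length_cM": round(sum(s.length_cM for s in summaries), 1),
    }


def summaries_to_dataframe(summaries: Sequence[LinkageGroupSummary]) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "group": s.group_id,
                "n_loci": s.n_loci,
                "est_ssr": s.n_framework_est_ssr,
                "length_cM": s.length_cM,
                "cM_per_marker": s.spacing_cM_per_marker,
            }
            for s in summaries
        ]
    )
    totals = summary_totals(summaries)
    df.loc[len(df)] = ["Total", totals["n_loci"], totals["n_framework_est_ssr"], totals["length_cM"], np.nan]
    return df


def write_map_tsv(maps: Sequence[MapOrder], path: str | Path) -> None:
    rows = [
        {"group": mo.group_id, "marker": m, "cM": pos}
        for mo in maps
        for m, pos in mo.entries
    ]
    pd.DataFrame(rows, columns=["group", "marker", "cM"]).to_csv(path, sep="\t", index=False)


def read_map_tsv(path: str | Path, algorithm_label: str = "external") -> list[MapOrder]:
    df = pd.read_csv(path, sep="\t", dtype={"group": str, "marker": str, "cM": float})
    maps = []
    for group_id, sub in df.groupby("group", sort=True):
        entries = [(r.marker, float(r.cM)) for r in sub.itertuples()]
        maps.append(MapOrder(str(group_id), entries, algorithm_label))
    return maps
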