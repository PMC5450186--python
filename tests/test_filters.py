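"""Premapping filter cascade: per-stage rules, boundaries, printed-scale
accounting, and statistical behaviour of the segregation screen."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ddradmap.filters import (
    CascadeReport,
    FilterParams,
    chi2_segregation,
    drop_individuals,
    f1_multi_snp,
    f2_position,
    f3_missing,
    f4_chi2_filter,
    run_cascade,
    similarity,
    similarity_dedup,
)
from ddradmap.genotyping import MISSING, CPMarker, MarkerSet

_RNG = np.random.default_rng(2024)


def _marker(mid, codes, seg="lmxll", source=None, position=50):
    return CPMarker(mid, seg, list(codes), source or mid, position)


def _counts_marker(mid, counts, seg="lmxll", **kw):
    from ddradmap.genotyping import SEG_CODES

    codes = []
    for code, n in zip(SEG_CODES[seg], counts):
        codes += [code] * n
    return _marker(mid, codes, seg, **kw)


class TestF1:
    def test_multi_snp_sequence_removed(self):
        ms = MarkerSet(
            ["i1"],
            [
                _marker("s1:20", ["lm"], source="s1", position=20),
                _marker("s2:15", ["lm"], source="s2", position=15),
                _marker("s2:70", ["lm"], source="s2", position=70),
            ],
        )
        out = f1_multi_snp(ms)
        assert [m.marker_id for m in out.markers] == ["s1:20"]

    def test_printed_scale_accounting(self):
        # 78,725 informative SNPs of which 60,687 sit on 21,526 multi-SNP
        # sequences: the multi-SNP filter leaves 18,038.
        markers = []
        n_multi_seq, n_multi_sites, n_single = 21526, 60687, 18038
        per_seq = [2] * n_multi_seq
        for i in range(n_multi_sites - 2 * n_multi_seq):
            per_seq[i] += 1
        for s, k in enumerate(per_seq):
            for p in range(k):
                markers.append(_marker(f"m{s}:{p + 10}", ["lm"], source=f"seq{s}", position=p + 10))
        for s in range(n_single):
            markers.append(_marker(f"u{s}:50", ["lm"], source=f"useq{s}"))
        ms = MarkerSet(["i1"], markers)
        assert len(ms) == 78725
        out = f1_multi_snp(ms)
        assert len(out) == 18038

    def test_single_snp_sequences_never_removed(self):
        ms = MarkerSet(["i1"], [_marker(f"s{i}:50", ["lm"], source=f"s{i}") for i in range(20)])
        assert len(f1_multi_snp(ms)) == 20


class TestF2:
    @pytest.mark.parametrize("position, kept", [(9, False), (10, True), (1, False), (50, True)])
    def test_first_nine_bases_boundary(self, position, kept):
        ms = MarkerSet(["i1"], [_marker("m1", ["lm"], position=position)])
        assert (len(f2_position(ms)) == 1) == kept

    def test_printed_scale_accounting(self):
        # 18,038 single-SNP markers, 2,263 of them in the first 9 bases.
        markers = [_marker(f"a{i}", ["lm"], position=5) for i in range(2263)]
        markers += [_marker(f"b{i}", ["lm"], position=42) for i in range(15775)]
        out = f2_position(MarkerSet(["i1"], markers))
        assert len(out) == 15775


class TestF3:
    def test_five_percent_boundary_at_217_individuals(self):
        inds = [f"i{j}" for j in range(217)]
        removed = _marker("a", ["lm"] * 206 + [MISSING] * 11)  # 11/217 = 5.07%
        retained = _marker("b", ["lm"] * 207 + [MISSING] * 10)  # 10/217 = 4.61%
        out = f3_missing(MarkerSet(inds, [removed, retained]), 0.05)
        assert [m.marker_id for m in out.markers] == ["b"]

    def test_zero_threshold_forbids_any_missing(self):
        ms = MarkerSet(["i1", "i2"], [_marker("a", ["lm", MISSING]), _marker("b", ["lm", "ll"])])
        assert [m.marker_id for m in f3_missing(ms, 0.0).markers] == ["b"]

    def test_loose_threshold_keeps_complete_markers(self):
        ms = MarkerSet(["i1", "i2"], [_marker("a", ["lm", "ll"])])
        assert len(f3_missing(ms, 0.30)) == 1


class TestChi2:
    def test_perfect_segregation_is_zero(self):
        m = _counts_marker("m", (50, 100, 50), seg="hkxhk")
        res = chi2_segregation(m)
        assert res.statistic == pytest.approx(0.0)
        assert res.df == 2

    def test_direct_formula_values(self):
        # hkxhk (60,100,40) vs expected (50,100,50): 100/50 + 0 + 100/50 = 4
        res = chi2_segregation(_counts_marker("m", (60, 100, 40), seg="hkxhk"))
        assert res.statistic == pytest.approx(4.0)
        # lmxll (120,80) vs (100,100): 400/100 + 400/100 = 8
        res = chi2_segregation(_counts_marker("m", (120, 80)))
        assert res.statistic == pytest.approx(8.0)
        assert res.pvalue == pytest.approx(stats.chi2.sf(8.0, 1))

    def test_missing_codes_excluded(self):
        m = _marker("m", ["lm"] * 60 + ["ll"] * 40 + [MISSING] * 10)
        res = chi2_segregation(m)
        assert res.statistic == pytest.approx(4.0)

    def test_all_missing_flagged_undefined(self):
        res = chi2_segregation(_marker("m", [MISSING] * 5))
        assert not res.defined

    def test_boundary_strictly_below_cutoff(self):
        # statistic 20.0 removed, just below retained: lmxll needs
        # (a-b)^2/n >= 20; n=180, diff 60 -> 3600/180 = 20.0
        at_cutoff = _counts_marker("m1", (120, 60))
        below = _counts_marker("m2", (119, 61))
        assert chi2_segregation(at_cutoff).statistic == pytest.approx(20.0)
        out = f4_chi2_filter(MarkerSet(["x"], []), FilterParams())
        ms = MarkerSet([f"i{j}" for j in range(180)], [at_cutoff, below])
        out = f4_chi2_filter(ms, FilterParams(chi2_cutoff=20.0))
        assert [m.marker_id for m in out.markers] == ["m2"]

    def test_forced_distortion_removed(self):
        # 3:1 distortion of a 1:1 type at n=217 gives a statistic of ~54,
        # far beyond the cutoff of 20
        m = _counts_marker("m", (163, 54))
        res = chi2_segregation(m)
        assert res.statistic > 50
        assert len(f4_chi2_filter(MarkerSet([f"i{j}" for j in range(217)], [m]), FilterParams()).markers) == 0

    def test_type_one_error_rate_matches_alpha(self):
        # >= 2000 true-Mendelian markers at n=217, pvalue mode alpha 0.025:
        # rejection rate within 3 binomial SDs of alpha
        n_markers, n_ind, alpha = 2000, 217, 0.025
        markers = []
        for i in range(n_markers):
            if i % 2:
                counts = _RNG.multinomial(n_ind, [0.5, 0.5])
                markers.append(_counts_marker(f"m{i}", counts))
            else:
                counts = _RNG.multinomial(n_ind, [0.25, 0.5, 0.25])
                markers.append(_counts_marker(f"m{i}", counts, seg="hkxhk"))
        ms = MarkerSet([f"i{j}" for j in range(n_ind)], markers)
        out = f4_chi2_filter(ms, FilterParams(chi2_mode="pvalue", chi2_alpha=alpha))
        rate = 1 - len(out) / n_markers
        sd = math.sqrt(alpha * (1 - alpha) / n_markers)
        assert abs(rate - alpha) <= 3 * sd


class TestDropIndividuals:
    def test_strict_boundary_at_90_percent(self):
        n = 100
        inds = ["at90", "at91", "full"]
        markers = []
        for i in range(n):
            codes = [
                MISSING if i < 90 else "lm",
                MISSING if i < 91 else "lm",
                "lm" if i % 2 else "ll",
            ]
            markers.append(_marker(f"m{i}", codes))
        out, dropped = drop_individuals(MarkerSet(inds, markers), 0.90)
        assert dropped == ["at91"]
        assert out.individuals == ["at90", "full"]

    def test_complete_data_drops_none(self, clean_result):
        out, dropped = drop_individuals(clean_result.markers_raw, 0.90)
        assert dropped == []

    def test_masked_individuals_dropped_exactly(self, tiny_result):
        ms = tiny_result.markers_raw
        masked = ms.individuals[:3]
        rng = np.random.default_rng(5)
        markers = []
        for m in ms.markers:
            codes = list(m.codes)
            for j, ind in enumerate(ms.individuals):
                if ind in masked and rng.random() < 0.95:
                    codes[j] = MISSING
            markers.append(CPMarker(m.marker_id, m.seg_type, codes, m.source_allele, m.position))
        out, dropped = drop_individuals(MarkerSet(ms.individuals, markers), 0.90)
        assert sorted(dropped) == sorted(masked)


class TestSimilarity:
    def test_identical_vectors(self):
        a = _marker("a", ["lm", "ll"] * 50)
        b = _marker("b", ["lm", "ll"] * 50)
        assert similarity(a, b) == 1.0

    def test_ten_of_two_hundred_differ(self):
        codes_a = ["lm"] * 200
        codes_b = ["lm"] * 190 + ["ll"] * 10
        assert similarity(_marker("a", codes_a), _marker("b", codes_b)) == pytest.approx(0.95)

    def test_complementary_vectors(self):
        a = _marker("a", ["lm", "ll"] * 50)
        b = _marker("b", ["ll", "lm"] * 50)
        assert similarity(a, b) == 0.0

    def test_no_shared_individuals_undefined(self):
        a = _marker("a", ["lm", MISSING])
        b = _marker("b", [MISSING, "ll"])
        assert similarity(a, b) is None


class TestSimilarityDedup:
    def test_identical_markers_collapse(self):
        ms = MarkerSet(["i1", "i2"], [_marker("a", ["lm", "ll"]), _marker("b", ["lm", "ll"])])
        out = similarity_dedup(ms)
        assert [m.marker_id for m in out.markers] == ["a"]

    def test_three_way_cluster_keeps_one(self):
        codes = ["lm"] * 100 + ["ll"] * 100
        near = codes[:99] + ["ll"] + codes[100:]
        ms = MarkerSet(
            [f"i{j}" for j in range(200)],
            [_marker("a", codes), _marker("b", codes), _marker("c", near)],
        )
        out = similarity_dedup(ms, 0.945)
        assert len(out.markers) == 1

    def test_representative_has_least_missing(self):
        full = _marker("zz", ["lm", "ll", "lm"])
        holey = _marker("aa", ["lm", "ll", MISSING])
        out = similarity_dedup(MarkerSet(["i1", "i2", "i3"], [holey, full]), 0.9)
        assert [m.marker_id for m in out.markers] == ["zz"]

    def test_independent_markers_all_kept(self):
        n_ind = 60
        markers = []
        for i in range(40):
            codes = ["lm" if x else "ll" for x in _RNG.integers(0, 2, size=n_ind)]
            markers.append(_marker(f"m{i:02d}", codes))
        out = similarity_dedup(MarkerSet([f"i{j}" for j in range(n_ind)], markers))
        assert len(out.markers) == 40


class TestCascade:
    def test_empty_input_all_zero(self):
        ms, report = run_cascade(MarkerSet(["i1"], []))
        assert len(ms) == 0
        assert all(n == 0 for _, n in report.stages)

    def test_counts_non_increasing(self, tiny_result):
        counts = [n for _, n in tiny_result.cascade.stages]
        assert counts == sorted(counts, reverse=True)

    def test_report_rejects_increasing_counts(self):
        report = CascadeReport()
        report.add("input", 5)
        with pytest.raises(ValueError, match="increased"):
            report.add("oops", 6)

    @settings(deadline=None, max_examples=20)
    @given(seed=st.integers(0, 10_000))
    def test_f1_f2_commute(self, seed):
        rng = np.random.default_rng(seed)
        markers = []
        for i in range(30):
            src = f"seq{rng.integers(0, 15)}"
            pos = int(rng.integers(1, 102))
            markers.append(_marker(f"m{i:02d}", ["lm", "ll"], source=src, position=pos))
        ms = MarkerSet(["i1", "i2"], markers)
        counts: dict[str, int] = {}
        for m in ms.markers:
            counts[m.source_allele] = counts.get(m.source_allele, 0) + 1
        ab = f2_position(f1_multi_snp(ms, site_counts=counts))
        ba = f1_multi_snp(f2_position(ms), site_counts=counts)
        # both are per-site predicates over the fixed called-site groups,
        # so the retained set is order-independent
        assert [m.marker_id for m in ab.markers] == [m.marker_id for m in ba.markers]
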