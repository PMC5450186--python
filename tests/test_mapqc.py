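"""Linkage QC: CP-format export, independence-LOD grouping, two-point
distances with the Kosambi function, inflation and order diagnostics,
and per-group summaries."""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy.stats import chi2_contingency

from ddradmap.genotyping import MISSING, CPMarker, MarkerSet
from ddradmap.mapqc import (
    GroupingParams,
    LinkageGroupSummary,
    MapOrder,
    group_markers,
    independence_lod,
    inflation_ratio,
    inverse_kosambi,
    kosambi_cM,
    map_length,
    order_concordance,
    read_fixed_order,
    read_loc,
    read_map_tsv,
    summaries_to_dataframe,
    summarize_map,
    summary_totals,
    two_point_rf,
    write_fixed_order,
    write_loc,
    write_map_tsv,
)
from ddradmap.simulate import SimConfig, markers_from_truth, simulate_family


def _marker(mid, codes, seg="lmxll"):
    return CPMarker(mid, seg, list(codes))


def _linked_markers(n_ind, r_adj, n_markers, seed=0, seg="lmxll"):
    """Markers in coupling phase along one chromosome; adjacent pairs
    recombine with probability r_adj."""
    rng = np.random.default_rng(seed)
    het, hom = ("lm", "ll") if seg == "lmxll" else ("np", "nn")
    state = rng.integers(0, 2, size=n_ind)
    out = []
    for i in range(n_markers):
        if i:
            flip = rng.random(n_ind) < r_adj
            state = np.where(flip, 1 - state, state)
        out.append(_marker(f"m{i:02d}", [het if s else hom for s in state], seg))
    return out


class TestLocFile:
    def test_header_counts(self, tmp_path):
        ms = MarkerSet(["i1", "i2"], [_marker("m1", ["lm", "ll"])])
        path = tmp_path / "x.loc"
        write_loc(ms, path, name="fam")
        text = path.read_text()
        assert "nloc = 1" in text and "nind = 2" in text and "popt = CP" in text
        assert "<lmxll>" in text

    def test_round_trip(self, tmp_path, tiny_result):
        ms = tiny_result.markers
        path = tmp_path / "x.loc"
        write_loc(ms, path)
        back = read_loc(path)
        assert back.individuals == ms.individuals
        assert [(m.marker_id, m.seg_type, m.codes) for m in back.markers] == [
            (m.marker_id, m.seg_type, m.codes) for m in ms.markers
        ]

    def test_byte_stable(self, tmp_path, tiny_result):
        p1, p2 = tmp_path / "a.loc", tmp_path / "b.loc"
        write_loc(tiny_result.markers, p1)
        write_loc(tiny_result.markers, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_illegal_code_refused_with_marker_name(self, tmp_path):
        m = _marker("badmark", ["lm", "ll"])
        m.codes[0] = "hh"  # corrupt after validation
        with pytest.raises(ValueError, match="badmark"):
            write_loc(MarkerSet(["i1", "i2"], [m]), tmp_path / "x.loc")


class TestFixedOrder:
    def test_round_trip_preserves_order(self, tmp_path):
        order = {"1": ["b", "a", "c"], "2": ["z", "y"]}
        ms = MarkerSet(["i1"], [_marker(n, ["lm"]) for n in "abcyz"])
        path = tmp_path / "x.order"
        write_fixed_order(order, ms, path)
        assert read_fixed_order(path) == order

    def test_duplicate_marker_rejected(self, tmp_path):
        ms = MarkerSet(["i1"], [_marker("a", ["lm"])])
        with pytest.raises(ValueError, match="duplicate"):
            write_fixed_order({"1": ["a", "a"]}, ms, tmp_path / "x.order")

    def test_marker_absent_from_table_rejected(self, tmp_path):
        ms = MarkerSet(["i1"], [_marker("a", ["lm"])])
        with pytest.raises(ValueError, match="absent"):
            write_fixed_order({"1": ["a", "ghost"]}, ms, tmp_path / "x.order")


class TestIndependenceLOD:
    def test_identical_markers_closed_form(self):
        # two lmxll markers, identical 100/100 codes:
        # G = 2 * 200 * ln 2, LOD = G / (2 ln 10) ~ 60.2
        codes = ["lm"] * 100 + ["ll"] * 100
        lod = independence_lod(_marker("a", codes), _marker("b", codes))
        assert lod == pytest.approx(400 * math.log(2) / (2 * math.log(10)), abs=1e-9)
        assert lod == pytest.approx(60.2, abs=0.01)

    def test_self_lod_is_maximal_for_table(self):
        codes = ["lm"] * 60 + ["ll"] * 40
        m = _marker("a", codes)
        self_lod = independence_lod(m, m)
        other = _marker("b", codes[10:] + codes[:10])
        assert self_lod >= independence_lod(m, other)

    def test_independent_markers_near_zero(self):
        rng = np.random.default_rng(77)
        lods = []
        for _ in range(30):
            a = _marker("a", ["lm" if x else "ll" for x in rng.integers(0, 2, 100)])
            b = _marker("b", ["lm" if x else "ll" for x in rng.integers(0, 2, 100)])
            lods.append(independence_lod(a, b))
        assert max(lods) < 3.0

    def test_degenerate_table_is_zero(self):
        a = _marker("a", ["lm"] * 50)  # single class
        b = _marker("b", ["lm"] * 25 + ["ll"] * 25)
        assert independence_lod(a, b) == 0.0

    def test_matches_scipy_g_test(self):
        codes_a = ["lm"] * 55 + ["ll"] * 45
        codes_b = ["np"] * 30 + ["nn"] * 40 + ["np"] * 10 + ["nn"] * 20
        a = _marker("a", codes_a)
        b = _marker("b", codes_b, seg="nnxnp")
        table = np.zeros((2, 2))
        for x, y in zip(codes_a, codes_b):
            table[int(x == "ll"), int(y == "nn")] += 1
        g, _, _, _ = chi2_contingency(table, correction=False, lambda_="log-likelihood")
        assert independence_lod(a, b) == pytest.approx(g / (2 * math.log(10)))


class TestGrouping:
    def test_recovers_three_chromosomes_from_truth(self):
        cfg = SimConfig(
            n_loci=90, n_chromosomes=3, n_progeny=200, het_rate=0.6,
            repeat_families=(), plastid_copy_factor=0.0, seed=31,
        )
        truth = simulate_family(cfg)
        ms = markers_from_truth(truth)
        groups, singletons = group_markers(ms, GroupingParams(lod_threshold=10.0))
        assert singletons == []
        assert len(groups) == 3
        chrom_of = {loc.locus_id: loc.chrom for loc in truth.loci}
        for g in groups:
            assert len({chrom_of[m] for m in g}) == 1

    def test_threshold_above_all_pairs_gives_singletons(self):
        markers = _linked_markers(50, 0.05, 5, seed=1)
        groups, singletons = group_markers(MarkerSet([f"i{j}" for j in range(50)], markers), GroupingParams(1e6))
        assert groups == [] and len(singletons) == 5

    def test_partition_invariant_to_input_order(self):
        markers = _linked_markers(80, 0.1, 6, seed=2) + _linked_markers(80, 0.1, 6, seed=3, seg="nnxnp")
        inds = [f"i{j}" for j in range(80)]
        p1 = group_markers(MarkerSet(inds, markers), GroupingParams(3.0))
        p2 = group_markers(MarkerSet(inds, markers[::-1]), GroupingParams(3.0))
        assert p1 == p2

    def test_monotone_in_threshold(self):
        markers = _linked_markers(80, 0.2, 8, seed=4)
        inds = [f"i{j}" for j in range(80)]
        lo, _ = group_markers(MarkerSet(inds, markers), GroupingParams(2.0))
        hi, hi_single = group_markers(MarkerSet(inds, markers), GroupingParams(8.0))
        # every group at the stricter threshold is inside one loose group
        lo_of = {m: i for i, g in enumerate(lo) for m in g}
        for g in hi:
            assert len({lo_of[m] for m in g}) == 1


class TestTwoPointRF:
    def test_identical_vectors_zero(self):
        codes = ["lm"] * 50 + ["ll"] * 50
        rf, lod = two_point_rf(_marker("a", codes), _marker("b", codes))
        assert rf == 0.0 and lod > 3

    def test_independent_markers_near_half(self):
        rng = np.random.default_rng(8)
        a = _marker("a", ["lm" if x else "ll" for x in rng.integers(0, 2, 2000)])
        b = _marker("b", ["lm" if x else "ll" for x in rng.integers(0, 2, 2000)])
        rf, _ = two_point_rf(a, b)
        assert abs(rf - 0.5) <= 3 * math.sqrt(0.25 / 2000)

    def test_ten_cM_pair_matches_inverse_kosambi(self):
        # truth-backed pair: codes derived from parent-1 gamete labels of
        # two loci 10 cM apart, coupling phase
        cfg = replace(
            SimConfig(), n_loci=2, n_chromosomes=1, n_progeny=2000, het_rate=1.0,
            repeat_families=(), plastid_copy_factor=0.0, seed=41,
        )
        from ddradmap.simulate import simulate_parents, simulate_progeny

        truth = simulate_parents(cfg)
        truth.loci[0].pos_cM = 0.0
        truth.loci[1].pos_cM = 10.0
        simulate_progeny(truth, cfg)
        a = _marker("a", ["lm" if h else "ll" for h in truth.inheritance[:, 0, 0]])
        b = _marker("b", ["lm" if h else "ll" for h in truth.inheritance[:, 1, 0]])
        rf, _ = two_point_rf(a, b)
        r = inverse_kosambi(10.0)
        assert abs(rf - r) <= 3 * math.sqrt(r * (1 - r) / cfg.n_progeny)

    def test_hkxhk_counting_is_unbiased(self):
        # simulate both-parent meioses directly at r = 0.2
        rng = np.random.default_rng(9)
        r, n = 0.2, 4000
        g1 = rng.integers(0, 2, size=(n, 2))  # gametes at marker A (h=1)
        flip = rng.random((n, 2)) < r
        g2 = np.where(flip, 1 - g1, g1)

        def codes(g):
            return ["hk" if x.sum() == 1 else ("hh" if x.sum() == 2 else "kk") for x in g]

        rf, _ = two_point_rf(_marker("a", codes(g1), "hkxhk"), _marker("b", codes(g2), "hkxhk"))
        assert abs(rf - r) <= 3 * math.sqrt(r * (1 - r) / n)

    def test_mixed_types_rejected(self):
        with pytest.raises(ValueError, match="unsupported"):
            two_point_rf(_marker("a", ["lm"]), _marker("b", ["np"], seg="nnxnp"))

    def test_no_shared_meioses_undefined(self):
        a = _marker("a", ["lm", MISSING])
        b = _marker("b", [MISSING, "ll"])
        assert two_point_rf(a, b) is None


class TestKosambi:
    @pytest.mark.parametrize("r, expected", [(0.0, 0.0), (0.25, 27.465), (0.1, 10.137)])
    def test_closed_form_values(self, r, expected):
        assert kosambi_cM(r) == pytest.approx(expected, abs=5e-4)

    def test_matches_independent_formula_everywhere(self):
        for r in np.linspace(0.0, 0.49, 200):
            d = 0.25 * math.log1p(4 * r / (1 - 2 * r)) * 100  # Morgans -> cM
            assert kosambi_cM(float(r)) == pytest.approx(d, abs=1e-9)

    def test_strictly_increasing_and_small_r_limit(self):
        rs = np.linspace(0.0, 0.49, 100)
        ds = [kosambi_cM(float(r)) for r in rs]
        assert all(b > a for a, b in zip(ds, ds[1:]))
        assert kosambi_cM(1e-6) / 100 == pytest.approx(1e-6, rel=1e-3)

    def test_inverse_round_trip(self):
        for d in (0.5, 5.0, 30.0, 80.0):
            assert kosambi_cM(inverse_kosambi(d)) == pytest.approx(d, rel=1e-9)

    def test_rejects_r_at_half(self):
        with pytest.raises(ValueError):
            kosambi_cM(0.5)


class TestMapLength:
    def test_single_marker_is_zero(self):
        ms = MarkerSet(["i1"], [_marker("a", ["lm"])])
        assert map_length(MapOrder("1", [("a", 0.0)]), ms) == 0.0

    def test_two_adjacent_tenths(self):
        # adjacent rf 0.1 twice -> 2 x kosambi(0.1) = 20.273
        codes_a = ["lm"] * 50 + ["ll"] * 50
        codes_b = ["lm"] * 45 + ["ll"] * 5 + ["lm"] * 5 + ["ll"] * 45
        codes_c = ["lm"] * 40 + ["ll"] * 10 + ["lm"] * 10 + ["ll"] * 40
        ms = MarkerSet(
            [f"i{j}" for j in range(100)],
            [_marker("a", codes_a), _marker("b", codes_b), _marker("c", codes_c)],
        )
        order = MapOrder("1", [("a", 0.0), ("b", 10.0), ("c", 20.0)])
        assert map_length(order, ms) == pytest.approx(2 * kosambi_cM(0.1), abs=1e-9)
        assert map_length(order, ms) == pytest.approx(20.273, abs=5e-4)

    def test_undefined_adjacent_rf_names_pair(self):
        a = _marker("a", ["lm", MISSING])
        b = _marker("b", [MISSING, "ll"])
        ms = MarkerSet(["i1", "i2"], [a, b])
        with pytest.raises(ValueError, match=r"pair \(a, b\)"):
            map_length(MapOrder("1", [("a", 0.0), ("b", 5.0)]), ms)

    def test_genotype_errors_lengthen_the_map(self):
        rng = np.random.default_rng(55)
        markers = _linked_markers(200, 0.05, 12, seed=6)
        inds = [f"i{j}" for j in range(200)]
        order = MapOrder("1", [(m.marker_id, float(i)) for i, m in enumerate(markers)])
        clean_len = map_length(order, MarkerSet(inds, markers))
        noisy = []
        for m in markers:
            codes = ["lm" if (c == "ll") else "ll" if rng.random() < 0.05 else c for c in m.codes]
            codes = [c if rng.random() > 0.05 else ("lm" if c == "ll" else "ll") for c in m.codes]
            noisy.append(CPMarker(m.marker_id, m.seg_type, codes))
        noisy_len = map_length(order, MarkerSet(inds, noisy))
        assert noisy_len > clean_len


class TestInflation:
    def test_identical_maps_ratio_one(self):
        mo = MapOrder("3", [("a", 0.0), ("b", 50.0)], "regression")
        assert inflation_ratio(mo, mo) == 1.0

    def test_tenfold_inflation(self):
        reg = MapOrder("3", [("a", 0.0), ("b", 100.0)], "regression")
        ml = MapOrder("3", [("a", 0.0), ("b", 1000.0)], "maximum_likelihood")
        assert inflation_ratio(ml, reg) == 10.0

    def test_zero_length_regression_rejected(self):
        reg = MapOrder("3", [("a", 0.0)], "regression")
        ml = MapOrder("3", [("a", 0.0), ("b", 10.0)], "maximum_likelihood")
        with pytest.raises(ValueError, match="zero length"):
            inflation_ratio(ml, reg)


class TestOrderConcordance:
    def test_identical_order(self):
        mo = MapOrder("1", [(m, float(i)) for i, m in enumerate("abcde")])
        assert order_concordance(mo, list("abcde")) == 1.0

    def test_reversed_order(self):
        mo = MapOrder("1", [(m, float(i)) for i, m in enumerate("edcba")])
        assert order_concordance(mo, list("abcde")) == 0.0

    def test_one_adjacent_swap_of_five(self):
        mo = MapOrder("1", [(m, float(i)) for i, m in enumerate("abdce")])
        assert order_concordance(mo, list("abcde")) == pytest.approx(0.9)

    def test_interleaved_snps_do_not_matter(self):
        mo = MapOrder("1", [(m, float(i)) for i, m in enumerate(["a", "s1", "b", "s2", "s3", "c"])])
        assert order_concordance(mo, ["a", "b", "c"]) == 1.0

    def test_fewer_than_two_shared_undefined(self):
        mo = MapOrder("1", [("a", 0.0)])
        assert order_concordance(mo, ["a", "zz"]) is None


class TestSummaries:
    @pytest.mark.parametrize(
        "n_loci, length, expected",
        [(122, 105.4, 0.86), (94, 72.5, 0.77), (51, 79.9, 1.56), (71, 84.4, 1.18)],
    )
    def test_density_is_truncated_cM_per_marker(self, n_loci, length, expected):
        s = LinkageGroupSummary("LG", n_loci, 0, length)
        assert s.spacing_cM_per_marker == expected

    def test_summarize_map_counts_est_ssrs(self):
        mo = MapOrder("2", [("REO_1", 0.0), ("snp1", 3.0), ("FIR_8", 10.0)])
        (s,) = summarize_map([mo], est_ssr_ids={"REO_1", "FIR_8"})
        assert s.n_loci == 3 and s.n_framework_est_ssr == 2 and s.length_cM == 10.0

    def test_totals_are_column_sums(self):
        summaries = [
            LinkageGroupSummary("1", 10, 2, 50.0),
            LinkageGroupSummary("2", 20, 3, 70.5),
        ]
        totals = summary_totals(summaries)
        assert totals == {"n_loci": 30, "n_framework_est_ssr": 5, "length_cM": 120.5}
        df = summaries_to_dataframe(summaries)
        assert df.iloc[-1]["n_loci"] == 30

    def test_map_tsv_round_trip(self, tmp_path):
        maps = [MapOrder("1", [("a", 0.0), ("b", 4.5)]), MapOrder("2", [("c", 0.0)])]
        path = tmp_path / "map.tsv"
        write_map_tsv(maps, path)
        back = read_map_tsv(path)
        assert [(m.group_id, m.entries) for m in back] == [(m.group_id, m.entries) for m in maps]
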