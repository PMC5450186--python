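"""Linkage quality control: independence-LOD grouping, two-point
distances with the Kosambi function, map-inflation and order diagnostics.
"""

from ddradmap import (
    GroupingParams,
    MapOrder,
    SimConfig,
    emit_reads,
    group_markers,
    inflation_ratio,
    kosambi_cM,
    markers_from_truth,
    order_concordance,
    run_pipeline,
    simulate_family,
    two_point_rf,
)

# group pipeline markers from a 3-chromosome family
truth = simulate_family(
    SimConfig(n_loci=90, n_chromosomes=3, n_progeny=150, het_rate=0.5, seed=11)
)
result = run_pipeline(emit_reads(truth))
groups, singletons = group_markers(result.markers, GroupingParams(lod_threshold=8.0))
print(f"{len(result.markers)} markers -> {len(groups)} linkage groups, "
      f"{len(singletons)} singletons (true chromosomes: 3)")

# two-point distance between truth-derived markers of one chromosome
ms = markers_from_truth(truth)
same_type = [m for m in ms.markers if m.seg_type == "lmxll"]
a, b = same_type[0], same_type[1]
est = two_point_rf(a, b)
if est:
    rf, lod = est
    print(f"pair ({a.marker_id}, {b.marker_id}): rf = {rf:.3f}, LOD = {lod:.1f}")
    if rf < 0.5:
        print(f"  Kosambi distance: {kosambi_cM(rf):.2f} cM")

# inflation: a maximum-likelihood map much longer than the regression map
# for the same group signals genotyping problems
reg = MapOrder("LG3", [("a", 0.0), ("b", 55.0), ("c", 103.0)], "regression")
ml = MapOrder("LG3", [("a", 0.0), ("b", 540.0), ("c", 1010.0)], "maximum_likelihood")
print(f"inflation ratio (ML / regression length): {inflation_ratio(ml, reg):.1f}")

# framework-order concordance: 1.0 means the fixed order is respected
mapped = MapOrder("LG1", [("ssr1", 0.0), ("snp9", 2.0), ("ssr2", 8.0), ("ssr3", 30.0)])
score = order_concordance(mapped, ["ssr1", "ssr2", "ssr3"])
print(f"framework-order concordance: {score:.2f}")
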