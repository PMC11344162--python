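"""Boundary classification and the four +/-50 kb boundary metrics.

Extracts deduplicated TAD boundaries, labels those with a developmental
gene in the adjacent decile, samples matched random positions, fills CTCF
count/signal and insulation/strength metrics in the 100 kb windows, and
compares the three classes with rank-sum tests, FDR correction and
Cliff's delta.
"""

from tadbound import (
    SyntheticConfig,
    boundary_comparisons,
    boundary_metrics,
    extract_boundaries,
    random_boundaries,
    simulate_genome,
)

bundle = simulate_genome(SyntheticConfig(seed=7))

boundaries = extract_boundaries(
    bundle.tad_map, bundle.transcripts, bundle.categories.developmental
)
boundaries += random_boundaries(bundle.tad_map.genome, n=500, seed=7)

ctcf = [p for p in bundle.ctcf_peaks if p.fold_enrichment > 4 and p.q_value < 0.01]
boundary_metrics(boundaries, ctcf, bundle.insulation_track, bundle.strength_track)

n = {c: sum(r.class_label == c for r in boundaries) for c in ("developmental", "other", "random")}
print(f"boundaries: {n}")

print(f"\n{'metric':<24}{'pair':<28}{'q':>10}{'Cliff d':>9}  effect")
for c in boundary_comparisons(boundaries):
    pair = f"{c.group_a} vs {c.group_b}"
    print(f"{c.metric:<24}{pair:<28}{c.q_value:>10.2e}{c.cliffs_delta:>9.2f}  {c.effect_label}")
print("\nReal boundaries of either class separate sharply from random "
      "positions on every metric, while developmental and other boundaries "
      "show comparable physical insulation (negligible effect sizes for the "
      "insulation minimum and strength maximum).")
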