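"""Gene-density tertiles and intra-TAD gene positions on a synthetic genome.

Simulates a genome in which developmental genes are placed with 2:1 odds
into gene-sparse TADs and with 60% probability into the boundary-proximal
decile (bin 1), then recovers both designs: the Fisher odds ratio of
developmental genes in low-density (LD) TADs, and the per-category
distribution of TSSs over bins 0 (inter-TAD) to 5 (TAD center).
"""

from tadbound import (
    SyntheticConfig,
    assign_bins,
    bin_distribution,
    density_tertiles,
    ld_enrichment,
    simulate_genome,
    tad_density,
)

# the density analysis wants many genes per TAD so the density-rank
# tertiles are well resolved; bin-1 placement is kept low here
dense_cfg = SyntheticConfig(
    seed=7,
    n_chromosomes=5,
    chrom_length=60_000_000,
    n_genes={"developmental": 500, "housekeeping": 400, "other": 1100},
    bin1_bias={"developmental": 0.05, "housekeeping": 0.05, "other": 0.05},
)
dense = simulate_genome(dense_cfg)
records = density_tertiles(tad_density(dense.tad_map, dense.transcripts))
enrichment = ld_enrichment(
    dense.categories.developmental, records, dense.transcripts, dense.tad_map
)
print("LD enrichment of developmental genes")
print(f"  odds ratio {enrichment.odds_ratio:.2f} "
      f"(95% CI {enrichment.ci_low:.2f}-{enrichment.ci_high:.2f}), "
      f"one-sided Fisher p = {enrichment.p_value:.2e}")

# the positional analysis uses the default conditions (60% bin-1 bias
# for developmental genes)
bundle = simulate_genome(SyntheticConfig(seed=7))
assignments = assign_bins(bundle.tad_map, bundle.transcripts)
dist = bin_distribution(assignments, bundle.categories)
print("\nPercent of genes per bin (0 = inter-TAD, 1 = boundary, 5 = center):")
print(dist.round(1).to_string())
print("\nA bin-1 excess for developmental genes reflects their designed "
      "placement next to TAD boundaries.")
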