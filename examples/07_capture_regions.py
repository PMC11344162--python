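"""Viewpoint interaction profiles and cross-boundary region quantification.

Simulates Capture-C style per-fragment pileups from an enhancer viewpoint
for wild-type and boundary-deletion genotypes, runs the quantification
chain (per-million normalization, replicate averaging, wild-type
subtraction, 16-fragment smoothing for display) and measures log2
fold-changes in the printed mm10 regions of the Gbx2/Asb18 locus: the
Asb18 gene body across the boundary and five 30 kb controls inside the
viewpoint's TAD.
"""

from tadbound import (
    SyntheticConfig,
    average_replicates,
    normalize_profile,
    parse_region,
    region_log2fc,
    simulate_capture_profiles,
    smooth_profile,
    subtract_reference,
)
from tadbound.validation import GBX2_LOCUS_REGIONS

config = SyntheticConfig(seed=2)
profiles = simulate_capture_profiles(config, genotypes=["WT", "d3xCTCF"])


def averaged(genotype):
    return average_replicates(*[normalize_profile(p) for p in profiles[genotype]])


wt, mut = averaged("WT"), averaged("d3xCTCF")
diff = smooth_profile(subtract_reference(mut, wt), window=16)
print(f"smoothed subtraction track: {diff.values.size} fragments, "
      f"max gain {diff.values.max():.1f} (cross-boundary side)")

regions = [parse_region(r) for r in GBX2_LOCUS_REGIONS.values()]
table = region_log2fc(mut, wt, regions)
table.insert(0, "name", list(GBX2_LOCUS_REGIONS))
print("\nlog2 fold-change vs WT per region:")
print(table[["name", "region", "n_fragments", "log2fc"]].to_string(index=False))
print("\nOnly the region beyond the deleted CTCF boundary (Asb18) gains "
      "contacts; the intra-TAD control regions stay near zero.")
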