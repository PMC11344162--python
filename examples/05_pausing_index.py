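"""RNA Pol2 pausing indices from strand-specific nascent transcription.

The pausing index of a transcript is the mean promoter signal (-50..+250
around the TSS) over the mean gene-body signal (+250..TTS), read from the
track of the transcript's strand.  The generator encodes an exact PI per
gene category, which the analysis recovers.
"""

from tadbound import (
    SyntheticConfig,
    gene_pausing,
    pausing_index,
    pausing_summary,
    simulate_genome,
)
from tadbound.geometry import assign_bins, gene_level_assignments

bundle = simulate_genome(SyntheticConfig(seed=3))

records = [
    pausing_index(t, bundle.proseq_plus, bundle.proseq_minus) for t in bundle.transcripts
]
table = gene_pausing(records, bundle.expression)
print(f"genes with a finite pausing index: {len(table)} "
      f"(of {len(bundle.categories.all_genes)}; inactive genes have zero "
      "body signal and are excluded)")

rep = gene_level_assignments(assign_bins(bundle.tad_map, bundle.transcripts))
bin1 = {g for g, a in rep.items() if a.bin == 1}
summary = pausing_summary(table, bundle.categories, bin1)
print("\nmedian PI by category, activity and boundary proximity:")
print(summary.to_string(index=False))
print("\nDesigned PIs (developmental 2.0 < all 4.0 < housekeeping 6.0) are "
      "recovered exactly because the tracks are noise-free and piecewise "
      "constant.")
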