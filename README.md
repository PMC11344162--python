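# tadbound

Statistics of gene organization at TAD boundaries: gene-density tertiles,
intra-TAD positional binning, boundary insulation metrics, CTCF cluster
asymmetry and orientation, RNA Pol2 pausing indices, and the locus-level
quantification used for engineered cell lines (2^−ΔΔCT and Capture-C
region fold-changes).

## The problem

Developmental regulator genes — genes whose promoters sit under broad
H3K27me3/Polycomb domains — tend to live in gene-poor topologically
associating domains (TADs) and unusually close to TAD boundaries, with
clusters of CTCF sites lying between the gene and the boundary. Testing
that picture genome-wide, and quantifying what happens to an insulated
neighbour gene when the CTCF cluster or the competing promoter is deleted,
requires a set of small, exactly specified computations:

* **Gene density tertiles.** For each TAD, density = (#TSS in TAD)/length;
  TADs are ranked into low/medium/high-density tertiles (LD/MD/HD) and the
  over-representation of a gene class in LD TADs is a one-sided Fisher
  exact test on the 2×2 (class × LD) table.
* **Intra-TAD bins.** Each TAD is split into ten equal deciles, paired by
  distance to the nearest boundary: bin 1 is the outermost pair, bin 5 the
  central pair, bin 0 is inter-TAD. A TSS at position *p* in TAD [s, e)
  gets bin = min(5, ⌊10·d/L⌋ + 1) with d = min(p−s, e−1−p).
* **Boundary metrics.** Every TAD start/end, expanded ±50 kb, is scored by
  CTCF peak count, aggregated CTCF signal (Σ per-peak maxima), minimum
  insulation score and maximum boundary strength (values ≤ 0.2 floored to
  0 when the track is unfiltered). Classes (developmental / other / random)
  are compared with two-sided Wilcoxon rank-sum tests, Benjamini–Hochberg
  FDR, and Cliff's delta effect sizes.
* **CTCF asymmetry.** For a bin-1 gene, ΔCTCFpeaks@Bdry = n_inner − n_outer
  counts peaks (by midpoint) in the 100 kb half-window toward the TAD
  center minus the half-window toward the boundary; ΔCTCFsignal@Bdry is the
  same difference in summed peak signal. Negative = boundary-skewed.
  Motif orientation is +1 (inward) when the best motif points at the TAD
  center, −1 otherwise; inner/outer × inward/outward tables are tested by
  chi-squared with Cramér's V.
* **Pausing index.** PI = mean promoter signal (−50..+250 bp of the TSS) /
  mean gene-body signal (+250 bp..TTS), strand-aware, per-gene maximum over
  transcripts, restricted to finite values; genes are "active" above
  5 FPKM.
* **Engineered-locus quantification.** Relative expression by 2^−ΔΔCT
  against two reference genes with the rule that a change is NS unless
  fold-change ≥ 2 *and* p ≤ 0.05 (two-sided unpaired t-test); Capture-C
  pileups are normalized to one million per viewpoint, replicate-averaged,
  WT-subtracted, smoothed over 16 fragments for display, and quantified as
  per-region mean log2 fold-changes.

Every stage is exercised by a seeded synthetic-genome generator
(`tadbound.simulate`) that plants known effects — positional bias, LD odds
ratio, CTCF side bias, pausing indices, ΔΔCT designs, cross-boundary
contact gains — and records them in a truth object, so the whole pipeline
is testable as a parameter-recovery experiment without any external data.

## Worked example

`examples/` holds one short script per capability. For instance, the
engineered-line expression analysis (`python examples/06_qpcr_fold_changes.py`)
simulates Ct tables for a wild type and five rearranged lines with designed
effects, and quantifies them with 2^−ΔΔCT:

```
line                      fold           p  call   designed
WT                         1.0    1.00e+00  NS         1.0
d3xCTCF                    5.0    1.55e-27  sig        5.5
inv71kb                   13.3    7.96e-23  sig       15.0
d3xCTCF_inv71kb           18.3    1.55e-29  sig       17.6
dPromGbx2                  6.7    1.32e-15  sig        7.5
d3xCTCF_dPromGbx2         57.7    1.43e-23  sig       61.8
```

Each row is one engineered line: `fold` is the recovered expression
fold-change of the insulated gene versus wild type (noisy Ct replicates),
`designed` the value planted by the generator, and `call` the significance
under the NS rule. The combined CTCF-cluster + promoter deletion (~58×)
far exceeds either single deletion — the synergy between an insulator
cluster and a competing promoter that the design encodes.

Likewise `examples/01_tad_gene_organization.py` recovers the designed LD
odds ratio (2.09, 95% CI 1.24–3.46, Fisher p = 2.6e-03 for a design of
2.0) and the designed 60% bin-1 placement of developmental genes (58.0%
recovered at n = 150), and `examples/07_capture_regions.py` shows a
cross-boundary contact gain confined to the region beyond the deleted
boundary (log2FC ≈ 1.45 there, ≈ −0.1 in five 30 kb intra-TAD controls).

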