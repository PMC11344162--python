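# Methods

This note documents the models, conventions and design choices behind
`tadbound`, and what its synthetic-data validation does and does not show.

## Coordinate and track conventions

All coordinates are 0-based half-open (BED semantics). Printed region
strings `chrN:a-b` are parsed as start = a, end = b, which makes each of
the ten printed 30 kb control intervals exactly 30,000 bp wide. The
minus-strand TSS is `end − 1` (the last covered base), so the TSS is
always a base inside the transcript. Signal tracks are piecewise constant;
bases not covered by a segment carry an implicit 0 — required by the
zero-fill rule for viewpoint pileups and harmless for ChIP tracks. Track
statistics are base-weighted: the mean over a region averages per-base
values counting uncovered bases as zero, and min/max range over per-base
values including those zeros.

## Intra-TAD binning

A TSS at position p in TAD [s, e) of length L is assigned
`bin = min(5, (10·d) // L + 1)` with `d = min(p − s, e − 1 − p)`. Computing
the decile from the integer boundary distance (rather than from the
fractional position f = (p−s)/L) makes bin assignment *exactly* invariant
under coordinate mirroring — a property the fractional formula violates at
decile edges in the right half of a TAD — and agrees with explicit decile
intervals whenever L is a multiple of ten. A TSS exactly on a TAD start
belongs to that TAD; one exactly on a TAD end belongs to the following TAD
or to bin 0 (half-open rule, no double counting). A TSS at the exact
midline resolves to bin 5 through the cap. Genes with several transcripts
are reported through the transcript nearest a boundary by default; a
per-transcript mode exists.

## Density tertiles and enrichment

TADs are sorted by ascending density with ties broken by genomic order;
when N is not divisible by three the extra members go to the lower
tertiles first (LD before MD). The enrichment test is a one-sided
("greater") Fisher exact test of category × LD membership over the
universe of genes whose TSS falls inside a TAD; inter-TAD genes are
excluded. The reported odds ratio is the sample cross-product ratio; with
a zero cell the conditional-MLE estimate from the exact test is reported
and the result flagged. Confidence intervals are the exact conditional
intervals.

## Boundary metrics and group statistics

Boundaries are points (deduplicated TAD start/end coordinates); an
inter-TAD gap therefore contributes two distinct boundaries. A boundary is
"developmental" when a developmental TSS occupies the boundary-adjacent
decile of either flanking TAD (a strict mode requires every flanking
decile). Windows are ±50 kb, clipped only at chromosome ends (logged).
The strength floor (max ≤ 0.2 → 0) is a flag applied to tracks that were
not pre-thresholded upstream. Group comparisons use two-sided
Mann–Whitney tests; all tests of one invocation form a single
Benjamini–Hochberg family. Cliff's delta is computed exactly
(d = (#{x>y} − #{x<y})/(n_x·n_y), via sorted ranks) and labelled by the
standard 0.147 / 0.33 / 0.474 cutoffs. Identical constant groups return
p = 1 and d = 0 rather than an undefined statistic.

## CTCF asymmetry and orientation

For a bin-1 gene the nearest boundary is the TAD start if the TSS lies in
the left half (exact midline → end). The outer window is the 100 kb
half-window on the boundary side of the TSS, the inner window the
opposite one; windows are *not* truncated at the TAD boundary or center,
only at chromosome ends. Peaks are assigned by midpoint so each peak
belongs to exactly one side; a midpoint exactly on the TSS base counts as
inner (a documented convention — such peaks are excluded from the
reflection-symmetry tests, whose statement the convention deliberately
breaks on a single base). Orientation is taken from the lowest-q motif of
a peak; with the motif strand read as pointing toward increasing
coordinates, a peak left of the TAD center with a plus motif is inward
(+1). Cramér's V uses the Pearson chi-squared statistic without
continuity correction.

Two exact reflection symmetries are enforced by tests: reflecting the
peak configuration about the TSS flips ΔCTCFpeaks@Bdry and
ΔCTCFsignal@Bdry (the half-windows swap contents), and reflecting peaks
about the TAD center with motif strands kept swaps inward/outward labels.
Mirroring an entire locus (TAD + gene + peaks) leaves Δ unchanged, since
the boundary-skew of a configuration is itself reflection-invariant; the
window *roles* swap, which is tested separately.

## Knee threshold for broad-domain calling

Peak calls are filtered with strict inequalities (fold enrichment > 3,
q < 0.1), merged when the inter-peak gap is ≤ 1 kb (the merge semantics of
`bedtools merge -d`), and attached to every gene whose TSS base lies in
the merged domain. The size threshold separating broad from narrow
domains is pluggable and recorded in the estimate. The default, `otsu`,
splits the sizes at the minimum intra-class-variance point and returns
the midpoint between the classes; on a bimodal size distribution it lands
between the modes (median ≈ 5.7 kb on the 9:1 mixture of ~2 kb and
~12 kb domains used in validation), which is the regime where a broad-
domain definition is meaningful. A chord-distance elbow estimator
(`chord`, maximum distance to the chord of the descending sorted-size
curve) is provided for L-shaped curves with a single sharp elbow; on a
bimodal curve it settles at the top of the narrow mode (~2.7 kb) and
would misclassify the upper tail of narrow domains, which is why it is
not the default. Gene calling uses a strict comparison (size > threshold)
and is monotone in the threshold. Housekeeping genes are supplied as a
user list, not re-derived.

## Pausing index

Promoter = 50 bp upstream to 250 bp downstream of the TSS; body = 250 bp
downstream of the TSS to the TTS inclusive; on the minus strand
"downstream" means decreasing coordinates and both windows are the exact
mirrors of the plus-strand ones, so strand-mirrored data give identical
indices. Means are base-weighted, signal values are taken as magnitudes
(minus-strand coverage is conventionally stored negative), and only the
track matching the transcript's strand is read; merged (non-strand-
specific) data is handled by passing the same track twice. Transcripts
with zero body mean have a non-finite PI and are dropped from summaries;
per gene the maximum finite PI is kept, and activity is expression
strictly above 5 FPKM.

## Relative expression (2^−ΔΔCT)

Per biological replicate, ΔCt = Ct_target − mean(Ct_ref1, Ct_ref2); the
arithmetic mean of the two reference Cts equals the geometric mean of
their linear quantities. ΔΔCt subtracts the mean baseline-line ΔCt;
fold-changes are averaged in log2 space and tested against the baseline
replicates with a two-sided unpaired t-test on log2 values — the natural
scale for this statistic. Significance requires both |log2FC| ≥ 1 and
p ≤ 0.05, the contrapositive of the "NS: fold-change < 2 or p > 0.05"
rule.

## Viewpoint interaction profiles

Profiles live on a complete fragment grid (default 200 bp), so zero-fill
is inherent; fragments are a fixed-width grid rather than a restriction
map because the quantification is generic in the fragment unit.
Normalization scales a profile to a total of 10^6. Region means are
unweighted over fragments whose midpoints fall in the region; the log2
fold-change uses a pseudocount defaulting to 10^−3 of the wild-type locus
mean (the measured regions carry abundant signal, so the choice is
uncritical; it is exposed as a parameter). Smoothing (centered 16-fragment
rolling mean, edges truncated) is for display tracks only and never feeds
quantification.

## The synthetic-genome generator

The generator is the package's experimental ground: every designed effect
is recorded in a truth object and recovered by the corresponding analysis
stage in the test suite. Each sub-generator draws from its own stream of
the master seed, so changing one component leaves the others bit-identical.

What it emulates, and the defaults (chosen as plausible mammalian-genome
magnitudes where no study condition fixes them): TADs with log-normal
lengths (default mean 1.2 Mb, floored at 500 kb) tiling six 80 Mb
chromosomes with ~6% inter-TAD gaps, 40% of junctions sharing a
coordinate; 1,000 single-transcript genes in three categories; bin-1
placement probabilities 0.6 / 0.35 / 0.2 (developmental / housekeeping /
other); a designed 2.0 odds ratio of developmental genes into a
pre-designated sparse third of TADs (placement weights 1:8:24 per bp for
sparse/medium/dense); H3K27me3 domain sizes from a 9:1 mixture of
N(2 kb, 0.3 kb) and N(12 kb, 1.5 kb) with the broad mode centered on
developmental TSSs; CTCF layouts around each bin-1 gene with the majority
side drawn Bernoulli(side bias 0.9 / 0.5 / 0.5) and at least one peak of
margin, plus Poisson(3) generic clusters at unclaimed boundaries and
sub-threshold decoys removed by the standard fold-change > 4, q < 0.01
filter; insulation dips (N(−0.8, 0.2) over ±20 kb) and strength bumps
(log-normal around 0.45) at boundaries; noise-free piecewise-constant
nascent-transcription tracks encoding exact pausing indices 2 / 6 / 4;
Ct tables with designed log2 fold-changes patterned on the engineered
mESC lines (replicate counts 18/21/10/14/6/6, Gaussian Ct noise, default
sd 0.25); and viewpoint pileups with power-law distance decay (exponent
1, offset 2 kb) times a per-genotype cross-boundary attenuation, with
unit-mean log-normal fragment noise.

Two structural choices keep designed effects exactly recoverable. First,
designed bin-1 genes occupy mutually exclusive boundary "slots" at least
300 kb apart — the distance at which one gene's designed peaks can never
enter another's ±100 kb windows — and generic clusters are suppressed near
slots; the designed sign of ΔCTCFpeaks@Bdry is then exactly the Bernoulli
draw. Requesting more bin-1 genes than slots raises an explicit
infeasible-placement error. Second, all capture genotypes share one
normalization constant (wild-type expected locus total = 10^6), so
designed contact ratios are preserved exactly; re-normalizing each
profile to exactly 10^6 afterwards (the reads-per-million contract)
compresses the recovered cross-boundary log2FC by the cross-boundary
share of total signal — about 0.04 at the validation geometry, inside the
recovery tolerance.

What the generator does *not* emulate: nucleotide sequence, read-level
noise, peak-caller artifacts, correlated placement of genes and CTCF
beyond the designed effects, Hi-C matrices (insulation and strength are
drawn directly as tracks), restriction-site geometry, or reference-gene
instability in qPCR. Recovery of a designed effect therefore demonstrates
the correctness of the computations and their statistical calibration,
not robustness to the full noise structure of real data.

Two regimes of the generator trade off against each other: resolving
density tertiles wants many genes per TAD, while designed bin-1 CTCF
layouts want many exclusive boundary slots. The density-recovery
experiments therefore use a gene-dense configuration (five 60 Mb
chromosomes, 2,000 genes, low bin-1 bias) and the asymmetry experiments a
boundary-rich one (twelve 100 Mb chromosomes, ~600 kb TADs); each
validation protocol in `tadbound.validation` states its configuration.

## Problem sizes in the validation suite

The recovery experiments run at the sizes their sampling bounds assume:
100 seeds × 1,000 developmental genes for the positional bias (±3 points
of 60%), 100 seeds × 2,000 genes for the LD odds ratio (exact-CI coverage
of 2.0), 100 seeds × 500 genes per category for the side bias (±5 points
of 90%), 100 seeds for the knee range and calling precision/recall, 200
simulations for the FDR null, 20 seeds × 10,000 fragments for the
capture chain (recovery of log2FC 1.0 within ±0.07), and 10 replicates ×
7 designs for the noisy ΔΔCT grid (mean absolute error < 0.15). Oracle-
equivalence checks (binning, Δ statistics, Cliff's delta, track means)
use 1,000 random instances each against brute-force enumeration.

## Interfaces

The package is a library: the importable API plus the narrative scripts
in `examples/` are the interface, and `scripts/acceptance.py` re-runs the
full validation. File I/O covers BED, bedGraph and headered TSV tables
for transcripts and peaks; BAM/FASTQ handling, alignment, peak calling,
Hi-C file formats and motif scanning are out of scope (peak tables carry
motif attributes as inputs).
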