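"""Parameter-recovery study protocols.

Each function runs one seeded trial of a recovery experiment: a synthetic
dataset is generated with a designed effect, the corresponding analysis
stage is executed, and the recovered quantity is returned.  The
configurations fix the study conditions (sample sizes, designed effect
sizes, noise levels) used throughout the package's validation suite; the
reproduction script and the test suite both drive these entry points.

The printed mm10 regions of the two engineered loci (the measured gene
bodies and the five 30 kb control regions of each locus) are kept here as
module data: parsing them under the 0-based half-open convention makes
each control region exactly 30,000 bp wide.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .annotation import call_developmental_genes
from .asymmetry import compare_delta_distributions, delta_ctcf_all
from .core import GenomicInterval, parse_region
from .geometry import assign_bins, bin_distribution, density_tertiles, ld_enrichment, tad_density
from .pausing import gene_pausing, pausing_index
from .quant import average_replicates, ddct_fold_change, normalize_profile, region_log2fc
from .simulate import SyntheticConfig, simulate_capture_profiles, simulate_ct_table, simulate_genome

__all__ = [
    "GBX2_LOCUS_REGIONS",
    "SIX3_LOCUS_REGIONS",
    "control_region_widths",
    "bin1_bias_trial",
    "ld_odds_trial",
    "side_bias_trial",
    "knee_trial",
    "ddct_grid_trial",
    "capture_gain_trial",
    "pausing_trial",
]

# Gbx2/Asb18 locus (mm10): measured Asb18 span and five 30 kb controls
GBX2_LOCUS_REGIONS = {
    "Asb18": "chr1:89952677-90014577",
    "ctrl1": "chr1:89803398-89833398",
    "ctrl2": "chr1:89753398-89783398",
    "ctrl3": "chr1:89703398-89733398",
    "ctrl4": "chr1:89653398-89683398",
    "ctrl5": "chr1:89603398-89633398",
}

# Six3/Six2 locus (mm10): measured Six2 span and five 30 kb controls
SIX3_LOCUS_REGIONS = {
    "Six2": "chr17:85674267-85698254",
    "ctrl1": "chr17:85388601-85418601",
    "ctrl2": "chr17:85338601-85368601",
    "ctrl3": "chr17:85288601-85318601",
    "ctrl4": "chr17:85238601-85268601",
    "ctrl5": "chr17:85188601-85218601",
}


def control_region_widths() -> dict[str, int]:
    """Widths (bp) of the ten printed 30 kb control regions."""
    out = {}
    for locus, regions in (("gbx2", GBX2_LOCUS_REGIONS), ("six3", SIX3_LOCUS_REGIONS)):
        for name, text in regions.items():
            if name.startswith("ctrl"):
                out[f"{locus}_{name}"] = parse_region(text).width
    return out


# ---------------------------------------------------------------------------
# positional bias of developmental genes (bin-1 placement)
# ---------------------------------------------------------------------------


def bin1_bias_trial(seed: int, n_dev: int = 1000, bias: float = 0.6) -> float:
    """Percentage of developmental genes recovered in bin 1 (designed: 100*bias)."""
    cfg = SyntheticConfig(
        seed=seed,
        n_chromosomes=10,
        chrom_length=100_000_000,
        n_genes={"developmental": n_dev, "housekeeping": 50, "other": 50},
        bin1_bias={"developmental": bias, "housekeeping": 0.1, "other": 0.1},
    )
    bundle = simulate_genome(cfg)
    dist = bin_distribution(assign_bins(bundle.tad_map, bundle.transcripts), bundle.categories)
    return float(dist.loc["developmental", 1])


# ---------------------------------------------------------------------------
# enrichment of developmental genes in low-density TADs
# ---------------------------------------------------------------------------


def ld_odds_trial(seed: int, odds: float = 2.0) -> tuple[float, float, float]:
    """(odds ratio, CI low, CI high) of the low-density enrichment test.

    2,000 genes on a genome dense enough in genes per TAD that the
    density-rank tertiles recover the designed sparse class.
    """
    cfg = SyntheticConfig(
        seed=seed,
        n_chromosomes=5,
        chrom_length=60_000_000,
        ld_dev_odds=odds,
        n_genes={"developmental": 500, "housekeeping": 400, "other": 1100},
        bin1_bias={"developmental": 0.05, "housekeeping": 0.05, "other": 0.05},
    )
    bundle = simulate_genome(cfg)
    records = density_tertiles(tad_density(bundle.tad_map, bundle.transcripts))
    res = ld_enrichment(
        bundle.categories.developmental, records, bundle.transcripts, bundle.tad_map
    )
    return res.odds_ratio, res.ci_low, res.ci_high


# ---------------------------------------------------------------------------
# CTCF side bias around boundary-proximal genes
# ---------------------------------------------------------------------------


def side_bias_trial(seed: int, n_per_category: int = 500) -> tuple[float, float]:
    """(developmental negative-delta fraction, dev-vs-all q value)."""
    cfg = SyntheticConfig(
        seed=seed,
        n_chromosomes=12,
        chrom_length=100_000_000,
        tad_size_log_mean=math.log(600_000),
        tad_min_size=350_000,
        n_genes={c: n_per_category for c in ("developmental", "housekeeping", "other")},
        bin1_bias={c: 1.0 for c in ("developmental", "housekeeping", "other")},
    )
    bundle = simulate_genome(cfg)
    peaks = [
        p for p in bundle.ctcf_peaks if p.fold_enrichment > 4 and p.q_value < 0.01
    ]
    records = delta_ctcf_all(bundle.tad_map, bundle.transcripts, peaks)
    deltas: dict[str, list[float]] = {}
    for rec in records:
        deltas.setdefault(bundle.truth.category_of[rec.gene_id], []).append(
            float(rec.delta_peaks)
        )
    deltas["all"] = [d for v in list(deltas.values()) for d in v]
    res = compare_delta_distributions(deltas)
    q = next(
        c.q_value
        for c in res.comparisons
        if {c.group_a, c.group_b} == {"developmental", "all"}
    )
    return res.negative_fraction["developmental"], q


# ---------------------------------------------------------------------------
# knee threshold and developmental-gene calling
# ---------------------------------------------------------------------------


def knee_trial(seed: int) -> tuple[float, float, float]:
    """(threshold, precision, recall) of broad-domain gene classification.

    100 broad domains over developmental genes against 900 narrow domains
    (the 9:1 bimodal size mixture).
    """
    cfg = SyntheticConfig(
        seed=seed, n_genes={"developmental": 100, "housekeeping": 300, "other": 600}
    )
    bundle = simulate_genome(cfg)
    called, knee, _ = call_developmental_genes(bundle.h3k27me3_peaks, bundle.transcripts)
    truth = bundle.categories.developmental
    tp = len(called & truth)
    precision = tp / len(called) if called else 0.0
    recall = tp / len(truth)
    return knee.threshold, precision, recall


# ---------------------------------------------------------------------------
# relative expression chain
# ---------------------------------------------------------------------------


def ddct_grid_trial(
    seed: int,
    designs: Sequence[float] = (0, 1, 2, 3, 4, 5, 6),
    noise_sd: float = 0.0,
    n_replicates: int = 10,
) -> dict[float, float]:
    """Designed log2 fold-change grid -> recovered log2 fold-change."""
    lines = {f"L{int(d)}": float(d) for d in designs if d != 0}
    cfg = SyntheticConfig(
        seed=seed,
        ddct_noise_sd=noise_sd,
        ddct_replicates={"WT": n_replicates, **{k: n_replicates for k in lines}},
        ddct_log2fc={"WT": {"g": 0.0}, **{k: {"g": v} for k, v in lines.items()}},
    )
    res = ddct_fold_change(simulate_ct_table(cfg), "g")
    out = {0.0: float(np.log2(res["WT"].fold_change))}
    for k, v in lines.items():
        out[v] = float(np.log2(res[k].fold_change))
    return out


def ddct_study_fold_changes(seed: int) -> dict[str, float]:
    """Recovered fold-changes of the engineered-line design (default config)."""
    cfg = SyntheticConfig(seed=seed)
    res = ddct_fold_change(simulate_ct_table(cfg), "Asb18")
    return {line: r.fold_change for line, r in res.items()}


# ---------------------------------------------------------------------------
# viewpoint interaction chain
# ---------------------------------------------------------------------------


def capture_gain_trial(
    seed: int, gain: float = 2.0, noise_sd: float = 0.1
) -> float:
    """Recovered cross-boundary region log2 fold-change for a designed gain.

    10,000 fragments of 200 bp; the full quantification chain (per-million
    normalization, replicate averaging, region means) is executed.
    """
    cfg = SyntheticConfig(
        seed=seed,
        capture_locus=("chr1", 89_000_000, 91_000_000),
        capture_viewpoint=89_500_000,
        capture_boundary=90_100_000,
        capture_noise_sd=noise_sd,
        capture_attenuation={"WT": 0.1, "mut": 0.1 * gain},
    )
    profiles = simulate_capture_profiles(cfg, genotypes=["WT", "mut"])
    wt = average_replicates(*[normalize_profile(p) for p in profiles["WT"]])
    mut = average_replicates(*[normalize_profile(p) for p in profiles["mut"]])
    region = [GenomicInterval("chr1", 90_300_000, 90_330_000)]
    return float(region_log2fc(mut, wt, region).log2fc.iloc[0])


# ---------------------------------------------------------------------------
# pausing index chain
# ---------------------------------------------------------------------------


def pausing_trial(seed: int) -> dict[str, float]:
    """Maximum absolute error of recovered gene PIs vs the designed values."""
    cfg = SyntheticConfig(seed=seed)
    bundle = simulate_genome(cfg)
    records = [
        pausing_index(t, bundle.proseq_plus, bundle.proseq_minus)
        for t in bundle.transcripts
    ]
    table = gene_pausing(records, bundle.expression)
    errs: dict[str, float] = {}
    for row in table.itertuples():
        if row.gene_id not in bundle.truth.active_genes:
            continue
        cat = bundle.truth.category_of[row.gene_id]
        designed = bundle.truth.designed_pausing[cat]
        errs[cat] = max(errs.get(cat, 0.0), abs(row.pi - designed))
    return errs
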