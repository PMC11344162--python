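"""Seeded synthetic-genome generator for boundary-organization analyses.

The generator emits a mutually consistent bundle — TAD map, transcripts,
gene categories, H3K27me3 and CTCF peak calls, insulation/boundary-strength
tracks, strand-specific nascent-transcription tracks and an expression
table — whose statistical structure carries *designed* effects recorded in
a truth object, so every downstream analysis stage can be exercised as a
parameter-recovery experiment with no external data:

* gene TSSs are placed in TADs with a configurable per-category probability
  of landing in the boundary-proximal decile (bin 1);
* TADs are pre-designated sparse/medium/dense and gene placement weights
  realize a configurable odds ratio of developmental genes in low-density
  TADs;
* each bin-1 gene receives a CTCF peak set that is deliberately skewed
  toward the boundary or the TAD center (Bernoulli with the per-category
  side bias), with motif orientations drawn relative to the TAD center;
* H3K27me3 peak sizes follow a bimodal mixture whose broad mode is centered
  on developmental-gene TSSs;
* nascent-transcription tracks encode an exact per-category pausing index
  as piecewise-constant promoter/body levels;
* Ct tables and viewpoint interaction profiles carry designed expression
  fold-changes and cross-boundary contact changes.

Every sub-generator draws from its own RNG stream derived from the master
seed by a fixed offset, so changing one component's parameters leaves the
others untouched.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core import (
    GeneCategorySet,
    GenomicInterval,
    PeakRecord,
    SignalTrack,
    TadMap,
    TranscriptRecord,
)
from .pausing import promoter_body_windows
from .quant import CaptureProfile

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "SyntheticBundle",
    "simulate_genome",
    "simulate_ct_table",
    "simulate_capture_profiles",
]

CATEGORIES = ("developmental", "housekeeping", "other")

# minimum separation between two designed bin-1 CTCF layouts; derived from
# the layout geometry (TSS <= 50 kb from its boundary, designed peaks
# <= 95 kb from the TSS, analysis windows reach 100 kb from the TSS), so
# neighbouring designs can never intrude into each other's windows
_SLOT_SPACING = 300_000
_SLOT_EDGE_MARGIN = 150_000
_BIN1_MAX_OFFSET = 50_000
_PEAK_MIN_OFFSET = 3_000
_PEAK_MAX_OFFSET = 95_000


def _default_n_genes() -> dict[str, int]:
    return {"developmental": 150, "housekeeping": 250, "other": 600}


def _default_bin1_bias() -> dict[str, float]:
    return {"developmental": 0.6, "housekeeping": 0.35, "other": 0.2}


def _default_side_bias() -> dict[str, float]:
    return {"developmental": 0.9, "housekeeping": 0.5, "other": 0.5}


def _default_pausing() -> dict[str, float]:
    return {"developmental": 2.0, "housekeeping": 6.0, "other": 4.0}


def _default_active_fraction() -> dict[str, float]:
    return {"developmental": 0.3, "housekeeping": 1.0, "other": 0.6}


def _default_ddct_replicates() -> dict[str, int]:
    # replicate counts follow the engineered mESC lines of the study design
    return {
        "WT": 18,
        "d3xCTCF": 21,
        "inv71kb": 10,
        "d3xCTCF_inv71kb": 14,
        "dPromGbx2": 6,
        "d3xCTCF_dPromGbx2": 6,
    }


def _default_ddct_log2fc() -> dict[str, dict[str, float]]:
    return {
        "WT": {"Asb18": 0.0, "Gbx2": 0.0},
        "d3xCTCF": {"Asb18": math.log2(5.5), "Gbx2": 0.0},
        "inv71kb": {"Asb18": math.log2(15.0), "Gbx2": 0.0},
        "d3xCTCF_inv71kb": {"Asb18": math.log2(17.6), "Gbx2": 0.0},
        "dPromGbx2": {"Asb18": math.log2(7.5), "Gbx2": math.log2(0.2)},
        "d3xCTCF_dPromGbx2": {"Asb18": math.log2(61.8), "Gbx2": math.log2(0.2)},
    }


def _default_capture_attenuation() -> dict[str, float]:
    # fraction of distance-expected contact surviving across the boundary
    return {
        "WT": 0.15,
        "d3xCTCF": 0.45,
        "dPromGbx2": 0.18,
        "d3xCTCF_dPromGbx2": 0.5,
    }


@dataclass
class SyntheticConfig:
    """All knobs of the generator; identical config + seed give identical output."""

    seed: int = 0
    # genome geometry
    n_chromosomes: int = 6
    chrom_length: int = 80_000_000
    tad_size_log_mean: float = math.log(1_200_000)
    tad_size_log_sd: float = 0.18
    tad_min_size: int = 500_000
    inter_tad_fraction: float = 0.06
    shared_boundary_prob: float = 0.4
    # genes
    n_genes: dict[str, int] = field(default_factory=_default_n_genes)
    bin1_bias: dict[str, float] = field(default_factory=_default_bin1_bias)
    ld_dev_odds: float = 2.0
    density_weights: tuple[float, float, float] = (1.0, 8.0, 24.0)
    gene_spacing: int = 12_000
    transcript_length: int = 8_000
    multi_transcript_prob: float = 0.0
    # H3K27me3 domains: (mean, sd, weight) per mode; broad mode is the last
    peak_size_modes: tuple[tuple[float, float, float], ...] = (
        (2000.0, 300.0, 0.9),
        (12000.0, 1500.0, 0.1),
    )
    # CTCF peaks
    ctcf_peaks_per_boundary: float = 3.0
    ctcf_signal_log_mean: float = math.log(8.0)
    ctcf_signal_log_sd: float = 0.5
    motif_missing_fraction: float = 0.1
    motif_inward_fraction: float = 0.55
    boundary_side_bias: dict[str, float] = field(default_factory=_default_side_bias)
    # nascent transcription / expression
    pausing: dict[str, float] = field(default_factory=_default_pausing)
    active_fraction: dict[str, float] = field(default_factory=_default_active_fraction)
    # boundary tracks
    insulation_baseline: float = 0.25
    insulation_dip_mean: float = -0.8
    insulation_dip_sd: float = 0.2
    strength_log_mean: float = math.log(0.45)
    strength_log_sd: float = 0.5
    # RT-qPCR design
    ddct_noise_sd: float = 0.25
    ddct_replicates: dict[str, int] = field(default_factory=_default_ddct_replicates)
    ddct_log2fc: dict[str, dict[str, float]] = field(default_factory=_default_ddct_log2fc)
    ddct_reference_ct: dict[str, float] = field(
        default_factory=lambda: {"Eef1a1": 17.0, "Hprt1": 19.0}
    )
    ddct_target_ct: float = 25.0
    ddct_baseline_line: str = "WT"
    # Capture-C design (synthetic stand-in for a viewpoint locus)
    capture_locus: tuple[str, int, int] = ("chr1", 89_228_752, 90_664_659)
    capture_viewpoint: int = 89_840_000
    capture_boundary: int = 89_900_000
    capture_fragment_size: int = 200
    capture_decay: float = 1.0
    capture_d0: float = 2_000.0
    capture_attenuation: dict[str, float] = field(
        default_factory=_default_capture_attenuation
    )
    capture_noise_sd: float = 0.1
    capture_replicates: int = 2

    def __post_init__(self) -> None:
        for name, probs in (
            ("bin1_bias", self.bin1_bias),
            ("boundary_side_bias", self.boundary_side_bias),
            ("active_fraction", self.active_fraction),
        ):
            for cat, p in probs.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"{name}[{cat!r}] = {p} outside [0, 1]")
        if not 0.0 <= self.inter_tad_fraction < 1.0:
            raise ValueError("inter_tad_fraction must be in [0, 1)")
        if self.tad_min_size <= 0 or self.chrom_length <= 0:
            raise ValueError("geometry parameters must be positive")
        if self.ld_dev_odds <= 0:
            raise ValueError("ld_dev_odds must be > 0")


@dataclass
class SyntheticTruth:
    """Record of every designed effect, for parameter-recovery tests."""

    tad_group: dict[tuple[str, int], str]
    category_of: dict[str, str]
    bin1_genes: set[str]
    gene_tss: dict[str, int]
    gene_slot: dict[str, tuple[str, int, str]]  # gene -> (chrom, boundary, side)
    neg_delta_designed: dict[str, bool]  # True: peaks skewed toward boundary
    active_genes: set[str]
    designed_pausing: dict[str, float]  # per category
    boundary_insulation: dict[tuple[str, int], float]
    boundary_strength: dict[tuple[str, int], float]
    ld_dev_odds: float
    bin1_bias: dict[str, float]
    boundary_side_bias: dict[str, float]


@dataclass
class SyntheticBundle:
    tad_map: TadMap
    transcripts: list[TranscriptRecord]
    categories: GeneCategorySet
    h3k27me3_peaks: list[PeakRecord]
    ctcf_peaks: list[PeakRecord]
    insulation_track: SignalTrack
    strength_track: SignalTrack
    proseq_plus: SignalTrack
    proseq_minus: SignalTrack
    expression: dict[str, float]
    truth: SyntheticTruth


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


# ---------------------------------------------------------------------------
# genome geometry
# ---------------------------------------------------------------------------


def _simulate_tads(config: SyntheticConfig) -> TadMap:
    rng = _rng(config, 0)
    genome = {f"chr{i + 1}": config.chrom_length for i in range(config.n_chromosomes)}
    tads: list[GenomicInterval] = []
    mean_gap = config.inter_tad_fraction / max(1e-9, 1.0 - config.inter_tad_fraction)
    for chrom in genome:
        pos = 0
        while True:
            size = int(
                np.exp(rng.normal(config.tad_size_log_mean, config.tad_size_log_sd))
            )
            size = max(size, config.tad_min_size)
            if pos > 0:
                if rng.random() < config.shared_boundary_prob:
                    gap = 0
                else:
                    gap = int(mean_gap * size * rng.uniform(0.5, 1.5))
            else:
                gap = int(mean_gap * size * rng.uniform(0.5, 1.5))
            start = pos + gap
            if start + size > config.chrom_length:
                break
            tads.append(GenomicInterval(chrom, start, start + size))
            pos = start + size
    return TadMap(tads, genome)


# ---------------------------------------------------------------------------
# gene placement
# ---------------------------------------------------------------------------


def _assign_tad_groups(
    tad_map: TadMap, rng: np.random.Generator
) -> dict[tuple[str, int], str]:
    tads = tad_map.all_tads()
    n = len(tads)
    labels = np.array(
        ["sparse"] * (n // 3) + ["medium"] * (n // 3) + ["dense"] * (n - 2 * (n // 3))
    )
    rng.shuffle(labels)
    return {(t.chrom, t.start): lab for t, lab in zip(tads, labels)}


def _bin1_slots(
    tad_map: TadMap, rng: np.random.Generator
) -> list[tuple[int, str]]:
    """Boundary-side slots for designed bin-1 genes, mutually >= 300 kb apart.

    Returns (tad_index, side) pairs; exclusivity guarantees that no two
    designed CTCF layouts can reach into each other's +/-100 kb windows.
    """
    tads = tad_map.all_tads()
    candidates = []
    for i, tad in enumerate(tads):
        for side, pos in (("start", tad.start), ("end", tad.end)):
            if _SLOT_EDGE_MARGIN <= pos <= tad_map.genome[tad.chrom] - _SLOT_EDGE_MARGIN:
                candidates.append((i, side, tad.chrom, pos))
    order = rng.permutation(len(candidates))
    accepted: list[tuple[int, str]] = []
    taken: dict[str, list[int]] = {}
    for j in order:
        i, side, chrom, pos = candidates[j]
        positions = taken.setdefault(chrom, [])
        k = bisect.bisect_left(positions, pos)
        if k > 0 and pos - positions[k - 1] < _SLOT_SPACING:
            continue
        if k < len(positions) and positions[k] - pos < _SLOT_SPACING:
            continue
        positions.insert(k, pos)
        accepted.append((i, side))
    return accepted


def _place_genes(
    config: SyntheticConfig,
    tad_map: TadMap,
    tad_group: dict[tuple[str, int], str],
) -> tuple[
    list[TranscriptRecord],
    GeneCategorySet,
    dict[str, int],
    set[str],
    dict[str, tuple[str, int, str]],
]:
    rng = _rng(config, 1)
    tads = tad_map.all_tads()
    lengths = np.array([t.width for t in tads], dtype=float)
    groups = np.array([tad_group[(t.chrom, t.start)] for t in tads])

    w = np.array(
        [
            config.density_weights[{"sparse": 0, "medium": 1, "dense": 2}[g]]
            for g in groups
        ]
    )
    base_w = w * lengths
    base_p = base_w / base_w.sum()
    share_sparse = base_p[groups == "sparse"].sum()
    odds = share_sparse / (1.0 - share_sparse) * config.ld_dev_odds
    p_sparse_dev = odds / (1.0 + odds)
    dev_p = base_p.copy()
    dev_p[groups == "sparse"] *= p_sparse_dev / share_sparse
    dev_p[groups != "sparse"] *= (1.0 - p_sparse_dev) / (1.0 - share_sparse)

    # designed bin-1 slots grouped by TAD density class
    slots = _bin1_slots(tad_map, rng)
    slot_pool: dict[str, list[tuple[int, str]]] = {"sparse": [], "medium": [], "dense": []}
    for i, side in slots:
        slot_pool[groups[i]].append((i, side))

    transcripts: list[TranscriptRecord] = []
    cat_sets: dict[str, set[str]] = {c: set() for c in CATEGORIES}
    gene_tss: dict[str, int] = {}
    bin1_genes: set[str] = set()
    gene_slot: dict[str, tuple[str, int, str]] = {}
    tss_by_tad: dict[int, list[int]] = {}

    prefix = {"developmental": "dev", "housekeeping": "hk", "other": "oth"}

    def pop_slot(group_choice: str) -> tuple[int, str]:
        pool = slot_pool[group_choice]
        if not pool:
            for g in ("sparse", "medium", "dense"):
                if slot_pool[g]:
                    pool = slot_pool[g]
                    break
        if not pool:
            raise RuntimeError(
                "infeasible placement: more designed bin-1 genes than available "
                "boundary slots; enlarge the genome or lower bin1_bias"
            )
        k = int(rng.integers(len(pool)))
        return pool.pop(k)

    def interior_position(tad: GenomicInterval) -> int:
        L = tad.width
        lo = tad.start + (L + 9) // 10
        hi = tad.start + (9 * L) // 10 - 1
        for _ in range(80):
            p = int(rng.integers(lo, hi + 1))
            if (10 * min(p - tad.start, tad.end - 1 - p)) // L >= 1 and _spaced(p):
                return p
        return -1

    current_tad_index = [0]

    def _spaced(p: int) -> bool:
        return all(
            abs(p - q) >= config.gene_spacing
            for q in tss_by_tad.get(current_tad_index[0], [])
        )

    for cat in CATEGORIES:
        n = config.n_genes.get(cat, 0)
        bias = config.bin1_bias.get(cat, 0.0)
        for k in range(n):
            gid = f"{prefix[cat]}{k:05d}"
            in_bin1 = rng.random() < bias
            if in_bin1:
                if cat == "developmental":
                    g_choice = rng.choice(
                        ["sparse", "medium", "dense"],
                        p=[
                            p_sparse_dev,
                            float(base_p[groups == "medium"].sum())
                            / (1 - share_sparse)
                            * (1 - p_sparse_dev),
                            float(base_p[groups == "dense"].sum())
                            / (1 - share_sparse)
                            * (1 - p_sparse_dev),
                        ],
                    )
                else:
                    g_choice = rng.choice(
                        ["sparse", "medium", "dense"],
                        p=[
                            share_sparse,
                            float(base_p[groups == "medium"].sum()),
                            float(base_p[groups == "dense"].sum()),
                        ],
                    )
                ti, side = pop_slot(str(g_choice))
                tad = tads[ti]
                current_tad_index[0] = ti
                max_off = min(tad.width // 10, _BIN1_MAX_OFFSET)
                for _ in range(80):
                    off = int(rng.integers(2_000, max(2_001, max_off)))
                    tss = tad.start + off if side == "start" else tad.end - 1 - off
                    if _spaced(tss):
                        break
                bin1_genes.add(gid)
                gene_slot[gid] = (
                    tad.chrom,
                    tad.start if side == "start" else tad.end,
                    side,
                )
            else:
                p_vec = dev_p if cat == "developmental" else base_p
                for _ in range(60):
                    ti = int(rng.choice(len(tads), p=p_vec))
                    tad = tads[ti]
                    current_tad_index[0] = ti
                    tss = interior_position(tad)
                    if tss >= 0:
                        break
                else:
                    raise RuntimeError(
                        "infeasible placement: could not place an interior gene "
                        "with the requested spacing"
                    )
                if tss < 0:
                    raise RuntimeError("infeasible placement")
            tss_by_tad.setdefault(current_tad_index[0], []).append(tss)
            gene_tss[gid] = tss
            cat_sets[cat].add(gid)
            strand = "+" if rng.random() < 0.5 else "-"
            length = config.transcript_length
            chrom_len = tad_map.genome[tad.chrom]
            if strand == "+":
                start, end = tss, min(tss + length, chrom_len)
            else:
                start, end = max(0, tss - length + 1), tss + 1
            transcripts.append(
                TranscriptRecord(gid, f"{gid}.1", GenomicInterval(tad.chrom, start, end), strand)
            )
            if config.multi_transcript_prob > 0 and rng.random() < config.multi_transcript_prob:
                short = max(400, int(length * 0.6))
                if strand == "+":
                    s2, e2 = tss, min(tss + short, chrom_len)
                else:
                    s2, e2 = max(0, tss - short + 1), tss + 1
                transcripts.append(
                    TranscriptRecord(gid, f"{gid}.2", GenomicInterval(tad.chrom, s2, e2), strand)
                )

    categories = GeneCategorySet(
        developmental=cat_sets["developmental"],
        housekeeping=cat_sets["housekeeping"],
        all_genes=set(gene_tss),
    )
    return transcripts, categories, gene_tss, bin1_genes, gene_slot


# ---------------------------------------------------------------------------
# CTCF peaks
# ---------------------------------------------------------------------------


def _make_ctcf_peak(
    rng: np.random.Generator,
    chrom: str,
    mid: int,
    tad_center: int | None,
    config: SyntheticConfig,
    passing: bool = True,
) -> PeakRecord:
    half = 200
    iv = GenomicInterval(chrom, max(0, mid - half), mid + half)
    if passing:
        fe = float(rng.uniform(4.5, 30.0))
        q = float(rng.uniform(1e-4, 0.009))
    else:
        fe = float(rng.uniform(1.0, 3.9))
        q = float(rng.uniform(0.02, 0.5))
    signal = float(
        np.exp(rng.normal(config.ctcf_signal_log_mean, config.ctcf_signal_log_sd))
    )
    if rng.random() < config.motif_missing_fraction or tad_center is None:
        strand, mq = None, None
    else:
        inward = rng.random() < config.motif_inward_fraction
        if mid < tad_center:
            strand = "+" if inward else "-"
        elif mid > tad_center:
            strand = "-" if inward else "+"
        else:
            strand = "+" if rng.random() < 0.5 else "-"
        mq = float(rng.uniform(1e-6, 0.05))
    return PeakRecord(iv, fe, q, signal, strand, mq)


def _simulate_ctcf(
    config: SyntheticConfig,
    tad_map: TadMap,
    gene_tss: dict[str, int],
    gene_slot: dict[str, tuple[str, int, str]],
    categories: GeneCategorySet,
) -> tuple[list[PeakRecord], dict[str, bool]]:
    rng = _rng(config, 2)
    tads = tad_map.all_tads()
    peaks: list[PeakRecord] = []
    neg_designed: dict[str, bool] = {}

    designed_positions: dict[str, list[int]] = {}
    for gid, (chrom, bpos, side) in gene_slot.items():
        designed_positions.setdefault(chrom, []).append(bpos)
    for chrom in designed_positions:
        designed_positions[chrom].sort()

    def category_of(gid: str) -> str:
        if gid in categories.developmental:
            return "developmental"
        if gid in categories.housekeeping:
            return "housekeeping"
        return "other"

    # designed asymmetric layout per bin-1 gene
    for gid, (chrom, bpos, side) in sorted(gene_slot.items()):
        tss = gene_tss[gid]
        cat = category_of(gid)
        toward_boundary = bool(rng.random() < config.boundary_side_bias.get(cat, 0.5))
        neg_designed[gid] = toward_boundary
        n_minor = int(rng.poisson(0.8))
        n_major = n_minor + 1 + int(rng.poisson(0.7))
        bdry_dir = -1 if side == "start" else +1  # genomic direction of the boundary
        major_dir = bdry_dir if toward_boundary else -bdry_dir
        tad = tad_map.find_tad(chrom, tss)
        center = tad.midpoint if tad is not None else None
        for n_peaks, direction in ((n_major, major_dir), (n_minor, -major_dir)):
            for _ in range(n_peaks):
                off = int(rng.integers(_PEAK_MIN_OFFSET, _PEAK_MAX_OFFSET + 1))
                mid = tss + direction * off
                peaks.append(_make_ctcf_peak(rng, chrom, mid, center, config))

    # generic boundary clusters, only far from every designed layout
    boundary_positions: dict[str, set[int]] = {}
    for tad in tads:
        boundary_positions.setdefault(tad.chrom, set()).update((tad.start, tad.end))
    for chrom in sorted(boundary_positions):
        designed = designed_positions.get(chrom, [])
        for bpos in sorted(boundary_positions[chrom]):
            k = bisect.bisect_left(designed, bpos)
            near = (k > 0 and bpos - designed[k - 1] < _SLOT_SPACING) or (
                k < len(designed) and designed[k] - bpos < _SLOT_SPACING
            )
            if near:
                continue
            n = int(rng.poisson(config.ctcf_peaks_per_boundary))
            tad = tad_map.find_tad(chrom, bpos)
            center = tad.midpoint if tad is not None else None
            for _ in range(n):
                off = int(np.clip(rng.normal(0, 20_000), -48_000, 48_000))
                mid = int(np.clip(bpos + off, 500, tad_map.genome[chrom] - 500))
                peaks.append(_make_ctcf_peak(rng, chrom, mid, center, config))

    # sub-threshold decoys, removed by the standard fold-change/q filter
    for chrom, length in tad_map.genome.items():
        for _ in range(length // 4_000_000):
            mid = int(rng.integers(500, length - 500))
            tad = tad_map.find_tad(chrom, mid)
            center = tad.midpoint if tad is not None else None
            peaks.append(_make_ctcf_peak(rng, chrom, mid, center, config, passing=False))

    return peaks, neg_designed


# ---------------------------------------------------------------------------
# H3K27me3 domains
# ---------------------------------------------------------------------------


def _simulate_h3k27me3(
    config: SyntheticConfig,
    tad_map: TadMap,
    gene_tss: dict[str, int],
    transcripts: Sequence[TranscriptRecord],
    categories: GeneCategorySet,
) -> list[PeakRecord]:
    rng = _rng(config, 3)
    chrom_of = {t.gene_id: t.interval.chrom for t in transcripts}
    peaks: list[PeakRecord] = []
    *narrow_modes, broad_mode = config.peak_size_modes
    broad_mean, broad_sd, broad_w = broad_mode

    def add_peak(chrom: str, center: int, size: float, passing: bool = True) -> None:
        size = max(400, int(size))
        start = max(0, center - size // 2)
        end = min(tad_map.genome[chrom], start + size)
        if passing:
            fe = float(rng.uniform(3.5, 15.0))
            q = float(rng.uniform(1e-4, 0.09))
        else:
            fe = float(rng.uniform(0.5, 2.9))
            q = float(rng.uniform(0.12, 0.9))
        peaks.append(PeakRecord(GenomicInterval(chrom, start, end), fe, q, fe))

    dev = sorted(categories.developmental)
    for gid in dev:
        add_peak(chrom_of[gid], gene_tss[gid], rng.normal(broad_mean, broad_sd))

    n_narrow_total = int(round(len(dev) * (1.0 - broad_w) / broad_w))
    nondev = sorted(set(gene_tss) - categories.developmental)
    rng.shuffle(nondev)
    narrow_weights = np.array([w for _, _, w in narrow_modes], dtype=float)
    narrow_weights /= narrow_weights.sum()
    tss_sorted: dict[str, list[int]] = {}
    for gid, tss in gene_tss.items():
        tss_sorted.setdefault(chrom_of[gid], []).append(tss)
    for c in tss_sorted:
        tss_sorted[c].sort()

    def far_from_tss(chrom: str, pos: int, margin: int = 20_000) -> bool:
        arr = tss_sorted.get(chrom, [])
        k = bisect.bisect_left(arr, pos)
        if k > 0 and pos - arr[k - 1] < margin:
            return False
        if k < len(arr) and arr[k] - pos < margin:
            return False
        return True

    chroms = sorted(tad_map.genome)
    for j in range(n_narrow_total):
        mode = narrow_modes[int(rng.choice(len(narrow_modes), p=narrow_weights))]
        size = rng.normal(mode[0], mode[1])
        if j < len(nondev):
            gid = nondev[j]
            add_peak(chrom_of[gid], gene_tss[gid], size)
        else:
            for _ in range(50):
                chrom = chroms[int(rng.integers(len(chroms)))]
                pos = int(rng.integers(30_000, tad_map.genome[chrom] - 30_000))
                if far_from_tss(chrom, pos):
                    add_peak(chrom, pos, size)
                    break

    # a few filter-failing calls to exercise the enrichment/q gate
    for _ in range(20):
        chrom = chroms[int(rng.integers(len(chroms)))]
        pos = int(rng.integers(30_000, tad_map.genome[chrom] - 30_000))
        add_peak(chrom, pos, rng.normal(2000.0, 300.0), passing=False)
    return peaks


# ---------------------------------------------------------------------------
# boundary tracks and nascent transcription
# ---------------------------------------------------------------------------


def _disjoint(
    pieces: list[tuple[int, int, float]], combine
) -> list[tuple[int, int, float]]:
    """Merge overlapping (start, end, value) pieces with ``combine`` on values."""
    pieces = sorted(pieces)
    out: list[tuple[int, int, float]] = []
    for s, e, v in pieces:
        if out and s < out[-1][1]:
            ps, pe, pv = out[-1]
            out[-1] = (ps, max(pe, e), combine(pv, v))
        else:
            out.append((s, e, v))
    return out


def _simulate_boundary_tracks(
    config: SyntheticConfig, tad_map: TadMap
) -> tuple[SignalTrack, SignalTrack, dict, dict]:
    rng = _rng(config, 4)
    insul_segments: list[tuple[GenomicInterval, float]] = []
    strength_segments: list[tuple[GenomicInterval, float]] = []
    truth_insul: dict[tuple[str, int], float] = {}
    truth_strength: dict[tuple[str, int], float] = {}
    for chrom in sorted(tad_map.genome):
        length = tad_map.genome[chrom]
        boundaries = sorted(
            {b for t in tad_map.tads.get(chrom, []) for b in (t.start, t.end)}
        )
        dips = []
        bumps = []
        for b in boundaries:
            v = float(rng.normal(config.insulation_dip_mean, config.insulation_dip_sd))
            s = float(np.exp(rng.normal(config.strength_log_mean, config.strength_log_sd)))
            truth_insul[(chrom, b)] = v
            truth_strength[(chrom, b)] = s
            dips.append((max(0, b - 20_000), min(length, b + 20_000), v))
            bumps.append((max(0, b - 5_000), min(length, b + 5_000), s))
        dips = _disjoint(dips, min)
        bumps = _disjoint(bumps, max)
        pos = 0
        for s, e, v in dips:
            if pos < s:
                insul_segments.append(
                    (
                        GenomicInterval(chrom, pos, s),
                        float(rng.normal(config.insulation_baseline, 0.05)),
                    )
                )
            insul_segments.append((GenomicInterval(chrom, s, e), v))
            pos = e
        if pos < length:
            insul_segments.append(
                (
                    GenomicInterval(chrom, pos, length),
                    float(rng.normal(config.insulation_baseline, 0.05)),
                )
            )
        for s, e, v in bumps:
            strength_segments.append((GenomicInterval(chrom, s, e), v))
    return (
        SignalTrack(insul_segments),
        SignalTrack(strength_segments),
        truth_insul,
        truth_strength,
    )


def _simulate_expression_and_proseq(
    config: SyntheticConfig,
    transcripts: Sequence[TranscriptRecord],
    categories: GeneCategorySet,
) -> tuple[dict[str, float], SignalTrack, SignalTrack, set[str]]:
    rng = _rng(config, 5)

    def category_of(gid: str) -> str:
        if gid in categories.developmental:
            return "developmental"
        if gid in categories.housekeeping:
            return "housekeeping"
        return "other"

    expression: dict[str, float] = {}
    active: set[str] = set()
    for gid in sorted(categories.all_genes):
        if rng.random() < config.active_fraction.get(category_of(gid), 0.5):
            expression[gid] = 5.0 + float(np.exp(rng.normal(math.log(20.0), 0.8)))
            active.add(gid)
        else:
            expression[gid] = float(rng.uniform(0.0, 0.5))

    plus: list[tuple[GenomicInterval, float]] = []
    minus: list[tuple[GenomicInterval, float]] = []
    primary_seen: set[str] = set()
    for t in transcripts:
        if t.gene_id not in active or t.gene_id in primary_seen:
            continue
        primary_seen.add(t.gene_id)
        pi = config.pausing.get(category_of(t.gene_id), 3.0)
        body_value = expression[t.gene_id] / 10.0
        promoter, body = promoter_body_windows(t)
        sign = 1.0 if t.strand == "+" else -1.0
        target = plus if t.strand == "+" else minus
        target.append((promoter, sign * pi * body_value))
        target.append((body, sign * body_value))
    return expression, SignalTrack(plus), SignalTrack(minus), active


# ---------------------------------------------------------------------------
# top-level generators
# ---------------------------------------------------------------------------


def simulate_genome(config: SyntheticConfig) -> SyntheticBundle:
    """Generate the full synthetic bundle for one config + seed."""
    tad_map = _simulate_tads(config)
    group_rng = _rng(config, 6)
    tad_group = _assign_tad_groups(tad_map, group_rng)
    transcripts, categories, gene_tss, bin1_genes, gene_slot = _place_genes(
        config, tad_map, tad_group
    )
    ctcf_peaks, neg_designed = _simulate_ctcf(
        config, tad_map, gene_tss, gene_slot, categories
    )
    h3k_peaks = _simulate_h3k27me3(config, tad_map, gene_tss, transcripts, categories)
    insul, strength, truth_insul, truth_strength = _simulate_boundary_tracks(
        config, tad_map
    )
    expression, proseq_plus, proseq_minus, active = _simulate_expression_and_proseq(
        config, transcripts, categories
    )
    category_of = {}
    for gid in categories.all_genes:
        if gid in categories.developmental:
            category_of[gid] = "developmental"
        elif gid in categories.housekeeping:
            category_of[gid] = "housekeeping"
        else:
            category_of[gid] = "other"
    truth = SyntheticTruth(
        tad_group=tad_group,
        category_of=category_of,
        bin1_genes=bin1_genes,
        gene_tss=gene_tss,
        gene_slot=gene_slot,
        neg_delta_designed=neg_designed,
        active_genes=active,
        designed_pausing=dict(config.pausing),
        boundary_insulation=truth_insul,
        boundary_strength=truth_strength,
        ld_dev_odds=config.ld_dev_odds,
        bin1_bias=dict(config.bin1_bias),
        boundary_side_bias=dict(config.boundary_side_bias),
    )
    return SyntheticBundle(
        tad_map=tad_map,
        transcripts=transcripts,
        categories=categories,
        h3k27me3_peaks=h3k_peaks,
        ctcf_peaks=ctcf_peaks,
        insulation_track=insul,
        strength_track=strength,
        proseq_plus=proseq_plus,
        proseq_minus=proseq_minus,
        expression=expression,
        truth=truth,
    )


def simulate_ct_table(config: SyntheticConfig):
    """Simulated RT-qPCR Ct table (line x biological replicate x gene).

    Target-gene Ct is ``baseline - designed_log2fc`` plus Gaussian noise;
    reference genes are flat across lines, so the downstream relative
    quantification recovers the designed fold-changes (exactly at sd = 0).
    """
    import pandas as pd

    rng = _rng(config, 10)
    sd = config.ddct_noise_sd
    target_genes = sorted({g for d in config.ddct_log2fc.values() for g in d})
    rows = []
    for line in config.ddct_replicates:
        design = config.ddct_log2fc.get(line, {})
        for rep in range(1, config.ddct_replicates[line] + 1):
            for ref, base in config.ddct_reference_ct.items():
                rows.append(
                    {
                        "line": line,
                        "replicate": rep,
                        "gene": ref,
                        "ct": base + float(rng.normal(0, sd)) if sd > 0 else base,
                    }
                )
            for gene in target_genes:
                ct = config.ddct_target_ct - design.get(gene, 0.0)
                if sd > 0:
                    ct += float(rng.normal(0, sd))
                rows.append({"line": line, "replicate": rep, "gene": gene, "ct": ct})
    return pd.DataFrame(rows)


def simulate_capture_profiles(
    config: SyntheticConfig,
    viewpoint: int | None = None,
    genotypes: Sequence[str] | None = None,
) -> dict[str, list[CaptureProfile]]:
    """Per-genotype replicate viewpoint interaction pileups on a fragment grid.

    Expected signal decays with distance from the viewpoint as
    ``(d + d0)^-decay`` and is multiplied by the genotype's attenuation for
    fragments on the far side of the boundary.  All genotypes share one
    normalization constant (chosen so the wild-type expected locus total is
    1e6), so designed cross-boundary ratios are preserved exactly;
    per-fragment noise is multiplicative log-normal with unit mean.
    """
    rng = _rng(config, 11)
    chrom, lo, hi = config.capture_locus
    vp = config.capture_viewpoint if viewpoint is None else viewpoint
    if not (lo <= vp < hi):
        raise ValueError("viewpoint outside the capture locus")
    if genotypes is None:
        genotypes = list(config.capture_attenuation)
    frag = config.capture_fragment_size
    starts = np.arange(lo, hi - frag + 1, frag, dtype=np.int64)
    ends = starts + frag
    mids = starts + frag // 2
    dist = np.abs(mids - vp).astype(float)
    base = (dist + config.capture_d0) ** (-config.capture_decay)
    cross = (mids >= config.capture_boundary) != (vp >= config.capture_boundary)
    wt_att = config.capture_attenuation.get("WT", 1.0)
    wt_expected = base * np.where(cross, wt_att, 1.0)
    scale = 1e6 / wt_expected.sum()
    sd = config.capture_noise_sd
    out: dict[str, list[CaptureProfile]] = {}
    for geno in genotypes:
        att = config.capture_attenuation.get(geno, 1.0)
        expected = scale * base * np.where(cross, att, 1.0)
        reps = []
        for r in range(config.capture_replicates):
            if sd > 0:
                noise = np.exp(rng.normal(-0.5 * sd * sd, sd, size=expected.size))
                values = expected * noise
            else:
                values = expected.copy()
            reps.append(
                CaptureProfile(
                    chrom=chrom,
                    starts=starts.copy(),
                    ends=ends.copy(),
                    values=values,
                    viewpoint=vp,
                    genotype=geno,
                    replicate=r + 1,
                )
            )
        out[geno] = reps
    return out
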