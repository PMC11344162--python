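"""CTCF peak asymmetry around boundary-proximal (bin-1) genes.

For a bin-1 gene, the 100 kb half-window running from its TSS toward the
nearest TAD boundary is the *outer* window and the opposite half-window
(toward the TAD center) is the *inner* window.  The per-gene statistics

    delta_peaks  = n_inner - n_outer
    delta_signal = sum(signal_max, inner) - sum(signal_max, outer)

are negative when CTCF peaks (or their aggregated signal) pile up between
the gene and the boundary — the organization characteristic of
developmental genes.  Peak membership uses the peak midpoint so every peak
belongs to exactly one side; a midpoint exactly on the TSS base counts as
inner.  Peak orientation (+1 inward toward the TAD center, -1 outward) is
taken from the best (lowest-q) CTCF motif of the peak and compared
between windows with a chi-squared test and Cramér's V.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import stats

from .core import GenomicInterval, PeakRecord, TadMap, TranscriptRecord
from .boundaries import GroupComparison, compare_groups

logger = logging.getLogger("tadbound")

__all__ = [
    "AsymmetryRecord",
    "OrientationRecord",
    "AsymmetryWindows",
    "asymmetry_windows",
    "delta_ctcf",
    "delta_ctcf_all",
    "peak_orientation",
    "orientation_contingency",
    "compare_delta_distributions",
]

HALF_WINDOW = 100_000


@dataclass(frozen=True)
class AsymmetryWindows:
    nearest_side: Literal["start", "end"]
    boundary_position: int
    inner: GenomicInterval | None  # None only when fully clipped away
    outer: GenomicInterval | None


@dataclass(frozen=True)
class AsymmetryRecord:
    gene_id: str
    chrom: str
    tss: int
    nearest_side: Literal["start", "end"]
    boundary_position: int
    n_inner: int
    n_outer: int
    signal_inner: float
    signal_outer: float

    @property
    def delta_peaks(self) -> int:
        return self.n_inner - self.n_outer

    @property
    def delta_signal(self) -> float:
        return self.signal_inner - self.signal_outer


@dataclass(frozen=True)
class OrientationRecord:
    window_side: Literal["inner", "outer"]
    orientation: int | None  # +1 inward, -1 outward, None when no motif
    flagged: bool = False


def asymmetry_windows(
    tss: int, tad: GenomicInterval, chrom_length: int
) -> AsymmetryWindows:
    """Inner/outer 100 kb half-windows around a bin-1 TSS.

    The nearest boundary is the TAD start when the TSS sits in the left
    half of the TAD, the TAD end otherwise (exact midline resolves to the
    end).  Windows are fixed 100 kb, clipped only at chromosome ends
    (logged); they are deliberately not truncated at the TAD boundary or
    center.  Raises for TSSs outside the bin-1 decile pair.
    """
    if not tad.contains(tss):
        raise ValueError("TSS outside the TAD")
    from .geometry import _bin_of

    if _bin_of(tss, tad.start, tad.end)[0] != 1:
        raise ValueError("asymmetry windows are defined for bin-1 genes only")
    f = (tss - tad.start) / tad.width

    def clip(lo: int, hi: int) -> GenomicInterval | None:
        lo2, hi2 = max(0, lo), min(chrom_length, hi)
        if (lo2, hi2) != (lo, hi):
            logger.warning(
                "asymmetry window [%d, %d) on %s clipped at chromosome end",
                lo,
                hi,
                tad.chrom,
            )
        if lo2 >= hi2:
            return None
        return GenomicInterval(tad.chrom, lo2, hi2)

    if f < 0.5:
        side: Literal["start", "end"] = "start"
        boundary = tad.start
        outer = clip(tss - HALF_WINDOW, tss)
        inner = clip(tss, tss + HALF_WINDOW)
    else:
        side = "end"
        boundary = tad.end
        outer = clip(tss, tss + HALF_WINDOW)
        inner = clip(tss - HALF_WINDOW, tss)
    return AsymmetryWindows(side, boundary, inner, outer)


class _MidpointIndex:
    """Sorted per-chromosome peak midpoints with prefix signal sums."""

    def __init__(self, peaks: Sequence[PeakRecord]):
        by_chrom: dict[str, list[PeakRecord]] = {}
        for p in peaks:
            by_chrom.setdefault(p.interval.chrom, []).append(p)
        self._data: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, plist in by_chrom.items():
            mids = np.array([p.midpoint for p in plist], dtype=np.int64)
            sig = np.array([p.signal_max for p in plist])
            order = np.argsort(mids, kind="stable")
            mids, sig = mids[order], sig[order]
            self._data[chrom] = (mids, np.concatenate([[0.0], np.cumsum(sig)]))

    def count_sum(self, chrom: str, lo: int, hi: int) -> tuple[int, float]:
        """Peaks with midpoint in [lo, hi): count and signal sum."""
        if chrom not in self._data or lo >= hi:
            return 0, 0.0
        mids, csum = self._data[chrom]
        i = int(np.searchsorted(mids, lo, side="left"))
        j = int(np.searchsorted(mids, hi, side="left"))
        return j - i, float(csum[j] - csum[i])


def delta_ctcf(
    gene_id: str,
    tss: int,
    tad: GenomicInterval,
    peaks: Sequence[PeakRecord] | _MidpointIndex,
    chrom_length: int,
) -> AsymmetryRecord:
    """Per-gene CTCF peak-count and signal asymmetry (midpoint membership).

    Peaks are expected pre-filtered (fold change > 4, q < 0.01).  A peak
    midpoint exactly on the TSS base is assigned to the inner window.
    """
    win = asymmetry_windows(tss, tad, chrom_length)
    index = peaks if isinstance(peaks, _MidpointIndex) else _MidpointIndex(peaks)

    def span(iv: GenomicInterval | None) -> tuple[int, float]:
        if iv is None:
            return 0, 0.0
        return index.count_sum(tad.chrom, iv.start, iv.end)

    n_inner, s_inner = span(win.inner)
    n_outer, s_outer = span(win.outer)
    # midpoint exactly at the TSS base counts as inner; when the inner
    # half-window lies left of the TSS, [tss, tss+100k) is the outer window
    # and would otherwise claim it
    if win.inner is not None and win.outer is not None and win.outer.start == tss:
        n_tss, s_tss = index.count_sum(tad.chrom, tss, tss + 1)
        n_outer -= n_tss
        s_outer -= s_tss
        n_inner += n_tss
        s_inner += s_tss
    return AsymmetryRecord(
        gene_id=gene_id,
        chrom=tad.chrom,
        tss=tss,
        nearest_side=win.nearest_side,
        boundary_position=win.boundary_position,
        n_inner=n_inner,
        n_outer=n_outer,
        signal_inner=s_inner,
        signal_outer=s_outer,
    )


def delta_ctcf_all(
    tad_map: TadMap,
    transcripts: Sequence[TranscriptRecord],
    peaks: Sequence[PeakRecord],
    genes: set[str] | None = None,
) -> list[AsymmetryRecord]:
    """Asymmetry records for every bin-1 gene (representative transcript)."""
    from .geometry import assign_bins, gene_level_assignments

    index = _MidpointIndex(peaks)
    assignments = assign_bins(tad_map, transcripts)
    rep = gene_level_assignments(assignments)
    tss_of = {t.transcript_id: t.tss for t in transcripts}
    tads = tad_map.all_tads()
    out = []
    for gene, asn in sorted(rep.items()):
        if asn.bin != 1 or (genes is not None and gene not in genes):
            continue
        tad = tads[asn.tad_index]
        out.append(
            delta_ctcf(
                gene, tss_of[asn.transcript_id], tad, index, tad_map.genome[tad.chrom]
            )
        )
    return out


def peak_orientation(
    peak: PeakRecord,
    tad_center: int,
    window_side: Literal["inner", "outer"] = "inner",
    candidate_motifs: Sequence[tuple[str, float]] | None = None,
) -> OrientationRecord:
    """Orientation of a CTCF peak relative to the TAD center.

    The motif of lowest q wins among candidates (default: the peak's own
    motif call).  A plus-strand motif points toward increasing coordinates,
    so a peak left of the center with a plus motif is inward (+1).  Peaks
    whose midpoint coincides with the center get no orientation (flagged).
    """
    if candidate_motifs:
        strand, _ = min(candidate_motifs, key=lambda sq: sq[1])
    else:
        strand = peak.motif_strand
    if strand is None:
        return OrientationRecord(window_side, None)
    mid = peak.midpoint
    if mid == tad_center:
        return OrientationRecord(window_side, None, flagged=True)
    toward_center = (mid < tad_center) == (strand == "+")
    return OrientationRecord(window_side, +1 if toward_center else -1)


def orientation_contingency(
    records: Sequence[OrientationRecord],
) -> tuple[np.ndarray, float, float]:
    """2x2 (inner/outer x inward/outward) chi-squared test and Cramér's V.

    Records without an orientation are excluded.  Returns (table, p, V);
    the chi-squared statistic is Pearson's without continuity correction
    and V = sqrt(chi2 / (n * (min(r, c) - 1))).  Zero margins raise.
    """
    table = np.zeros((2, 2), dtype=int)
    for rec in records:
        if rec.orientation is None:
            continue
        i = 0 if rec.window_side == "inner" else 1
        j = 0 if rec.orientation == +1 else 1
        table[i, j] += 1
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError(f"contingency table has a zero margin:\n{table}")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    n = table.sum()
    v = float(np.sqrt(chi2 / (n * (min(table.shape) - 1))))
    return table, float(p), v


@dataclass
class DeltaComparison:
    comparisons: list[GroupComparison]
    negative_fraction: dict[str, float]
    cdfs: dict[str, np.ndarray]  # sorted values per category


def compare_delta_distributions(
    deltas: Mapping[str, Sequence[float]],
) -> DeltaComparison:
    """Pairwise rank-sum tests (one FDR family) on per-category delta values.

    Also reports the per-category fraction of genes with a strictly
    negative delta (peaks skewed toward the boundary) and the sorted value
    arrays for cumulative-distribution plots.  With a single category only
    the CDF and fraction are produced.
    """
    cdfs = {k: np.sort(np.asarray(v, dtype=float)) for k, v in deltas.items()}
    neg = {k: float(np.mean(v < 0)) if v.size else float("nan") for k, v in cdfs.items()}
    comps: list[GroupComparison] = []
    if len(cdfs) > 1:
        comps = compare_groups({"delta": {k: v for k, v in cdfs.items()}})
    return DeltaComparison(comparisons=comps, negative_fraction=neg, cdfs=cdfs)
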