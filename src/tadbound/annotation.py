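"""Developmental-gene annotation from broad H3K27me3/Polycomb domains.

Broad Polycomb (H3K27me3) domains over gene promoters mark a class of
developmental regulator genes.  The classifier reproduces the standard
pipeline: filter peak calls on enrichment and significance, merge nearby
peaks into domains, attach each domain to the genes whose TSS it covers,
estimate a size threshold from the bimodal domain-size distribution, and
call every gene under an above-threshold domain developmental.

The size threshold is estimated from the domain-size distribution itself.
The default estimator ("otsu") splits the sizes at the point minimizing
intra-class variance, which places the cut between the narrow and broad
modes of a bimodal distribution — the regime in which the broad-domain
definition is meaningful.  A chord-distance elbow estimator ("chord",
maximum distance to the chord of the descending sorted-size curve) is
available for curves with a single sharp elbow rather than two modes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .core import GenomicInterval, PeakRecord, TranscriptRecord

__all__ = [
    "BroadDomainCall",
    "KneeEstimate",
    "filter_broad_peaks",
    "merge_within_gap",
    "assign_domains_to_genes",
    "knee_threshold",
    "call_developmental_genes",
]


@dataclass(frozen=True)
class BroadDomainCall:
    """A merged peak domain and the genes whose TSS it overlaps."""

    merged_interval: GenomicInterval
    gene_ids: frozenset[str]

    @property
    def size(self) -> int:
        return self.merged_interval.width


@dataclass(frozen=True)
class KneeEstimate:
    """A domain-size threshold with the estimator that produced it."""

    threshold: float
    method: str
    curve: tuple[float, ...]  # sizes, sorted ascending


def filter_broad_peaks(
    peaks: Sequence[PeakRecord], fe_min: float = 3.0, q_max: float = 0.1
) -> list[PeakRecord]:
    """Keep peaks with fold_enrichment strictly > fe_min and q strictly < q_max."""
    return [p for p in peaks if p.fold_enrichment > fe_min and p.q_value < q_max]


def merge_within_gap(
    peaks: Sequence[PeakRecord | GenomicInterval], max_gap: int = 1000
) -> list[GenomicInterval]:
    """Merge intervals whose inter-peak gap is <= max_gap (transitively).

    The gap between two intervals is ``next.start - prev.end`` (0 for
    touching or overlapping intervals).  Output is sorted and
    non-overlapping; chromosomes are handled independently.
    """
    ivs = [p.interval if isinstance(p, PeakRecord) else p for p in peaks]
    ivs.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if (
            merged
            and iv.chrom == merged[-1].chrom
            and iv.start - merged[-1].end <= max_gap
        ):
            if iv.end > merged[-1].end:
                merged[-1] = GenomicInterval(iv.chrom, merged[-1].start, iv.end)
        else:
            merged.append(iv)
    return merged


def assign_domains_to_genes(
    domains: Sequence[GenomicInterval], transcripts: Sequence[TranscriptRecord]
) -> list[BroadDomainCall]:
    """Attach to each domain every gene whose TSS base lies inside it."""
    calls = []
    for dom in domains:
        genes = frozenset(
            t.gene_id
            for t in transcripts
            if t.interval.chrom == dom.chrom and dom.contains(t.tss)
        )
        calls.append(BroadDomainCall(merged_interval=dom, gene_ids=genes))
    return calls


def _otsu_threshold(sizes: np.ndarray) -> float:
    y = np.sort(sizes)
    n = y.size
    csum = np.cumsum(y)
    total = csum[-1]
    k = np.arange(1, n, dtype=float)
    mu_lo = csum[:-1] / k
    mu_hi = (total - csum[:-1]) / (n - k)
    w = k / n
    between = w * (1.0 - w) * (mu_lo - mu_hi) ** 2
    i = int(np.argmax(between))
    return 0.5 * (y[i] + y[i + 1])


def _chord_threshold(sizes: np.ndarray) -> float:
    y = np.sort(sizes)[::-1]
    n = y.size
    x = np.arange(n)
    chord = y[0] + (y[-1] - y[0]) * x / (n - 1)
    # argmax of the perpendicular distance to the chord equals argmax of the
    # vertical gap (fixed chord), so no axis normalization is needed
    return float(y[int(np.argmax(chord - y))])


def knee_threshold(
    sizes: Sequence[float], method: Literal["otsu", "chord"] = "otsu"
) -> KneeEstimate:
    """Estimate the domain-size threshold separating broad from narrow domains.

    ``otsu`` (default): minimum intra-class-variance split of the size
    distribution, returning the midpoint between the two classes; suited to
    bimodal size distributions.  ``chord``: maximum distance to the chord of
    the descending sorted-size curve (elbow of an L-shaped curve).

    Requires at least 10 sizes that are not all equal.
    """
    arr = np.asarray(list(sizes), dtype=float)
    if arr.size < 10:
        raise ValueError(f"need >= 10 sizes to estimate a knee, got {arr.size}")
    if np.all(arr == arr[0]):
        raise ValueError("all sizes equal; no knee exists")
    if method == "otsu":
        thr = _otsu_threshold(arr)
    elif method == "chord":
        thr = _chord_threshold(arr)
    else:
        raise ValueError(f"unknown knee method {method!r}")
    return KneeEstimate(threshold=float(thr), method=method, curve=tuple(np.sort(arr)))


def call_developmental_genes(
    peaks: Sequence[PeakRecord],
    transcripts: Sequence[TranscriptRecord],
    fe_min: float = 3.0,
    q_max: float = 0.1,
    max_gap: int = 1000,
    threshold: float | None = None,
    knee_method: Literal["otsu", "chord"] = "otsu",
) -> tuple[set[str], KneeEstimate | None, list[BroadDomainCall]]:
    """Full classification chain: filter, merge, assign, threshold, call.

    Returns the developmental gene-id set, the knee estimate (None when a
    fixed ``threshold`` was supplied), and the per-domain calls.  A gene is
    developmental iff it is attached to a merged domain whose size is
    strictly greater than the threshold.
    """
    kept = filter_broad_peaks(peaks, fe_min=fe_min, q_max=q_max)
    domains = merge_within_gap(kept, max_gap=max_gap)
    calls = assign_domains_to_genes(domains, transcripts)
    estimate: KneeEstimate | None = None
    if threshold is None:
        estimate = knee_threshold([c.size for c in calls], method=knee_method)
        threshold = estimate.threshold
    dev: set[str] = set()
    for call in calls:
        if call.size > threshold:
            dev |= call.gene_ids
    return dev, estimate, calls
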